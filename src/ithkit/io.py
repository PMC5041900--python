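"""Plain-text readers/writers for the pipeline's on-disk formats.

Conventions: all in-memory coordinates are 1-based inclusive; BED files are
half-open 0-based on disk and converted at this boundary.  Variants travel as
multi-sample VCF 4.2 with per-sample GT:GQ:AD and the annotation fields
(consequence, SIFT/PolyPhen labels, gene, flanking context) in INFO; reading
uses cyvcf2.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .design import SampleMeta
from .simulate import BAFRecord
from .variants import VariantCall


# ----------------------------------------------------------------------
# TSV matrices and metadata
# ----------------------------------------------------------------------
def write_counts_tsv(counts: pd.DataFrame, path: Path | str) -> None:
    counts.to_csv(path, sep="\t", index_label="core_id")


def read_counts_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="core_id")


def write_coverage_tsv(coverage: pd.DataFrame, targets: pd.DataFrame, path: Path | str) -> None:
    out = targets.join(coverage)
    out.to_csv(path, sep="\t", index_label="target_id")


def read_coverage_tsv(path: Path | str) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="target_id")
    ann_cols = ["gene", "chrom", "start", "end"]
    return df.drop(columns=ann_cols), df[ann_cols]


def write_meta_tsv(meta: list[SampleMeta], path: Path | str) -> None:
    pd.DataFrame([m.__dict__ for m in meta]).to_csv(path, sep="\t", index=False)


def read_meta_tsv(path: Path | str) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        resp = r.get("response")
        out.append(
            SampleMeta(
                sample_id=r["sample_id"],
                patient_id=r["patient_id"],
                role=r["role"],
                timepoint=r["timepoint"],
                cohort=r.get("cohort", "sunitinib"),
                response=None if pd.isna(resp) else resp,
            )
        )
    return out


# ----------------------------------------------------------------------
# cores BED (half-open 0-based on disk)
# ----------------------------------------------------------------------
def write_cores_bed(cores: pd.DataFrame, path: Path | str) -> None:
    with open(path, "w") as fh:
        for core_id, r in cores.iterrows():
            gene = r["gene"] if r["gene"] is not None and not pd.isna(r["gene"]) else "."
            fh.write(
                f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{core_id}\t"
                f"{1 if r['promoter'] else 0}\t{gene}\n"
            )


def read_cores_bed(path: Path | str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start0, end, core_id, prom, gene = line.rstrip("\n").split("\t")[:6]
            rows.append(
                (core_id, chrom, int(start0) + 1, int(end), prom == "1",
                 None if gene == "." else gene)
            )
    return pd.DataFrame(
        rows, columns=["core_id", "chrom", "start", "end", "promoter", "gene"]
    ).set_index("core_id")


# ----------------------------------------------------------------------
# BAF TSV
# ----------------------------------------------------------------------
def write_baf_tsv(records: list[BAFRecord], path: Path | str) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.chrom, r.pos, r.ref_count, r.alt_count, r.n_alleles)
            for r in records
        ],
        columns=["sample_id", "chrom", "pos", "ref_count", "alt_count", "n_alleles"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_baf_tsv(path: Path | str) -> list[BAFRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        BAFRecord(r.sample_id, r.chrom, int(r.pos), int(r.ref_count), int(r.alt_count),
                  int(r.n_alleles))
        for r in df.itertuples(index=False)
    ]


# ----------------------------------------------------------------------
# VCF 4.2
# ----------------------------------------------------------------------
_VCF_INFO_FIELDS = (
    ('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">'),
    ('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term">'),
    ('##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT label">'),
    ('##INFO=<ID=PPH,Number=1,Type=String,Description="PolyPhen-2 label">'),
    ('##INFO=<ID=FLANK,Number=1,Type=String,Description="Reference context around POS">'),
    ('##INFO=<ID=FOFF,Number=1,Type=Integer,Description="0-based offset of POS in FLANK">'),
)


def write_vcf(
    calls: list[VariantCall],
    meta: list[SampleMeta],
    path: Path | str,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write one multi-sample VCF 4.2; absent genotypes are emitted as 0/0.

    Per-variant annotations (identical across carriers by construction) go to
    INFO; GT/GQ/AD are per-sample FORMAT fields.
    """
    samples = [m.sample_id for m in meta]
    sample_pos = {s: i for i, s in enumerate(samples)}
    by_key: dict[tuple, list[VariantCall]] = {}
    for c in calls:
        by_key.setdefault(c.key, []).append(c)

    keys = sorted(by_key, key=lambda k: (k[0], k[1], k[2], k[3]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for chrom, length in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for line in _VCF_INFO_FIELDS:
            fh.write(line + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "\t".join(["FORMAT"] + samples) + "\n")
        for key in keys:
            chrom, pos, ref, alt = key
            carriers = by_key[key]
            first = carriers[0]
            info = []
            if first.gene:
                info.append(f"GENE={first.gene}")
            if first.consequence:
                info.append(f"CSQ={first.consequence}")
            if first.sift:
                info.append(f"SIFT={first.sift}")
            if first.polyphen:
                info.append(f"PPH={first.polyphen}")
            if first.flank_seq is not None:
                info.append(f"FLANK={first.flank_seq}")
                info.append(f"FOFF={first.flank_offset}")
            cells = ["0/0:99:500,0"] * len(samples)
            for c in carriers:
                gt = "/".join(str(a) for a in c.genotype)
                ad = ",".join(str(d) for d in c.allele_depths)
                cells[sample_pos[c.sample_id]] = f"{gt}:{int(round(c.gq))}:{ad}"
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                + (";".join(info) if info else ".")
                + "\tGT:GQ:AD\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: Path | str, meta: list[SampleMeta]) -> list[VariantCall]:
    """Read carrier calls (non-reference genotypes) from a multi-sample VCF."""
    patient_of = {m.sample_id: m.patient_id for m in meta}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[VariantCall] = []
    for var in vcf:
        gene = var.INFO.get("GENE")
        csq = var.INFO.get("CSQ")
        sift = var.INFO.get("SIFT")
        pph = var.INFO.get("PPH")
        flank = var.INFO.get("FLANK")
        foff = var.INFO.get("FOFF")
        gqs = var.format("GQ")
        ads = var.format("AD")
        for si, sample in enumerate(samples):
            g = var.genotypes[si]
            alleles = tuple(int(a) for a in g[:-1])
            if not any(a > 0 for a in alleles):
                continue
            calls.append(
                VariantCall(
                    patient_id=patient_of[sample],
                    sample_id=sample,
                    chrom=var.CHROM,
                    pos=int(var.POS),
                    ref=var.REF,
                    alt=var.ALT[0],
                    genotype=alleles,
                    gq=float(np.ravel(gqs[si])[0]),
                    allele_depths=tuple(int(x) for x in np.ravel(ads[si])),
                    flank_seq=flank,
                    flank_offset=int(foff) if foff is not None else None,
                    consequence=csq,
                    sift=sift,
                    polyphen=pph,
                    gene=gene,
                )
            )
    vcf.close()
    return calls


# ----------------------------------------------------------------------
# segments BED + JSON
# ----------------------------------------------------------------------
def write_segments_bed(segments, path: Path | str, name_fn=None) -> None:
    """LOH/CNV segments as BED (score column carries the segment statistic)."""
    with open(path, "w") as fh:
        for seg in segments:
            name = name_fn(seg) if name_fn else getattr(seg, "gene", None) or "seg"
            stat = getattr(seg, "log2_ratio", None)
            if stat is None:
                stat = getattr(seg, "mean_dev", 0.0)
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{name}\t{stat:.4f}\n")


def write_json(obj, path: Path | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")
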