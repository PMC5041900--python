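"""Synthetic multi-region cohort generators with recoverable ground truth.

Every generator is a pure function of a :class:`~ithkit.design.CohortDesign`;
the design's seed fans out to fixed per-stage child streams so stages can be
re-simulated in isolation and remain bit-identical.

What is emulated
----------------
* methylation: negative-binomial fragment counts per methylation core with
  library-size variation (biopsies systematically shallower), per-patient
  log2-scale effects shared by all of a patient's samples, and an injected
  post-vs-pre log2 fold change on designated target promoter cores;
* variants: per-patient germline/truncal/shared/private sharing structure with
  genotype quality, allele depths, flanking sequence context and
  consequence/damaging annotations, plus a configurable fraction of calls that
  deliberately violate each quality filter;
* BAF: binomial allele counts at heterozygous SNPs, with the tumor allele
  fraction shifted inside injected LOH segments (never fully to 0 or 1);
* coverage: per-amplicon-target depths with gene-level copy-number events.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .design import (
    ROLE_BIOPSY,
    ROLE_NEPHRECTOMY,
    ROLE_NORMAL,
    BAFTruth,
    CNVTruth,
    CohortDesign,
    MethylationTruth,
    SampleMeta,
    SimTruth,
    VariantTruth,
)
from .variants import (
    CATEGORY_GERMLINE,
    CATEGORY_PRIVATE,
    CATEGORY_SHARED,
    CATEGORY_TRUNCAL,
    VariantCall,
)

_FLANK_HALF = 10  # 21-bp reference context window around each variant

# child-stream indices for the per-stage RNGs
_STREAM_METHYLATION = 0
_STREAM_VARIANTS = 1
_STREAM_BAF = 2
_STREAM_CNV = 3


def _rng(design: CohortDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(design.seed), stream])


# ----------------------------------------------------------------------
# genome layout
# ----------------------------------------------------------------------
def gene_intervals(design: CohortDesign) -> pd.DataFrame:
    """Deterministic layout of the target genes on the simulated genome.

    Genes are placed round-robin over the chromosomes at 2-Mb spacing with a
    100-kb footprint each; the promoter core sits at the gene start.
    """
    chroms = list(design.chromosomes)
    rows = []
    for g, gene in enumerate(design.target_gene_names()):
        chrom = chroms[g % len(chroms)]
        start = 2_000_000 + (g // len(chroms)) * 2_000_000
        end = start + 100_000
        if end > design.chromosomes[chrom]:
            raise ValueError("too many target genes for the simulated chromosome lengths")
        rows.append((gene, chrom, start, end))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")


def make_cores(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Methylation-core definitions: target promoter cores first, then background.

    Coordinates are 1-based inclusive.  Target cores are always
    promoter-annotated, so targets are a subset of the promoter cores.
    """
    genes = gene_intervals(design)
    if design.n_cores < len(genes):
        raise ValueError("n_cores must be >= n_target_genes")
    rows = []
    for i, (gene, row) in enumerate(genes.iterrows()):
        rows.append(
            (f"core_{i + 1:06d}", row["chrom"], int(row["start"]), int(row["start"]) + 152, True, gene)
        )
    chroms = list(design.chromosomes)
    n_bg = design.n_cores - len(genes)
    bg_chrom = rng.integers(0, len(chroms), size=n_bg)
    bg_len = rng.integers(150, 1000, size=n_bg)
    bg_prom = rng.random(n_bg) < design.promoter_fraction
    for k in range(n_bg):
        chrom = chroms[bg_chrom[k]]
        start = int(rng.integers(1, design.chromosomes[chrom] - int(bg_len[k])))
        rows.append(
            (f"core_{len(genes) + k + 1:06d}", chrom, start, start + int(bg_len[k]), bool(bg_prom[k]), None)
        )
    return pd.DataFrame(
        rows, columns=["core_id", "chrom", "start", "end", "promoter", "gene"]
    ).set_index("core_id")


def resolve_treatment_logfc(design: CohortDesign, cores: pd.DataFrame) -> dict[str, float]:
    """Map ``treatment_logfc`` keys (gene symbols or core ids) to core ids."""
    gene_to_core = {g: cid for cid, g in cores["gene"].items() if g is not None}
    out: dict[str, float] = {}
    for key, lfc in design.treatment_logfc.items():
        if key in gene_to_core:
            out[gene_to_core[key]] = float(lfc)
        elif key in cores.index:
            out[key] = float(lfc)
        else:
            raise ValueError(f"treatment_logfc key {key!r} is neither a target gene nor a core id")
    return out


# ----------------------------------------------------------------------
# methylation counts
# ----------------------------------------------------------------------
def simulate_methylation_counts(
    design: CohortDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, list[SampleMeta], MethylationTruth]:
    """Negative-binomial fragment counts for the cohort's tumor samples.

    Returns ``(counts, cores, meta, truth)`` where ``counts`` is cores x
    samples, ``meta`` covers the tumor samples in the count matrix, and the
    per-observation mean is

        mu = library_size * base_abundance * 2**(patient_effect + post * logFC)

    with gamma-Poisson (NB) sampling at the design's dispersion.
    """
    design.validate()
    if design.n_patients < 2:
        raise ValueError("methylation simulation needs at least 2 patients")
    rng = _rng(design, _STREAM_METHYLATION)
    cores = make_cores(design, rng)
    meta = [m for m in design.sample_meta() if m.is_tumor]
    patients = design.patient_ids()
    p_index = {p: i for i, p in enumerate(patients)}
    G, n = len(cores), len(meta)

    base = rng.lognormal(mean=0.0, sigma=design.core_abundance_sigma, size=G)
    base = base / base.sum()

    lo, hi = design.library_size_range
    lib = rng.integers(lo, hi + 1, size=n).astype(float)
    frac_lo, frac_hi = design.biopsy_library_fraction
    for i, m in enumerate(meta):
        if m.role == ROLE_BIOPSY:
            lib[i] = max(1.0, round(lib[i] * rng.uniform(frac_lo, frac_hi)))
    lib = lib.astype(np.int64)

    patient_effect = rng.normal(0.0, design.patient_effect_sd, size=(G, len(patients)))
    core_lfc = resolve_treatment_logfc(design, cores)
    lfc = np.zeros(G)
    core_pos = {cid: i for i, cid in enumerate(cores.index)}
    for cid, v in core_lfc.items():
        lfc[core_pos[cid]] = v

    post = np.array([1.0 if m.timepoint == "post" else 0.0 for m in meta])
    pe = patient_effect[:, [p_index[m.patient_id] for m in meta]]
    log2_mu = np.log2(base)[:, None] + np.log2(lib.astype(float))[None, :] + pe + lfc[:, None] * post[None, :]
    mu = np.exp2(log2_mu)

    shape = 1.0 / design.nb_dispersion
    counts = rng.poisson(rng.gamma(shape, mu / shape)).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=cores.index, columns=[m.sample_id for m in meta])

    truth = MethylationTruth(
        core_logfc=dict(core_lfc),
        target_cores={g: cid for cid, g in cores["gene"].items() if g is not None},
        library_sizes={m.sample_id: int(lib[i]) for i, m in enumerate(meta)},
    )
    return counts_df, cores, meta, truth


# ----------------------------------------------------------------------
# variants
# ----------------------------------------------------------------------
_CONSEQUENCES = (
    ("missense_variant", 0.45),
    ("synonymous_variant", 0.15),
    ("stop_gained", 0.10),
    ("frameshift_variant", 0.08),
    ("inframe_deletion", 0.05),
    ("splice_acceptor_variant", 0.04),
    ("splice_donor_variant", 0.03),
    ("intron_variant", 0.10),
)
_BASES = "ACGT"


def _random_flank(rng: np.random.Generator, length: int = 2 * _FLANK_HALF + 1) -> str:
    """Reference context with no homopolymer run longer than 2."""
    seq: list[str] = []
    for _ in range(length):
        b = _BASES[rng.integers(0, 4)]
        while len(seq) >= 2 and seq[-1] == seq[-2] == b:
            b = _BASES[rng.integers(0, 4)]
        seq.append(b)
    return "".join(seq)


def _flank_with_adjacent_run(rng: np.random.Generator) -> str:
    """Context carrying a 4-bp homopolymer run immediately adjacent to the variant."""
    flank = list(_random_flank(rng))
    base = _BASES[rng.integers(0, 4)]
    side = rng.integers(0, 2)
    if side == 0:  # run ends at offset-1
        lo = _FLANK_HALF - 4
    else:  # run starts at offset+1
        lo = _FLANK_HALF + 1
    for i in range(lo, lo + 4):
        flank[i] = base
    # keep the variant base itself from extending the run
    if flank[_FLANK_HALF] == base:
        flank[_FLANK_HALF] = _BASES[(_BASES.index(base) + 1) % 4]
    return "".join(flank)


def _draw_allele(rng: np.random.Generator, consequence: str) -> tuple[str, str]:
    if consequence == "frameshift_variant":
        a = _BASES[rng.integers(0, 4)]
        return a + _BASES[rng.integers(0, 4)], a
    if consequence == "inframe_deletion":
        a = _BASES[rng.integers(0, 4)]
        return a + "".join(_BASES[rng.integers(0, 4)] for _ in range(3)), a
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return ref, alt


def simulate_variants(design: CohortDesign) -> tuple[list[VariantCall], VariantTruth]:
    """Somatic + germline variant calls with known sharing structure.

    Somatic variants are truncal (all tumor samples), shared (>= 2 but not
    all) or private (exactly one); a ``filter_fail_fraction`` of somatic calls
    deliberately violates one quality filter (low GQ, low VAF, or adjacency to
    a homopolymer run) and is recorded in the truth as such.  A small
    ``panel_normal_leak`` fraction also appears in another patient's normal,
    making the variant non-tumor-specific.
    """
    design.validate()
    rng = _rng(design, _STREAM_VARIANTS)
    meta = design.sample_meta()
    by_patient: dict[str, list[SampleMeta]] = {}
    for m in meta:
        by_patient.setdefault(m.patient_id, []).append(m)
    genes = gene_intervals(design)
    gene_names = list(genes.index)
    cons_names = [c for c, _ in _CONSEQUENCES]
    cons_probs = np.array([p for _, p in _CONSEQUENCES])
    cons_probs = cons_probs / cons_probs.sum()

    calls: list[VariantCall] = []
    categories: dict[tuple, str] = {}
    presence_truth: dict[tuple, tuple[str, ...]] = {}
    should_filter: dict[tuple, str] = {}
    tumor_specific: dict[tuple, bool] = {}
    private_counts: dict[str, dict[str, int]] = {}
    all_patients = design.patient_ids()

    for pid in all_patients:
        samples = by_patient[pid]
        normal = [m for m in samples if m.role == ROLE_NORMAL]
        tumors = [m for m in samples if m.is_tumor]
        n_tumor = len(tumors)
        private_counts[pid] = {m.sample_id: 0 for m in tumors}

        plan: list[tuple[str, list[SampleMeta]]] = []
        if normal:
            for _ in range(rng.poisson(design.n_germline)):
                plan.append((CATEGORY_GERMLINE, samples))
        for _ in range(rng.poisson(design.n_truncal)):
            plan.append((CATEGORY_TRUNCAL, tumors))
        if n_tumor >= 3:
            for _ in range(rng.poisson(design.n_shared)):
                k = int(rng.integers(2, n_tumor))  # 2 .. n_tumor-1
                idx = rng.choice(n_tumor, size=k, replace=False)
                plan.append((CATEGORY_SHARED, [tumors[i] for i in sorted(idx)]))
        if n_tumor >= 2:
            for _ in range(rng.poisson(design.n_private)):
                plan.append((CATEGORY_PRIVATE, [tumors[int(rng.integers(0, n_tumor))]]))

        for category, carriers in plan:
            gene = gene_names[int(rng.integers(0, len(gene_names)))]
            grow = genes.loc[gene]
            pos = int(rng.integers(int(grow["start"]), int(grow["end"])))
            consequence = cons_names[int(rng.choice(len(cons_names), p=cons_probs))]
            ref, alt = _draw_allele(rng, consequence)
            sift = polyphen = None
            if consequence == "missense_variant":
                sift = "deleterious" if rng.random() < 0.4 else "tolerated"
                polyphen = ["benign", "possibly_damaging", "probably_damaging"][
                    int(rng.choice(3, p=[0.5, 0.25, 0.25]))
                ]

            violation: str | None = None
            if category != CATEGORY_GERMLINE and rng.random() < design.filter_fail_fraction:
                violation = ["low_gq", "low_vaf", "homopolymer"][int(rng.integers(0, 3))]
            flank = _flank_with_adjacent_run(rng) if violation == "homopolymer" else _random_flank(rng)

            key = (pid, str(grow["chrom"]), pos, ref, alt)
            if key in categories or key in should_filter:
                continue  # vanishingly rare positional collision: skip

            leak_normal: SampleMeta | None = None
            if category != CATEGORY_GERMLINE and rng.random() < design.panel_normal_leak:
                others = [
                    m for m in meta
                    if m.role == ROLE_NORMAL and m.patient_id != pid
                ]
                if others:
                    leak_normal = others[int(rng.integers(0, len(others)))]

            for sample in carriers + ([leak_normal] if leak_normal else []):
                depth = max(50, int(rng.poisson(design.variant_depth)))
                if violation == "low_vaf":
                    frac = rng.uniform(0.02, 0.08)
                    alt_depth = min(int(rng.binomial(depth, frac)), int(0.095 * depth))
                    alt_depth = max(alt_depth, 1)
                else:
                    frac = 0.5 if category == CATEGORY_GERMLINE or sample.role == ROLE_NORMAL \
                        else rng.uniform(0.15, 0.6)
                    alt_depth = int(rng.binomial(depth, frac))
                    alt_depth = max(alt_depth, int(math.ceil(0.12 * depth)))
                # GQ stays integer-round-trip safe on either side of the 60 cutoff
                gq = rng.uniform(10, 59.0) if violation == "low_gq" else rng.uniform(60, 99)
                calls.append(
                    VariantCall(
                        patient_id=sample.patient_id,
                        sample_id=sample.sample_id,
                        chrom=str(grow["chrom"]),
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        genotype=(0, 1),
                        gq=float(gq),
                        allele_depths=(depth - alt_depth, alt_depth),
                        flank_seq=flank,
                        flank_offset=_FLANK_HALF,
                        consequence=consequence,
                        sift=sift,
                        polyphen=polyphen,
                        gene=gene,
                    )
                )

            if violation is not None:
                should_filter[key] = violation
                continue
            categories[key] = category
            presence_truth[key] = tuple(m.sample_id for m in carriers if m.is_tumor)
            tumor_specific[key] = category != CATEGORY_GERMLINE and leak_normal is None
            if category == CATEGORY_PRIVATE and leak_normal is None:
                private_counts[pid][carriers[0].sample_id] += 1

    truth = VariantTruth(
        categories=categories,
        presence=presence_truth,
        should_filter=should_filter,
        private_counts=private_counts,
        tumor_specific=tumor_specific,
    )
    return calls, truth


# ----------------------------------------------------------------------
# BAF
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BAFRecord:
    """Allele counts at one SNP in one sample (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref_count: int
    alt_count: int
    n_alleles: int = 2

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def baf(self) -> float:
        d = self.depth
        if d == 0:
            raise ValueError("BAF undefined at zero depth")
        return self.alt_count / d


def simulate_baf(design: CohortDesign) -> tuple[list[BAFRecord], BAFTruth]:
    """Binomial allele counts at germline-het SNPs, LOH-shifted in tumors.

    The same SNP panel is used for every patient; injected LOH segments apply
    to all tumor samples (truncal events).  Tumor allele fractions inside a
    segment move to ``0.5 + shift`` (never fully to 0 or 1, emulating impure
    or sub-clonal LOH).
    """
    design.validate()
    rng = _rng(design, _STREAM_BAF)
    meta = design.sample_meta()
    sites: dict[str, np.ndarray] = {}
    for chrom, length in design.chromosomes.items():
        pos = np.sort(rng.choice(np.arange(1, length), size=design.baf_snps_per_chrom, replace=False))
        sites[chrom] = pos

    seg_truth: list[tuple[str, int, int, float, int, int]] = []
    shift_by_chrom: dict[str, np.ndarray] = {c: np.zeros(len(p)) for c, p in sites.items()}
    for chrom, start, end, shift in design.loh_segments:
        pos = sites[chrom]
        inside = np.flatnonzero((pos >= start) & (pos <= end))
        if inside.size:
            shift_by_chrom[chrom][inside] = shift
            seg_truth.append((chrom, int(pos[inside[0]]), int(pos[inside[-1]]),
                              float(shift), int(inside[0]), int(inside[-1])))

    records: list[BAFRecord] = []
    for pid in design.patient_ids():
        p_meta = [m for m in meta if m.patient_id == pid]
        for chrom, pos in sites.items():
            n = len(pos)
            shifted = 0.5 + shift_by_chrom[chrom]
            for m in p_meta:
                depth = np.maximum(1, rng.poisson(design.baf_mean_depth, size=n))
                frac = shifted if m.is_tumor else np.full(n, 0.5)
                # inverse-CDF binomial: one uniform per site, so records outside
                # LOH segments are unaffected by the segment parameters
                u = rng.random(n)
                alt = sp_stats.binom.ppf(u, depth, frac).astype(np.int64)
                for j in range(n):
                    records.append(
                        BAFRecord(m.sample_id, chrom, int(pos[j]), int(depth[j] - alt[j]), int(alt[j]))
                    )
    return records, BAFTruth(segments=seg_truth, n_snps={c: len(p) for c, p in sites.items()})


# ----------------------------------------------------------------------
# target coverage / CNV
# ----------------------------------------------------------------------
def simulate_target_coverage(design: CohortDesign) -> tuple[pd.DataFrame, pd.DataFrame, CNVTruth]:
    """Per-amplicon-target mean coverages with gene-level CNV events.

    Returns ``(coverage, targets, truth)``: coverage is targets x samples,
    targets carries (gene, chrom, start, end) per target id.  Each tumor
    sample receives a Poisson(``cnv_event_rate``) number of single-copy
    gene-level events (log2 ratio -1 for loss, +0.585 for gain).
    """
    design.validate()
    rng = _rng(design, _STREAM_CNV)
    meta = design.sample_meta()
    genes = gene_intervals(design)
    rows = []
    for gene, grow in genes.iterrows():
        width = 1000
        for k in range(design.targets_per_gene):
            start = int(grow["start"]) + k * 2000
            rows.append((f"{gene}_t{k + 1}", gene, grow["chrom"], start, start + width - 1))
    targets = pd.DataFrame(rows, columns=["target_id", "gene", "chrom", "start", "end"]).set_index(
        "target_id"
    )
    T = len(targets)
    base = rng.lognormal(mean=np.log(500.0), sigma=0.3, size=T)

    events: dict[str, list[tuple[str, float]]] = {}
    cov = {}
    gene_names = list(genes.index)
    gene_of_target = targets["gene"].to_numpy()
    for m in meta:
        scale = rng.uniform(0.7, 1.3)
        lr = np.zeros(T)
        if m.is_tumor:
            k = int(rng.poisson(design.cnv_event_rate))
            k = min(k, len(gene_names))
            ev_genes = rng.choice(gene_names, size=k, replace=False)
            ev = []
            for g in ev_genes:
                r = float(rng.choice([-1.0, 0.585]))
                lr[gene_of_target == g] = r
                ev.append((str(g), r))
            events[m.sample_id] = ev
        noise = rng.lognormal(0.0, 0.1, size=T)
        cov[m.sample_id] = base * scale * np.exp2(lr) * noise
    coverage = pd.DataFrame(cov, index=targets.index)
    return coverage, targets, CNVTruth(events=events)


# ----------------------------------------------------------------------
# whole cohort
# ----------------------------------------------------------------------
@dataclass
class SimulatedCohort:
    design: CohortDesign
    meta: list[SampleMeta]
    counts: pd.DataFrame
    cores: pd.DataFrame
    methylation_meta: list[SampleMeta]
    variant_calls: list[VariantCall]
    baf_records: list[BAFRecord]
    coverage: pd.DataFrame
    targets: pd.DataFrame
    truth: SimTruth


def simulate_cohort(design: CohortDesign) -> SimulatedCohort:
    """Run all four generators and bundle their outputs and ground truth."""
    counts, cores, meth_meta, m_truth = simulate_methylation_counts(design)
    calls, v_truth = simulate_variants(design)
    baf, b_truth = simulate_baf(design)
    coverage, targets, c_truth = simulate_target_coverage(design)
    return SimulatedCohort(
        design=design,
        meta=design.sample_meta(),
        counts=counts,
        cores=cores,
        methylation_meta=meth_meta,
        variant_calls=calls,
        baf_records=baf,
        coverage=coverage,
        targets=targets,
        truth=SimTruth(methylation=m_truth, variants=v_truth, baf=b_truth, cnv=c_truth),
    )
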