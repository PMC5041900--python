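"""End-to-end orchestration: simulate -> variants -> cnv/loh -> phylo ->
methylome -> summary report.

The runner is deterministic given (config, seed): the seed fans out to fixed
per-stage child streams inside the simulators, every numeric parameter lives
in the :class:`RunConfig`, and the config is serialized into the output
directory as a reproducibility manifest.  The reporter never recomputes
anything: each summary number is read from a stage output.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import cnv_loh as cl
from . import io as kio
from . import methylome as me
from . import phylo as ph
from . import variants as va
from .design import ROLE_BIOPSY, ROLE_NEPHRECTOMY, ROLE_NORMAL, CohortDesign, SampleMeta
from .simulate import SimulatedCohort, simulate_cohort

log = logging.getLogger("ithkit")


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
class StageToggles(BaseModel):
    variants: bool = True
    cnv_loh: bool = True
    phylo: bool = True
    methylome: bool = True


class LOHParams(BaseModel):
    min_snps: int = 10
    deviation_threshold: float = 0.15
    alpha: float = 0.01
    clonal_threshold: float = 0.45


class CNVParams(BaseModel):
    loss_threshold: float = -0.4
    gain_threshold: float = 0.3


class RunConfig(BaseModel):
    seed: int = 0
    out_dir: Path = Path("ith_run")
    design: dict[str, Any] = Field(default_factory=dict)  # CohortDesign overrides
    blocked_design: bool = True
    top_k_variance: int = 1000
    include_loh_in_profiles: bool = False  # subclonal LOH excluded from trees by default
    loh: LOHParams = Field(default_factory=LOHParams)
    cnv: CNVParams = Field(default_factory=CNVParams)
    stages: StageToggles = Field(default_factory=StageToggles)

    def cohort_design(self) -> CohortDesign:
        d = dict(self.design)
        d["seed"] = self.seed
        return CohortDesign.from_dict(d)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: Path | str) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ----------------------------------------------------------------------
# report schema
# ----------------------------------------------------------------------
class TestResult(BaseModel):
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    df: Optional[float] = None
    note: Optional[str] = None


class ConcordanceTally(BaseModel):
    complete: int = 0
    partial: int = 0
    none: int = 0

    @property
    def total(self) -> int:
        return self.complete + self.partial + self.none


class DMRecord(BaseModel):
    gene: str
    core_id: str
    logfc: float
    t: float
    p: float
    fdr: float


class HyperSummary(BaseModel):
    gene: str
    core_id: str
    pre_pct: float
    post_pct: float
    n_patients: int


class PrivateSplit(BaseModel):
    biopsy_greater: int
    nephrectomy_greater: int
    equal: int


class SummaryReport(BaseModel):
    seed: int
    n_patients: int
    cohort: str
    methylome_concordance: Optional[ConcordanceTally] = None
    mutation_concordance: Optional[ConcordanceTally] = None
    dm_targets: list[DMRecord] = Field(default_factory=list)
    n_targets_significant: Optional[int] = None
    top_target: Optional[DMRecord] = None
    hypermethylation: Optional[HyperSummary] = None
    responder_test: Optional[TestResult] = None
    private_split: Optional[PrivateSplit] = None
    private_test: Optional[TestResult] = None
    driver_genes_significant: Optional[int] = None
    cnv_test: Optional[TestResult] = None
    n_loh_segments: Optional[int] = None
    n_loh_subclonal: Optional[int] = None
    tree_files: list[str] = Field(default_factory=list)


# ----------------------------------------------------------------------
# stage helpers
# ----------------------------------------------------------------------
def _write_inputs(sim: SimulatedCohort, out: Path) -> None:
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    kio.write_counts_tsv(sim.counts, inputs / "counts.tsv")
    kio.write_cores_bed(sim.cores, inputs / "cores.bed")
    kio.write_meta_tsv(sim.meta, inputs / "meta.tsv")
    kio.write_vcf(sim.variant_calls, sim.meta, inputs / "variants.vcf",
                  contigs=sim.design.chromosomes)
    kio.write_baf_tsv(sim.baf_records, inputs / "baf.tsv")
    kio.write_coverage_tsv(sim.coverage, sim.targets, inputs / "coverage.tsv")
    (inputs / "truth.json").write_text(sim.truth.to_json())


def run_variant_stage(sim: SimulatedCohort, out: Path) -> dict[str, Any]:
    calls = va.filter_variants(sim.variant_calls)
    sharing = va.classify_sharing(calls, sim.meta)
    drivers = va.call_candidate_drivers(calls)
    private = va.count_private_mutations(sharing, sim.meta)
    private_test = va.compare_private_counts(private)
    driver_table = va.compare_driver_counts(drivers, sharing, sim.meta)

    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "patient_id": pid,
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "category": sc.category,
            "tumor_specific": sc.tumor_specific,
            "samples": ",".join(sorted(sc.presence)),
        }
        for (pid, key), sc in sorted(sharing.items())
    ]
    pd.DataFrame(rows).to_csv(out / "classified_variants.tsv", sep="\t", index=False)
    private.to_csv(out / "private_counts.tsv", sep="\t", index_label="patient_id")
    driver_table.to_csv(out / "driver_gene_tests.tsv", sep="\t")
    kio.write_json(
        {"private_test": private_test,
         "n_filtered_in": len(sim.variant_calls), "n_filtered_out": len(calls)},
        out / "variant_summary.json",
    )
    log.info("variants: %d calls in, %d kept, %d classified keys",
             len(sim.variant_calls), len(calls), len(sharing))
    return {
        "sharing": sharing,
        "drivers": drivers,
        "private": private,
        "private_test": private_test,
        "driver_table": driver_table,
    }


def run_cnv_loh_stage(sim: SimulatedCohort, cfg: RunConfig, out: Path) -> dict[str, Any]:
    out.mkdir(parents=True, exist_ok=True)
    meta = sim.meta
    baf_by_sample: dict[str, list] = {}
    for rec in sim.baf_records:
        baf_by_sample.setdefault(rec.sample_id, []).append(rec)

    loh_segments: dict[str, list[cl.LOHSegment]] = {}
    cnv_segments: dict[str, list[cl.CNVSegment]] = {}
    pre_counts: dict[str, float] = {}
    post_counts: dict[str, float] = {}
    for pid in sorted({m.patient_id for m in meta}):
        p_meta = [m for m in meta if m.patient_id == pid]
        normal = next((m for m in p_meta if m.role == ROLE_NORMAL), None)
        tumors = [m for m in p_meta if m.is_tumor]
        if normal is None:
            continue  # BAF/CNV need the matched normal
        het_sites, _skipped = cl.select_het_snps(baf_by_sample.get(normal.sample_id, []))
        het = set(het_sites)
        for m in tumors:
            recs = [r for r in baf_by_sample.get(m.sample_id, [])
                    if (r.chrom, r.pos) in het and r.depth > 0]
            recs.sort(key=lambda r: (r.chrom, r.pos))
            segs, _notes = cl.segment_loh(
                recs,
                min_snps=cfg.loh.min_snps,
                deviation_threshold=cfg.loh.deviation_threshold,
                alpha=cfg.loh.alpha,
                clonal_threshold=cfg.loh.clonal_threshold,
            )
            loh_segments[m.sample_id] = segs
            cnvs = cl.call_cnv(
                sim.coverage[m.sample_id],
                sim.coverage[normal.sample_id],
                sim.targets,
                loss_threshold=cfg.cnv.loss_threshold,
                gain_threshold=cfg.cnv.gain_threshold,
            )
            cnv_segments[m.sample_id] = cnvs
        n_by_sample = {
            m.sample_id: sum(1 for s in cnv_segments[m.sample_id] if s.state != cl.STATE_NEUTRAL)
            for m in tumors
        }
        biopsy = [m for m in tumors if m.role == ROLE_BIOPSY]
        nephs = [m for m in tumors if m.role == ROLE_NEPHRECTOMY]
        if biopsy and nephs:
            pre_counts[pid] = float(n_by_sample[biopsy[0].sample_id])
            post_counts[pid] = float(np.mean([n_by_sample[m.sample_id] for m in nephs]))

    cnv_test = cl.compare_cnv_counts(pre_counts, post_counts) if len(pre_counts) >= 2 else None

    all_loh = [s for segs in loh_segments.values() for s in segs if s.is_loh]
    kio.write_segments_bed(all_loh, out / "loh_segments.bed", name_fn=lambda s: "loh")
    all_cnv = [s for segs in cnv_segments.values() for s in segs if s.state != cl.STATE_NEUTRAL]
    kio.write_segments_bed(all_cnv, out / "cnv_segments.bed")
    kio.write_json(
        {
            "cnv_test": cnv_test,
            "pre_counts": pre_counts,
            "post_counts": post_counts,
            "n_loh_segments": len(all_loh),
            "n_loh_subclonal": sum(1 for s in all_loh if s.subclonal),
        },
        out / "cnv_loh_summary.json",
    )
    log.info("cnv_loh: %d LOH segments, %d CNV calls", len(all_loh), len(all_cnv))
    return {
        "loh_segments": loh_segments,
        "cnv_segments": cnv_segments,
        "cnv_test": cnv_test,
        "n_loh": len(all_loh),
        "n_loh_subclonal": sum(1 for s in all_loh if s.subclonal),
    }


def build_profiles(
    sharing: dict,
    cnv_segments: dict[str, list],
    meta: list[SampleMeta],
    loh_segments: dict[str, list] | None = None,
    include_subclonal_loh: bool = False,
) -> pd.DataFrame:
    """Binary mutation profiles (samples x features) over SNV/indel + CNV keys.

    Subclonal LOH is excluded unless asked for: with unphased SNPs such calls
    are likely sub-clonal and unstable as phylogenetic characters.
    """
    tumor = [m for m in meta if m.is_tumor]
    features: set[str] = set()
    values: dict[str, set[str]] = {m.sample_id: set() for m in tumor}
    for (pid, key), sc in sharing.items():
        if sc.category == va.CATEGORY_GERMLINE or not sc.tumor_specific:
            continue
        feat = f"{key[0]}:{key[1]}:{key[2]}>{key[3]}"
        features.add(feat)
        for s in sc.presence:
            if s in values:
                values[s].add(feat)
    for sample, segs in (cnv_segments or {}).items():
        if sample not in values:
            continue
        for seg in segs:
            if seg.state == cl.STATE_NEUTRAL:
                continue
            feat = f"cnv:{seg.gene}:{seg.state}"
            features.add(feat)
            values[sample].add(feat)
    if loh_segments:
        for sample, segs in loh_segments.items():
            if sample not in values:
                continue
            for seg in segs:
                if not seg.is_loh or (seg.subclonal and not include_subclonal_loh):
                    continue
                feat = f"loh:{seg.chrom}"
                features.add(feat)
                values[sample].add(feat)
    cols = sorted(features)
    data = np.zeros((len(tumor), len(cols)))
    for i, m in enumerate(tumor):
        for j, f in enumerate(cols):
            data[i, j] = 1.0 if f in values[m.sample_id] else 0.0
    return pd.DataFrame(data, index=[m.sample_id for m in tumor], columns=cols)


def run_phylo_stage(
    sim: SimulatedCohort,
    variant_out: dict[str, Any],
    cnv_out: dict[str, Any] | None,
    cfg: RunConfig,
    out: Path,
) -> dict[str, Any]:
    out.mkdir(parents=True, exist_ok=True)
    sharing = variant_out["sharing"]
    drivers = variant_out["drivers"]
    cnv_segments = (cnv_out or {}).get("cnv_segments", {})
    loh_segments = (cnv_out or {}).get("loh_segments", {}) if cfg.include_loh_in_profiles else None
    profiles = build_profiles(sharing, cnv_segments, sim.meta, loh_segments)

    tree_files: list[str] = []
    for pid in sorted({m.patient_id for m in sim.meta if m.is_tumor}):
        samples = [m.sample_id for m in sim.meta if m.patient_id == pid and m.is_tumor]
        if len(samples) < 3:
            continue
        sub = profiles.loc[samples]
        D = ph.manhattan_distance(sub)
        tree = ph.bionj(D)
        presence = {}
        for d in drivers:
            if d.patient_id != pid or not d.is_candidate_driver:
                continue
            sc = sharing.get((pid, d.key))
            if sc is None or sc.category == va.CATEGORY_GERMLINE:
                continue
            name = f"{d.gene or 'NA'}:{d.key[0]}:{d.key[1]}"
            presence[name] = frozenset(s for s in sc.presence if s in set(samples))
        presence = {k: v for k, v in presence.items() if v}
        tree, _inconsistent = ph.label_branches(tree, presence)
        fname = out / f"tree_{pid}.nwk"
        fname.write_text(ph.to_newick(tree) + "\n")
        tree_files.append(fname.name)

    # cross-cohort mutation dendrogram (Manhattan + complete linkage)
    concordance = None
    if profiles.shape[1] >= 1 and len(profiles) >= 2 and np.ptp(profiles.to_numpy()) > 0:
        D_all = ph.manhattan_distance(profiles)
        dend = ph.dendrogram_from_distance(D_all, linkage_method="complete")
        results = ph.score_concordance(dend, sim.meta)
        concordance = ph.concordance_tally(results)
        kio.write_json(
            {"merges": dend.to_merge_list(), "labels": dend.labels,
             "verdicts": {r.patient_id: r.verdict for r in results}},
            out / "mutation_dendrogram.json",
        )
    log.info("phylo: %d trees, concordance %s", len(tree_files), concordance)
    return {"tree_files": tree_files, "concordance": concordance, "profiles": profiles}


def run_methylome_stage(sim: SimulatedCohort, cfg: RunConfig, out: Path) -> dict[str, Any]:
    out.mkdir(parents=True, exist_ok=True)
    meta = sim.methylation_meta
    lib = pd.Series(sim.truth.methylation.library_sizes)
    dm = me.differential_methylation(
        sim.counts, sim.cores, meta, blocked=cfg.blocked_design, lib_sizes=lib
    )
    dm.table.to_csv(out / "dm_table.tsv", sep="\t", index_label="core_id")
    dm.gene_table.to_csv(out / "dm_genes.tsv", sep="\t")

    gene_table = dm.gene_table.sort_values("p", kind="stable")
    top = gene_table.iloc[0] if len(gene_table) else None
    region_summary = None
    responder = None
    if top is not None:
        values = dm.normalized.loc[top["core_id"]]
        region_table, boundaries, _excluded = me.categorize_region(values, meta)
        region_table.to_csv(out / "top_region_categories.tsv", sep="\t", index_label="patient_id")
        region_summary = me.hypermethylation_summary(region_table)
        region_summary.update(gene=str(gene_table.index[0]), core_id=str(top["core_id"]))
        deltas = (region_table["post_value"] - region_table["pre_value"]).to_dict()
        response = {m.patient_id: m.response for m in meta}
        try:
            responder = me.responder_comparison(deltas, response)
        except ValueError:
            responder = None

    dend = me.top_variance_clustering(dm.normalized, k=cfg.top_k_variance)
    results = ph.score_concordance(dend, meta)
    tally = ph.concordance_tally(results)
    kio.write_json(
        {"merges": dend.to_merge_list(), "labels": dend.labels,
         "verdicts": {r.patient_id: r.verdict for r in results},
         "filter_stats": dm.filter_stats,
         "prior": {"s0_squared": dm.fit.s0_squared, "d0": dm.fit.d0}},
        out / "methylome_summary.json",
    )
    log.info("methylome: %d cores kept, top gene %s", dm.filter_stats["kept"],
             gene_table.index[0] if len(gene_table) else None)
    return {
        "dm": dm,
        "gene_table": gene_table,
        "region_summary": region_summary,
        "responder": responder,
        "concordance": tally,
    }


# ----------------------------------------------------------------------
# full run
# ----------------------------------------------------------------------
def _test_result(d: dict | None, stat_key: str = "t") -> TestResult | None:
    if d is None:
        return None
    return TestResult(statistic=d.get(stat_key), p_value=d.get("p"),
                      df=d.get("df"), note=d.get("note"))


def run_pipeline(cfg: RunConfig) -> SummaryReport:
    """Execute all enabled stages on a synthetic cohort and build the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    design = cfg.cohort_design()
    sim = simulate_cohort(design)
    _write_inputs(sim, out)

    variant_out = cnv_out = phylo_out = meth_out = None
    if cfg.stages.variants:
        variant_out = run_variant_stage(sim, out / "variants")
    if cfg.stages.cnv_loh:
        cnv_out = run_cnv_loh_stage(sim, cfg, out / "cnv_loh")
    if cfg.stages.phylo and variant_out is not None:
        phylo_out = run_phylo_stage(sim, variant_out, cnv_out, cfg, out / "phylo")
    if cfg.stages.methylome:
        meth_out = run_methylome_stage(sim, cfg, out / "methylome")

    report = SummaryReport(seed=cfg.seed, n_patients=design.n_patients, cohort=design.cohort)
    if meth_out is not None:
        report.methylome_concordance = ConcordanceTally(**meth_out["concordance"])
        gt = meth_out["gene_table"]
        report.dm_targets = [
            DMRecord(gene=str(g), core_id=str(r["core_id"]), logfc=float(r["logFC"]),
                     t=float(r["t"]), p=float(r["p"]), fdr=float(r["fdr"]))
            for g, r in gt.iterrows()
        ]
        report.n_targets_significant = int((gt["fdr"] < 0.1).sum())
        if len(gt):
            report.top_target = report.dm_targets[0]
        if meth_out["region_summary"] is not None:
            rs = meth_out["region_summary"]
            report.hypermethylation = HyperSummary(
                gene=rs["gene"], core_id=rs["core_id"], pre_pct=rs["pre_pct"],
                post_pct=rs["post_pct"], n_patients=rs["n_patients"],
            )
        report.responder_test = _test_result(meth_out["responder"])
    if phylo_out is not None:
        if phylo_out["concordance"] is not None:
            report.mutation_concordance = ConcordanceTally(**phylo_out["concordance"])
        report.tree_files = phylo_out["tree_files"]
    if variant_out is not None:
        pt = variant_out["private_test"]
        report.private_test = _test_result(pt)
        report.private_split = PrivateSplit(**pt["split"])
        dt = variant_out["driver_table"]
        report.driver_genes_significant = int((dt["p"].dropna() < 0.05).sum())
    if cnv_out is not None:
        report.cnv_test = _test_result(cnv_out["cnv_test"])
        report.n_loh_segments = cnv_out["n_loh"]
        report.n_loh_subclonal = cnv_out["n_loh_subclonal"]
    return report


# ----------------------------------------------------------------------
# report writer
# ----------------------------------------------------------------------
def write_report(report: SummaryReport, out_dir: Path | str, formats=("json", "markdown")) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = out / "report.json"
        path.write_text(report.model_dump_json(indent=1) + "\n")
        # schema round-trip validation
        SummaryReport.model_validate_json(path.read_text())
        written.append(path)
    if "markdown" in formats:
        path = out / "report.md"
        path.write_text(render_markdown(report))
        written.append(path)
    return written


def load_report(path: Path | str) -> SummaryReport:
    return SummaryReport.model_validate_json(Path(path).read_text())


def _fmt_test(t: TestResult | None) -> str:
    if t is None or t.p_value is None:
        return "not computed"
    return f"t = {t.statistic:.3f}, p = {t.p_value:.3g}"


def render_markdown(r: SummaryReport) -> str:
    lines = [f"# Cohort summary (seed {r.seed}, {r.n_patients} patients, {r.cohort} arm)", ""]
    lines.append("## Clustering of methylation and mutational data")
    for name, tally in (("Methylome", r.methylome_concordance), ("Mutational", r.mutation_concordance)):
        if tally is None:
            lines.append(f"- {name}: stage disabled")
        else:
            lines.append(
                f"- {name}: {tally.complete}/{tally.total} complete, "
                f"{tally.partial} partial, {tally.none} none"
            )
    lines.append("")
    if r.dm_targets:
        lines.append("## Differential methylation of target genes (post vs pre)")
        lines.append(f"Targets below FDR 0.1: {r.n_targets_significant}")
        lines.append("")
        lines.append("| gene | core | logFC | p | FDR |")
        lines.append("|---|---|---|---|---|")
        for rec in r.dm_targets[:10]:
            lines.append(
                f"| {rec.gene} | {rec.core_id} | {rec.logfc:.3f} | {rec.p:.3g} | {rec.fdr:.3g} |"
            )
        lines.append("")
    if r.hypermethylation is not None:
        h = r.hypermethylation
        lines.append(
            f"Hypermethylated (top two quantile categories) at {h.gene} ({h.core_id}): "
            f"{h.pre_pct:.0f}% of patients pre-treatment, {h.post_pct:.0f}% post-treatment."
        )
        lines.append(f"Good vs poor responders: {_fmt_test(r.responder_test)}")
        lines.append("")
    lines.append("## Mutation frequency after treatment")
    if r.private_split is not None:
        s = r.private_split
        lines.append(
            f"- Private mutations greater in biopsy for {s.biopsy_greater} patients, "
            f"nephrectomy for {s.nephrectomy_greater}, equal in {s.equal}; "
            f"unpaired t-test {_fmt_test(r.private_test)}"
        )
    if r.driver_genes_significant is not None:
        lines.append(
            f"- Driver-count Wilcoxon tests with p < 0.05: {r.driver_genes_significant} genes"
        )
    if r.cnv_test is not None:
        lines.append(f"- CNV count change (paired t): {_fmt_test(r.cnv_test)}")
    if r.n_loh_segments is not None:
        lines.append(
            f"- LOH segments: {r.n_loh_segments} ({r.n_loh_subclonal} subclonal)"
        )
    lines.append("")
    if r.tree_files:
        lines.append("## Per-patient phylogenies")
        for f in r.tree_files:
            lines.append(f"- {f}")
        lines.append("")
    return "\n".join(lines) + "\n"
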