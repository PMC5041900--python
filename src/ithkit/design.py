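"""Cohort design and simulation ground-truth containers.

A cohort mirrors the multi-region renal-cancer sampling scheme: per patient
one normal sample, one pre-treatment needle biopsy, and several spatially
separate post-treatment nephrectomy samples.  The design object carries every
tunable of the synthetic generators so that a (seed, design) pair fully
determines the simulated data.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

ROLE_NORMAL = "normal"
ROLE_BIOPSY = "biopsy"
ROLE_NEPHRECTOMY = "nephrectomy"
TUMOR_ROLES = (ROLE_BIOPSY, ROLE_NEPHRECTOMY)

#: 48-gene renal-cancer panel used to name target genes in the simulator
#: (tumor suppressors, chromatin modifiers, PI3K/mTOR and angiogenesis axis).
TARGET_GENES: tuple[str, ...] = (
    "VHL", "PBRM1", "BAP1", "SETD2", "KDM5C", "KDM6A", "MTOR", "PTEN",
    "TP53", "PIK3CA", "ARID1A", "SMARCA4", "TSC1", "TSC2", "TCEB1", "ATM",
    "CDKN2A", "NF2", "FH", "MET", "SDHB", "SDHC", "SDHD", "FLCN",
    "FLT1", "FLT3", "FLT4", "KDR", "KIT", "PDGFRA", "PDGFRB", "VEGFA",
    "HIF1A", "EPAS1", "EGLN1", "EGLN2", "CUL2", "RBX1", "AKT1", "AKT2",
    "RAF1", "BRAF", "MAP2K1", "NRAS", "KRAS", "HRAS", "STK11", "CDKN1A",
)


@dataclass(frozen=True)
class SampleMeta:
    """One physical sample: who it came from and its role in the design."""

    sample_id: str
    patient_id: str
    role: str                    # normal | biopsy | nephrectomy
    timepoint: str               # pre | post | na
    cohort: str = "sunitinib"    # sunitinib | hypoxia
    response: str | None = None  # good | poor | None

    @property
    def is_tumor(self) -> bool:
        return self.role in TUMOR_ROLES


@dataclass
class CohortDesign:
    """All knobs of the synthetic cohort generators.

    ``treatment_logfc`` maps a target gene symbol (or an explicit core id)
    to the log2 fold change injected on that gene's promoter core in
    post-treatment samples.  The default injects the headline-sized effect
    (0.87 log2 units) on the VHL promoter core.
    """

    n_patients: int = 14
    samples_per_patient: dict[str, int] = field(
        default_factory=lambda: {"normal": 1, "biopsy": 1, "nephrectomy": 3}
    )
    # --- methylome ---
    n_cores: int = 1200
    n_target_genes: int = 48
    promoter_fraction: float = 0.6
    core_abundance_sigma: float = 0.7
    library_size_range: tuple[int, int] = (300_000, 600_000)
    biopsy_library_fraction: tuple[float, float] = (0.25, 0.50)
    nb_dispersion: float = 0.01
    patient_effect_sd: float = 1.0
    treatment_logfc: dict[str, float] = field(default_factory=lambda: {"VHL": 0.87})
    # --- variants ---
    n_truncal: float = 5.0
    n_shared: float = 3.0
    n_private: float = 2.0
    n_germline: float = 10.0
    filter_fail_fraction: float = 0.10
    panel_normal_leak: float = 0.05
    variant_depth: int = 500
    # --- genome / BAF / CNV ---
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr3": 40_000_000, "chr10": 40_000_000}
    )
    loh_segments: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [("chr3", 1, 20_000_000, 0.25)]
    )
    baf_snps_per_chrom: int = 150
    baf_mean_depth: int = 200
    targets_per_gene: int = 6
    cnv_event_rate: float = 1.0
    # --- bookkeeping ---
    cohort: str = "sunitinib"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be a positive integer")
        spp = self.samples_per_patient
        if spp.get("normal", 0) not in (0, 1):
            raise ValueError("samples_per_patient['normal'] must be 0 or 1")
        if spp.get("biopsy", 0) != 1:
            raise ValueError("samples_per_patient['biopsy'] must be 1")
        if spp.get("nephrectomy", 0) < 1:
            raise ValueError("samples_per_patient['nephrectomy'] must be >= 1")
        if self.n_cores < 1:
            raise ValueError("n_cores must be positive")
        if self.n_target_genes < 1:
            raise ValueError("n_target_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be a positive real")
        if self.patient_effect_sd < 0:
            raise ValueError("patient_effect_sd must be non-negative")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be a pair of positive integers, lo <= hi")
        for chrom, start, end, shift in self.loh_segments:
            if chrom not in self.chromosomes:
                raise ValueError(f"LOH segment on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= self.chromosomes[chrom]):
                raise ValueError("LOH segment outside simulated chromosome bounds")
            if not (0.0 < 0.5 + abs(shift) < 1.0):
                raise ValueError("baf_shift would put the mean allele fraction outside (0, 1)")
        for mean in (self.n_truncal, self.n_shared, self.n_private, self.n_germline):
            if mean < 0:
                raise ValueError("variant count means must be non-negative")

    # ------------------------------------------------------------------
    @property
    def n_nephrectomy(self) -> int:
        return self.samples_per_patient["nephrectomy"]

    @property
    def has_normal(self) -> bool:
        return self.samples_per_patient.get("normal", 0) > 0

    def patient_ids(self) -> list[str]:
        return [f"SU{i + 1:02d}" for i in range(self.n_patients)]

    def target_gene_names(self) -> list[str]:
        names = list(TARGET_GENES[: self.n_target_genes])
        for i in range(len(names), self.n_target_genes):
            names.append(f"GENE{i + 1:02d}")
        return names

    def sample_meta(self) -> list[SampleMeta]:
        """Enumerate the cohort's samples in deterministic order."""
        out: list[SampleMeta] = []
        for p_idx, pid in enumerate(self.patient_ids()):
            response = "good" if p_idx % 2 == 0 else "poor"
            if self.has_normal:
                out.append(SampleMeta(f"{pid}_N", pid, ROLE_NORMAL, "na", self.cohort, response))
            out.append(SampleMeta(f"{pid}_Bx", pid, ROLE_BIOPSY, "pre", self.cohort, response))
            for k in range(self.n_nephrectomy):
                out.append(
                    SampleMeta(f"{pid}_Nx{k + 1}", pid, ROLE_NEPHRECTOMY, "post", self.cohort, response)
                )
        return out

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["library_size_range"] = list(self.library_size_range)
        d["biopsy_library_fraction"] = list(self.biopsy_library_fraction)
        d["loh_segments"] = [list(s) for s in self.loh_segments]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortDesign":
        d = dict(d)
        if "library_size_range" in d:
            d["library_size_range"] = tuple(d["library_size_range"])
        if "biopsy_library_fraction" in d:
            d["biopsy_library_fraction"] = tuple(d["biopsy_library_fraction"])
        if "loh_segments" in d:
            d["loh_segments"] = [tuple(s) for s in d["loh_segments"]]
        return cls(**d)


def hypoxia_preset(seed: int = 0, **overrides: Any) -> CohortDesign:
    """Two-patient control design: pre- vs post-renal-artery-ligation pairs.

    No treatment effect is injected; this emulates the sampling-procedure
    control arm (biopsy before ligation, one matched sample after).
    """
    kwargs: dict[str, Any] = dict(
        n_patients=2,
        samples_per_patient={"normal": 1, "biopsy": 1, "nephrectomy": 1},
        treatment_logfc={},
        cohort="hypoxia",
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


# ----------------------------------------------------------------------
# Ground truth
# ----------------------------------------------------------------------
@dataclass
class MethylationTruth:
    core_logfc: dict[str, float]          # injected log2 FC per core (non-zero entries)
    target_cores: dict[str, str]          # gene symbol -> promoter core id
    library_sizes: dict[str, int]


@dataclass
class VariantTruth:
    #: (patient, chrom, pos, ref, alt) -> expected sharing category for
    #: filter-passing variants
    categories: dict[tuple[str, str, int, str, str], str]
    #: same key space -> set of carrying tumor sample ids
    presence: dict[tuple[str, str, int, str, str], tuple[str, ...]]
    #: variants deliberately violating a filter, with the violated rule
    should_filter: dict[tuple[str, str, int, str, str], str]
    #: per patient -> per tumor sample -> number of passing private variants
    private_counts: dict[str, dict[str, int]]
    #: keys whose presence pattern is tumor-specific (never in any normal)
    tumor_specific: dict[tuple[str, str, int, str, str], bool]


@dataclass
class BAFTruth:
    #: injected segments as (chrom, start_pos, end_pos, shift, idx_start, idx_end)
    #: where idx_* are 0-based indices into that chromosome's sorted SNP list
    segments: list[tuple[str, int, int, float, int, int]]
    n_snps: dict[str, int]


@dataclass
class CNVTruth:
    #: tumor sample id -> list of (gene, injected log2 ratio)
    events: dict[str, list[tuple[str, float]]]

    def counts(self) -> dict[str, int]:
        return {s: len(ev) for s, ev in self.events.items()}


@dataclass
class SimTruth:
    """Aggregated ground truth for one simulated cohort."""

    methylation: MethylationTruth | None = None
    variants: VariantTruth | None = None
    baf: BAFTruth | None = None
    cnv: CNVTruth | None = None

    def to_json(self) -> str:
        def _enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {
                    (k if isinstance(k, str) else "|".join(map(str, k))): _enc(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [_enc(v) for v in obj]
            return obj

        return json.dumps(_enc(self), indent=1, sort_keys=True)
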