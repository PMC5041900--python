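"""Somatic variant filtering, sharing classification and mutation-count tests.

The filtering rules mirror targeted amplicon-sequencing practice: calls are
dropped when genotype quality < 60, when the variant allele frequency (summed
over alternate alleles) < 10%, or when the call lies within 1 bp of a
homopolymer run of >= 4 identical bases (a classic ion-semiconductor error
mode).  Surviving calls are grouped per patient and classified by how widely
the genotype is shared across that patient's tumor samples.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CATEGORY_GERMLINE = "germline"
CATEGORY_TRUNCAL = "truncal"
CATEGORY_SHARED = "shared"
CATEGORY_PRIVATE = "private"

#: consequences that are candidate drivers irrespective of predictor labels
DRIVER_CONSEQUENCES = frozenset(
    {
        "frameshift_variant",
        "inframe_deletion",
        "stop_gained",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)
MISSENSE = "missense_variant"
#: consequences recognized as (putative) passengers
PASSENGER_CONSEQUENCES = frozenset(
    {"synonymous_variant", "intron_variant", "upstream_gene_variant",
     "downstream_gene_variant", "3_prime_UTR_variant", "5_prime_UTR_variant"}
)
DAMAGING_SIFT = frozenset({"deleterious", "damaging"})
DAMAGING_POLYPHEN = frozenset({"possibly_damaging", "probably_damaging"})

VariantKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample (positions 1-based)."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[int, int]
    gq: float
    allele_depths: tuple[int, ...]
    flank_seq: str | None = None
    flank_offset: int | None = None  # 0-based index of `pos` within flank_seq
    consequence: str | None = None
    sift: str | None = None
    polyphen: str | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if any(d < 0 for d in self.allele_depths):
            raise ValueError("allele depths must be non-negative")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_nonref(self) -> bool:
        return any(a > 0 for a in self.genotype)

    @property
    def vaf(self) -> float:
        """Variant allele frequency summed over all alternate alleles."""
        total = sum(self.allele_depths)
        if total == 0:
            return 0.0
        return sum(self.allele_depths[1:]) / total


@dataclass(frozen=True)
class SharingClass:
    category: str  # germline | truncal | shared | private
    tumor_specific: bool
    presence: frozenset[str] = field(default_factory=frozenset)  # carrying sample ids


@dataclass(frozen=True)
class DriverCall:
    patient_id: str
    key: VariantKey
    gene: str | None
    is_candidate_driver: bool
    rationale: str | None

    def __post_init__(self) -> None:
        if self.is_candidate_driver != (self.rationale is not None):
            raise ValueError("rationale must be present iff is_candidate_driver")


# ----------------------------------------------------------------------
# homopolymer context filter
# ----------------------------------------------------------------------
def detect_homopolymer_runs(seq: str, min_len: int = 4) -> list[tuple[int, int, str]]:
    """Maximal runs of identical non-N bases with length >= ``min_len``.

    Coordinates are local to ``seq``, 1-based inclusive.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if seq[i] != "N" and j - i >= min_len:
            runs.append((i + 1, j, seq[i]))
        i = j
    return runs


def near_homopolymer(
    flank_seq: str,
    flank_offset: int,
    ref: str,
    alt: str,
    min_len: int = 4,
    max_dist: int = 1,
) -> bool:
    """True if the variant's affected reference span lies within ``max_dist``
    of a homopolymer run of >= ``min_len`` bases in the flanking context.

    Distance 0 means inside the run; 1 means immediately adjacent.  The
    affected span is the substituted/deleted reference bases, or the single
    anchor base for pure insertions.
    """
    span = max(1, len(ref))
    lo, hi = flank_offset + 1, flank_offset + span  # 1-based within flank
    for start, end, _base in detect_homopolymer_runs(flank_seq, min_len=min_len):
        if start > hi:
            dist = start - hi
        elif end < lo:
            dist = lo - end
        else:
            dist = 0
        if dist <= max_dist:
            return True
    return False


class ContextUnavailableError(ValueError):
    """Raised when a variant has no resolvable flanking reference sequence."""


def filter_variants(
    calls: list[VariantCall],
    reference: "object | None" = None,
    min_gq: float = 60.0,
    min_vaf: float = 0.10,
    hp_min_len: int = 4,
    hp_max_dist: int = 1,
    flank_pad: int = 10,
) -> list[VariantCall]:
    """Quality-filter calls; input order is preserved.

    A call is kept iff GQ >= ``min_gq`` AND VAF >= ``min_vaf`` AND it is not
    within ``hp_max_dist`` bp of a homopolymer run of >= ``hp_min_len`` bases.
    ``reference`` (any object with ``fetch(chrom, start0, end0)``, e.g. a
    :class:`pyfaidx.Fasta`-like accessor) is consulted only for calls lacking
    an embedded ``flank_seq``; if neither is available the call is rejected
    loudly rather than silently kept.
    """
    kept: list[VariantCall] = []
    for call in calls:
        if call.gq < min_gq or call.vaf < min_vaf:
            continue
        flank, offset = call.flank_seq, call.flank_offset
        if flank is None:
            if reference is None:
                raise ContextUnavailableError(
                    f"context unavailable for {call.chrom}:{call.pos} {call.ref}>{call.alt}"
                )
            start0 = max(0, call.pos - 1 - flank_pad)
            end0 = call.pos - 1 + max(1, len(call.ref)) + flank_pad
            flank = str(reference.fetch(call.chrom, start0, end0))
            offset = call.pos - 1 - start0
        if offset is None:
            raise ContextUnavailableError(
                f"context unavailable for {call.chrom}:{call.pos} (flank without offset)"
            )
        if near_homopolymer(flank, offset, call.ref, call.alt, hp_min_len, hp_max_dist):
            continue
        kept.append(call)
    return kept


# ----------------------------------------------------------------------
# sharing classification
# ----------------------------------------------------------------------
def classify_sharing(
    calls: list[VariantCall],
    meta: list["SampleMeta"],
) -> dict[tuple[str, VariantKey], SharingClass]:
    """Classify each (patient, variant) by the degree of genotype sharing.

    germline: non-reference genotype in the patient's own normal sample;
    truncal: all of the patient's tumor samples; private: exactly one tumor
    sample; shared: at least two but not all.  ``tumor_specific`` is True when
    the variant is absent from the patient's normal and from every normal in
    the cohort.  A patient without a normal sample is classified against the
    cohort normal panel only (no germline category available).
    """
    from .design import ROLE_NORMAL  # local import to avoid cycle at module load

    meta_by_sample = {m.sample_id: m for m in meta}
    tumor_by_patient: dict[str, set[str]] = {}
    normal_by_patient: dict[str, set[str]] = {}
    for m in meta:
        if m.is_tumor:
            tumor_by_patient.setdefault(m.patient_id, set()).add(m.sample_id)
        elif m.role == ROLE_NORMAL:
            normal_by_patient.setdefault(m.patient_id, set()).add(m.sample_id)

    presence: dict[tuple[str, VariantKey], set[str]] = {}
    cohort_normal_keys: set[VariantKey] = set()
    for call in calls:
        if not call.is_nonref:
            continue
        m = meta_by_sample.get(call.sample_id)
        if m is None:
            raise ValueError(f"sample {call.sample_id!r} missing from metadata")
        presence.setdefault((call.patient_id, call.key), set()).add(call.sample_id)
        if m.role == ROLE_NORMAL:
            cohort_normal_keys.add(call.key)

    out: dict[tuple[str, VariantKey], SharingClass] = {}
    for (pid, key), samples in presence.items():
        tumors = tumor_by_patient.get(pid, set())
        if not tumors:
            raise ValueError(f"patient {pid!r} has no tumor samples")
        normals = normal_by_patient.get(pid, set())
        in_own_normal = bool(samples & normals)
        tumor_present = samples & tumors
        if in_own_normal:
            category = CATEGORY_GERMLINE
        else:
            k = len(tumor_present)
            if k == len(tumors):
                category = CATEGORY_TRUNCAL
            elif k == 1:
                category = CATEGORY_PRIVATE
            elif k >= 2:
                category = CATEGORY_SHARED
            else:  # present only in another patient's normal: not this patient's call
                continue
        tspec = (not in_own_normal) and key not in cohort_normal_keys
        out[(pid, key)] = SharingClass(category, tspec, frozenset(samples))
    return out


# ----------------------------------------------------------------------
# candidate drivers
# ----------------------------------------------------------------------
def call_candidate_drivers(
    calls: list[VariantCall],
    strict: bool = True,
) -> list[DriverCall]:
    """Apply the consequence-based candidate-driver rules.

    Candidate iff the consequence is frameshift / in-frame deletion / stop
    gained / splice acceptor / splice donor, OR missense predicted at least
    possibly damaging by SIFT or PolyPhen-2.  Everything else is a putative
    passenger.  Unknown consequence terms raise in strict mode (default) and
    are passengers in lenient mode.  One verdict per (patient, variant).
    """
    seen: dict[tuple[str, VariantKey], VariantCall] = {}
    order: list[tuple[str, VariantKey]] = []
    for call in calls:
        k = (call.patient_id, call.key)
        if k not in seen:
            seen[k] = call
            order.append(k)

    out: list[DriverCall] = []
    for pid, key in order:
        call = seen[(pid, key)]
        cons = call.consequence
        if cons is None:
            raise ValueError(f"variant {key} has no consequence annotation")
        rationale: str | None = None
        if cons in DRIVER_CONSEQUENCES:
            rationale = f"consequence:{cons}"
        elif cons == MISSENSE:
            if call.sift in DAMAGING_SIFT:
                rationale = "missense_damaging:sift"
            elif call.polyphen in DAMAGING_POLYPHEN:
                rationale = "missense_damaging:polyphen"
        elif cons not in PASSENGER_CONSEQUENCES:
            if strict:
                raise ValueError(f"unknown consequence term {cons!r}")
        out.append(DriverCall(pid, key, call.gene, rationale is not None, rationale))
    return out


# ----------------------------------------------------------------------
# count comparisons
# ----------------------------------------------------------------------
def count_private_mutations(
    sharing: dict[tuple[str, VariantKey], SharingClass],
    meta: list["SampleMeta"],
) -> pd.DataFrame:
    """Per-patient private-mutation counts.

    Columns: ``biopsy`` (count in the single biopsy), ``neph_median`` (median
    of the per-nephrectomy counts) plus one ``neph_<k>`` column per
    nephrectomy sample.  Only tumor-specific somatic variants whose presence
    set is exactly one sample contribute.
    """
    from .design import ROLE_BIOPSY, ROLE_NEPHRECTOMY

    per_sample: dict[str, int] = {m.sample_id: 0 for m in meta if m.is_tumor}
    for (pid, _key), sc in sharing.items():
        if sc.category == CATEGORY_PRIVATE and sc.tumor_specific:
            (sample,) = tuple(sc.presence)
            per_sample[sample] += 1

    rows = {}
    for pid in sorted({m.patient_id for m in meta if m.is_tumor}):
        p_samples = [m for m in meta if m.patient_id == pid and m.is_tumor]
        biopsy = [m for m in p_samples if m.role == ROLE_BIOPSY]
        nephs = sorted(
            (m for m in p_samples if m.role == ROLE_NEPHRECTOMY), key=lambda m: m.sample_id
        )
        row: dict[str, float] = {
            "biopsy": per_sample[biopsy[0].sample_id] if biopsy else np.nan
        }
        neph_counts = [per_sample[m.sample_id] for m in nephs]
        for k, c in enumerate(neph_counts):
            row[f"neph_{k + 1}"] = c
        row["neph_median"] = float(np.median(neph_counts)) if neph_counts else np.nan
        rows[pid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_private_counts(per_patient: pd.DataFrame) -> dict:
    """Unpaired two-sided Student t: biopsy vs median-nephrectomy private counts.

    Also reports the per-patient (greater in biopsy / greater in nephrectomy /
    equal) split.  Both groups constant and equal gives p = 1; constant but
    unequal is flagged as a degenerate comparison.
    """
    df = per_patient.dropna(subset=["biopsy", "neph_median"])
    if len(df) < 2:
        raise ValueError("need >= 2 patients with both biopsy and nephrectomy counts")
    x = df["biopsy"].to_numpy(float)
    y = df["neph_median"].to_numpy(float)
    split = {
        "biopsy_greater": int((x > y).sum()),
        "nephrectomy_greater": int((x < y).sum()),
        "equal": int((x == y).sum()),
    }
    note = None
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            t, p = 0.0, 1.0
        else:
            t, p, note = math.nan, math.nan, "zero variance in both groups with unequal means"
    else:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        t, p = float(t), float(p)
    return {"t": t, "p": p, "df": len(x) + len(y) - 2, "split": split, "note": note}


def wilcoxon_rank_sum(x, y, exact_max: int = 10) -> dict:
    """Two-sided Wilcoxon rank-sum test.

    Exact null distribution (enumeration over all group assignments of the
    pooled midranks) when both group sizes are <= ``exact_max``; otherwise a
    normal approximation with tie correction.  The two-sided exact p doubles
    the smaller tail and is capped at 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    t_obs = ranks[:nx].sum()
    n = nx + ny
    if nx <= exact_max and ny <= exact_max:
        sums = np.fromiter(
            (sum(ranks[list(c)]) for c in itertools.combinations(range(n), nx)),
            dtype=float,
            count=math.comb(n, nx),
        )
        eps = 1e-9
        lower = np.mean(sums <= t_obs + eps)
        upper = np.mean(sums >= t_obs - eps)
        p = min(1.0, 2.0 * min(lower, upper))
        return {"statistic": float(t_obs), "p": float(p), "method": "exact"}
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return {"statistic": float(t_obs), "p": 1.0, "method": "normal"}
    z = (t_obs - mu) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return {"statistic": float(t_obs), "p": float(p), "method": "normal"}


def compare_driver_counts(
    drivers: list[DriverCall],
    sharing: dict[tuple[str, VariantKey], SharingClass],
    meta: list["SampleMeta"],
) -> pd.DataFrame:
    """Per-gene biopsy-vs-nephrectomy candidate-driver count comparison.

    For each gene: the mean number of candidate driver mutations per biopsy
    sample vs per nephrectomy sample, with a two-sided Wilcoxon rank-sum
    p-value over the per-sample counts.  Genes absent from all samples get an
    NA p-value.
    """
    from .design import ROLE_BIOPSY, ROLE_NEPHRECTOMY

    biopsy_ids = [m.sample_id for m in meta if m.role == ROLE_BIOPSY]
    neph_ids = [m.sample_id for m in meta if m.role == ROLE_NEPHRECTOMY]
    genes = sorted({d.gene for d in drivers if d.gene is not None})
    counts = {g: {s: 0 for s in biopsy_ids + neph_ids} for g in genes}
    for d in drivers:
        if not d.is_candidate_driver or d.gene is None:
            continue
        sc = sharing.get((d.patient_id, d.key))
        if sc is None or sc.category == CATEGORY_GERMLINE:
            continue
        for s in sc.presence:
            if s in counts[d.gene]:
                counts[d.gene][s] += 1

    rows = []
    for g in genes:
        bx = np.array([counts[g][s] for s in biopsy_ids], float)
        nx_ = np.array([counts[g][s] for s in neph_ids], float)
        if bx.sum() == 0 and nx_.sum() == 0:
            rows.append((g, 0.0, 0.0, np.nan))
            continue
        res = wilcoxon_rank_sum(bx, nx_)
        rows.append((g, float(bx.mean()), float(nx_.mean()), res["p"]))
    return pd.DataFrame(
        rows, columns=["gene", "mean_biopsy", "mean_nephrectomy", "p"]
    ).set_index("gene")
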