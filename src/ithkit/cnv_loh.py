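"""B-allele-frequency LOH segmentation and a simple coverage-ratio CNV caller.

LOH detection works on the mirrored deviation ``d_j = |BAF_j - 0.5|`` of
tumor BAFs at SNPs that are clearly heterozygous in the matched normal
(normal BAF in [0.4, 0.6]).  Mirroring removes phase ambiguity, which is
unobservable from unphased SNPs.  Segmentation is recursive binary splitting:
at each step the split maximizing the two-sample Welch t statistic between the
flanks is taken while its p-value stays below ``alpha``.

The CNV caller compares median-normalized per-target coverage between a tumor
sample and the matched normal, averages log2 ratios per gene, and thresholds
the result into loss / neutral / gain states.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BAFRecord

STATE_LOSS = "loss"
STATE_NEUTRAL = "neutral"
STATE_GAIN = "gain"


@dataclass(frozen=True)
class LOHSegment:
    chrom: str
    start: int            # genomic position of first SNP, 1-based inclusive
    end: int              # genomic position of last SNP
    mean_dev: float       # mean |BAF - 0.5| over the segment's tumor SNPs
    n_snps: int
    is_loh: bool
    subclonal: bool       # LOH but BAF not shifted (near) entirely to 0/1
    idx_start: int        # 0-based index bounds within the chromosome's SNP list
    idx_end: int


@dataclass(frozen=True)
class CNVSegment:
    chrom: str
    start: int
    end: int
    gene: str
    log2_ratio: float
    state: str


# ----------------------------------------------------------------------
# het-SNP selection
# ----------------------------------------------------------------------
def select_het_snps(
    normal_records: list[BAFRecord],
    lo: float = 0.4,
    hi: float = 0.6,
) -> tuple[list[tuple[str, int]], int]:
    """Sites clearly heterozygous in the normal: ``lo <= BAF <= hi`` inclusive.

    Bi-allelic sites only; zero-depth sites are skipped and counted.  Returns
    ``(sites, n_skipped_zero_depth)`` with sites as (chrom, pos) pairs in
    input order.
    """
    sites: list[tuple[str, int]] = []
    skipped = 0
    for rec in normal_records:
        if rec.n_alleles != 2:
            continue
        if rec.depth == 0:
            skipped += 1
            continue
        if lo <= rec.baf <= hi:
            sites.append((rec.chrom, rec.pos))
    return sites, skipped


# ----------------------------------------------------------------------
# binary segmentation on mirrored BAF
# ----------------------------------------------------------------------
def _welch_t_splits(d: np.ndarray, min_size: int) -> tuple[int, float] | None:
    """Best split of ``d`` into two flanks of >= min_size points each.

    Returns (split index, two-sided Welch p) or None when no admissible split.
    """
    n = len(d)
    if n < 2 * min_size:
        return None
    c1 = np.cumsum(d)
    c2 = np.cumsum(d * d)
    s = np.arange(min_size, n - min_size + 1)  # left block = d[:s]
    n1 = s.astype(float)
    n2 = n - n1
    m1 = c1[s - 1] / n1
    m2 = (c1[-1] - c1[s - 1]) / n2
    ss1 = c2[s - 1] - n1 * m1**2
    ss2 = (c2[-1] - c2[s - 1]) - n2 * m2**2
    v1 = np.maximum(ss1 / np.maximum(n1 - 1, 1), 1e-12)
    v2 = np.maximum(ss2 / np.maximum(n2 - 1, 1), 1e-12)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    best = int(np.argmax(np.abs(t)))
    df = se2[best] ** 2 / (
        (v1[best] / n1[best]) ** 2 / max(n1[best] - 1, 1)
        + (v2[best] / n2[best]) ** 2 / max(n2[best] - 1, 1)
    )
    p = 2.0 * stats.t.sf(abs(t[best]), df)
    return int(s[best]), float(p)


def _binseg(d: np.ndarray, lo: int, hi: int, min_size: int, alpha: float, breaks: list[int]) -> None:
    res = _welch_t_splits(d[lo:hi], min_size)
    if res is None:
        return
    split, p = res
    if p >= alpha:
        return
    cut = lo + split
    breaks.append(cut)
    _binseg(d, lo, cut, min_size, alpha, breaks)
    _binseg(d, cut, hi, min_size, alpha, breaks)


def _refine_breaks(d: np.ndarray, breaks: list[int], alpha: float, rounds: int = 3) -> list[int]:
    """Relocate each breakpoint to the best split between its neighbors and
    drop breakpoints that are no longer significant.

    The recursive search is constrained by the minimum segment size, which can
    leave a changepoint stranded a few points off the true boundary (the true
    split being closer to a block edge than ``min_size``); re-optimizing each
    breakpoint over its full flanking window removes that bias.
    """
    bs = sorted(set(breaks))
    for _ in range(rounds):
        if not bs:
            return bs
        bounds = [0] + bs + [len(d)]
        moved: list[int] = []
        for k in range(len(bs)):
            lo, hi = bounds[k], bounds[k + 2]
            res = _welch_t_splits(d[lo:hi], min_size=2)
            if res is None:
                continue
            split, p = res
            if p < alpha:
                moved.append(lo + split)
        new = sorted(set(moved))
        if new == bs:
            break
        bs = new
    return bs


def segment_loh(
    tumor_records: list[BAFRecord],
    min_snps: int = 10,
    deviation_threshold: float = 0.15,
    alpha: float = 0.01,
    clonal_threshold: float = 0.45,
) -> tuple[list[LOHSegment], list[str]]:
    """Segment one tumor sample's BAF track into LOH / non-LOH regions.

    ``tumor_records`` must be restricted to germline-het sites and sorted by
    (chrom, pos).  Segments never span a chromosome boundary.  A segment is
    flagged LOH when its mean mirrored deviation is >= ``deviation_threshold``
    and it has >= ``min_snps`` SNPs; adjacent LOH segments are merged.  LOH
    with mean deviation below ``clonal_threshold`` is additionally flagged
    subclonal (the allele fraction has not shifted entirely to 0 or 1).

    Returns ``(segments, notes)``; chromosomes with fewer than ``min_snps``
    informative sites produce a note instead of calls.
    """
    by_chrom: dict[str, list[BAFRecord]] = {}
    for rec in tumor_records:
        by_chrom.setdefault(rec.chrom, []).append(rec)

    segments: list[LOHSegment] = []
    notes: list[str] = []
    for chrom, recs in by_chrom.items():
        pos = np.array([r.pos for r in recs])
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"records on {chrom} are not sorted by position")
        d = np.array([abs(r.baf - 0.5) for r in recs])
        if len(d) < min_snps:
            notes.append(f"{chrom}: insufficient informative SNPs ({len(d)} < {min_snps})")
            continue
        breaks: list[int] = []
        _binseg(d, 0, len(d), min_snps, alpha, breaks)
        breaks = _refine_breaks(d, breaks, alpha)
        bounds = [0] + breaks + [len(d)]
        raw: list[LOHSegment] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            mean_dev = float(d[a:b].mean())
            is_loh = mean_dev >= deviation_threshold and (b - a) >= min_snps
            raw.append(
                LOHSegment(
                    chrom=chrom,
                    start=int(pos[a]),
                    end=int(pos[b - 1]),
                    mean_dev=mean_dev,
                    n_snps=b - a,
                    is_loh=is_loh,
                    subclonal=is_loh and mean_dev < clonal_threshold,
                    idx_start=a,
                    idx_end=b - 1,
                )
            )
        # merge neighboring LOH segments
        merged: list[LOHSegment] = []
        for seg in raw:
            if merged and merged[-1].is_loh and seg.is_loh:
                prev = merged.pop()
                n = prev.n_snps + seg.n_snps
                mean_dev = (prev.mean_dev * prev.n_snps + seg.mean_dev * seg.n_snps) / n
                merged.append(
                    LOHSegment(
                        chrom=chrom,
                        start=prev.start,
                        end=seg.end,
                        mean_dev=float(mean_dev),
                        n_snps=n,
                        is_loh=True,
                        subclonal=mean_dev < clonal_threshold,
                        idx_start=prev.idx_start,
                        idx_end=seg.idx_end,
                    )
                )
            else:
                merged.append(seg)
        segments.extend(merged)
    return segments, notes


# ----------------------------------------------------------------------
# CNV calling on normalized target coverage
# ----------------------------------------------------------------------
def call_cnv(
    tumor_coverage: pd.Series,
    normal_coverage: pd.Series,
    targets: pd.DataFrame,
    loss_threshold: float = -0.4,
    gain_threshold: float = 0.3,
) -> list[CNVSegment]:
    """Gene-level CNV states from median-normalized tumor/normal coverage.

    Each sample is scaled by its median target coverage (making the call
    invariant to global multiplicative scaling of either sample); per-target
    log2 ratios are averaged within each gene, and thresholds assign the
    state.  Targets with zero normal coverage are masked.
    """
    if not (loss_threshold < 0 < gain_threshold):
        raise ValueError("thresholds must partition the log2-ratio axis around 0")
    t = tumor_coverage.reindex(targets.index).to_numpy(float)
    n = normal_coverage.reindex(targets.index).to_numpy(float)
    mask = n > 0
    if not mask.any():
        raise ValueError("no targets with positive normal coverage")
    t_norm = t / np.median(t[mask])
    n_norm = n / np.median(n[mask])
    lr = np.full(len(targets), np.nan)
    lr[mask] = np.log2(np.maximum(t_norm[mask], 1e-12) / n_norm[mask])

    out: list[CNVSegment] = []
    for gene, sub in targets.assign(lr=lr).groupby("gene", sort=True):
        vals = sub["lr"].dropna()
        if vals.empty:
            continue
        mean_lr = float(vals.mean())
        if mean_lr < loss_threshold:
            state = STATE_LOSS
        elif mean_lr > gain_threshold:
            state = STATE_GAIN
        else:
            state = STATE_NEUTRAL
        out.append(
            CNVSegment(
                chrom=str(sub["chrom"].iloc[0]),
                start=int(sub["start"].min()),
                end=int(sub["end"].max()),
                gene=str(gene),
                log2_ratio=mean_lr,
                state=state,
            )
        )
    return out


def compare_cnv_counts(pre: dict[str, float], post: dict[str, float]) -> dict:
    """Two-sided paired Student t on per-patient (post - pre) CNV counts.

    ``pre`` maps patient -> biopsy CNV count, ``post`` maps patient -> mean
    CNV count over nephrectomy samples.  All-zero differences give p = 1.
    """
    patients = sorted(set(pre) & set(post))
    if len(patients) < 2:
        raise ValueError("need >= 2 patients with both pre and post CNV counts")
    diffs = np.array([post[p] - pre[p] for p in patients], float)
    if np.allclose(diffs, 0.0):
        return {"t": 0.0, "p": 1.0, "df": len(diffs) - 1, "n": len(diffs)}
    if np.ptp(diffs) == 0:
        # constant non-zero differences: mean shift with zero variance
        return {"t": math.inf if diffs[0] > 0 else -math.inf, "p": 0.0,
                "df": len(diffs) - 1, "n": len(diffs)}
    t, p = stats.ttest_rel(np.array([post[p] for p in patients], float),
                           np.array([pre[p] for p in patients], float))
    return {"t": float(t), "p": float(p), "df": len(diffs) - 1, "n": len(diffs)}
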