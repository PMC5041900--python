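"""Count-based differential methylation with precision weights and moderated t.

The engine follows the standard workflow for capture-sequencing methylation
counts: promoter/coverage core filtering, log2 counts-per-million, quantile
normalization, observation-level precision weights from an empirical
mean-variance trend (lowess of sqrt-residual-sd against average log count),
per-core weighted least squares with empirical-Bayes variance shrinkage, and
Benjamini-Hochberg FDR restricted to the target cores.  Per-patient
methylation levels are additionally binned into four cohort-quantile
categories, the top two of which define the hypermethylated state.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .design import ROLE_BIOPSY, ROLE_NEPHRECTOMY, SampleMeta

CATEGORY_LABELS = (
    "No to low methylation",
    "Low to medium",
    "Medium to high",
    "High to very high",
)


# ----------------------------------------------------------------------
# core filtering and transforms
# ----------------------------------------------------------------------
def filter_cores(counts: pd.DataFrame, cores: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep promoter-annotated cores with mean coverage >= 1 fragment.

    Returns the filtered count matrix and the number of cores removed by each
    criterion.  Raises if nothing survives.
    """
    cores = cores.reindex(counts.index)
    if cores["promoter"].isna().any():
        missing = counts.index[cores["promoter"].isna()][:3].tolist()
        raise ValueError(f"count matrix rows missing from core annotations, e.g. {missing}")
    promoter = cores["promoter"].astype(bool).to_numpy()
    mean_ok = counts.mean(axis=1).to_numpy() >= 1.0
    keep = promoter & mean_ok
    stats_ = {
        "removed_non_promoter": int((~promoter).sum()),
        "removed_low_coverage": int((promoter & ~mean_ok).sum()),
        "kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError("no analyzable cores after filtering")
    return counts.loc[keep], stats_


def logcpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """log2 counts-per-million with the standard half-count offset:

        x = log2((y + 0.5) / (R + 1) * 1e6)
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib = lib_sizes.reindex(counts.columns).to_numpy(float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    x = np.log2((counts.to_numpy(float) + 0.5) / (lib + 1.0) * 1e6)
    return pd.DataFrame(x, index=counts.index, columns=counts.columns)


def quantile_normalize(X: pd.DataFrame, ties: str = "stable") -> pd.DataFrame:
    """Force every column onto the mean order-statistic distribution.

    ``ties="stable"`` assigns each value the rank-mean at its (stable-sorted)
    position, so all columns have *identical sorted vectors exactly*, ties
    included.  ``ties="average"`` instead gives tied values within a column
    the mean of their tied rank-means (the microarray convention), which
    sacrifices the exact post-condition in the presence of ties.
    """
    if X.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    A = X.to_numpy(float)
    order = np.argsort(A, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(A, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(A)
    if ties == "stable":
        np.put_along_axis(out, order, rank_means[:, None].repeat(A.shape[1], axis=1), axis=0)
    elif ties == "average":
        for c in range(A.shape[1]):
            col_sorted = sorted_vals[:, c]
            vals = rank_means.copy()
            start = 0
            for i in range(1, len(col_sorted) + 1):
                if i == len(col_sorted) or col_sorted[i] != col_sorted[start]:
                    vals[start:i] = vals[start:i].mean()
                    start = i
            out[order[:, c], c] = vals
    else:
        raise ValueError("ties must be 'stable' or 'average'")
    return pd.DataFrame(out, index=X.index, columns=X.columns)


# ----------------------------------------------------------------------
# design matrices
# ----------------------------------------------------------------------
def make_design(meta: list[SampleMeta], blocked: bool = True) -> pd.DataFrame:
    """Design matrix for the post-vs-pre contrast over tumor samples.

    ``blocked`` (default) adds patient fixed effects, appropriate for the
    patient-matched sampling; the unblocked alternative is a plain two-group
    comparison.  The treatment column is named ``treat``.
    """
    tumor = [m for m in meta if m.is_tumor]
    if not tumor:
        raise ValueError("no tumor samples in metadata")
    idx = [m.sample_id for m in tumor]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(tumor))}
    if blocked:
        patients = sorted({m.patient_id for m in tumor})
        for pid in patients[1:]:
            cols[f"patient_{pid}"] = np.array(
                [1.0 if m.patient_id == pid else 0.0 for m in tumor]
            )
    cols["treat"] = np.array([1.0 if m.timepoint == "post" else 0.0 for m in tumor])
    X = pd.DataFrame(cols, index=idx)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


# ----------------------------------------------------------------------
# voom-style precision weights
# ----------------------------------------------------------------------
def _batched_wls(Y: np.ndarray, X: np.ndarray, W: np.ndarray | None):
    """Per-row (weighted) least squares for a shared design matrix.

    Returns (beta, s2, df, unscaled_cov) where unscaled_cov[g] is
    (X'W_gX)^-1 so that cov(beta_g) = s2_g * unscaled_cov[g].
    """
    G, n = Y.shape
    p = X.shape[1]
    df = n - p
    if df < 1:
        raise ValueError("at least one residual degree of freedom is required")
    if W is None:
        XtX = X.T @ X
        xtx_inv = np.linalg.inv(XtX)
        beta = Y @ X @ xtx_inv
        resid = Y - beta @ X.T
        s2 = (resid**2).sum(axis=1) / df
        cov = np.broadcast_to(xtx_inv, (G, p, p))
        return beta, s2, df, cov
    XtWX = np.einsum("gn,np,nq->gpq", W, X, X, optimize=True)
    XtWy = np.einsum("gn,np,gn->gp", W, X, Y, optimize=True)
    cov = np.linalg.inv(XtWX)
    beta = np.einsum("gpq,gq->gp", cov, XtWy)
    resid = Y - beta @ X.T
    s2 = (W * resid**2).sum(axis=1) / df
    return beta, s2, df, cov


def voom_weights(
    E: pd.DataFrame,
    design: pd.DataFrame,
    lib_sizes: pd.Series,
    span: float = 0.5,
    min_loci: int = 50,
) -> np.ndarray:
    """Observation-level precision weights from the mean-variance trend.

    Per-core OLS residual standard deviations are square-rooted and lowess-
    smoothed against average log2 count; the trend evaluated at each fitted
    log2 count predicts that observation's sd, and the weight is the inverse
    fourth power (i.e. inverse predicted variance of the log-cpm value).
    Falls back to unit weights (with a warning) below ``min_loci`` loci.
    """
    Y = E.to_numpy(float)
    X = design.reindex(E.columns).to_numpy(float)
    G, n = Y.shape
    if G < min_loci:
        warnings.warn(
            f"only {G} loci (< {min_loci}); falling back to unit precision weights",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.ones_like(Y)
    lib = lib_sizes.reindex(E.columns).to_numpy(float)
    beta, s2, _df, _ = _batched_wls(Y, X, None)
    sigma = np.sqrt(s2)
    sx = Y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - math.log2(1e6)
    sy = np.sqrt(sigma)
    trend = sm_lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]
    fitted = beta @ X.T
    lam = fitted + (np.log2(lib + 1.0) - math.log2(1e6))[None, :]
    lam = np.clip(lam, tx[0], tx[-1])
    pred_sqrt_sd = np.interp(lam, tx, ty)
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-4)
    return pred_sqrt_sd**-4.0


# ----------------------------------------------------------------------
# empirical-Bayes moderated t
# ----------------------------------------------------------------------
def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma is positive")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


@dataclass
class ModeratedFit:
    """Per-core moderated test results plus the shared shrinkage prior."""

    table: pd.DataFrame        # logFC, se, s2, t, p (index = core ids)
    s0_squared: float
    d0: float                  # prior degrees of freedom (may be inf)
    residual_df: float
    design_columns: list[str] = field(default_factory=list)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimation of the scaled-F prior (s0^2, d0) from log s2.

    Uses the standard empirical-Bayes moment match on z = log(s2):
    E[z] and Var[z] identify d0 via the trigamma function and s0^2 via the
    digamma function.  Near-identical variances give d0 = +inf.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return s0_sq, d0


def fit_moderated(
    E: pd.DataFrame,
    design: pd.DataFrame,
    weights: np.ndarray | None = None,
    coef: str = "treat",
    prior: tuple[float, float] | None = None,
) -> ModeratedFit:
    """Weighted least squares per core + empirical-Bayes variance moderation.

    The reported ``logFC`` is the coefficient of ``coef`` (post minus pre by
    the design convention).  ``prior`` overrides the estimated (s0^2, d0),
    which is mainly useful for studying the shrinkage limits: d0 = 0 recovers
    the ordinary t statistic exactly.
    """
    if coef not in design.columns:
        raise ValueError(f"design has no column {coef!r}")
    Y = E.to_numpy(float)
    X = design.reindex(E.columns).to_numpy(float)
    beta, s2, df, cov = _batched_wls(Y, X, weights)
    ci = list(design.columns).index(coef)
    logfc = beta[:, ci]
    u2 = cov[:, ci, ci]  # unscaled variance of the coefficient

    if prior is not None:
        s0_sq, d0 = prior
    else:
        s0_sq, d0 = squeeze_variances(s2, df)
    if math.isinf(d0):
        var_post = np.full_like(s2, s0_sq)
        total_df = np.inf
    else:
        var_post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = d0 + df
    se = np.sqrt(np.maximum(u2 * var_post, 1e-300))
    t = logfc / se
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "se": se,
            "s2": s2,
            "t": t,
            "p": p,
        },
        index=E.index,
    )
    return ModeratedFit(
        table=table,
        s0_squared=float(s0_sq),
        d0=float(d0),
        residual_df=float(df),
        design_columns=list(design.columns),
    )


def bh_fdr(p, restrict_to=None) -> np.ndarray:
    """Benjamini-Hochberg adjusted values over ``restrict_to`` only.

    ``restrict_to`` is a boolean mask or an index array into ``p``; positions
    outside the restriction get NaN.  The classic step-up definition:
    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if restrict_to is None:
        mask = np.ones(len(p), bool)
    else:
        restrict_to = np.asarray(restrict_to)
        if restrict_to.dtype == bool:
            mask = restrict_to
        else:
            mask = np.zeros(len(p), bool)
            mask[restrict_to] = True
    m = int(mask.sum())
    if m == 0:
        raise ValueError("empty restriction set for FDR")
    sub = p[mask]
    order = np.argsort(sub, kind="stable")
    q_sorted = sub[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q_sub = np.empty(m)
    q_sub[order] = q_sorted
    out = np.full(len(p), np.nan)
    out[mask] = q_sub
    return out


# ----------------------------------------------------------------------
# clustering and per-patient categories
# ----------------------------------------------------------------------
def top_variance_matrix(E: pd.DataFrame, k: int = 1000) -> pd.DataFrame:
    """The k largest-variance loci (all, with a warning, if fewer exist)."""
    v = E.var(axis=1, ddof=1)
    if len(E) < k:
        warnings.warn(
            f"only {len(E)} loci available (< k={k}); clustering on all of them",
            RuntimeWarning,
            stacklevel=2,
        )
        k = len(E)
    top = v.sort_values(ascending=False, kind="stable").index[:k]
    return E.loc[top]


def top_variance_clustering(E: pd.DataFrame, k: int = 1000):
    """Complete-linkage Euclidean dendrogram on the top-k-variance loci."""
    from .phylo import cohort_dendrogram

    sub = top_variance_matrix(E, k)
    return cohort_dendrogram(sub.T, metric="euclidean", linkage_method="complete")


def categorize_region(
    values: pd.Series,
    meta: list[SampleMeta],
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Four-category cohort-quantile methylation state for one region.

    Quartile boundaries (25/50/75th percentiles, linear-interpolation
    quantiles) are computed over all samples' normalized values for the
    region; each patient's pre value is the biopsy value and the post value is
    the mean over nephrectomy samples.  Intervals are left-closed: a value
    exactly at a boundary falls into the higher category.  Categories 2-3
    ("Medium to high", "High to very high") define the hypermethylated state.
    Degenerate regions (all values equal) collapse to the lowest category.

    Returns (per-patient table, boundaries, excluded patients).
    """
    vals = values.to_numpy(float)
    boundaries = np.quantile(vals, [0.25, 0.5, 0.75])
    degenerate = np.ptp(vals) == 0

    def category(v: float) -> int:
        if degenerate:
            return 0
        return int(np.sum(v >= boundaries))

    by_sample = values.to_dict()
    patients = sorted({m.patient_id for m in meta if m.is_tumor})
    rows = {}
    excluded: list[str] = []
    for pid in patients:
        pre_vals = [
            by_sample[m.sample_id]
            for m in meta
            if m.patient_id == pid and m.role == ROLE_BIOPSY and m.sample_id in by_sample
        ]
        post_vals = [
            by_sample[m.sample_id]
            for m in meta
            if m.patient_id == pid and m.role == ROLE_NEPHRECTOMY and m.sample_id in by_sample
        ]
        if not pre_vals or not post_vals:
            excluded.append(pid)
            continue
        pre = float(np.mean(pre_vals))
        post = float(np.mean(post_vals))
        c_pre, c_post = category(pre), category(post)
        rows[pid] = {
            "pre_value": pre,
            "post_value": post,
            "pre_category": CATEGORY_LABELS[c_pre],
            "post_category": CATEGORY_LABELS[c_post],
            "pre_hyper": c_pre >= 2,
            "post_hyper": c_post >= 2,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table, boundaries, excluded


def hypermethylation_summary(region_table: pd.DataFrame) -> dict[str, float]:
    """Percent of patients hypermethylated pre and post treatment."""
    n = len(region_table)
    if n == 0:
        return {"pre_pct": math.nan, "post_pct": math.nan, "n_patients": 0}
    return {
        "pre_pct": 100.0 * float(region_table["pre_hyper"].mean()),
        "post_pct": 100.0 * float(region_table["post_hyper"].mean()),
        "n_patients": n,
    }


def responder_comparison(
    deltas: dict[str, float],
    response: dict[str, str],
    good_label: str = "good",
    poor_label: str = "poor",
) -> dict:
    """Unpaired two-sided Student t on post-minus-pre deltas, good vs poor."""
    good = [deltas[p] for p in deltas if response.get(p) == good_label]
    poor = [deltas[p] for p in deltas if response.get(p) == poor_label]
    if len(good) < 2 or len(poor) < 2:
        raise ValueError("need >= 2 patients per response group")
    t, p = stats.ttest_ind(good, poor, equal_var=True)
    return {"t": float(t), "p": float(p), "df": len(good) + len(poor) - 2,
            "n_good": len(good), "n_poor": len(poor)}


# ----------------------------------------------------------------------
# end-to-end differential methylation
# ----------------------------------------------------------------------
@dataclass
class DMResult:
    """Everything the differential-methylation stage produces."""

    table: pd.DataFrame          # per-core: logFC, t, p, fdr (targets), gene
    gene_table: pd.DataFrame     # per target gene: best core by p, gene-level FDR
    normalized: pd.DataFrame     # quantile-normalized log2-cpm (filtered cores)
    fit: ModeratedFit
    filter_stats: dict[str, int]


def differential_methylation(
    counts: pd.DataFrame,
    cores: pd.DataFrame,
    meta: list[SampleMeta],
    blocked: bool = True,
    lib_sizes: pd.Series | None = None,
    voom_span: float = 0.5,
) -> DMResult:
    """Full post-vs-pre differential methylation over promoter cores.

    FDR is computed by Benjamini-Hochberg restricted to the target cores
    (cores carrying a gene symbol); the per-gene table keeps, for each gene,
    the core with the smallest p-value and additionally reports a gene-level
    BH adjustment over those per-gene p-values.
    """
    tumor = [m for m in meta if m.is_tumor]
    filtered, fstats = filter_cores(counts[[m.sample_id for m in tumor]], cores)
    if lib_sizes is None:
        lib_sizes = counts[[m.sample_id for m in tumor]].sum(axis=0)
    E = logcpm(filtered, lib_sizes)
    E = quantile_normalize(E)
    design = make_design(tumor, blocked=blocked)
    W = voom_weights(E, design, lib_sizes, span=voom_span)
    fit = fit_moderated(E, design, weights=W, coef="treat")

    table = fit.table.copy()
    table["gene"] = cores["gene"].reindex(table.index)
    is_target = table["gene"].notna().to_numpy()
    if is_target.any():
        table["fdr"] = bh_fdr(table["p"].to_numpy(), restrict_to=is_target)
    else:
        table["fdr"] = np.nan

    gene_rows = []
    for gene, sub in table[is_target].groupby("gene", sort=True):
        best = sub.sort_values("p", kind="stable").iloc[0]
        gene_rows.append(
            (gene, best.name, float(best["logFC"]), float(best["t"]),
             float(best["p"]), float(best["fdr"]))
        )
    gene_table = pd.DataFrame(
        gene_rows, columns=["gene", "core_id", "logFC", "t", "p", "fdr"]
    ).set_index("gene")
    if len(gene_table):
        gene_table["gene_fdr"] = bh_fdr(gene_table["p"].to_numpy())

    return DMResult(table=table, gene_table=gene_table, normalized=E, fit=fit, filter_stats=fstats)
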