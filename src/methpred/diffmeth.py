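"""Differential methylation statistics, DM-set partitioning and clustering.

Two-group contrasts on beta values use a moderated t-statistic with
empirical-Bayes variance shrinkage: per-probe pooled variances s2_g with
d_g = n1 + n2 - 2 degrees of freedom are shrunk toward a prior (d0, s0^2)
fitted by method of moments on the log variances, giving

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)
    t_mod   = delta_beta / sqrt(s2_post * (1/n1 + 1/n2))

with p-values from a t distribution on d0 + d_g degrees of freedom and
Benjamini-Hochberg q-values per contrast. A probe is called differentially
methylated when q < q_max and |delta_beta| > db_min (strict inequalities).

The module also provides the exclusive/shared partition of two DM sets,
genomic-context proportion summaries, SD-based probe filtering with
correlation-distance hierarchical clustering of samples, and the two-sided
Fisher exact test used for cluster enrichment.

Tests are computed on beta values by default so the effect filter and the
statistic share a scale; an M-value (logit2 beta) option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .formats_io import BetaMatrix, ProbeAnnotation, get_logger

__all__ = [
    "ModTParams",
    "VennPartition",
    "fit_variance_prior",
    "moderated_t_test",
    "bh_fdr",
    "call_dm",
    "venn_partition",
    "context_summary",
    "select_variable_probes",
    "hcluster",
    "fisher_exact_2x2",
]

_log = get_logger(__name__)


@dataclass(frozen=True)
class ModTParams:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0_sq prior variance.

    d0 = 0 is the no-shrinkage boundary (the moderated statistic collapses to
    the ordinary pooled t); d0 = inf pools all probes to the common variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


@dataclass(frozen=True)
class VennPartition:
    """Exclusive/shared partition of two DM probe sets."""

    only_A: frozenset
    only_B: frozenset
    shared: frozenset


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on the monotone map)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(per_probe_variances, df_g: int) -> ModTParams:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the marginal distribution of log sample variances: with
    s2_g ~ s0^2 * chi2_{d0,d_g} mixtures, e_g = log s2_g - digamma(d_g/2)
    + log(d_g/2) has mean log s0^2 + digamma(d0/2) - log(d0/2) and excess
    variance trigamma(d0/2) beyond the sampling term trigamma(d_g/2).
    Zero or negative excess dispersion yields d0 = inf (no shrinkage target
    dispersion; every probe shares variance s0^2).
    """
    s2 = np.asarray(per_probe_variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) == 0 or np.all(s2 <= 0):
        raise ValueError("degenerate input: no positive per-probe variances")
    s2 = s2[s2 > 0]
    if len(s2) < 10:
        _log.warning(
            "variance prior fitted on only %d probes; estimate is low-confidence", len(s2)
        )
    if df_g <= 0:
        raise ValueError("df_g must be positive")
    z = np.log(s2)
    e = z - special.digamma(df_g / 2.0) + np.log(df_g / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = evar - float(special.polygamma(1, df_g / 2.0))
    if excess <= 0:
        # no excess dispersion: all probes share one variance; its MLE under
        # s2_g ~ s0^2 chi2_df / df is the arithmetic mean
        return ModTParams(d0=np.inf, s0_sq=float(np.mean(s2)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModTParams(d0=d0, s0_sq=s0_sq)


def _m_values(values: np.ndarray) -> np.ndarray:
    return np.log2(values / (1.0 - values))


def moderated_t_test(
    bm: BetaMatrix,
    group1,
    group2,
    params: ModTParams | None = None,
    use_m_values: bool = False,
) -> pd.DataFrame:
    """Per-probe moderated two-sample test of group1 vs group2.

    Returns a DataFrame indexed by probe with columns delta_beta (mean group1
    minus mean group2, always on the beta scale), t_mod, df_total, p, q,
    direction (hyper/hypo with respect to group1) and tested. Probes with
    fewer than two usable samples in either group are marked untested and
    excluded from the BH denominator. When ``params`` is None the prior is
    fitted on the complete-case probes with the modal residual df.
    """
    g1 = list(group1)
    g2 = list(group2)
    beta1 = bm.values[g1].to_numpy(dtype=float)
    beta2 = bm.values[g2].to_numpy(dtype=float)
    x1, x2 = (( _m_values(beta1), _m_values(beta2)) if use_m_values else (beta1, beta2))

    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    tested = (n1 >= 2) & (n2 >= 2)
    if not tested.all():
        _log.info("%d probe(s) untestable (missing data) excluded from FDR", int((~tested).sum()))

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are untestable anyway
        mean1 = np.nanmean(x1, axis=1)
        mean2 = np.nanmean(x2, axis=1)
        var1 = np.nanvar(x1, axis=1, ddof=1)
        var2 = np.nanvar(x2, axis=1, ddof=1)
        delta_beta = np.nanmean(beta1, axis=1) - np.nanmean(beta2, axis=1)

    df_g = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_pool = ((n1 - 1) * var1 + (n2 - 1) * var2) / df_g

    if params is None:
        mode_df = int(pd.Series(df_g[tested]).mode().iloc[0])
        fit_mask = tested & (df_g == mode_df) & (s2_pool > 0)
        params = fit_variance_prior(s2_pool[fit_mask], mode_df)

    if np.isinf(params.d0):
        s2_post = np.full_like(s2_pool, params.s0_sq)
        df_total = np.full(len(s2_pool), np.inf)
    else:
        s2_post = (params.d0 * params.s0_sq + df_g * s2_pool) / (params.d0 + df_g)
        df_total = params.d0 + df_g

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t_mod = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    q = np.full(len(p), np.nan)
    ok = tested & np.isfinite(p)
    if ok.any():
        q[ok] = bh_fdr(p[ok])

    direction = np.where(delta_beta > 0, "hyper", np.where(delta_beta < 0, "hypo", ""))
    out = pd.DataFrame(
        {
            "delta_beta": delta_beta,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "q": q,
            "direction": direction,
            "tested": tested,
        },
        index=bm.probe_ids.copy(),
    )
    out.index.name = "probe_id"
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_dm(results: pd.DataFrame, q_max: float = 0.05, db_min: float = 0.15) -> pd.Index:
    """DM probes of a contrast: q < q_max and |delta_beta| > db_min, both strict."""
    mask = (
        results["tested"]
        & (results["q"] < q_max)
        & (results["delta_beta"].abs() > db_min)
    )
    dm = results.index[mask]
    n_hyper = int((results.loc[dm, "direction"] == "hyper").sum())
    _log.info("DM call: %d probes (%d hyper, %d hypo)", len(dm), n_hyper, len(dm) - n_hyper)
    return dm


def venn_partition(dm_A, dm_B) -> VennPartition:
    """Exclusive and shared members of two DM sets (exact set algebra)."""
    a, b = frozenset(dm_A), frozenset(dm_B)
    return VennPartition(only_A=a - b, only_B=b - a, shared=a & b)


def context_summary(
    dm, ann: ProbeAnnotation, direction: pd.Series | None = None
) -> pd.DataFrame:
    """Counts and proportions of DM probes by region class, island context, direction.

    Proportions are within each direction margin (within the whole set when no
    direction is given). Raises on probes missing from the annotation.
    """
    dm = list(dm)
    missing = [p for p in dm if p not in ann.table.index]
    if missing:
        raise KeyError(f"probe(s) not annotated: {missing[:5]}")
    if not dm:
        return pd.DataFrame(columns=["direction", "region_class", "island_class", "count", "proportion"])
    sub = ann.table.loc[dm, ["region_class", "island_class"]].copy()
    sub["direction"] = direction.reindex(dm) if direction is not None else "all"
    counts = (
        sub.groupby(["direction", "region_class", "island_class"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("direction")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts


def select_variable_probes(bm: BetaMatrix, sd_min: float = 0.2) -> pd.Index:
    """Probes whose across-sample SD (denominator n-1) strictly exceeds sd_min."""
    sd = bm.values.std(axis=1, ddof=1)
    return bm.probe_ids[sd > sd_min]


def hcluster(bm: BetaMatrix, k: int = 3, linkage: str = "average") -> pd.Series:
    """Agglomerative clustering of samples on 1 - Pearson correlation distance.

    Cut to k clusters; deterministic given input column order (scipy breaks
    merge ties by original observation index). Returns labels 1..k indexed by
    sample id.
    """
    n = bm.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    x = bm.values.to_numpy(dtype=float).T  # samples as observations
    dist = ssd.pdist(x, metric="correlation")
    z = sch.linkage(dist, method=linkage)
    labels = sch.fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=bm.sample_ids, name="cluster")


def linkage_matrix(bm: BetaMatrix, linkage: str = "average") -> np.ndarray:
    """Raw scipy linkage matrix for the sample dendrogram (merge heights etc.)."""
    x = bm.values.to_numpy(dtype=float).T
    return sch.linkage(ssd.pdist(x, metric="correlation"), method=linkage)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Standard two-sided convention: the sum of hypergeometric probabilities,
    at fixed margins, of all tables whose point probability does not exceed
    the observed one (within floating-point tolerance).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)
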