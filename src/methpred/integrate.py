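"""Methylation-expression correlation and probe-to-regulatory-interval overlap.

Links each marker CpG to a candidate target gene (e.g. a gene-body CpG to its
host gene, or an enhancer-proximal CpG to the enhancer's inferred target) and
reports the Spearman correlation of methylation with expression on the
intersected samples, plus a Mann-Whitney comparison of expression between
responder groups. Probes are also placed relative to regulatory intervals
(BED, 0-based half-open): overlap or signed distance to the nearest region.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import (
    BetaMatrix,
    ExpressionMatrix,
    IntervalSet,
    ProbeAnnotation,
    SampleSheet,
    get_logger,
)

__all__ = [
    "spearman_corr",
    "mannwhitney",
    "overlap_probes",
    "correlate_markers",
]

_log = get_logger(__name__)


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for |rho| by full enumeration of y orderings.

    Rank correlation is linear in the permuted rank vector, so each
    permutation's rho is an affine function of a dot product; enumerate in
    vectorized batches. Feasible for n <= 10 (10! ~ 3.6e6 permutations).
    """
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt(float((xc**2).sum() * (yc**2).sum()))
    target = abs(rho_obs) * denom - 1e-12 * denom
    count = 0
    total = 0
    batch = []
    for perm in itertools.permutations(range(n)):
        batch.append(perm)
        if len(batch) == 100_000:
            dots = np.abs(yc[np.array(batch)] @ xc)
            count += int((dots >= target).sum())
            total += len(batch)
            batch = []
    if batch:
        dots = np.abs(yc[np.array(batch)] @ xc)
        count += int((dots >= target).sum())
        total += len(batch)
    return count / total


def spearman_corr(x, y, exact_max_n: int = 10) -> tuple[float | None, float | None]:
    """Spearman rank correlation with average-rank ties.

    The p-value uses the t approximation for n > ``exact_max_n`` and exact
    permutation enumeration otherwise. Pairs with a missing member are
    dropped; a constant vector gives (None, None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 paired non-missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        _log.warning("constant vector: Spearman rho undefined")
        return None, None
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) > exact_max_n:
        p = float(stats.spearmanr(x, y).pvalue)
    else:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        p = _spearman_exact_p(xr, yr, rho)
    return rho, p


def mannwhitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample).

    Exact enumeration when n1*n2 <= 10,000 and the data are tie-free;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= 10_000 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def overlap_probes(ann: ProbeAnnotation, regions: IntervalSet) -> pd.DataFrame:
    """Overlaps and nearest regions for every probe against an interval set.

    Probe manifest positions (1-based points) are converted to 0-based;
    a probe overlaps a region iff start <= pos0 < end. Distances follow the
    interval-gap convention: 0 for overlap, otherwise the number of bases
    separating the probe from the region, negative when the probe lies
    upstream of the region start (+ strand orientation assumed).

    Returns one row per probe-region overlap plus, for every probe, exactly
    one nearest-region row (``nearest`` column True). Probes on chromosomes
    absent from the interval set appear once with no match.
    """
    rows = []
    reg = regions.table
    for probe_id, rec in ann.table.iterrows():
        pos0 = int(rec["position"]) - 1
        sub = reg[reg["chromosome"] == rec["chromosome"]]
        if sub.empty:
            rows.append((probe_id, None, np.nan, False, True))
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        # gap between the 1-bp probe interval [pos0, pos0+1) and each region
        dist = np.where(
            (start <= pos0) & (pos0 < end),
            0,
            np.where(pos0 < start, (pos0 + 1) - start, pos0 - end),
        )
        overl = dist == 0
        for j in np.flatnonzero(overl):
            rows.append((probe_id, sub.iloc[j]["name"], 0, True, False))
        j_near = int(np.argmin(np.abs(dist)))
        rows.append(
            (probe_id, sub.iloc[j_near]["name"], int(dist[j_near]), bool(overl[j_near]), True)
        )
    return pd.DataFrame(
        rows, columns=["probe_id", "region", "distance", "overlaps", "nearest"]
    )


def correlate_markers(
    bm: BetaMatrix,
    em: ExpressionMatrix,
    links: dict,
    sheet: SampleSheet | None = None,
) -> pd.DataFrame:
    """Per-link methylation-expression report on the intersected samples.

    ``links`` maps marker probe id to gene id. Each row carries the Spearman
    rho and p of marker beta vs gene expression, plus the Mann-Whitney
    comparison of the gene's expression between pCR and pIR (when a sample
    sheet is given). Links with fewer than 4 overlapping samples are skipped
    with a warning.
    """
    shared = [s for s in bm.sample_ids if s in set(em.sample_ids)]
    rows = []
    for marker, gene in links.items():
        if marker not in bm.probe_ids or gene not in em.gene_ids:
            _log.warning("link %s -> %s skipped: id not found", marker, gene)
            continue
        meth = bm.values.loc[marker, shared].to_numpy(dtype=float)
        expr = em.values.loc[gene, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(meth) | np.isnan(expr))
        if ok.sum() < 4:
            _log.warning("link %s -> %s skipped: <4 overlapping samples", marker, gene)
            continue
        rho, p = spearman_corr(meth[ok], expr[ok])
        u = p_mw = mean_pcr = mean_pir = None
        if sheet is not None:
            grp = sheet.table.reindex(shared)["group"].to_numpy()
            e_pcr = expr[ok & (grp == "pCR")]
            e_pir = expr[ok & (grp == "pIR")]
            if len(e_pcr) and len(e_pir):
                u, p_mw = mannwhitney(e_pcr, e_pir)
                mean_pcr = float(np.mean(e_pcr))
                mean_pir = float(np.mean(e_pir))
        rows.append(
            {
                "marker": marker,
                "gene": gene,
                "n": int(ok.sum()),
                "spearman_rho": rho,
                "spearman_p": p,
                "mw_U": u,
                "mw_p": p_mw,
                "mean_expr_pCR": mean_pcr,
                "mean_expr_pIR": mean_pir,
            }
        )
    return pd.DataFrame(rows)
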