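"""Synthetic three-group methylation cohorts with known, injected structure.

The generator emulates the statistical structure of a discovery study of
locally advanced rectal cancer: a small cohort of normal rectal tissue (NT),
pathological complete responders (pCR) and incomplete responders (pIR);
genome-scale beta values with the usual bimodal, CpG-context-dependent
distribution; differential methylation vs NT injected with configurable
fractions, direction biases (pCR hypermethylation island-biased, pIR dominated
by hypomethylation) and a fixed effect size; three designated marker CpGs
hypomethylated in pIR with per-probe AUCs calibrated to given targets; a
pyrosequencing replica of the markers on the 0-100 percent scale with assay
noise, an FFPE offset for marker A and QC dropout; and expression values for
linked genes with calibrated signed Spearman correlations.

Every injected effect is recorded in a truth table so downstream recovery
(power, false-positive rate, context proportions) can be scored exactly.

Randomness: one global seed feeds a fixed hierarchy of per-stage substreams
(annotation, background, DM injection, markers, pyro replica, expression), so
each stage is reproducible when rerun independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .formats_io import (
    ARRAY_SCALE,
    PYRO_SCALE,
    BetaMatrix,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleSheet,
)

__all__ = [
    "SimConfig",
    "ConfigError",
    "marker_mean_gap_for_auc",
    "generate_cohort",
    "generate_pyro_replica",
    "generate_expression",
]

MARKER_IDS = ("cg01072658", "cg03085846", "cg13770628")  # CpG-A, CpG-B, CpG-C

# fixed marker coordinates: A in the OBSL1 gene body (chr2), B upstream of the
# GPR1 enhancer (chr2), C downstream of the INSIG1 enhancer (chr7)
_MARKER_ANNOTATION = {
    "cg01072658": ("chr2", 220436581, "body", "shore"),
    "cg03085846": ("chr2", 207073931, "body", "open_sea"),
    "cg13770628": ("chr7", 155078215, "intergenic", "open_sea"),
}

# substream indices in the per-stage seed hierarchy
_STREAMS = {"annotation": 0, "background": 1, "dm": 2, "markers": 3, "pyro": 4, "expression": 5}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def marker_mean_gap_for_auc(auc: float, sd: float) -> float:
    """Group-mean gap giving a target AUC for two equal-variance Gaussians.

    Uses the closed form AUC = Phi(dmu / (sigma * sqrt(2))), inverted.
    """
    if not 0.5 < auc < 1.0:
        raise ConfigError(f"AUC target must be in (0.5, 1), got {auc}")
    return float(ndtri(auc) * sd * np.sqrt(2.0))


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 5 NT / 11 pCR / 21 pIR samples; DM
    fractions scaled from the reported 24,428 (pCR vs NT) and 75,398 (pIR vs
    NT) DM probes out of 722,807; hypermethylation proportions 44% (pCR) vs
    18% (pIR) with island biases 66% vs 36%; injected effect size
    |delta-beta| = 0.30; marker AUC targets 0.706 / 0.754 / 0.697. Marker
    within-group SD is a calibration choice (see docs/methods.md), default
    0.12 beta units.
    """

    n_NT: int = 5
    n_pCR: int = 11
    n_pIR: int = 21
    n_probes: int = 20_000
    dm_fraction_pCR: float = 0.03
    dm_fraction_pIR: float = 0.10
    hyper_prop_pCR: float = 0.44
    hyper_prop_pIR: float = 0.18
    island_hyper_prop_pCR: float = 0.66
    island_hyper_prop_pIR: float = 0.36
    delta_beta_effect: float = 0.30
    marker_auc_targets: tuple = (0.706, 0.754, 0.697)
    marker_mean_pCR: float = 0.55
    marker_sd: float = 0.12
    marker_means: dict | None = None  # {"NT"|"pCR"|"pIR": (mA, mB, mC)}; None -> derived
    ffpe_fraction: float = 0.0  # discovery biopsies are fresh-frozen
    pyro_noise_sd: float = 3.5  # percentage points
    ffpe_offset_markerA: float = 5.0  # percentage points, FFPE samples only
    pyro_missing_fraction: float = 0.0
    # gene -> (marker probe id, target Spearman rho); signs as reported for
    # the marker-A (positive) and marker-C (negative) genes
    expr_rho_targets: dict = field(
        default_factory=lambda: {
            "OBSL1": ("cg01072658", 0.5178),
            "INSIG1": ("cg13770628", -0.4249),
        }
    )
    expr_noise: float | None = None  # None -> calibrated from rho target
    n_expression_samples: int = 27
    n_background_genes: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_NT", "n_pCR", "n_pIR", "n_probes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in (
            "dm_fraction_pCR",
            "dm_fraction_pIR",
            "hyper_prop_pCR",
            "hyper_prop_pIR",
            "island_hyper_prop_pCR",
            "island_hyper_prop_pIR",
            "ffpe_fraction",
            "pyro_missing_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_probes < len(MARKER_IDS):
            raise ConfigError("n_probes smaller than number of marker CpGs")
        means = self.resolved_marker_means()
        for k in range(3):
            for g in ("NT", "pCR", "pIR"):
                if not 0.0 < means[g][k] < 1.0:
                    raise ConfigError(f"marker mean {means[g][k]} for {g} outside (0, 1)")
            if not means["pIR"][k] < means["pCR"][k]:
                raise ConfigError(
                    "marker means must be ordered pIR < pCR (markers are "
                    f"hypomethylated in pIR); got pCR={means['pCR'][k]}, pIR={means['pIR'][k]}"
                )

    def resolved_marker_means(self) -> dict:
        """Per-group marker means; NT tracks pCR, pIR lower by the AUC-derived gap."""
        if self.marker_means is not None:
            return {g: tuple(v) for g, v in self.marker_means.items()}
        gaps = [marker_mean_gap_for_auc(a, self.marker_sd) for a in self.marker_auc_targets]
        pcr = (self.marker_mean_pCR,) * 3
        pir = tuple(self.marker_mean_pCR - g for g in gaps)
        return {"NT": pcr, "pCR": pcr, "pIR": pir}

    def stream(self, stage: str) -> np.random.Generator:
        """Named per-stage substream of the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stage]])


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, size) -> np.ndarray:
    """Moment-matched Beta draws; keeps values in (0,1) without transforms."""
    var = sd**2
    # cap variance below the Bernoulli bound so both shape parameters are > 0
    var = np.minimum(var, 0.95 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    a = mean * nu
    b = (1.0 - mean) * nu
    return rng.beta(a, b, size=size)


def _simulate_annotation(cfg: SimConfig, probe_ids: list[str]) -> ProbeAnnotation:
    rng = cfg.stream("annotation")
    n = len(probe_ids)
    island = rng.choice(
        ["island", "shore", "shelf", "open_sea"], size=n, p=[0.31, 0.23, 0.10, 0.36]
    )
    region = rng.choice(["promoter", "body", "intergenic"], size=n, p=[0.41, 0.33, 0.26])
    chrom = rng.integers(1, 23, size=n)
    pos = rng.integers(1_000_000, 240_000_000, size=n)
    table = pd.DataFrame(
        {
            "chromosome": [f"chr{c}" for c in chrom],
            "position": pos,
            "region_class": region,
            "island_class": island,
            "flags": "",
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    for mid, (c, p, reg, isl) in _MARKER_ANNOTATION.items():
        table.loc[mid, ["chromosome", "position", "region_class", "island_class"]] = [c, p, reg, isl]
    table["position"] = table["position"].astype(int)
    return ProbeAnnotation(table)


def _pick_dm_probes(
    rng: np.random.Generator,
    candidates: np.ndarray,
    is_island: pd.Series,
    n_dm: int,
    hyper_prop: float,
    island_hyper_prop: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Choose (hyper, hypo) probe id arrays honouring the island bias for hyper."""
    n_hyper = int(round(hyper_prop * n_dm))
    n_hypo = n_dm - n_hyper
    n_isl = int(round(island_hyper_prop * n_hyper))
    island_pool = candidates[is_island.loc[candidates].to_numpy()]
    other_pool = candidates[~is_island.loc[candidates].to_numpy()]
    n_isl = min(n_isl, len(island_pool))
    hyper_isl = rng.choice(island_pool, size=n_isl, replace=False)
    hyper_other = rng.choice(other_pool, size=n_hyper - n_isl, replace=False)
    hyper = np.concatenate([hyper_isl, hyper_other])
    remaining = np.setdiff1d(candidates, hyper, assume_unique=False)
    hypo = rng.choice(remaining, size=min(n_hypo, len(remaining)), replace=False)
    return hyper, hypo


def generate_cohort(cfg: SimConfig):
    """Generate one cohort: (BetaMatrix, ProbeAnnotation, SampleSheet, truth).

    Background probes follow bimodal Beta mixtures conditioned on island
    context (islands mostly low-methylated, open sea mostly high). DM probes
    are injected by shifting the affected tumour group's mean by
    +/- ``delta_beta_effect`` relative to NT, with direction sampled from the
    configured hypermethylation proportions and hypermethylated probes drawn
    preferentially from islands. The three marker CpGs get the configured
    per-group means (NT ~ pCR > pIR). All values are clamped to
    [0.001, 0.999] so logit transforms stay finite.

    The truth table lists one row per (probe, tumour group) whose mean was
    shifted away from NT, with the signed injected delta.
    """
    probe_ids = list(MARKER_IDS) + [f"cgSIM{i:06d}" for i in range(cfg.n_probes - len(MARKER_IDS))]
    ann = _simulate_annotation(cfg, probe_ids)

    sample_ids = (
        [f"NT{i + 1:02d}" for i in range(cfg.n_NT)]
        + [f"PCR{i + 1:02d}" for i in range(cfg.n_pCR)]
        + [f"PIR{i + 1:02d}" for i in range(cfg.n_pIR)]
    )
    groups = ["NT"] * cfg.n_NT + ["pCR"] * cfg.n_pCR + ["pIR"] * cfg.n_pIR

    rng_bg = cfg.stream("background")
    n = cfg.n_probes
    isl = ann.table["island_class"].to_numpy()
    # probability of the low-methylation mode by island context
    p_low = np.select(
        [isl == "island", isl == "shore", isl == "shelf"], [0.80, 0.60, 0.35], default=0.15
    )
    low_mode = rng_bg.random(n) < p_low
    base_mean = np.where(
        low_mode,
        rng_bg.normal(0.15, 0.05, size=n),
        rng_bg.normal(0.80, 0.06, size=n),
    )
    base_mean = np.clip(base_mean, 0.03, 0.97)
    probe_sd = rng_bg.uniform(0.02, 0.08, size=n)

    # --- DM injection ---------------------------------------------------
    rng_dm = cfg.stream("dm")
    is_island = pd.Series(isl == "island", index=probe_ids)
    non_marker = np.array(probe_ids[len(MARKER_IDS):])
    delta = cfg.delta_beta_effect
    injected: dict[str, dict[str, float]] = {"pCR": {}, "pIR": {}}
    for grp, frac, hyper_p, isl_p in (
        ("pCR", cfg.dm_fraction_pCR, cfg.hyper_prop_pCR, cfg.island_hyper_prop_pCR),
        ("pIR", cfg.dm_fraction_pIR, cfg.hyper_prop_pIR, cfg.island_hyper_prop_pIR),
    ):
        n_dm = int(round(frac * len(non_marker)))
        if n_dm == 0:
            continue
        hyper, hypo = _pick_dm_probes(rng_dm, non_marker, is_island, n_dm, hyper_p, isl_p)
        for pid in hyper:
            injected[grp][pid] = +delta
        for pid in hypo:
            injected[grp][pid] = -delta

    pos_of = {pid: i for i, pid in enumerate(probe_ids)}
    # keep the NT baseline of injected probes inside a window where the full
    # shift stays within (0.02, 0.98) for every affected group
    lo_bound = np.full(n, 0.03)
    hi_bound = np.full(n, 0.97)
    for grp in ("pCR", "pIR"):
        for pid, d in injected[grp].items():
            i = pos_of[pid]
            if d > 0:
                hi_bound[i] = min(hi_bound[i], 0.98 - delta)
            else:
                lo_bound[i] = max(lo_bound[i], 0.02 + delta)
    needs_adjust = (base_mean < lo_bound) | (base_mean > hi_bound)
    if needs_adjust.any():
        base_mean[needs_adjust] = rng_dm.uniform(
            lo_bound[needs_adjust], hi_bound[needs_adjust]
        )

    group_means = {g: base_mean.copy() for g in ("NT", "pCR", "pIR")}
    for grp in ("pCR", "pIR"):
        for pid, d in injected[grp].items():
            group_means[grp][pos_of[pid]] += d

    # --- markers ---------------------------------------------------------
    mm = cfg.resolved_marker_means()
    for g in ("NT", "pCR", "pIR"):
        group_means[g][: len(MARKER_IDS)] = mm[g]
    probe_sd[: len(MARKER_IDS)] = cfg.marker_sd

    rng_mark = cfg.stream("markers")
    values = np.empty((n, len(sample_ids)))
    col = 0
    for g, count in (("NT", cfg.n_NT), ("pCR", cfg.n_pCR), ("pIR", cfg.n_pIR)):
        mean_g = group_means[g][:, None].repeat(count, axis=1)
        sd_g = probe_sd[:, None].repeat(count, axis=1)
        values[:, col : col + count] = _beta_draw(rng_bg, mean_g, sd_g, (n, count))
        col += count
    # marker rows redrawn from the dedicated stream so marker statistics are
    # invariant to the background configuration
    for g, sl in _group_slices(cfg).items():
        count = sl.stop - sl.start
        mean_g = np.array(mm[g])[:, None].repeat(count, axis=1)
        values[: len(MARKER_IDS), sl] = rng_mark.normal(mean_g, cfg.marker_sd)
    values = np.clip(values, 0.001, 0.999)

    bm = BetaMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
        ARRAY_SCALE,
    )

    # --- sample sheet ----------------------------------------------------
    n_tumour = cfg.n_pCR + cfg.n_pIR
    n_ffpe = int(round(cfg.ffpe_fraction * n_tumour))
    preservation = ["FF"] * len(sample_ids)
    if n_ffpe:
        tumour_idx = np.arange(cfg.n_NT, len(sample_ids))
        for i in rng_mark.choice(tumour_idx, size=n_ffpe, replace=False):
            preservation[i] = "FFPE"
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group": groups,
                "preservation": preservation,
                "batch": "b1",
                "cohort": "discovery",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # --- truth table ------------------------------------------------------
    rows = []
    for k, mid in enumerate(MARKER_IDS):
        for g in ("pCR", "pIR"):
            d = mm[g][k] - mm["NT"][k]
            if d != 0.0:
                rows.append((mid, g, "hyper" if d > 0 else "hypo", d, True))
    for grp in ("pCR", "pIR"):
        for pid, d in injected[grp].items():
            rows.append((pid, grp, "hyper" if d > 0 else "hypo", d, False))
    truth = pd.DataFrame(
        rows, columns=["probe_id", "group", "direction", "delta_injected", "is_marker"]
    )
    return bm, ann, sheet, truth


def _group_slices(cfg: SimConfig) -> dict[str, slice]:
    return {
        "NT": slice(0, cfg.n_NT),
        "pCR": slice(cfg.n_NT, cfg.n_NT + cfg.n_pCR),
        "pIR": slice(cfg.n_NT + cfg.n_pCR, cfg.n_NT + cfg.n_pCR + cfg.n_pIR),
    }


def generate_pyro_replica(
    bm: BetaMatrix, cfg: SimConfig, sheet: SampleSheet | None = None
) -> BetaMatrix:
    """Pyrosequencing replica of the marker probes on the 0-100 percent scale.

    value = 100 * beta + Gaussian assay noise (+ FFPE offset on marker A for
    FFPE samples), clamped to [0, 100]; a configurable fraction of entries is
    set missing to emulate QC failures.
    """
    if bm.scale != ARRAY_SCALE:
        raise ValueError("pyro replica requires an array-scale input matrix")
    rng = cfg.stream("pyro")
    markers = [m for m in MARKER_IDS if m in bm.probe_ids]
    sub = bm.values.loc[markers]
    vals = 100.0 * sub.to_numpy() + rng.normal(0.0, cfg.pyro_noise_sd, size=sub.shape)
    if sheet is not None and cfg.ffpe_offset_markerA and MARKER_IDS[0] in markers:
        ffpe = (
            sheet.table.reindex(sub.columns)["preservation"].fillna("FF") == "FFPE"
        ).to_numpy()
        vals[markers.index(MARKER_IDS[0]), ffpe] += cfg.ffpe_offset_markerA
    vals = np.clip(vals, 0.0, 100.0)
    if cfg.pyro_missing_fraction > 0:
        miss = rng.random(vals.shape) < cfg.pyro_missing_fraction
        vals[miss] = np.nan
    return BetaMatrix(pd.DataFrame(vals, index=sub.index, columns=sub.columns), PYRO_SCALE)


def generate_expression(
    bm: BetaMatrix, cfg: SimConfig, sheet: SampleSheet | None = None
) -> ExpressionMatrix:
    """Expression matrix with calibrated marker-methylation correlations.

    For each configured gene, expression is a signed linear function of its
    linked marker's (z-scored) beta plus Gaussian noise. The noise level is
    set so the realized Spearman rho approximates the signed target: the
    target is converted to its bivariate-normal Pearson equivalent
    rho_P = 2 sin(pi * rho_S / 6) and the mixing weights are (rho_P,
    sqrt(1 - rho_P^2)). Values are reported on an arbitrary log2-like scale
    (8 +/- 1.5 units); background genes are uncorrelated noise.
    """
    rng = cfg.stream("expression")
    if sheet is not None:
        eligible = [s for s in bm.sample_ids if sheet.table.loc[s, "group"] != "NT"]
    else:
        eligible = list(bm.sample_ids)
    n_take = min(cfg.n_expression_samples, len(eligible))
    samples = sorted(rng.choice(eligible, size=n_take, replace=False).tolist())

    genes = {}
    for gene, (marker, rho_s) in cfg.expr_rho_targets.items():
        if marker not in bm.probe_ids:
            raise ConfigError(f"expression link for {gene!r}: marker {marker!r} not in matrix")
        x = bm.values.loc[marker, samples].to_numpy(dtype=float)
        z = (x - x.mean()) / x.std(ddof=0)
        if cfg.expr_noise is not None:
            e = np.sign(rho_s) * z + rng.normal(0.0, cfg.expr_noise, size=len(z))
        elif abs(rho_s) >= 1.0:
            e = np.sign(rho_s) * z
        elif rho_s == 0.0:
            e = rng.normal(size=len(z))
        else:
            rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
            e = rho_p * z + np.sqrt(1.0 - rho_p**2) * rng.normal(size=len(z))
        genes[gene] = 8.0 + 1.5 * e
    for i in range(cfg.n_background_genes):
        genes[f"GENE{i + 1:03d}"] = rng.normal(8.0, 1.5, size=len(samples))
    df = pd.DataFrame(genes, index=samples).T
    df.index.name = "gene_id"
    return ExpressionMatrix(df)
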