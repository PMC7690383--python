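"""Readers, writers and validated containers for the pipeline's tabular formats.

The pipeline's central object is a probes-by-samples matrix of methylation
levels: beta values in the open interval (0, 1) on the microarray scale, or
percent methylation in [0, 100] on the bisulfite-pyrosequencing scale.
Alongside it travel a probe annotation manifest (genomic coordinates and
context classes), a sample sheet (response group, preservation, batch,
cohort), optional expression matrices and BED4 regulatory-interval files.

Coordinate conventions: manifest positions are 1-based (Illumina manifest
convention); interval files are 0-based half-open (BED). Conversion between
the two happens only inside the overlap operation in :mod:`methpred.integrate`.

Missing values are encoded as empty cells in text files and propagated as NaN,
never silently as 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "RangeError",
    "BetaMatrix",
    "ProbeAnnotation",
    "SampleSheet",
    "IntervalSet",
    "ExpressionMatrix",
    "read_beta_matrix",
    "read_sample_sheet",
    "read_manifest",
    "read_intervals",
    "read_expression",
    "read_table",
    "write_table",
    "load_config",
    "config_hash",
    "write_run_metadata",
    "get_logger",
]

ARRAY_SCALE = "array"
PYRO_SCALE = "pyro"
GROUPS = ("NT", "pCR", "pIR")
PRESERVATIONS = ("FF", "FFPE")
COHORTS = ("discovery", "validation")
REGION_CLASSES = ("promoter", "body", "intergenic")
ISLAND_CLASSES = ("island", "shore", "shelf", "open_sea")
PROBE_FLAGS = ("xy", "cross_reactive", "snp")


class FormatError(ValueError):
    """A file or container violates the declared format contract."""


class RangeError(FormatError):
    """A value lies outside the declared scale's range."""


def get_logger(name: str = "methpred") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


_log = get_logger(__name__)


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise FormatError(f"duplicated {what} id(s): {dups[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples methylation levels on a declared, uniform scale.

    ``values`` rows are probes, columns are samples. Array-scale entries must
    lie strictly inside (0, 1); pyro-scale entries in [0, 100]. NaN marks a
    missing measurement (e.g. a pyrosequencing QC failure).
    """

    values: pd.DataFrame
    scale: str = ARRAY_SCALE

    def __post_init__(self) -> None:
        if self.scale not in (ARRAY_SCALE, PYRO_SCALE):
            raise FormatError(f"unknown scale {self.scale!r}")
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == ARRAY_SCALE:
            bad = (vals <= 0.0) | (vals >= 1.0)
        else:
            bad = (vals < 0.0) | (vals > 100.0)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise RangeError(
                f"value {vals[i, j]!r} for probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r} outside {self.scale} scale range"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probes)], self.scale)

    def subset_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.values[list(samples)], self.scale)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic coordinates, context classes and exclusion flags.

    ``table`` is indexed by probe id with columns ``chromosome``, ``position``
    (1-based), ``region_class``, ``island_class``, ``flags`` (comma-joined
    subset of xy/cross_reactive/snp, empty string for none).
    ``detection_fail`` is an optional probes x samples boolean mask.
    """

    table: pd.DataFrame
    detection_fail: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "probe")
        required = {"chromosome", "position", "region_class", "island_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"manifest missing column(s): {sorted(missing)}")
        if "flags" not in self.table.columns:
            self.table = self.table.assign(flags="")
        self.table["flags"] = self.table["flags"].fillna("")
        for col, allowed in (("region_class", REGION_CLASSES), ("island_class", ISLAND_CLASSES)):
            bad = ~self.table[col].isin(allowed)
            if bad.any():
                probe = self.table.index[bad][0]
                raise FormatError(
                    f"probe {probe!r}: unknown {col} {self.table.loc[probe, col]!r}"
                )
        for probe, raw in self.table["flags"].items():
            for flag in str(raw).split(","):
                if flag and flag not in PROBE_FLAGS:
                    raise FormatError(f"probe {probe!r}: unknown flag {flag!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def flags_of(self, probe_id: str) -> frozenset:
        raw = str(self.table.loc[probe_id, "flags"])
        return frozenset(f for f in raw.split(",") if f)

    def excluded_probes(self) -> pd.Index:
        """Probes carrying any exclusion flag (XY / cross-reactive / SNP)."""
        has_flag = self.table["flags"].astype(str).str.len() > 0
        return self.table.index[has_flag]


@dataclass
class SampleSheet:
    """Sample metadata: response group, preservation, batch, cohort."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        if "group" not in self.table.columns:
            raise FormatError("sample sheet missing 'group' column")
        bad = ~self.table["group"].isin(GROUPS)
        if bad.any():
            sid = self.table.index[bad][0]
            raise FormatError(f"sample {sid!r}: unknown group {self.table.loc[sid, 'group']!r}")
        if "preservation" in self.table.columns:
            bad = ~self.table["preservation"].isin(PRESERVATIONS)
            if bad.any():
                sid = self.table.index[bad][0]
                raise FormatError(
                    f"sample {sid!r}: unknown preservation {self.table.loc[sid, 'preservation']!r}"
                )
        if "cohort" in self.table.columns:
            bad = ~self.table["cohort"].isin(COHORTS)
            if bad.any():
                sid = self.table.index[bad][0]
                raise FormatError(
                    f"sample {sid!r}: unknown cohort {self.table.loc[sid, 'cohort']!r}"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise FormatError(f"unknown group {group!r}")
        return self.table.index[self.table["group"] == group].tolist()

    def check_matches(self, bm: BetaMatrix) -> None:
        missing = bm.sample_ids.difference(self.table.index)
        if len(missing):
            raise FormatError(f"beta-matrix sample(s) absent from sample sheet: {missing.tolist()[:5]}")


@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open (BED convention)."""

    table: pd.DataFrame  # columns: chromosome, start, end, name

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end", "name"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"interval set missing column(s): {sorted(missing)}")
        bad = self.table["start"] >= self.table["end"]
        if bad.any():
            rec = self.table[bad].iloc[0]
            raise FormatError(
                f"interval {rec['name']!r}: start {rec['start']} >= end {rec['end']}"
            )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression levels (log scale assumed, pre-normalized)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# readers / writers


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    _log.debug("delimiter for %s detected as %r", path, sep)
    return sep


def read_beta_matrix(path, scale: str = ARRAY_SCALE) -> BetaMatrix:
    """Read a delimited probes-by-samples matrix; empty cells become NaN."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    try:
        return BetaMatrix(df.astype(float), scale)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: non-numeric entry in beta matrix ({exc})") from exc


def read_sample_sheet(path) -> SampleSheet:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, dtype=str)
    return SampleSheet(df)


def read_manifest(path) -> ProbeAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    df["position"] = df["position"].astype(int)
    return ProbeAnnotation(df)


def read_intervals(path) -> IntervalSet:
    """Read BED4 (chromosome, start, end, name), whitespace- or tab-delimited."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED4 line needs 4 fields, got {len(parts)}")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])
    return IntervalSet(df)


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    return ExpressionMatrix(df.astype(float))


def read_table(path) -> pd.DataFrame:
    """Generic result-table reader (counterpart of :func:`write_table`)."""
    path = Path(path)
    return pd.read_csv(path, sep=_detect_sep(path), index_col=0)


def write_table(obj, path) -> None:
    """Write a result table (or any of the containers above) as TSV.

    Round-trips losslessly with the corresponding reader: floats are written
    at full precision, missing values as empty cells.
    """
    path = Path(path)
    if isinstance(obj, (BetaMatrix, ExpressionMatrix)):
        df = obj.values
    elif isinstance(obj, (ProbeAnnotation, SampleSheet, IntervalSet)):
        df = obj.table
    else:
        df = obj
    if isinstance(obj, IntervalSet):
        df.to_csv(path, sep="\t", index=False)
    else:
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# config / run metadata


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "q_max": 0.05,
    "db_min": 0.15,
    "sd_min": 0.2,
    "top_k": 10,
    "paths": {},
}


def load_config(path) -> dict:
    """Load the YAML key-value config, merged over documented defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise FormatError(f"{path}: config must be a mapping")
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_run_metadata(path, seed: int, cfg: dict | None = None) -> None:
    """Record seed, config hash and library versions for reproducibility."""
    import scipy

    from . import __version__

    meta = {
        "seed": int(seed),
        "config_hash": config_hash(cfg or {}),
        "versions": {
            "methpred": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
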