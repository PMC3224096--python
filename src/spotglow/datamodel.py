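"""Domain types and file I/O for spotted-microarray preprocessing.

The central objects are

* :class:`SpotDataset` — spot-level foreground/background intensities with
  grid coordinates and replicate-spot structure, spanning arrays, two
  conditions (A/B) and one or more sites;
* :class:`CorrectedMatrix` — background-corrected intensities, still at
  spot resolution (rows are ``(gene_id, spot_replicate)``, columns arrays);
* :class:`TransformedMatrix` — intensities on the log2 scale after a log2
  or glog transformation, at spot or gene resolution;
* :class:`GoldStandard` — low-noise per-gene reference log2 fold-changes
  and p-values (qPCR-like);
* :class:`DEResult` — per-gene differential-expression output (log2
  fold-change, moderated t, p-value, reference intensity);
* :class:`ConfusionTable` — volcano-classification agreement counts.

All text formats are plain TSV/CSV with ``NA`` for missing values, and
every write→read round trip is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

NA_REP = "NA"

SPOT_COLUMNS = [
    "gene_id",
    "site",
    "condition",
    "array_id",
    "spot_replicate",
    "grid_row",
    "grid_col",
    "F",
    "B",
]

CORRECTION_METHODS = ("standard", "none", "edwards", "normexp")
TRANSFORMS = ("log2", "glog")


class SpotglowError(Exception):
    """Base class for all package errors."""


class FormatError(SpotglowError):
    """A file does not have the expected layout (e.g. a missing column)."""


class ValidationError(SpotglowError):
    """Input values violate a type invariant; the message locates the row."""


class ConfigurationError(SpotglowError):
    """A simulation or pipeline configuration is internally inconsistent."""


class FittingError(SpotglowError):
    """A model fit failed to converge or is degenerate."""

    def __init__(self, message: str, best: object | None = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlogParams:
    """Parameters of the generalized logarithm glog(x) = ln(x - alpha + sqrt((x - alpha)^2 + lambda)).

    ``alpha`` (AFU) shifts the transform; ``lambda_`` (AFU^2) controls the
    curvature near zero and must be strictly positive.
    """

    alpha: float
    lambda_: float

    def __post_init__(self):
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValidationError(f"glog alpha must be finite and >= 0, got {self.alpha}")
        if not np.isfinite(self.lambda_) or self.lambda_ <= 0:
            raise ValidationError(f"glog lambda must be finite and > 0, got {self.lambda_}")


@dataclass(frozen=True)
class EdwardsParams:
    """Threshold of the Edwards correction.

    ``delta`` is either one positive threshold (AFU) for all arrays or a
    mapping ``array_id -> threshold``.
    """

    delta: float | Mapping[str, float]

    def __post_init__(self):
        values = self.delta.values() if isinstance(self.delta, Mapping) else [self.delta]
        for d in values:
            if not np.isfinite(d) or d <= 0:
                raise ValidationError(f"Edwards delta must be finite and > 0, got {d}")

    def for_array(self, array_id: str) -> float:
        if isinstance(self.delta, Mapping):
            try:
                return float(self.delta[array_id])
            except KeyError:
                raise ValidationError(f"no Edwards delta for array {array_id!r}") from None
        return float(self.delta)


@dataclass(frozen=True)
class NormexpParams:
    """Normal-plus-exponential convolution parameters.

    The observed intensity is modelled as S + N with S ~ Exponential(mean
    ``alpha_signal``) and N ~ Normal(``mu``, ``sigma``^2).
    """

    mu: float
    sigma: float
    alpha_signal: float
    log_likelihood: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValidationError(f"normexp sigma must be > 0, got {self.sigma}")
        if not np.isfinite(self.alpha_signal) or self.alpha_signal <= 0:
            raise ValidationError(f"normexp alpha_signal must be > 0, got {self.alpha_signal}")


# ---------------------------------------------------------------------------
# SpotDataset
# ---------------------------------------------------------------------------


@dataclass
class SpotDataset:
    """Spot-level intensity table for one platform.

    ``spots`` has one row per physical spot per array with columns
    ``gene_id, site, condition, array_id, spot_replicate, grid_row,
    grid_col, F, B``.  Conditions are the two compared samples ``A`` and
    ``B``; ``F`` and ``B`` are the foreground and local-background mean
    intensities in arbitrary fluorescence units.
    """

    spots: pd.DataFrame
    n_spot_replicates: int

    def __post_init__(self):
        df = self.spots
        missing = [c for c in SPOT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"spot table lacks column(s): {', '.join(missing)}")
        df = df.reset_index(drop=True)
        bad_cond = ~df["condition"].isin(["A", "B"])
        if bad_cond.any():
            raise ValidationError(
                f"condition must be 'A' or 'B'; first bad row index {int(np.flatnonzero(bad_cond)[0])}"
            )
        for col in ("F", "B"):
            vals = pd.to_numeric(df[col], errors="coerce")
            neg = vals < 0
            if neg.any():
                raise ValidationError(
                    f"negative {col} at row index {int(np.flatnonzero(neg)[0])}"
                )
            df[col] = vals.astype(float)
        counts = df.groupby(["gene_id", "array_id"], sort=False).size()
        wrong = counts[counts != self.n_spot_replicates]
        if len(wrong):
            g, a = wrong.index[0]
            raise ValidationError(
                f"gene {g!r} on array {a!r} has {int(wrong.iloc[0])} spots, "
                f"expected {self.n_spot_replicates}"
            )
        dup = df.duplicated(subset=["array_id", "grid_row", "grid_col"])
        if dup.any():
            raise ValidationError(
                f"duplicate grid position within an array at row index {int(np.flatnonzero(dup)[0])}"
            )
        self.spots = df

    # -- convenient views ---------------------------------------------------

    @property
    def array_ids(self) -> list[str]:
        return list(pd.unique(self.spots["array_id"]))

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.spots["gene_id"]))

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.spots["site"]))

    def array_conditions(self) -> pd.Series:
        """condition label per array_id (each array measures one sample)."""
        cond = self.spots.groupby("array_id", sort=False)["condition"].agg(
            lambda s: s.iloc[0]
        )
        nuniq = self.spots.groupby("array_id", sort=False)["condition"].nunique()
        if (nuniq > 1).any():
            raise ValidationError("an array carries more than one condition label")
        return cond

    def subset_site(self, site: str) -> "SpotDataset":
        sub = self.spots[self.spots["site"] == site]
        if sub.empty:
            raise ValidationError(f"no spots for site {site!r}")
        return SpotDataset(sub.copy(), self.n_spot_replicates)

    def spot_matrix(self, column: str = "F") -> pd.DataFrame:
        """Pivot a spot-level column to (gene_id, spot_replicate) x array_id."""
        return self.spots.pivot_table(
            index=["gene_id", "spot_replicate"],
            columns="array_id",
            values=column,
            aggfunc="first",
            sort=False,
        )[self.array_ids]


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass
class CorrectedMatrix:
    """Background-corrected intensities (AFU; ``standard`` may be negative)."""

    values: pd.DataFrame
    method: str
    params: object | None = None

    def __post_init__(self):
        if self.method not in CORRECTION_METHODS:
            raise ValidationError(f"unknown correction method {self.method!r}")


@dataclass
class TransformedMatrix:
    """gene (or spot) x array intensities on the log2 scale.

    ``log2`` leaves NaN exactly where the corrected intensity was <= 0;
    ``glog`` is total and never produces missing entries.
    """

    values: pd.DataFrame
    transform: str
    glog_params: GlogParams | None = None

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.transform == "glog":
            if self.glog_params is None:
                raise ValidationError("glog matrix requires glog_params")
            if self.values.isna().any().any():
                raise ValidationError("glog matrix must not contain missing entries")


# ---------------------------------------------------------------------------
# gold standard and DE results
# ---------------------------------------------------------------------------


@dataclass
class GoldStandard:
    """Reference per-gene log2 fold-changes and p-values (qPCR-like)."""

    table: pd.DataFrame  # columns: gene_id, logfc_gold, p_gold

    def __post_init__(self):
        df = self.table.reset_index(drop=True)
        for col in ("gene_id", "logfc_gold", "p_gold"):
            if col not in df.columns:
                raise FormatError(f"gold standard lacks column {col!r}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r} in gold standard")
        p = pd.to_numeric(df["p_gold"], errors="coerce")
        bad = ~((p > 0) & (p <= 1))
        if bad.any():
            raise ValidationError(
                f"p_gold outside (0, 1] at row index {int(np.flatnonzero(bad)[0])}"
            )
        df["logfc_gold"] = pd.to_numeric(df["logfc_gold"]).astype(float)
        df["p_gold"] = p.astype(float)
        self.table = df[["gene_id", "logfc_gold", "p_gold"]]

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("gene_id")


@dataclass
class DEResult:
    """Per-gene differential-expression result (sign convention: B minus A).

    ``table`` columns: gene_id, logfc, t_stat, p, ref_intensity; NaN marks
    genes the pipeline could not fit (e.g. all-negative corrected replicates
    under log2).  ``provenance`` records correction/transform methods and
    their parameters.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.table.reset_index(drop=True)
        for col in ("gene_id", "logfc", "t_stat", "p", "ref_intensity"):
            if col not in df.columns:
                raise FormatError(f"DE result lacks column {col!r}")
        p = pd.to_numeric(df["p"], errors="coerce")
        defined = p.notna()
        bad = defined & ~((p > 0) & (p <= 1))
        if bad.any():
            raise ValidationError(
                f"p outside (0, 1] at row index {int(np.flatnonzero(bad)[0])}"
            )
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in DE result")
        self.table = df

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("gene_id")


@dataclass(frozen=True)
class ConfusionTable:
    """Volcano-call agreement counts against a reference classification."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def metrics(self, ndigits: int | None = 3) -> dict:
        """sensitivity, specificity and accuracy; ``None`` where undefined."""
        sens = self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None
        spec = self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None
        acc = (self.tp + self.tn) / self.total if self.total else None
        out = {"sensitivity": sens, "specificity": spec, "accuracy": acc}
        if ndigits is not None:
            out = {k: (None if v is None else round(v, ndigits)) for k, v in out.items()}
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_spot_table(path) -> SpotDataset:
    """Read a long-format TSV spot table (one row per spot per array)."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    counts = df.groupby(["gene_id", "array_id"], sort=False).size()
    n_rep = int(counts.iloc[0]) if len(counts) else 1
    return SpotDataset(df, n_spot_replicates=n_rep)


def write_spot_table(dataset: SpotDataset, path) -> None:
    dataset.spots.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def read_gold_standard(path) -> GoldStandard:
    df = pd.read_csv(path, na_values=[NA_REP], keep_default_na=False)
    for col in ("gene_id", "logfc_gold", "p_gold"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return GoldStandard(df)


def write_gold_standard(gold: GoldStandard, path) -> None:
    gold.table.to_csv(path, index=False, na_rep=NA_REP)


def write_matrix(values: pd.DataFrame, path) -> None:
    """Write a gene x array (or spot x array) matrix as TSV.

    A spot-level matrix with a (gene_id, spot_replicate) MultiIndex is
    flattened to two leading columns.
    """
    out = values.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t", na_rep=NA_REP)


def read_matrix(path, spot_level: bool = False) -> pd.DataFrame:
    index_col = [0, 1] if spot_level else 0
    return pd.read_csv(
        path, sep="\t", index_col=index_col, na_values=[NA_REP], keep_default_na=False
    )


def write_de_result(de: DEResult, path) -> None:
    de.table.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def read_de_result(path) -> DEResult:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    for col in ("logfc", "t_stat", "p", "ref_intensity"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return DEResult(df)
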