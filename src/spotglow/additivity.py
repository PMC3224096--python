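"""Test of the additive-background hypothesis.

If background noise adds to the foreground, an increase of the local
background B should produce the same increase in the foreground F of a
spot whose specific hybridization is fixed.  Replicate spots of one gene
on one array share (roughly) the same hybridization, so the OLS slope of
F on B across those spots should be close to 1.  Slopes are pooled over
all (gene, array) pairs and summarised by a trimmed mean with a 95%
confidence interval; the spatial structure of B itself is exposed as a
dense grid plus a neighbour-correlation statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SpotDataset, ValidationError


@dataclass
class AdditivityResult:
    slopes: np.ndarray
    n_excluded: int
    trimmed_mean: float
    ci_low: float
    ci_high: float
    trim_fraction: float
    contains_one: bool = field(init=False)
    bootstrap_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.trimmed_mean <= self.ci_high):
            raise ValidationError("confidence interval must bracket the trimmed mean")
        self.contains_one = bool(self.ci_low <= 1.0 <= self.ci_high)


def per_spot_regression(f_triplet, b_triplet) -> float | None:
    """OLS slope of foreground on background over one gene's replicate spots.

    Returns ``None`` for degenerate triplets (constant background), which
    callers exclude and count.
    """
    f = np.asarray(f_triplet, dtype=float)
    b = np.asarray(b_triplet, dtype=float)
    if f.size < 2 or f.size != b.size:
        raise ValidationError("slope needs >= 2 paired spots")
    if np.ptp(b) == 0:
        return None
    bc = b - b.mean()
    return float(np.dot(bc, f - f.mean()) / np.dot(bc, bc))


def trimmed_mean_slope(slopes, trim_fraction: float = 0.05,
                       n_excluded: int = 0,
                       bootstrap: bool = False,
                       n_boot: int = 2000,
                       seed: int = 0) -> AdditivityResult:
    """Symmetrically trimmed mean of the slopes with a 95% CI.

    ``trim_fraction`` is the total fraction trimmed (half per tail).  The
    CI is trimmed mean +/- 1.96 * SE, with the SE of the trimmed mean
    computed from the winsorized variance; a seeded percentile bootstrap
    CI is available as a sensitivity check.
    """
    s = np.sort(np.asarray(slopes, dtype=float))
    s = s[np.isfinite(s)]
    n = s.size
    if n < 20:
        raise ValidationError(f"trimmed mean needs >= 20 slopes, got {n}")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValidationError("trim_fraction must be in [0, 1)")
    g = int(np.floor(n * trim_fraction / 2.0))
    core = s[g:n - g]
    tm = float(core.mean())
    winsor = np.concatenate([np.full(g, core[0]), core, np.full(g, core[-1])])
    var_w = float(np.var(winsor, ddof=1))
    se = np.sqrt(var_w / n) / (1.0 - 2.0 * g / n)
    ci = (tm - 1.96 * se, tm + 1.96 * se)
    boot_ci = None
    if bootstrap:
        rng = np.random.default_rng(seed)
        stats_boot = np.empty(n_boot)
        for i in range(n_boot):
            res = np.sort(rng.choice(s, size=n, replace=True))
            stats_boot[i] = res[g:n - g].mean()
        boot_ci = tuple(np.quantile(stats_boot, [0.025, 0.975]))
    return AdditivityResult(
        slopes=s,
        n_excluded=int(n_excluded),
        trimmed_mean=tm,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        trim_fraction=float(trim_fraction),
        bootstrap_ci=boot_ci,
    )


def all_slopes(dataset: SpotDataset) -> tuple[np.ndarray, int]:
    """All per-(gene, array) OLS slopes of F on B, vectorized.

    Returns the finite slopes and the number of degenerate (constant-B)
    triplets excluded; total = n_genes * n_arrays - n_excluded.
    """
    genes = dataset.gene_ids
    n_rep = dataset.n_spot_replicates
    f = dataset.spot_matrix("F").loc[genes]
    b = dataset.spot_matrix("B").loc[genes]
    n_genes, n_arrays = len(genes), f.shape[1]
    fa = f.to_numpy(float).reshape(n_genes, n_rep, n_arrays)
    ba = b.to_numpy(float).reshape(n_genes, n_rep, n_arrays)
    bc = ba - ba.mean(axis=1, keepdims=True)
    ssb = np.sum(bc**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = np.sum(bc * (fa - fa.mean(axis=1, keepdims=True)), axis=1) / ssb
    ok = ssb > 0
    return slopes[ok], int((~ok).sum())


def run_additivity_test(dataset: SpotDataset, trim_fraction: float = 0.05,
                        bootstrap: bool = False, seed: int = 0) -> AdditivityResult:
    """One slope per (gene, array), aggregated by the trimmed-mean estimator."""
    if dataset.n_spot_replicates < 2:
        raise ValidationError("additivity test needs >= 2 replicate spots per gene")
    slopes, n_excluded = all_slopes(dataset)
    return trimmed_mean_slope(
        slopes, trim_fraction=trim_fraction, n_excluded=n_excluded,
        bootstrap=bootstrap, seed=seed,
    )


def spatial_background_grid(dataset: SpotDataset, array_id: str) -> np.ndarray:
    """Dense (rows x cols) grid of local-background values for one array.

    Unspotted positions are NaN.  Intended for heatmap rendering and for
    :func:`neighbour_correlation`.
    """
    sub = dataset.spots[dataset.spots["array_id"] == array_id]
    if sub.empty:
        raise ValidationError(f"no spots for array {array_id!r}")
    if sub.duplicated(subset=["grid_row", "grid_col"]).any():
        raise ValidationError(f"duplicate grid coordinates on array {array_id!r}")
    rows = int(sub["grid_row"].max()) + 1
    cols = int(sub["grid_col"].max()) + 1
    grid = np.full((rows, cols), np.nan)
    grid[sub["grid_row"].to_numpy(int), sub["grid_col"].to_numpy(int)] = sub["B"].to_numpy(float)
    return grid


def neighbour_correlation(grid: np.ndarray) -> float:
    """Pearson correlation of background between grid-adjacent spots.

    Pools horizontal and vertical neighbour pairs with both cells observed.
    """
    pairs = []
    for a, b in ((grid[:, :-1], grid[:, 1:]), (grid[:-1, :], grid[1:, :])):
        ok = np.isfinite(a) & np.isfinite(b)
        pairs.append(np.stack([a[ok], b[ok]], axis=1))
    xy = np.concatenate(pairs, axis=0)
    if len(xy) < 3:
        raise ValidationError("too few adjacent observed pairs")
    if np.std(xy[:, 0]) == 0 or np.std(xy[:, 1]) == 0:
        raise ValidationError("neighbour correlation undefined: constant background")
    return float(np.corrcoef(xy[:, 0], xy[:, 1])[0, 1])
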