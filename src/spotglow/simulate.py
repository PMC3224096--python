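"""Synthetic spotted-array data with the statistical structure the
downstream analyses assume.

The generative model per spot is additive in the local background:

    F = background_slope * B_true + mu_{g,cond} * exp(eta) + eps,
    B_observed = B_true,

with a two-component measurement error — multiplicative log-normal
``eta ~ Normal(0, eta_sd^2)`` and additive ``eps ~ Normal(0, eps_sd^2)``
(truncated so F >= 0).  The true background ``B_true`` is a smooth spatial
surface (sum of low-frequency cosine modes) plus independent per-spot
noise.  Per-gene baselines are log-normal on the log2 scale; a fraction
``prop_de`` of genes carries a true log2 fold-change drawn uniformly in
magnitude with random sign.  Two sites share the same truth but are
otherwise independent replicate experiments.

Under this model the SD of log2(F - B_true) across replicates rises
sharply at low intensity while a suitably calibrated glog is roughly flat
— the structure the evaluation module measures.  A matched low-noise
"gold standard" emulates qPCR: a few replicate log2 measurements per
condition, t-tested per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ConfigurationError, GoldStandard, SpotDataset


@dataclass
class SimulationConfig:
    """Study conditions for the simulated spotted-array experiment.

    Defaults mirror a two-site, 5-arrays-per-condition design with
    triplicate spots per gene; intensities are arbitrary fluorescence
    units (AFU), fold-changes log2 units.
    """

    n_genes: int = 1000
    n_arrays_per_condition: int = 5
    n_spot_replicates: int = 3
    grid_shape: tuple[int, int] = (60, 50)
    background_mean: float = 100.0
    background_spatial_sd: float = 25.0
    background_spot_sd: float = 10.0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.5
    prop_de: float = 0.3
    logfc_range: tuple[float, float] = (0.5, 6.0)
    eta_sd: float = 0.25
    eps_sd: float = 40.0
    background_slope: float = 1.0
    gold_noise_sd: float = 0.1
    gold_n_replicates: int = 4
    n_sites: int = 2
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.grid_shape
        if rows * cols < self.n_genes * self.n_spot_replicates:
            raise ConfigurationError(
                f"grid {rows}x{cols} too small for {self.n_genes} genes x "
                f"{self.n_spot_replicates} spots"
            )
        for name in ("background_spatial_sd", "background_spot_sd", "eta_sd",
                     "eps_sd", "gold_noise_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.prop_de <= 1.0:
            raise ConfigurationError("prop_de must be in [0, 1]")
        if self.background_mean <= 0:
            raise ConfigurationError("background_mean must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["logfc_range"] = list(self.logfc_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "logfc_range" in d:
            d["logfc_range"] = tuple(d["logfc_range"])
        return cls(**d)


@dataclass
class SimulatedTruth:
    """Per-gene ground truth: baselines (AFU) and true log2 fold-change."""

    table: pd.DataFrame  # gene_id, true_logfc, is_de, mu_A, mu_B

    def __post_init__(self):
        df = self.table.reset_index(drop=True)
        mismatch = df["is_de"] != (df["true_logfc"] != 0)
        if mismatch.any():
            raise ConfigurationError("is_de must hold exactly where true_logfc != 0")
        self.table = df


_N_COSINE_MODES = 3


def simulate_background_field(
    grid_shape: tuple[int, int],
    background_mean: float,
    background_spatial_sd: float,
    background_spot_sd: float,
    seed,
) -> np.ndarray:
    """Smooth spatial background surface plus per-spot noise, clipped at 0.

    The spatial trend is a sum of low-frequency 2-D cosine modes (three per
    axis) with random amplitudes and phases, rescaled so its SD equals
    ``background_spatial_sd``; independent Normal(0, background_spot_sd)
    noise is added per cell.
    """
    rows, cols = grid_shape
    if rows < 1 or cols < 1:
        raise ConfigurationError("grid dimensions must be >= 1")
    if background_mean <= 0:
        raise ConfigurationError("background_mean must be positive")
    rng = np.random.default_rng(seed)
    r = np.arange(rows)[:, None] / max(rows, 1)
    c = np.arange(cols)[None, :] / max(cols, 1)
    surface = np.zeros((rows, cols))
    # amplitudes/phases are always drawn so the rng stream does not depend
    # on whether the trend is switched off
    amp_r = rng.normal(size=_N_COSINE_MODES)
    ph_r = rng.uniform(0, 2 * np.pi, _N_COSINE_MODES)
    amp_c = rng.normal(size=_N_COSINE_MODES)
    ph_c = rng.uniform(0, 2 * np.pi, _N_COSINE_MODES)
    for k in range(_N_COSINE_MODES):
        surface = surface + amp_r[k] * np.cos(2 * np.pi * (k + 1) * r + ph_r[k])
        surface = surface + amp_c[k] * np.cos(2 * np.pi * (k + 1) * c + ph_c[k])
    sd = surface.std()
    if background_spatial_sd > 0 and sd > 0:
        surface = (surface - surface.mean()) / sd * background_spatial_sd
    else:
        surface = np.zeros((rows, cols))
    noise = rng.normal(0.0, 1.0, size=(rows, cols)) * background_spot_sd
    return np.clip(background_mean + surface + noise, 0.0, None)


def _simulate_truth(config: SimulationConfig, rng: np.random.Generator) -> SimulatedTruth:
    n = config.n_genes
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    mu_a = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    n_de = int(round(config.prop_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    logfc = np.zeros(n)
    lo, hi = config.logfc_range
    magnitudes = rng.uniform(lo, hi, n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    logfc[de_idx] = magnitudes * signs
    mu_b = mu_a * 2.0 ** logfc
    return SimulatedTruth(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "true_logfc": logfc,
                "is_de": logfc != 0,
                "mu_A": mu_a,
                "mu_B": mu_b,
            }
        )
    )


_MAX_TRUNCATION_RESAMPLES = 100


def _draw_signal(mu: np.ndarray, bg: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """F = slope*B_true + mu*exp(eta) + eps, truncated at F >= 0.

    eps is resampled for offending spots a bounded number of times, then
    the remainder (a negligible tail) is clipped.
    """
    eta = rng.normal(0.0, config.eta_sd, mu.size)
    eps = rng.normal(0.0, config.eps_sd, mu.size)
    f = config.background_slope * bg + mu * np.exp(eta) + eps
    for _ in range(_MAX_TRUNCATION_RESAMPLES):
        neg = f < 0
        if not neg.any():
            break
        eps_new = rng.normal(0.0, config.eps_sd, int(neg.sum()))
        f[neg] = config.background_slope * bg[neg] + mu[neg] * np.exp(eta[neg]) + eps_new
    return np.clip(f, 0.0, None)


def simulate_dataset(config: SimulationConfig) -> tuple[SpotDataset, SimulatedTruth]:
    """Simulate the full two-site, two-condition spotted-array experiment."""
    root = np.random.SeedSequence(config.seed)
    truth_seq, layout_seq, arrays_seq = root.spawn(3)
    rng_truth = np.random.default_rng(truth_seq)
    truth = _simulate_truth(config, rng_truth)

    rows, cols = config.grid_shape
    n_spots = config.n_genes * config.n_spot_replicates
    # one physical layout shared by all arrays: (gene, replicate) -> grid cell
    layout_rng = np.random.default_rng(layout_seq)
    cells = layout_rng.permutation(rows * cols)[:n_spots]
    grid_rows = cells // cols
    grid_cols = cells % cols

    gene_col = np.repeat(truth.table["gene_id"].to_numpy(), config.n_spot_replicates)
    rep_col = np.tile(
        np.arange(1, config.n_spot_replicates + 1), config.n_genes
    )
    mu_by_cond = {
        "A": np.repeat(truth.table["mu_A"].to_numpy(), config.n_spot_replicates),
        "B": np.repeat(truth.table["mu_B"].to_numpy(), config.n_spot_replicates),
    }

    frames = []
    array_seqs = arrays_seq.spawn(config.n_sites * 2 * config.n_arrays_per_condition)
    k = 0
    for s in range(1, config.n_sites + 1):
        site = f"site{s}"
        for cond in ("A", "B"):
            for r in range(1, config.n_arrays_per_condition + 1):
                bg_seq, sig_seq = array_seqs[k].spawn(2)
                k += 1
                field_grid = simulate_background_field(
                    config.grid_shape,
                    config.background_mean,
                    config.background_spatial_sd,
                    config.background_spot_sd,
                    bg_seq,
                )
                b_true = field_grid[grid_rows, grid_cols]
                f = _draw_signal(
                    mu_by_cond[cond], b_true, config, np.random.default_rng(sig_seq)
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_col,
                            "site": site,
                            "condition": cond,
                            "array_id": f"{site}_{cond}{r}",
                            "spot_replicate": rep_col,
                            "grid_row": grid_rows,
                            "grid_col": grid_cols,
                            "F": f,
                            "B": b_true,
                        }
                    )
                )
    spots = pd.concat(frames, ignore_index=True)
    return SpotDataset(spots, config.n_spot_replicates), truth


def simulate_gold_standard(
    truth: SimulatedTruth,
    gold_noise_sd: float,
    gold_n_replicates: int = 4,
    seed=0,
    moderated: bool = True,
) -> GoldStandard:
    """qPCR-like reference: replicate log2 measurements, moderated per gene.

    Each gene gets ``gold_n_replicates`` measurements per condition equal
    to the true log2 level plus Normal(0, gold_noise_sd) noise;
    ``logfc_gold`` is the difference of condition means.  ``p_gold``
    comes from the same two-group linear-model + empirical-Bayes
    moderation used for the array pipelines (``moderated=False`` gives
    the plain pooled two-sample t-test instead).  p-values are clipped
    into (0, 1] so noise-free degenerate cases stay representable.
    """
    if gold_noise_sd < 0:
        raise ConfigurationError("gold_noise_sd must be >= 0")
    if gold_n_replicates < 2:
        raise ConfigurationError("gold_n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    t = truth.table
    n = len(t)
    la = np.log2(t["mu_A"].to_numpy())[:, None] + rng.normal(
        0.0, gold_noise_sd, (n, gold_n_replicates)
    )
    lb = np.log2(t["mu_B"].to_numpy())[:, None] + rng.normal(
        0.0, gold_noise_sd, (n, gold_n_replicates)
    )
    logfc = lb.mean(axis=1) - la.mean(axis=1)
    s2 = (
        np.sum((la - la.mean(axis=1, keepdims=True)) ** 2, axis=1)
        + np.sum((lb - lb.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ) / (2 * gold_n_replicates - 2)
    df = float(2 * gold_n_replicates - 2)
    v = 2.0 / gold_n_replicates
    p = _gold_pvalues(logfc, s2, df, v, moderated=moderated)
    # zero-variance degeneracies: identical groups -> p = 1; exact separation -> p ~ 0
    p = np.where(np.isnan(p), np.where(logfc == 0, 1.0, np.nextafter(0, 1)), p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return GoldStandard(
        pd.DataFrame({"gene_id": t["gene_id"], "logfc_gold": logfc, "p_gold": p})
    )


def _gold_pvalues(logfc: np.ndarray, s2: np.ndarray, df: float, v: float,
                  moderated: bool) -> np.ndarray:
    from .datamodel import FittingError
    from .inference import estimate_prior  # deferred: inference imports this module's peers

    df_vec = np.full_like(s2, df)
    prior = None
    if moderated:
        try:
            prior = estimate_prior(s2, df_vec)
        except FittingError:
            prior = None
    with np.errstate(divide="ignore", invalid="ignore"):
        if prior is None or prior.d0 == 0:
            tstat = logfc / np.sqrt(s2 * v)
            return 2.0 * stats.t.sf(np.abs(tstat), df)
        if np.isinf(prior.d0):
            tstat = logfc / np.sqrt(prior.s0_sq * v)
            return 2.0 * stats.norm.sf(np.abs(tstat))
        s2_post = (prior.d0 * prior.s0_sq + df_vec * s2) / (prior.d0 + df_vec)
        tstat = logfc / np.sqrt(s2_post * v)
        return 2.0 * stats.t.sf(np.abs(tstat), prior.d0 + df_vec)
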