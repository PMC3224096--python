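"""Normalization, replicate-spot averaging, and differential-expression
inference.

The pipeline for one preprocessing method is

    correct -> transform -> global-median normalize -> average replicate
    spots -> per-gene linear model -> empirical-Bayes moderation,

with the log2 fold-change defined as condition B minus condition A.  The
moderated t shrinks per-gene variances toward a scaled-F prior (d0, s0^2)
estimated across genes from the marginal distribution of log residual
variances, and gains d0 extra degrees of freedom.  The hybrid method
takes fold-changes from the log2 pipeline and t/p-values from the glog
pipeline run under the same background correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from . import background, transforms
from .datamodel import (
    CorrectedMatrix,
    DEResult,
    FittingError,
    GlogParams,
    SpotDataset,
    TransformedMatrix,
    ValidationError,
)


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled-F prior for per-gene variances: d0 degrees of freedom, s0^2 location."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0:
            raise ValidationError("d0 must be >= 0 (0 disables moderation)")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise ValidationError("s0_sq must be > 0")


def global_median_normalize(matrix: TransformedMatrix) -> TransformedMatrix:
    """Shift each array so all array medians equal the grand median.

    The grand median is the median of the per-array medians, which makes
    the operation idempotent; within-array differences are untouched.
    """
    vals = matrix.values
    medians = vals.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()][0]
        raise ValidationError(f"array {bad!r} has no finite value to normalize")
    grand = float(medians.median())
    out = vals.sub(medians, axis=1) + grand
    return TransformedMatrix(out, matrix.transform, matrix.glog_params)


def average_replicate_spots(
    matrix: TransformedMatrix, dataset: SpotDataset | None = None
) -> TransformedMatrix:
    """Per gene per array, mean of the non-missing replicate-spot values."""
    vals = matrix.values
    if not isinstance(vals.index, pd.MultiIndex):
        raise ValidationError("expected a spot-level matrix indexed by (gene_id, spot_replicate)")
    gene_order = vals.index.get_level_values(0).unique()
    out = vals.groupby(level=0, sort=False).mean()
    out = out.loc[gene_order]
    out.index.name = "gene_id"
    if matrix.transform == "glog":
        return TransformedMatrix(out, "glog", matrix.glog_params)
    return TransformedMatrix(out, matrix.transform, matrix.glog_params)


@dataclass
class LinearFits:
    """Per-gene two-group linear-model summaries.

    logfc = mean(B) - mean(A); s2 the pooled residual variance with df
    residual degrees of freedom; v the unscaled variance factor
    1/n_A + 1/n_B.  NaN rows mark genes with fewer than two finite values
    in either condition.
    """

    table: pd.DataFrame  # index gene_id; columns logfc, s2, df, v


def fit_linear_model(matrix: TransformedMatrix, design: pd.Series) -> LinearFits:
    """Two-sample linear model per gene from a gene x array matrix.

    ``design`` maps array_id -> condition ('A'/'B').  Genes need at least
    two finite values per condition; others get all-NaN rows.
    """
    vals = matrix.values
    cond = design.reindex(vals.columns)
    if cond.isna().any():
        raise ValidationError("design missing for some arrays")
    a = vals.loc[:, (cond == "A").to_numpy()].to_numpy(dtype=float)
    b = vals.loc[:, (cond == "B").to_numpy()].to_numpy(dtype=float)
    na = np.sum(np.isfinite(a), axis=1)
    nb = np.sum(np.isfinite(b), axis=1)
    ok = (na >= 2) & (nb >= 2)
    if not ok.any():
        raise ValidationError("no gene has >= 2 finite values in both conditions")
    with np.errstate(invalid="ignore"):
        mean_a = np.where(na > 0, np.nansum(a, axis=1) / np.maximum(na, 1), np.nan)
        mean_b = np.where(nb > 0, np.nansum(b, axis=1) / np.maximum(nb, 1), np.nan)
        ss_a = np.nansum((a - mean_a[:, None]) ** 2, axis=1)
        ss_b = np.nansum((b - mean_b[:, None]) ** 2, axis=1)
    df = na + nb - 2.0
    s2 = np.where(df > 0, (ss_a + ss_b) / np.where(df > 0, df, 1.0), np.nan)
    out = pd.DataFrame(
        {
            "logfc": np.where(ok, mean_b - mean_a, np.nan),
            "s2": np.where(ok, s2, np.nan),
            "df": np.where(ok, df, np.nan),
            "v": np.where(ok, 1.0 / na + 1.0 / nb, np.nan),
        },
        index=vals.index,
    )
    return LinearFits(out)


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> EBayesPrior:
    """Moment-match the scaled-F prior from observed log residual variances.

    Under the hierarchical model, e_g = ln s_g^2 - digamma(d_g/2) +
    ln(d_g/2) has mean ln s0^2 + digamma(d0/2) - ln(d0/2) and variance
    trigamma(d_g/2) + trigamma(d0/2); d0 follows by inverting the
    trigamma function, s0^2 from the mean equation.
    """
    ok = np.isfinite(s2) & np.isfinite(df) & (df >= 1) & (s2 > 0)
    if not ok.any():
        raise FittingError("cannot estimate prior: no positive residual variance")
    s2, df = s2[ok], df[ok]
    if s2.size < 10:
        raise FittingError("cannot estimate prior: fewer than 10 usable genes")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(
    fits: LinearFits,
    prior: EBayesPrior | None = None,
    ref_intensity: pd.Series | None = None,
    provenance: dict | None = None,
) -> DEResult:
    """Moderated t-statistics and p-values from per-gene linear fits.

    Posterior variance s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g);
    moderated t = logfc / (s~_g sqrt(v)); two-sided p from Student t with
    d0 + d_g degrees of freedom.  d0 = 0 reproduces the classical pooled
    two-sample t exactly; d0 = inf pins every variance at s0^2.
    """
    tab = fits.table
    s2 = tab["s2"].to_numpy(dtype=float)
    df = tab["df"].to_numpy(dtype=float)
    if prior is None:
        prior = estimate_prior(s2, df)
    d0, s0_sq = prior.d0, prior.s0_sq
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        elif d0 == 0:
            s2_post = s2
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        t = tab["logfc"].to_numpy(dtype=float) / np.sqrt(s2_post * tab["v"].to_numpy(dtype=float))
        df_total = df + (0.0 if np.isinf(d0) else d0)
        if np.isinf(d0):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(t), np.clip(p, np.nextafter(0, 1), 1.0), np.nan)
    ref = (
        ref_intensity.reindex(tab.index).to_numpy(dtype=float)
        if ref_intensity is not None
        else np.full(len(tab), np.nan)
    )
    prov = dict(provenance or {})
    prov["ebayes_prior"] = {"d0": float(d0), "s0_sq": float(s0_sq)}
    return DEResult(
        pd.DataFrame(
            {
                "gene_id": tab.index,
                "logfc": tab["logfc"].to_numpy(dtype=float),
                "t_stat": np.where(np.isfinite(t), t, np.nan),
                "p": p,
                "ref_intensity": ref,
            }
        ),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def preprocess(
    dataset: SpotDataset,
    correction: str,
    transform: str,
    glog_params: GlogParams | None = None,
    correction_kwargs: dict | None = None,
) -> tuple[TransformedMatrix, GlogParams | None]:
    """correct -> transform -> normalize -> average, at gene level.

    glog parameters, when not supplied, are estimated once from the
    Standard-corrected intensities (alpha then absorbs any residual
    additive offset of the chosen correction).
    """
    corrected = background.correct(dataset, correction, **(correction_kwargs or {}))
    if transform == "log2":
        tm = transforms.log2_transform(corrected)
    elif transform == "glog":
        if glog_params is None:
            ref_corrected = (
                corrected
                if correction == "standard"
                else background.correct_standard(dataset)
            )
            glog_params = transforms.estimate_glog_params(
                ref_corrected, dataset.array_conditions()
            )
        tm = transforms.glog_transform(corrected, glog_params)
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    tm = global_median_normalize(tm)
    gene_level = average_replicate_spots(tm, dataset)
    return gene_level, glog_params


def run_pipeline(
    dataset: SpotDataset,
    correction: str = "standard",
    transform: str = "log2",
    glog_params: GlogParams | None = None,
    prior: EBayesPrior | None = None,
    correction_kwargs: dict | None = None,
) -> DEResult:
    """Full single-method pipeline from spots to a per-gene DEResult.

    ``transform='hybrid'`` runs both the log2 and the glog pipeline under
    the same correction and combines them via :func:`hybrid_combine`.
    """
    if transform == "hybrid":
        de_log2 = run_pipeline(dataset, correction, "log2", None, prior, correction_kwargs)
        de_glog = run_pipeline(dataset, correction, "glog", glog_params, prior, correction_kwargs)
        return hybrid_combine(de_log2, de_glog)
    gene_level, fitted_glog = preprocess(
        dataset, correction, transform, glog_params, correction_kwargs
    )
    design = dataset.array_conditions()
    fits = fit_linear_model(gene_level, design)
    from .evaluation import reference_intensity  # local import to avoid a cycle

    ref = reference_intensity(dataset)
    prov = {"correction": correction, "transform": transform}
    if fitted_glog is not None:
        prov["glog_params"] = {"alpha": fitted_glog.alpha, "lambda_": fitted_glog.lambda_}
    if prior is None:
        try:
            prior = estimate_prior(
                fits.table["s2"].to_numpy(float), fits.table["df"].to_numpy(float)
            )
        except FittingError:
            # degenerate (e.g. noise-free) data: report unmoderated statistics
            prior = EBayesPrior(d0=0.0, s0_sq=1.0)
    return ebayes_moderate(fits, prior, ref_intensity=ref, provenance=prov)


def hybrid_combine(de_log2: DEResult, de_glog: DEResult) -> DEResult:
    """Fold-changes from the log2 pipeline, t/p-values from the glog one."""
    t2, tg = de_log2.indexed(), de_glog.indexed()
    if set(t2.index) != set(tg.index):
        raise ValidationError("hybrid combination requires identical gene sets")
    c2 = de_log2.provenance.get("correction")
    cg = de_glog.provenance.get("correction")
    if c2 is not None and cg is not None and c2 != cg:
        raise ValidationError(
            f"hybrid combination requires the same correction ({c2!r} != {cg!r})"
        )
    tg = tg.loc[t2.index]
    out = pd.DataFrame(
        {
            "gene_id": t2.index,
            "logfc": t2["logfc"].to_numpy(),
            "t_stat": tg["t_stat"].to_numpy(),
            "p": tg["p"].to_numpy(),
            "ref_intensity": t2["ref_intensity"].to_numpy(),
        }
    )
    prov = {
        "correction": c2,
        "transform": "hybrid",
        "logfc_from": de_log2.provenance,
        "p_from": de_glog.provenance,
    }
    return DEResult(out, provenance=prov)
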