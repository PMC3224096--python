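"""log2 and generalized-log (glog) transformations.

glog(x; alpha, lambda) = ln(x - alpha + sqrt((x - alpha)^2 + lambda)),
reported on the log2 scale (multiplied by log2(e)) so both transforms are
directly comparable.  Unlike log2 it is defined for negative corrected
intensities, strictly increasing, and converges to log2(x) at high
intensity; with alpha = 0, lambda = 1 it equals log2(e) * arcsinh(x).

Parameters (alpha, lambda) are estimated by transform-both-sides maximum
likelihood on replicated intensities, assuming constant variance of the
transformed values within each gene x condition group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datamodel import (
    CorrectedMatrix,
    FittingError,
    GlogParams,
    TransformedMatrix,
    ValidationError,
)

LOG2E = float(np.log2(np.e))


def log2_transform(corrected: CorrectedMatrix) -> TransformedMatrix:
    """Entry-wise log2; entries <= 0 become missing (NaN)."""
    vals = corrected.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return TransformedMatrix(
        pd.DataFrame(out, index=corrected.values.index, columns=corrected.values.columns),
        transform="log2",
    )


def glog_values(x, alpha: float, lambda_: float) -> np.ndarray:
    """glog on the log2 scale, numerically stable for y = x - alpha << 0.

    For y < 0 the direct sum y + sqrt(y^2 + lambda) cancels; the
    rationalized form lambda / (sqrt(y^2 + lambda) - y) is used instead.
    """
    if lambda_ <= 0:
        raise ValidationError(f"glog lambda must be > 0, got {lambda_}")
    y = np.asarray(x, dtype=float) - alpha
    root = np.sqrt(y**2 + lambda_)
    with np.errstate(divide="ignore"):  # unused branch may hit root == y
        inner = np.where(y >= 0, y + root, lambda_ / (root - y))
    return LOG2E * np.log(inner)


def glog_transform(corrected: CorrectedMatrix, params: GlogParams) -> TransformedMatrix:
    out = glog_values(corrected.values.to_numpy(dtype=float), params.alpha, params.lambda_)
    return TransformedMatrix(
        pd.DataFrame(out, index=corrected.values.index, columns=corrected.values.columns),
        transform="glog",
        glog_params=params,
    )


# ---------------------------------------------------------------------------
# parameter estimation (transform-both-sides maximum likelihood)
# ---------------------------------------------------------------------------


def _tbs_negloglik(alpha: float, lambda_: float, x: np.ndarray,
                   groups: np.ndarray, n_groups: int) -> float:
    """Profile negative log-likelihood of (alpha, lambda).

    Model: glog-transformed replicates are Normal with a free mean per
    gene x condition group and one common variance.  Profiling out the
    means and the variance leaves

        -l = (N/2) ln(SS_within / N) - sum log J(x),

    with Jacobian J(x) = 1 / sqrt((x - alpha)^2 + lambda) (the log2(e)
    scale factor shifts the likelihood by a constant and is dropped).
    """
    y = x - alpha
    sq = y**2 + lambda_
    h = np.log(y + np.sqrt(sq)) if np.all(y >= 0) else np.log(
        np.where(y >= 0, y + np.sqrt(sq), lambda_ / (np.sqrt(sq) - y))
    )
    n = x.size
    sums = np.bincount(groups, weights=h, minlength=n_groups)
    counts = np.bincount(groups, minlength=n_groups)
    means = sums / counts
    ss = float(np.sum((h - means[groups]) ** 2))
    if ss <= 0:
        return np.inf
    log_jac = -0.5 * float(np.sum(np.log(sq)))
    return 0.5 * n * np.log(ss / n) - log_jac


def estimate_glog_params(
    corrected: CorrectedMatrix,
    conditions: pd.Series,
    fix_alpha: float | None = None,
) -> GlogParams:
    """Estimate (alpha, lambda) from replicated corrected intensities.

    ``conditions`` maps array_id -> condition label; replicate groups are
    gene x condition (every array of a condition is a replicate; replicate
    spots within an array are additional replicates of the same group).
    A coarse grid over lambda (log-spaced, scaled to the data) and alpha
    (between 0 and the 5th percentile of x) seeds a Nelder-Mead
    refinement.
    """
    vals = corrected.values
    cond = conditions.reindex(vals.columns)
    if cond.isna().any():
        raise ValidationError("conditions missing for some arrays")

    gene_index = vals.index.get_level_values(0) if isinstance(vals.index, pd.MultiIndex) \
        else vals.index
    gene_codes, _ = pd.factorize(gene_index)
    cond_codes, _ = pd.factorize(cond.to_numpy())

    x_list, grp_list = [], []
    n_genes = gene_codes.max() + 1
    for j, col in enumerate(vals.columns):
        v = vals[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        x_list.append(v[ok])
        grp_list.append((gene_codes[ok] * 2 + cond_codes[j]))
    x = np.concatenate(x_list)
    groups = np.concatenate(grp_list)
    n_group_slots = int(n_genes * 2)

    counts = np.bincount(groups, minlength=n_group_slots)
    usable = counts[groups] >= 2
    x, groups = x[usable], groups[usable]
    if np.unique(groups[np.isfinite(x)]).size < 50:
        raise FittingError("glog estimation needs >= 50 genes with replicated values")
    groups = pd.factorize(groups)[0]
    n_groups = groups.max() + 1

    # degenerate: no within-group variability at all
    probe = _tbs_negloglik(0.0, float(np.var(x) + 1.0), x, groups, n_groups)
    if not np.isfinite(probe):
        raise FittingError("glog estimation is degenerate: zero within-group variance")

    scale = float(np.median(np.abs(x - np.median(x)))) or float(np.std(x)) or 1.0
    lam_grid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 25)) * scale**2
    if fix_alpha is None:
        q5 = float(np.percentile(x, 5))
        alpha_grid = np.linspace(0.0, max(q5, 0.0), 5)
    else:
        alpha_grid = np.array([fix_alpha])

    best = (np.inf, 0.0, scale**2)
    for a in alpha_grid:
        for lam in lam_grid:
            nll = _tbs_negloglik(a, lam, x, groups, n_groups)
            if nll < best[0]:
                best = (nll, float(a), float(lam))

    if fix_alpha is None:
        def obj(theta):
            a, loglam = theta
            if a < 0:
                return np.inf
            return _tbs_negloglik(a, np.exp(loglam), x, groups, n_groups)
        start = np.array([best[1], np.log(best[2])])
    else:
        def obj(theta):
            return _tbs_negloglik(fix_alpha, np.exp(theta[0]), x, groups, n_groups)
        start = np.array([np.log(best[2])])

    res = minimize(obj, start, method="Nelder-Mead",
                   options={"maxiter": 1000, "xatol": 1e-6, "fatol": 1e-9})
    if fix_alpha is None:
        alpha = float(max(res.x[0], 0.0))
        lam = float(np.exp(res.x[1]))
    else:
        alpha = float(fix_alpha)
        lam = float(np.exp(res.x[0]))
    if not np.isfinite(lam) or lam <= 0:
        raise FittingError("glog estimation did not converge", best=res)
    return GlogParams(alpha=alpha, lambda_=lam)
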