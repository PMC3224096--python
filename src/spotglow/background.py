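"""Background-correction methods for spot-level intensities.

Four corrections are provided:

* ``standard`` — plain subtraction F - B (negative values preserved);
* ``none`` — no subtraction, corrected = F;
* ``edwards`` — subtraction replaced below a small threshold delta by a
  smooth, strictly positive, monotone function of F, so the log2 pipeline
  never produces missing values;
* ``normexp`` — posterior-mean signal under the normal-plus-exponential
  convolution model, fitted per array by maximum likelihood.

All corrections return a spot-level :class:`CorrectedMatrix` with rows
``(gene_id, spot_replicate)`` and one column per array.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr

from .datamodel import (
    CorrectedMatrix,
    EdwardsParams,
    FittingError,
    NormexpParams,
    SpotDataset,
    ValidationError,
)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def correct_standard(dataset: SpotDataset) -> CorrectedMatrix:
    """corrected = F - B per spot; negatives are kept as-is."""
    f = dataset.spot_matrix("F")
    b = dataset.spot_matrix("B")
    return CorrectedMatrix(f - b, method="standard")


def correct_none(dataset: SpotDataset) -> CorrectedMatrix:
    """corrected = F; the local background is ignored entirely."""
    return CorrectedMatrix(dataset.spot_matrix("F"), method="none")


def edwards_correct_values(f: np.ndarray, b: np.ndarray, delta: float) -> np.ndarray:
    """Edwards correction of foreground ``f`` given background ``b``.

    Returns F - B where F - B > delta and delta * exp(1 - (B + delta)/F)
    otherwise.  The two branches agree at F - B = delta, the result is
    strictly positive and strictly increasing in F for fixed B.
    """
    f = np.asarray(f, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(f <= 0):
        raise ValidationError("Edwards correction requires F > 0 for every spot")
    diff = f - b
    smooth = delta * np.exp(1.0 - (b + delta) / f)
    return np.where(diff > delta, diff, smooth)


def correct_edwards(dataset: SpotDataset, params: EdwardsParams | None = None) -> CorrectedMatrix:
    if params is None:
        params = default_edwards_delta(dataset)
    f = dataset.spot_matrix("F")
    b = dataset.spot_matrix("B")
    out = f.copy()
    for array_id in f.columns:
        out[array_id] = edwards_correct_values(
            f[array_id].to_numpy(), b[array_id].to_numpy(), params.for_array(array_id)
        )
    return CorrectedMatrix(out, method="edwards", params=params)


def default_edwards_delta(dataset: SpotDataset) -> EdwardsParams:
    """Per-array default threshold for the Edwards correction.

    delta is the quantile of the F - B differences at probability
    1.1 * (fraction of non-positive differences) — just above the largest
    non-positive difference, the convention of the reference
    backgroundCorrect implementation — floored by the smallest strictly
    positive difference so delta is always positive.
    """
    diff = dataset.spots["F"] - dataset.spots["B"]
    deltas: dict[str, float] = {}
    for array_id, d in diff.groupby(dataset.spots["array_id"], sort=False):
        pos = d[d > 0]
        if pos.empty:
            raise ValidationError(
                f"array {array_id!r} has no spot with F > B; cannot choose Edwards delta"
            )
        q = float(d.quantile(min(1.1 * float((d <= 0).mean()), 1.0)))
        deltas[str(array_id)] = max(q, float(pos.min()))
    return EdwardsParams(delta=deltas)


# ---------------------------------------------------------------------------
# normexp
# ---------------------------------------------------------------------------


def _normexp_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    """Negative log-likelihood; theta = (mu, log sigma, log alpha)."""
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    z = (x - mu) / sigma - sigma / alpha
    ll = -log_alpha + (mu - x) / alpha + sigma**2 / (2.0 * alpha**2) + log_ndtr(z)
    total = ll.sum()
    if not np.isfinite(total):
        return 1e300
    return -float(total)


def _moment_start(x: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments start: background stats from the left half, signal
    mean from the excess over the background mean."""
    med = np.median(x)
    left = x[x <= med]
    mu0 = float(np.mean(left))
    sigma0 = float(np.std(left - mu0, ddof=1))
    if sigma0 <= 0:
        sigma0 = max(1e-3, 0.1 * abs(mu0) + 1e-3)
    alpha0 = float(max(np.mean(x) - mu0, sigma0 / 10.0))
    return mu0, sigma0, alpha0


def fit_normexp(x, max_restarts: int = 5, seed: int = 0) -> NormexpParams:
    """Maximum-likelihood fit of the normal + exponential convolution model.

    The density of an observation x = N + S with N ~ Normal(mu, sigma^2)
    and S ~ Exponential(mean alpha) is

        f(x) = (1/alpha) exp((mu - x)/alpha + sigma^2/(2 alpha^2))
               * Phi((x - mu)/sigma - sigma/alpha).

    Optimization is Nelder-Mead over (mu, log sigma, log alpha) from a
    moment start plus jittered restarts.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise FittingError(f"normexp fit needs >= 100 finite values, got {x.size}")
    if np.std(x) == 0:
        raise FittingError("normexp fit is degenerate: input has zero variance")
    mu0, sigma0, alpha0 = _moment_start(x)
    starts = [np.array([mu0, np.log(sigma0), np.log(alpha0)])]
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        jitter = rng.normal(0.0, [0.2 * sigma0 + 1e-6, 0.3, 0.3])
        starts.append(starts[0] + jitter)
    best = None
    for s in starts:
        res = minimize(
            _normexp_negloglik,
            s,
            args=(x,),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FittingError("normexp fit did not converge", best=best)
    mu, log_sigma, log_alpha = best.x
    return NormexpParams(
        mu=float(mu),
        sigma=float(np.exp(log_sigma)),
        alpha_signal=float(np.exp(log_alpha)),
        log_likelihood=float(-best.fun),
    )


def normexp_loglik(x, params: NormexpParams) -> float:
    """Total log-likelihood of ``x`` under the convolution model."""
    x = np.asarray(x, dtype=float)
    theta = np.array([params.mu, np.log(params.sigma), np.log(params.alpha_signal)])
    return -_normexp_negloglik(theta, x[np.isfinite(x)])


def correct_normexp_values(x, params: NormexpParams) -> np.ndarray:
    """Posterior mean E[S | X = x]: strictly positive, increasing in x.

    corrected = mu_sf + sigma * phi(mu_sf/sigma) / Phi(mu_sf/sigma) with
    mu_sf = x - mu - sigma^2/alpha.  The Mills-ratio term is evaluated
    through log-space (log_ndtr) so the far-left tail stays stable.
    """
    x = np.asarray(x, dtype=float)
    sigma = params.sigma
    mu_sf = x - params.mu - sigma**2 / params.alpha_signal
    z = mu_sf / sigma
    log_phi = -0.5 * z**2 - _LOG_SQRT_2PI
    ratio = np.exp(log_phi - log_ndtr(z))  # phi(z)/Phi(z)
    out = sigma * (z + ratio)
    return np.maximum(out, np.finfo(float).tiny)


def correct_normexp(dataset: SpotDataset, params: NormexpParams | dict | None = None,
                    seed: int = 0) -> CorrectedMatrix:
    """Fit (per array, on F - B values) and apply the normexp correction."""
    f = dataset.spot_matrix("F")
    b = dataset.spot_matrix("B")
    diff = f - b
    out = diff.copy()
    fitted: dict[str, NormexpParams] = {}
    for array_id in diff.columns:
        if params is None:
            p = fit_normexp(diff[array_id].to_numpy(), seed=seed)
        elif isinstance(params, dict):
            p = params[array_id]
        else:
            p = params
        fitted[str(array_id)] = p
        out[array_id] = correct_normexp_values(diff[array_id].to_numpy(), p)
    return CorrectedMatrix(out, method="normexp", params=fitted)


_CORRECTORS = {
    "standard": correct_standard,
    "none": correct_none,
    "edwards": correct_edwards,
    "normexp": correct_normexp,
}


def correct(dataset: SpotDataset, method: str, **kwargs) -> CorrectedMatrix:
    """Dispatch to one of the four correction methods by name."""
    try:
        fn = _CORRECTORS[method]
    except KeyError:
        raise ValidationError(f"unknown correction method {method!r}") from None
    return fn(dataset, **kwargs)
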