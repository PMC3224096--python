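"""Comparison machinery: fold-change compression, variance curves,
concordance with a gold standard, probit p-value concordance, volcano
classification and confusion metrics.

Conventions used throughout:

* the per-gene *reference intensity* is always computed after the
  Standard background correction and the log2 transformation — the
  minimum over conditions of the mean processed intensity — regardless
  of which method is being evaluated, so every method is plotted on the
  same x-axis;
* *compression* is |gold log2 fold-change| minus |platform log2
  fold-change|: positive values mean the platform attenuates effect
  sizes, negative values mean expansion;
* concordance is summarised by the Pearson product-moment correlation r
  and by the one-way random-effects single-measure intraclass
  correlation ICC(1,1) = (MSB - MSW) / (MSB + MSW) for two measurements
  per gene — the ICC penalises location and scale disagreement that r
  ignores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from . import background, transforms
from .datamodel import (
    ConfusionTable,
    DEResult,
    GoldStandard,
    SpotDataset,
    ValidationError,
)
from .inference import average_replicate_spots, global_median_normalize, preprocess, run_pipeline, hybrid_combine

DEFAULT_LOWESS_FRAC = 0.3
DEFAULT_LOWESS_ITERS = 3

P_CLIP_LO = 1e-300
P_CLIP_HI = 1.0 - 1e-16


@dataclass(frozen=True)
class VolcanoThresholds:
    """Joint calling rule: |log2 fold-change| > fc AND p < p (strict)."""

    fc_threshold: float = 1.0
    p_threshold: float = 1e-6


@dataclass
class ConcordanceResult:
    pearson_r: float
    icc: float
    n: int


@dataclass
class CompressionCurve:
    points: pd.DataFrame  # columns: ref_intensity, compression
    lowess: pd.DataFrame  # columns: x, y (x strictly increasing)
    method: str


# ---------------------------------------------------------------------------
# reference intensity
# ---------------------------------------------------------------------------


def reference_intensity(dataset: SpotDataset) -> pd.Series:
    """Per-gene min over conditions of mean log2(Standard-corrected) intensity.

    The mean is over all arrays and replicate spots of one condition,
    ignoring missing (non-positive corrected) values; the result is
    missing when a condition has no finite value at all.
    """
    corrected = background.correct_standard(dataset)
    logged = transforms.log2_transform(corrected).values
    cond = dataset.array_conditions()
    means = {}
    for c in ("A", "B"):
        cols = [a for a in logged.columns if cond[a] == c]
        # gene mean over replicate spots and arrays jointly, NaN-aware
        flat = logged[cols].stack(future_stack=True)
        means[c] = flat.groupby(level=0, sort=False).mean()
    genes = logged.index.get_level_values(0).unique()
    out = pd.concat([means["A"].reindex(genes), means["B"].reindex(genes)], axis=1).min(
        axis=1, skipna=False
    )
    out.name = "ref_intensity"
    return out


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------


def compression_per_gene(de: DEResult, gold: GoldStandard) -> pd.DataFrame:
    """|gold logFC| - |platform logFC| per shared gene, with reference intensity."""
    d = de.indexed()
    g = gold.indexed()
    shared = d.index.intersection(g.index)
    d = d.loc[shared]
    ok = d["logfc"].notna()
    if not ok.any():
        raise ValidationError("no shared gene with a finite platform fold-change")
    d = d[ok]
    comp = g.loc[d.index, "logfc_gold"].abs() - d["logfc"].abs()
    return pd.DataFrame(
        {"ref_intensity": d["ref_intensity"], "compression": comp}
    ).reset_index()


def lowess_curve(
    x,
    y,
    frac: float = DEFAULT_LOWESS_FRAC,
    iters: int = DEFAULT_LOWESS_ITERS,
) -> pd.DataFrame:
    """Robust locally weighted regression, evaluated at sorted unique x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 10:
        raise ValidationError(f"lowess needs >= 10 finite pairs, got {int(ok.sum())}")
    fitted = _sm_lowess(y[ok], x[ok], frac=frac, it=iters, return_sorted=True)
    df = pd.DataFrame(fitted, columns=["x", "y"])
    df = df.groupby("x", as_index=False, sort=True)["y"].mean()
    return df


def compression_curve(
    de: DEResult,
    gold: GoldStandard,
    method: str = "",
    frac: float = DEFAULT_LOWESS_FRAC,
    iters: int = DEFAULT_LOWESS_ITERS,
) -> CompressionCurve:
    pts = compression_per_gene(de, gold)
    fit = lowess_curve(pts["ref_intensity"], pts["compression"], frac=frac, iters=iters)
    return CompressionCurve(points=pts, lowess=fit, method=method)


# ---------------------------------------------------------------------------
# SD-versus-intensity
# ---------------------------------------------------------------------------


def sd_vs_intensity(
    dataset: SpotDataset,
    correction: str,
    transform: str,
    glog_params=None,
    frac: float = DEFAULT_LOWESS_FRAC,
    iters: int = DEFAULT_LOWESS_ITERS,
) -> dict:
    """SD across replicate arrays of the processed values, one point per
    gene x condition, against the Standard+log2 mean intensity of the same
    gene x condition; plus a lowess fit.
    """
    processed, _ = preprocess(dataset, correction, transform, glog_params)
    ref_gene = average_replicate_spots(
        global_median_normalize(
            transforms.log2_transform(background.correct_standard(dataset))
        ),
        dataset,
    )
    cond = dataset.array_conditions()
    frames = []
    for c in ("A", "B"):
        cols = [a for a in processed.values.columns if cond[a] == c]
        if len(cols) < 2:
            raise ValidationError(f"need >= 2 replicate arrays in condition {c}")
        sd = processed.values[cols].std(axis=1, ddof=1)
        xbar = ref_gene.values[cols].mean(axis=1)
        frames.append(pd.DataFrame({"mean_intensity": xbar, "sd": sd, "condition": c}))
    pts = pd.concat(frames).reset_index()
    ok = pts[["mean_intensity", "sd"]].notna().all(axis=1)
    fit = lowess_curve(
        pts.loc[ok, "mean_intensity"], pts.loc[ok, "sd"], frac=frac, iters=iters
    )
    return {"points": pts, "lowess": fit, "correction": correction, "transform": transform}


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def concordance(a, b) -> ConcordanceResult:
    """Pearson r and one-way random-effects single-measure ICC of paired values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 3:
        raise ValidationError(f"concordance needs >= 3 finite pairs, got {n}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("concordance undefined: zero variance input")
    r = float(np.corrcoef(a, b)[0, 1])
    # one-way ANOVA with genes as random rows, k = 2 columns
    rows = np.stack([a, b], axis=1)
    row_means = rows.mean(axis=1)
    grand = rows.mean()
    k = 2
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((rows - row_means[:, None]) ** 2) / n
    icc = float((msb - msw) / (msb + (k - 1) * msw))
    return ConcordanceResult(pearson_r=r, icc=icc, n=int(n))


def pvalue_concordance(p_a, p_b) -> ConcordanceResult:
    """Concordance of p-values on the probit (standard-normal quantile) scale."""
    def probit(p):
        p = np.asarray(p, dtype=float)
        return stats.norm.ppf(np.clip(p, P_CLIP_LO, P_CLIP_HI))

    return concordance(probit(p_a), probit(p_b))


# ---------------------------------------------------------------------------
# volcano classification
# ---------------------------------------------------------------------------


def classify_volcano(result, thresholds: VolcanoThresholds = VolcanoThresholds()) -> pd.DataFrame:
    """Per-gene differential-expression calls from joint strict thresholds.

    Accepts a :class:`DEResult` or a :class:`GoldStandard`; returns a
    frame indexed by gene_id with boolean ``called`` and ``valid`` (False
    where logfc or p is missing; such genes are never called).
    """
    if isinstance(result, GoldStandard):
        tab = result.indexed().rename(columns={"logfc_gold": "logfc", "p_gold": "p"})
    elif isinstance(result, DEResult):
        tab = result.indexed()
    else:
        tab = pd.DataFrame(result)
    logfc = tab["logfc"].to_numpy(dtype=float)
    p = tab["p"].to_numpy(dtype=float)
    valid = np.isfinite(logfc) & np.isfinite(p)
    called = valid & (np.abs(logfc) > thresholds.fc_threshold) & (p < thresholds.p_threshold)
    return pd.DataFrame({"called": called, "valid": valid}, index=tab.index)


def confusion_metrics(calls_gold, calls_platform) -> tuple[ConfusionTable, dict]:
    """Agreement counts and sensitivity/specificity/accuracy (3 decimals).

    ``calls_gold`` is the reference classification.  Metrics whose
    denominator is zero are reported as ``None`` rather than 0.
    """
    g = np.asarray(calls_gold, dtype=bool)
    m = np.asarray(calls_platform, dtype=bool)
    if g.shape != m.shape:
        raise ValidationError("classification vectors must cover the same gene set")
    table = ConfusionTable(
        tp=int(np.sum(g & m)),
        tn=int(np.sum(~g & ~m)),
        fp=int(np.sum(~g & m)),
        fn=int(np.sum(g & ~m)),
    )
    return table, table.metrics(ndigits=3)


# ---------------------------------------------------------------------------
# the full comparison grid
# ---------------------------------------------------------------------------

ALL_CORRECTIONS = ("standard", "none", "edwards", "normexp")


def compare_methods(
    dataset: SpotDataset,
    gold: GoldStandard,
    corrections=ALL_CORRECTIONS,
    thresholds: VolcanoThresholds = VolcanoThresholds(),
    confusion_correction: str = "edwards",
    lowess_frac: float = DEFAULT_LOWESS_FRAC,
) -> dict:
    """Run every correction x transform combination and assemble the report.

    Differential expression is computed per site; fold-change and p-value
    concordance against the gold standard are reported per site per
    method, while compression points and volcano confusion tables pool
    genes across sites.  Confusion tables compare log2, glog and the
    hybrid transformation under ``confusion_correction``.
    """
    sites = dataset.sites
    per_site_results: dict[tuple[str, str, str], DEResult] = {}
    report: dict = {"sites": sites, "methods": [], "concordance": {}, "compression": {},
                    "sd_curves": {}, "confusion": {}}

    gold_idx = gold.indexed()
    for correction in corrections:
        for transform in ("log2", "glog"):
            method = f"{correction}+{transform}"
            report["methods"].append(method)
            conc_entry = {}
            comp_frames = []
            for site in sites:
                sub = dataset.subset_site(site)
                de = run_pipeline(sub, correction, transform)
                per_site_results[(site, correction, transform)] = de
                d = de.indexed()
                shared = d.index.intersection(gold_idx.index)
                d = d.loc[shared]
                ok = d["logfc"].notna() & d["p"].notna()
                fc = concordance(
                    gold_idx.loc[shared, "logfc_gold"][ok], d["logfc"][ok]
                )
                pv = pvalue_concordance(
                    gold_idx.loc[shared, "p_gold"][ok], d["p"][ok]
                )
                conc_entry[site] = {
                    "fc_pearson_r": fc.pearson_r,
                    "fc_icc": fc.icc,
                    "p_pearson_r": pv.pearson_r,
                    "p_icc": pv.icc,
                    "n": fc.n,
                }
                comp_frames.append(compression_per_gene(de, gold))
            report["concordance"][method] = conc_entry
            pooled = pd.concat(comp_frames, ignore_index=True)
            fit = lowess_curve(pooled["ref_intensity"], pooled["compression"],
                               frac=lowess_frac)
            report["compression"][method] = CompressionCurve(
                points=pooled, lowess=fit, method=method
            )
            sd_frames = []
            for site in sites:
                sd = sd_vs_intensity(dataset.subset_site(site), correction, transform,
                                     frac=lowess_frac)
                sd_frames.append(sd["points"])
            sd_pts = pd.concat(sd_frames, ignore_index=True)
            ok = sd_pts[["mean_intensity", "sd"]].notna().all(axis=1)
            report["sd_curves"][method] = {
                "points": sd_pts,
                "lowess": lowess_curve(sd_pts.loc[ok, "mean_intensity"],
                                       sd_pts.loc[ok, "sd"], frac=lowess_frac),
            }

    # confusion tables: log2 / glog / hybrid under one correction, pooled sites
    gold_calls_one = classify_volcano(gold, thresholds)
    for transform in ("log2", "glog", "hybrid"):
        g_list, m_list = [], []
        for site in sites:
            if transform == "hybrid":
                de = hybrid_combine(
                    per_site_results[(site, confusion_correction, "log2")],
                    per_site_results[(site, confusion_correction, "glog")],
                )
            else:
                de = per_site_results[(site, confusion_correction, transform)]
            calls = classify_volcano(de, thresholds)
            shared = calls.index.intersection(gold_calls_one.index)
            joint = calls.loc[shared, "valid"]
            g_list.append(gold_calls_one.loc[shared, "called"][joint])
            m_list.append(calls.loc[shared, "called"][joint])
        table, metrics = confusion_metrics(
            pd.concat(g_list).to_numpy(), pd.concat(m_list).to_numpy()
        )
        report["confusion"][f"{confusion_correction}+{transform}"] = {
            "table": table,
            "metrics": metrics,
        }
    return report
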