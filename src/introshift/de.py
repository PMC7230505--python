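"""Negative-binomial differential expression with BH correction.

A deliberately compact NB testing stage: features are filtered on an FPKM
floor, normalized with median-of-ratios size factors, and tested per feature
with a Wald test on the difference of log2 normalized condition means. The
per-feature dispersion is a method-of-moments estimate, shrunk 50/50 toward
the across-feature mean and floored, which stabilizes the test at small n.
This is comparable in kind — not identical — to the heavier machinery of
dedicated DE packages (no Cook's filtering, no independent filtering, no
shrunken fold changes).

Calls: UP iff log2FC >= +lfc and q < alpha; DOWN iff log2FC <= -lfc and
q < alpha; NS otherwise (defaults lfc=1, alpha=0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix
from .shift import PairedDesign

logger = logging.getLogger(__name__)

DE_COLUMNS = ["feature_id", "base_mean", "log2FC", "p_value", "q_value", "call"]


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of feature per million library fragments.

    FPKM[f, s] = counts[f, s] / ((length_f / 1e3) * (library_size_s / 1e6)).
    """
    if (cm.lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if (cm.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    kb = cm.lengths.to_numpy(dtype=float)[:, None] / 1e3
    millions = cm.library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    return pd.DataFrame(
        cm.counts.to_numpy(dtype=float) / (kb * millions),
        index=cm.counts.index,
        columns=cm.counts.columns,
    )


def filter_low_expression(
    cm: CountMatrix,
    fpkm_threshold: float = 5.0,
    sample_fraction: float = 0.8,
    mode: str = "per_sample",
) -> CountMatrix:
    """Drop scarcely expressed features before testing.

    mode="per_sample" (default): a feature is excluded when its FPKM is below
    `fpkm_threshold` in at least `sample_fraction` of the samples.
    mode="mean": excluded when its mean FPKM across samples is below the
    threshold. Retained features keep their original counts.
    """
    x = fpkm(cm)
    if mode == "per_sample":
        low_frac = (x < fpkm_threshold).mean(axis=1)
        keep = low_frac < sample_fraction
    elif mode == "mean":
        keep = x.mean(axis=1) >= fpkm_threshold
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    logger.info("expression filter: kept %d of %d features", int(keep.sum()), len(keep))
    return cm.subset(cm.counts.index[keep])


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    Each factor is the median, over features nonzero in every sample, of the
    ratio of the sample's count to the feature's geometric mean across
    samples. If no feature is nonzero everywhere, falls back to
    upper-quartile factors scaled to geometric mean 1 (logged).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    x = df.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if all_nonzero.any():
        xs = x[all_nonzero]
        geo = np.exp(np.log(xs).mean(axis=1, keepdims=True))
        factors = np.median(xs / geo, axis=0)
    else:
        logger.warning("no feature nonzero in every sample; upper-quartile fallback")
        uq = np.array([np.quantile(col[col > 0], 0.75) if (col > 0).any() else 1.0 for col in x.T])
        factors = uq / np.exp(np.mean(np.log(uq)))
    return pd.Series(factors, index=df.columns)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dispersion_mom(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion pooled across groups."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for cols in groups:
        g = norm[:, cols]
        if g.shape[1] < 2:
            continue
        mu = g.mean(axis=1)
        var = g.var(axis=1, ddof=1)
        w = g.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - mu) / np.square(mu), 0.0)
        num += w * np.nan_to_num(a)
        den += w
    return np.clip(num / max(den.max(), 1), 0.0, None)


def _calls(log2fc: np.ndarray, q: np.ndarray, lfc: float, alpha: float) -> np.ndarray:
    call = np.full(log2fc.shape, "NS", dtype=object)
    call[(log2fc >= lfc) & (q < alpha)] = "UP"
    call[(log2fc <= -lfc) & (q < alpha)] = "DOWN"
    return call


def nb_test(
    cm: CountMatrix,
    design: PairedDesign | Mapping[str, str],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    paired: bool = False,
    pseudocount: float = 0.5,
    dispersion_floor: float = 0.01,
    dispersion_shrink: float = 0.5,
    sample_size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Test each feature for a T1-vs-T0 expression difference.

    `design` is a PairedDesign or a sample_id -> condition mapping with
    conditions "T0"/"T1". The default is an unpaired two-group Wald test on
    the NB log2 mean difference; with paired=True (requires a PairedDesign)
    the per-subject log2 ratios of normalized counts are tested with a
    one-sample t-test instead.

    Returns a DataFrame with feature_id, base_mean, log2FC (T1 vs T0),
    p_value, q_value (BH) and call.
    """
    if isinstance(design, PairedDesign):
        cond = {sid: c for sub in design.samples.values() for c, sid in sub.items()}
    else:
        cond = dict(design)
        if paired:
            raise ValueError("paired testing requires a PairedDesign")
    samples = list(cm.counts.columns)
    missing = [s for s in samples if s not in cond]
    if missing:
        raise KeyError(f"samples missing from design: {missing}")
    cols0 = np.array([i for i, s in enumerate(samples) if cond[s] == "T0"])
    cols1 = np.array([i for i, s in enumerate(samples) if cond[s] == "T1"])
    if len(cols0) < 2 or len(cols1) < 2:
        raise ValueError("need at least 2 samples per condition")

    if sample_size_factors is not None:
        sf = sample_size_factors.reindex(cm.counts.columns)
        if sf.isna().any():
            raise ValueError("size factors missing for some samples")
    else:
        sf = size_factors(cm.counts)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)
    m0 = norm[:, cols0].mean(axis=1)
    m1 = norm[:, cols1].mean(axis=1)
    log2fc = np.log2((m1 + pseudocount) / (m0 + pseudocount))

    if paired:
        p = _paired_p(cm, design, sf, pseudocount)
    else:
        alpha_raw = _dispersion_mom(norm, [cols0, cols1])
        expressed = base_mean > 0
        trend = float(alpha_raw[expressed].mean()) if expressed.any() else 0.0
        disp = np.maximum(
            dispersion_floor,
            (1 - dispersion_shrink) * alpha_raw + dispersion_shrink * trend,
        )
        inv_sf = 1.0 / sf.to_numpy()
        ln2sq = np.log(2.0) ** 2
        var_log2 = np.zeros_like(base_mean)
        for cols, m in ((cols0, m0), (cols1, m1)):
            n_g = len(cols)
            # delta method on log2 of the mean of normalized NB counts:
            # Var(mean) = (m * sum(1/sf) + disp * m^2 * n) / n^2
            var_mean = (m * inv_sf[cols].sum() + disp * np.square(m) * n_g) / n_g**2
            var_log2 += var_mean / (np.square(m + pseudocount) * ln2sq)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var_log2 > 0, log2fc / np.sqrt(var_log2), 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = cm.counts.to_numpy().sum(axis=1) == 0
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "feature_id": cm.counts.index,
            "base_mean": base_mean,
            "log2FC": log2fc,
            "p_value": p,
            "q_value": q,
            "call": _calls(log2fc, q, lfc_threshold, alpha),
        }
    )
    return out.reset_index(drop=True)


def _paired_p(cm: CountMatrix, design: PairedDesign, sf: pd.Series, pseudocount: float) -> np.ndarray:
    """One-sample t-test on per-subject log2 ratios of normalized counts."""
    norm = cm.counts / sf
    ratios = []
    for subject in design.subjects:
        s0, s1 = design.samples[subject]["T0"], design.samples[subject]["T1"]
        ratios.append(np.log2((norm[s1] + pseudocount) / (norm[s0] + pseudocount)))
    r = np.column_stack(ratios)
    n = r.shape[1]
    mean = r.mean(axis=1)
    sd = r.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return 2.0 * stats.t.sf(np.abs(t), n - 1)


@dataclass
class RepeatClassSummary:
    """UP/DOWN tallies and modulated fractions per repeat class."""

    table: pd.DataFrame  # repeat_class, n_up, n_down, n_modulated, fraction

    def fractions(self) -> pd.Series:
        return self.table.set_index("repeat_class")["fraction"]


def aggregate_repeat_classes(
    de: pd.DataFrame, repeat_classes: Mapping[str, str] | pd.Series
) -> RepeatClassSummary:
    """Aggregate per-locus repeat DE results at class level.

    `repeat_classes` maps feature_id -> class; loci without metadata are
    tallied under "Unknown". Fractions are over all modulated (UP or DOWN)
    loci and sum to 1; with no modulated locus the summary is empty.
    """
    classes = pd.Series(dict(repeat_classes)) if not isinstance(repeat_classes, pd.Series) else repeat_classes
    mod = de[de["call"].isin(("UP", "DOWN"))].copy()
    if mod.empty:
        return RepeatClassSummary(
            pd.DataFrame(columns=["repeat_class", "n_up", "n_down", "n_modulated", "fraction"])
        )
    mod["repeat_class"] = mod["feature_id"].map(classes).fillna("Unknown")
    g = mod.groupby("repeat_class")["call"]
    tbl = pd.DataFrame(
        {
            "n_up": g.apply(lambda s: int((s == "UP").sum())),
            "n_down": g.apply(lambda s: int((s == "DOWN").sum())),
        }
    )
    tbl["n_modulated"] = tbl["n_up"] + tbl["n_down"]
    tbl["fraction"] = tbl["n_modulated"] / tbl["n_modulated"].sum()
    tbl = tbl.sort_values("n_modulated", ascending=False).reset_index()
    return RepeatClassSummary(tbl)
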