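"""Per-unit and population statistics of binocular modulation.

Binocular modulation of a unit at a contrast pair is the percent difference
between its mean monocular and mean binocular F1 response,

    percent_diff = 100 * (binoc - mono) / mono,

negative for suppression. Population medians are screened by a 3-scaled-MAD
outlier rule and tested against zero with the Wilcoxon signed-rank test;
confidence intervals on medians come from a seeded percentile bootstrap.
Per-unit significance uses ROC analysis: the AUC (probability that a
random binocular-trial F1 exceeds a random monocular-trial F1, ties
counted half) is compared with a Monte-Carlo shuffle null built by
resampling, with replacement, across both conditions pooled. Because both
suppression and facilitation are tested, the folded statistic
max(AUC, 1-AUC) is compared against the upper quantile of the null AUC
distribution, giving a two-sided test of size 2*(1-quantile): 0.975 for
alpha = 0.05, 0.9 for the relaxed alpha = 0.2 criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAD_SCALE = 1.4826


@dataclass
class ModulationRecord:
    unit_id: object
    dom_bin: str
    nondom_bin: str
    mono_f1_mean: float
    binoc_f1_mean: float
    percent_diff: float
    outlier: bool = False
    roc_auc: float = float("nan")
    roc_significant: bool = False
    direction: str = "none"           # suppression / facilitation / none
    n_mono: int = 0
    n_binoc: int = 0


@dataclass
class PopulationSummary:
    condition: str
    n_units: int
    median_percent_diff: float
    wilcoxon_p: float | None
    ci_low: float
    ci_high: float
    n_significant_suppressed: int = 0
    n_significant_facilitated: int = 0


def percent_modulation(mono_mean: float, binoc_mean: float) -> float:
    """100*(binoc - mono)/mono; negative = suppression."""
    if mono_mean <= 0:
        raise ValueError("monocular mean response must be positive")
    return 100.0 * (binoc_mean - mono_mean) / mono_mean


def mad_outlier_filter(values, k: float = 3.0) -> np.ndarray:
    """Inlier mask: |x - median| <= k * 1.4826 * MAD.

    With a zero MAD (more than half the values identical) only exact-median
    values are retained, matching the rule's literal reading.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values for the MAD rule")
    med = np.median(x)
    smad = MAD_SCALE * np.median(np.abs(x - med))
    if smad == 0:
        return np.isclose(x, med)
    return np.abs(x - med) <= k * smad


def bootstrap_median_ci(values, n_boot: int = 10000, level: float = 0.95,
                        rng: np.random.Generator | None = None
                        ) -> tuple[float, float]:
    """Seeded percentile-bootstrap confidence interval on the median."""
    x = np.asarray(values, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    meds = np.median(x[idx], axis=1)
    lo, hi = np.quantile(meds, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def population_test(values, condition: str = "", n_boot: int = 10000,
                    rng: np.random.Generator | None = None) -> PopulationSummary:
    """Wilcoxon signed-rank test of the median against zero, with a
    bootstrap CI on the median.

    Exact null distribution for n <= 25 (when free of zeros and ties),
    normal approximation with continuity correction otherwise. Fewer than
    5 values yield a summary with an undefined p-value.
    """
    x = np.asarray(values, dtype=float)
    med = float(np.median(x)) if len(x) else float("nan")
    if len(x) < 5:
        return PopulationSummary(condition, len(x), med, None,
                                 float("nan"), float("nan"))
    nonzero = x[x != 0]
    exact_ok = (len(x) <= 25 and len(nonzero) == len(x)
                and len(np.unique(np.abs(x))) == len(x))
    if len(nonzero) == 0:
        p = 1.0
    elif exact_ok:
        p = float(stats.wilcoxon(x, method="exact").pvalue)
    else:
        p = float(stats.wilcoxon(x, method="approx", correction=True,
                                 zero_method="wilcox").pvalue)
    lo, hi = bootstrap_median_ci(x, n_boot=n_boot, rng=rng)
    return PopulationSummary(condition, len(x), med, p, lo, hi)


def roc_auc(binoc, mono) -> float:
    """AUC = P(binoc > mono) + 0.5 * P(tie), by the rank statistic.

    Identical to the trapezoidal area under the empirical ROC curve.
    """
    b = np.asarray(binoc, dtype=float)
    m = np.asarray(mono, dtype=float)
    if len(b) == 0 or len(m) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([b, m])
    ranks = stats.rankdata(pooled)
    u = ranks[: len(b)].sum() - len(b) * (len(b) + 1) / 2.0
    return float(u / (len(b) * len(m)))


def _auc_matrix(B: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Row-wise AUC for stacked samples B (S, nb) vs M (S, nm)."""
    nb, nm = B.shape[1], M.shape[1]
    pooled = np.concatenate([B, M], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    u = ranks[:, :nb].sum(axis=1) - nb * (nb + 1) / 2.0
    return u / (nb * nm)


@dataclass
class ShuffleResult:
    auc: float
    folded_auc: float
    null_quantile_value: float
    significant: bool
    direction: str                 # suppression / facilitation / none


def shuffle_null(binoc, mono, n_shuffles: int = 2000, quantile: float = 0.975,
                 rng: np.random.Generator | None = None,
                 method: str = "pooled_bootstrap") -> ShuffleResult:
    """Per-unit significance of binocular modulation by a Monte-Carlo null.

    ``pooled_bootstrap`` (default, as described for the study): each
    shuffle draws, with replacement, surrogate samples of the original
    sizes from the two conditions pooled and computes their AUC; the folded
    observed statistic max(A, 1-A) is compared against the ``quantile`` of
    the null AUC distribution, a two-sided test of size 2*(1-quantile).
    ``label_permutation`` permutes condition labels without replacement
    instead. Direction comes from the comparison of sample means.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    if rng is None:
        rng = np.random.default_rng(0)
    b = np.asarray(binoc, dtype=float)
    m = np.asarray(mono, dtype=float)
    a = roc_auc(b, m)
    folded = max(a, 1.0 - a)
    pooled = np.concatenate([b, m])
    n_tot, nb = len(pooled), len(b)
    if method == "pooled_bootstrap":
        idx = rng.integers(0, n_tot, size=(n_shuffles, n_tot))
    elif method == "label_permutation":
        idx = np.argsort(rng.random((n_shuffles, n_tot)), axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    surro = pooled[idx]
    null_auc = _auc_matrix(surro[:, :nb], surro[:, nb:])
    thresh = float(np.quantile(null_auc, quantile))
    significant = folded > thresh
    if not significant:
        direction = "none"
    else:
        direction = "facilitation" if b.mean() > m.mean() else "suppression"
    return ShuffleResult(auc=a, folded_auc=folded, null_quantile_value=thresh,
                         significant=bool(significant), direction=direction)


def proportion_trend(proportions, contrasts) -> tuple[float, float, int]:
    """OLS slope of percent-of-units-suppressed on dominant-eye contrast.

    Returns (slope, two-sided p, residual df). Proportions are expected in
    percent so the slope is percent-per-unit-contrast.
    """
    y = np.asarray(proportions, dtype=float)
    x = np.asarray(contrasts, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 contrast bins for a trend")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue), len(x) - 2


def crf_average(unit_responses: dict, min_bins: int = 2
                ) -> tuple[np.ndarray, dict]:
    """Min-max-normalized contrast-response averaging across units.

    ``unit_responses`` maps unit_id -> {contrast: mean response}. Each
    unit's responses are normalized to [0, 1] across its own contrasts,
    then averaged per contrast across units. Units with a constant
    response (normalization undefined) are excluded with a note. Returns
    (sorted contrast grid, {"mean", "sem", "n", "excluded"}).
    """
    grid = sorted({c for r in unit_responses.values() for c in r})
    cols = {c: [] for c in grid}
    excluded = []
    for unit, resp in unit_responses.items():
        if len(resp) < min_bins:
            excluded.append(unit)
            continue
        vals = np.array(list(resp.values()), dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            excluded.append(unit)
            continue
        for c, v in resp.items():
            cols[c].append((v - lo) / (hi - lo))
    mean = np.array([np.mean(cols[c]) if cols[c] else np.nan for c in grid])
    sem = np.array([
        np.std(cols[c], ddof=1) / np.sqrt(len(cols[c])) if len(cols[c]) > 1 else 0.0
        for c in grid
    ])
    n = np.array([len(cols[c]) for c in grid])
    return np.asarray(grid, dtype=float), dict(mean=mean, sem=sem, n=n,
                                               excluded=excluded)


def modulation_density(values, grid: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of a modulation distribution (plotting aid).

    Rule-of-thumb bandwidth; carries no inferential weight.
    """
    x = np.asarray(values, dtype=float)
    kde = stats.gaussian_kde(x)
    if grid is None:
        pad = 3 * x.std()
        grid = np.linspace(x.min() - pad, x.max() + pad, 256)
    return grid, kde(grid)
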