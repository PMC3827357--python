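"""Normality-gated two-sample screening and correlation-based feature selection.

Each locomotor variable is compared between the two behaviour classes.  If
both class samples pass an Anderson-Darling normality check (5% level,
parameters estimated, small-sample-corrected critical value), Welch's
unequal-variance t test is used; otherwise an unpaired rank-sum
(Mann-Whitney) test with normal approximation and tie correction.  Variables
significant at ``alpha`` feed a CFS (correlation-based feature selection)
search that favours subsets highly correlated with the class but weakly
correlated with each other:

    merit(S) = k · r̄_cf / sqrt(k + k(k−1) · r̄_ff)

with k = |S|, r̄_cf the mean absolute point-biserial feature-class
correlation, and r̄_ff the mean absolute pairwise feature correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sensor_io import ValidationError

logger = logging.getLogger("finstart")

MIN_NORMALITY_N = 8


def anderson_darling(sample: np.ndarray, alpha: float = 0.05) -> tuple[float, bool]:
    """A² statistic and a normality decision for the normal family.

    Mean and variance are estimated from the sample; the decision compares
    A² against the small-sample-corrected critical value at ``alpha``.
    Location-scale invariant.  Degenerate (constant) samples are non-normal.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < MIN_NORMALITY_N:
        raise ValidationError(
            f"Anderson-Darling needs n >= {MIN_NORMALITY_N}, got {x.size}"
        )
    if np.ptp(x) == 0:
        return float("inf"), False
    import warnings

    with warnings.catch_warnings():
        # critical-value API is what the decision rule needs; silence the
        # p-value-method transition notice
        warnings.simplefilter("ignore", FutureWarning)
        res = sps.anderson(x, dist="norm")
    levels = list(res.significance_level)
    crit = res.critical_values[levels.index(alpha * 100)]
    a2 = float(res.statistic)
    return a2, a2 < crit


def two_sample_test(
    a: np.ndarray, b: np.ndarray, mode: str = "welch", paired: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample test: Welch's t or a rank test.

    ``mode='rank'`` is the unpaired rank-sum (Mann-Whitney) test with normal
    approximation and tie correction; with ``paired=True`` it becomes the
    signed-rank test on differences.  Two samples that are both constant and
    equal give p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("two_sample_test needs n >= 2 in each sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        logger.info("zero variance in both groups with equal means: p = 1")
        return 0.0, 1.0
    if mode == "welch":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif mode == "rank":
        if paired:
            if a.size != b.size:
                raise ValidationError("paired test needs equal sample sizes")
            stat, p = sps.wilcoxon(a, b, method="approx")
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic")
    else:
        raise ValidationError(f"unknown test mode {mode!r}")
    return float(stat), float(p)


def welch_t_from_summary(
    mean_a: float, sem_a: float, n_a: int, mean_b: float, sem_b: float, n_b: int
) -> tuple[float, float, float]:
    """Welch's t from group summaries (mean, SEM, n).

    Returns (t, Welch-Satterthwaite df, two-sided p).  Useful for checking
    published tables that print only means and standard errors.
    """
    va, vb = sem_a**2, sem_b**2
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class ScreeningResult:
    """Per-feature screening outcomes.

    ``table`` has columns: feature, normal_a, normal_b, test, statistic, p,
    significant.  ``welch_t`` is used iff both class samples pass normality.
    """

    table: pd.DataFrame
    alpha: float
    classes: tuple[str, str]

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "feature"])


def screen_features(
    table: pd.DataFrame, alpha: float = 0.05, paired: bool = False
) -> ScreeningResult:
    """Run the normality-gated screening over every feature column."""
    if "label" not in table.columns:
        raise ValidationError("feature table must have a 'label' column")
    classes = sorted(table["label"].unique())
    if len(classes) != 2:
        raise ValidationError(f"screening needs exactly 2 classes, got {classes}")
    ga = table[table["label"] == classes[0]]
    gb = table[table["label"] == classes[1]]
    if len(ga) < MIN_NORMALITY_N or len(gb) < MIN_NORMALITY_N:
        raise ValidationError(
            f"each class needs >= {MIN_NORMALITY_N} rows for normality testing"
        )
    rows = []
    for feat in [c for c in table.columns if c != "label"]:
        xa = ga[feat].to_numpy(dtype=float)
        xb = gb[feat].to_numpy(dtype=float)
        _, norm_a = anderson_darling(xa)
        _, norm_b = anderson_darling(xb)
        mode = "welch" if (norm_a and norm_b) else "rank"
        stat, p = two_sample_test(xa, xb, mode=mode, paired=paired)
        rows.append({
            "feature": feat, "normal_a": norm_a, "normal_b": norm_b,
            "test": "welch_t" if mode == "welch" else "wilcoxon",
            "statistic": stat, "p": p, "significant": bool(p < alpha),
        })
    return ScreeningResult(pd.DataFrame(rows), alpha, (classes[0], classes[1]))


# ---------------------------------------------------------------------------
# CFS — correlation-based feature-subset selection
# ---------------------------------------------------------------------------

def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson correlation|; 0 when either input has zero variance."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def cfs_merit(subset: list[str], table: pd.DataFrame) -> float:
    """CFS merit of a feature subset against a binary class column.

    Feature-class correlation is the absolute point-biserial correlation
    (Pearson with the 0/1-coded class); feature-feature correlation is the
    absolute Pearson correlation.  ``merit = k r̄_cf / sqrt(k + k(k−1) r̄_ff)``.
    """
    if not subset:
        raise ValidationError("cfs_merit needs a non-empty subset")
    classes = sorted(table["label"].unique())
    if len(classes) != 2:
        raise ValidationError("cfs_merit needs a binary class")
    y = (table["label"] == classes[1]).to_numpy(dtype=float)
    X = {f: table[f].to_numpy(dtype=float) for f in subset}
    k = len(subset)
    r_cf = np.mean([_abs_corr(X[f], y) for f in subset])
    if k == 1:
        return float(r_cf)
    r_ff = np.mean([
        _abs_corr(X[f], X[g]) for f, g in itertools.combinations(subset, 2)
    ])
    return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))


def cfs_select(
    table: pd.DataFrame,
    candidates: list[str] | None = None,
    search: str = "forward",
    max_stale: int = 5,
) -> list[str]:
    """Select a feature subset maximising CFS merit.

    ``forward`` (default) greedily adds the merit-maximising feature until no
    addition improves; ``best_first`` explores a queue of subsets and stops
    after ``max_stale`` non-improving expansions.  Ties break by feature-name
    order, so selection is deterministic.  Returns [] for an empty candidate
    set.
    """
    if candidates is None:
        candidates = [c for c in table.columns if c != "label"]
    candidates = sorted(candidates)
    if not candidates:
        return []
    if search == "forward":
        selected: list[str] = []
        best = -np.inf
        while True:
            scored = [
                (-cfs_merit(selected + [f], table), f)
                for f in candidates if f not in selected
            ]
            if not scored:
                break
            neg_merit, feat = min(scored)   # highest merit, earliest name on ties
            merit = -neg_merit
            if merit <= best + 1e-12:
                break
            best = merit
            selected.append(feat)
        return sorted(selected)
    if search == "best_first":
        start: tuple[str, ...] = ()
        frontier: list[tuple[float, tuple[str, ...]]] = [(0.0, start)]
        visited = {start}
        best, best_subset = -np.inf, start
        stale = 0
        while frontier and stale < max_stale:
            frontier.sort(key=lambda t: (-t[0], t[1]))
            merit, subset = frontier.pop(0)
            improved = False
            for f in candidates:
                if f in subset:
                    continue
                child = tuple(sorted(subset + (f,)))
                if child in visited:
                    continue
                visited.add(child)
                m = cfs_merit(list(child), table)
                frontier.append((m, child))
                if m > best + 1e-12:
                    best, best_subset = m, child
                    improved = True
            stale = 0 if improved else stale + 1
        return list(best_subset)
    raise ValidationError(f"unknown search {search!r}")


__all__ = [
    "MIN_NORMALITY_N", "ScreeningResult",
    "anderson_darling", "two_sample_test", "welch_t_from_summary",
    "screen_features", "cfs_merit", "cfs_select",
]
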