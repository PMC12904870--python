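"""Two-group statistical comparison of snore feature distributions.

The battery mirrors common practice in clinical acoustics: per
variable, a Shapiro-Wilk normality gate decides between parametric and
rank-based testing; among parametric tests a Levene gate decides Student
vs Welch.  Effect sizes are Cohen's d for the t-tests and the rank-biserial
correlation r = 2U/(n1 n2) - 1 for Mann-Whitney.  SER is log-transformed
(base 10) before testing to restore approximate normality; interpretation
stays on the raw SER scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st

from snorelab.reference import COMPARISON_VARIABLES, VARIABLE_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "StatsConfig",
    "GROUP_APNEA",
    "GROUP_CONTINUOUS",
    "REPORTED_TEST_ASSIGNMENT",
    "canonical_group",
    "group_samples_from_frame",
    "descriptive_table",
    "select_test",
    "student_t",
    "welch_t",
    "mann_whitney_u",
    "cohens_d",
    "cohens_d_from_samples",
    "rank_biserial",
    "compare_groups",
    "results_to_frame",
]

GROUP_APNEA = "apnea"
GROUP_CONTINUOUS = "continuous"

TEST_STUDENT = "student_t"
TEST_WELCH = "welch_t"
TEST_MANN_WHITNEY = "mann_whitney"

# Manual per-variable test assignment reproducing the reference report's
# choices, usable instead of the data-driven gate.
REPORTED_TEST_ASSIGNMENT = {
    "f1_hz": TEST_STUDENT,
    "f2_hz": TEST_WELCH,
    "f3_hz": TEST_STUDENT,
    "f2_f1": TEST_MANN_WHITNEY,
    "hnr_db": TEST_MANN_WHITNEY,
    "pitch_slope_hz_s": TEST_MANN_WHITNEY,
    "log_ser": TEST_WELCH,
}


def canonical_group(label: str) -> str:
    """Map event labels to group names: preapneic -> apnea."""
    label = str(label).strip().lower()
    if label in ("apnea", "preapneic"):
        return GROUP_APNEA
    if label in ("continuous", "cont", "cont.", "simple"):
        return GROUP_CONTINUOUS
    raise ValueError(f"unknown group label {label!r}")


@dataclass
class GroupSample:
    """Observations of one variable in one group; NaN entries are dropped."""

    variable: str
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.group = canonical_group(self.group)
        vals = np.asarray(self.values, dtype=float)
        n_missing = int(np.sum(~np.isfinite(vals)))
        if n_missing:
            logger.info("%s/%s: dropping %d missing values", self.variable, self.group, n_missing)
        self.values = vals[np.isfinite(vals)]

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class ComparisonResult:
    """One row of the test report."""

    variable: str
    test: str
    statistic: float
    p_value: float
    effect_size: float
    effect_kind: str
    n_apnea: int
    n_continuous: int
    significant: bool


@dataclass
class StatsConfig:
    """Testing options.

    ``log_transform`` names raw variables replaced by their base-10 log for
    testing (default: SER, tested as logSER).  ``test_override`` maps
    variables to a fixed test, bypassing the normality/variance gates;
    ``REPORTED_TEST_ASSIGNMENT`` is the shipped preset.  Holm correction is
    available but off by default (raw p-values across the battery).
    """

    alpha: float = 0.05
    normality_alpha: float = 0.05
    variance_alpha: float = 0.05
    log_transform: tuple = ("ser",)
    test_override: Optional[dict] = None
    holm: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def group_samples_from_frame(
    df: pd.DataFrame, variables: Optional[list] = None, label_col: str = "label"
) -> list:
    """Tidy feature table (one row per event) -> list of GroupSample."""
    variables = variables or [c for c in VARIABLE_ORDER if c in df.columns]
    samples = []
    for var in variables:
        for group, sub in df.groupby(df[label_col].map(canonical_group)):
            samples.append(GroupSample(var, group, sub[var].to_numpy()))
    return samples


def descriptive_table(samples: list) -> pd.DataFrame:
    """Per variable and group: n, mean, SD (n-1), min, max.

    Rows follow the canonical variable order; an empty group yields a row
    of NaNs with a warning.
    """
    rows = []
    order = {v: i for i, v in enumerate(VARIABLE_ORDER)}
    for s in sorted(samples, key=lambda s: (order.get(s.variable, 99), s.group)):
        if s.n == 0:
            logger.warning("%s/%s: no observations", s.variable, s.group)
            rows.append({"variable": s.variable, "group": s.group, "n": 0,
                         "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan})
            continue
        rows.append({
            "variable": s.variable, "group": s.group, "n": s.n,
            "mean": float(np.mean(s.values)),
            "sd": float(np.std(s.values, ddof=1)) if s.n > 1 else np.nan,
            "min": float(np.min(s.values)),
            "max": float(np.max(s.values)),
        })
    return pd.DataFrame(rows, columns=["variable", "group", "n", "mean", "sd", "min", "max"])


def _is_constant(x: np.ndarray) -> bool:
    return len(x) > 0 and float(np.ptp(x)) == 0.0


def select_test(a: GroupSample, b: GroupSample, cfg: Optional[StatsConfig] = None) -> str:
    """Normality-gated test choice.

    Both groups Shapiro-normal -> Levene (Brown-Forsythe, median-centered)
    picks Student vs Welch; any normality failure (or a constant sample,
    for which normality is undefined) -> Mann-Whitney.
    """
    cfg = cfg or StatsConfig()
    if a.n < 3 or b.n < 3:
        raise ValueError(
            f"{a.variable}: need >= 3 values per group for the test-selection gate "
            f"(got {a.n}, {b.n}); choose a test explicitly via test_override"
        )
    if _is_constant(a.values) or _is_constant(b.values):
        return TEST_MANN_WHITNEY
    p_a = st.shapiro(a.values).pvalue
    p_b = st.shapiro(b.values).pvalue
    if p_a <= cfg.normality_alpha or p_b <= cfg.normality_alpha:
        return TEST_MANN_WHITNEY
    p_var = st.levene(a.values, b.values, center="median").pvalue
    return TEST_STUDENT if p_var > cfg.variance_alpha else TEST_WELCH


def _t_test(a: np.ndarray, b: np.ndarray, equal_var: bool):
    if _is_constant(a) and _is_constant(b):
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0  # no variance, no difference
        return np.inf * np.sign(np.mean(a) - np.mean(b)), 0.0
    res = st.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def student_t(a, b):
    """Two-sided pooled-variance t-test; accepts arrays or GroupSamples."""
    return _t_test(_values(a), _values(b), equal_var=True)


def welch_t(a, b):
    """Two-sided unequal-variance t-test; accepts arrays or GroupSamples."""
    return _t_test(_values(a), _values(b), equal_var=False)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, GroupSample) else np.asarray(x, dtype=float)


def mann_whitney_u(a, b):
    """Two-sided Mann-Whitney U test.

    U counts pairs where a exceeds b (ties half-counted).  The p-value uses
    exact enumeration for small tie-free samples (both n <= 20) and the
    tie-corrected normal approximation otherwise.
    """
    x, y = _values(a), _values(b)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if _is_constant(np.concatenate([x, y])):
        return len(x) * len(y) / 2.0, 1.0  # complete ties
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not has_ties and max(len(x), len(y)) <= 20) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cohens_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Standardized mean difference from summary statistics.

    With known group sizes the pooled SD uses (n-1)-weighted variances;
    pass ``n_a = n_b = None`` for equal-weight pooling
    s = sqrt((sd_a^2 + sd_b^2)/2), the fallback when sizes are unknown.
    """
    if (n_a is None) != (n_b is None):
        raise ValueError("give both group sizes or neither")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_a is None:
        s = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    else:
        s = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    if s == 0:
        return np.nan
    return float((mean_a - mean_b) / s)


def cohens_d_from_samples(a, b) -> float:
    x, y = _values(a), _values(b)
    return cohens_d(np.mean(x), np.std(x, ddof=1), len(x),
                    np.mean(y), np.std(y, ddof=1), len(y))


def rank_biserial(u: float, n_a: int, n_b: int) -> float:
    """Rank-biserial correlation r = 2U/(n_a n_b) - 1 for Mann-Whitney U."""
    if n_a * n_b == 0:
        return np.nan
    if not 0 <= u <= n_a * n_b:
        raise ValueError(f"U must lie in [0, {n_a * n_b}], got {u}")
    return 2.0 * u / (n_a * n_b) - 1.0


_TESTS = {TEST_STUDENT: student_t, TEST_WELCH: welch_t, TEST_MANN_WHITNEY: mann_whitney_u}


def compare_groups(
    features: pd.DataFrame,
    cfg: Optional[StatsConfig] = None,
    variables: Optional[list] = None,
    label_col: str = "label",
) -> list:
    """Run the full per-variable test battery on a labeled feature table.

    Configured raw variables (default: SER) are replaced by their base-10
    log before testing.  Returns one :class:`ComparisonResult` per variable
    with statistic, two-sided p, and the matching effect size.
    """
    cfg = cfg or StatsConfig()
    df = features.copy()
    groups = df[label_col].map(canonical_group)
    present = sorted(groups.unique())
    if len(present) != 2:
        raise ValueError(f"need both groups present, found {present}")

    variables = list(variables) if variables else [
        v for v in COMPARISON_VARIABLES if v in df.columns or v == "log_ser"
    ]
    if "ser" in cfg.log_transform and "log_ser" in variables and "log_ser" not in df.columns:
        if "ser" not in df.columns:
            raise ValueError("neither log_ser nor ser present in the feature table")
        df["log_ser"] = np.log10(np.maximum(df["ser"].astype(float), 1e-3))

    results = []
    for var in variables:
        if var not in df.columns:
            logger.warning("%s: column absent; row skipped", var)
            continue
        sub = {g: GroupSample(var, g, df.loc[groups == g, var].to_numpy()) for g in present}
        a, b = sub[GROUP_APNEA], sub[GROUP_CONTINUOUS]
        if a.n == 0 or b.n == 0:
            logger.warning("%s: entirely missing in one group; row skipped", var)
            continue
        if cfg.test_override and var in cfg.test_override:
            test = cfg.test_override[var]
        else:
            test = select_test(a, b, cfg)
        statistic, p = _TESTS[test](a, b)
        if test == TEST_MANN_WHITNEY:
            effect = rank_biserial(statistic, a.n, b.n)
            effect_kind = "rank_biserial"
        else:
            effect = cohens_d_from_samples(a, b)
            effect_kind = "cohens_d"
        results.append(ComparisonResult(
            variable=var, test=test, statistic=statistic, p_value=p,
            effect_size=effect, effect_kind=effect_kind,
            n_apnea=a.n, n_continuous=b.n, significant=bool(p < cfg.alpha),
        ))

    if cfg.holm and results:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests([r.p_value for r in results], alpha=cfg.alpha,
                                            method="holm")
        for r, pa, rej in zip(results, p_adj, reject):
            r.p_value_holm = float(pa)
            r.significant = bool(rej)
    return results


def results_to_frame(results: list) -> pd.DataFrame:
    cols = ["variable", "test", "statistic", "p_value", "effect_size", "effect_kind",
            "n_apnea", "n_continuous", "significant"]
    rows = [{c: getattr(r, c) for c in cols} for r in results]
    df = pd.DataFrame(rows, columns=cols)
    for r, row in zip(results, rows):
        if hasattr(r, "p_value_holm"):
            df.loc[df["variable"] == r.variable, "p_value_holm"] = r.p_value_holm
    return df
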