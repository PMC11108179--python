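"""Pairwise comparison of per-genotype kinetic metrics.

The comparison pattern used throughout the knockout panels: every
unordered pair of strains is tested two-sided on its biological-replicate
metric values, and significance is flagged at two tiers — ``double`` for
p below the Bonferroni-corrected threshold alpha/m (m = number of
pairwise comparisons), ``single`` for p below the uncorrected alpha only.
Thresholds are printed at three significant figures (0.05/28 -> 0.00179)
but decisions always use full precision.

The default test is Welch's unequal-variance t on biological replicates;
Student's t and a permutation test (exact when the number of label
assignments is small, otherwise Monte Carlo) are available.  With n = 3
per group an exact two-sided permutation p cannot go below 0.1, so
corrected significance at these panel sizes is only reachable with the
parametric tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

FLAG_NS = "ns"
FLAG_SINGLE = "single"
FLAG_DOUBLE = "double"
FLAG_UNTESTABLE = "insufficient-n"


@dataclass(frozen=True)
class GroupMetrics:
    """One strain/condition's biological-replicate metric values."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {self.label!r}: values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def testable(self) -> bool:
        return len(self.values) >= 2


def bonferroni_threshold(alpha: float, n_groups: int) -> tuple[int, float]:
    """Comparison count m = C(n_groups, 2) and per-comparison threshold
    alpha/m (full precision; round only for display)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    m = n_groups * (n_groups - 1) // 2
    return m, alpha / m


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            logger.info("zero variance and equal means; p = 1 by convention")
            return 1.0
        return 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def _student_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def _permutation_p(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
    max_exact: int = 20000, n_mc: int = 9999,
) -> float:
    """Two-sided permutation test on the difference of means."""
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    observed = abs(np.mean(a) - np.mean(b))
    total = math.comb(n, n_a)
    if total <= max_exact:
        count = 0
        for combo in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            if stat >= observed - 1e-12:
                count += 1
        return count / total
    hits = 1  # include the observed assignment
    for _ in range(n_mc):
        perm = rng.permutation(n)
        stat = abs(pooled[perm[:n_a]].mean() - pooled[perm[n_a:]].mean())
        if stat >= observed - 1e-12:
            hits += 1
    return hits / (n_mc + 1)


@dataclass
class ComparisonMatrix:
    """Symmetric p-value matrix with two-tier significance flags."""

    labels: list[str]
    pvalues: pd.DataFrame
    flags: pd.DataFrame
    alpha: float
    n_comparisons: int
    threshold: float
    method: str

    @property
    def threshold_display(self) -> float:
        return round_sig(self.threshold, 3)

    def audit(self) -> bool:
        """Check flag/p-value consistency on every off-diagonal cell."""
        for i in self.labels:
            for j in self.labels:
                if i == j:
                    continue
                p = self.pvalues.loc[i, j]
                f = self.flags.loc[i, j]
                if f == FLAG_UNTESTABLE:
                    if not np.isnan(p):
                        return False
                    continue
                expected = (FLAG_DOUBLE if p < self.threshold
                            else FLAG_SINGLE if p < self.alpha else FLAG_NS)
                if f != expected:
                    return False
        return True


def pairwise_compare(
    groups: list[GroupMetrics],
    method: str = "welch",
    alpha: float = 0.05,
    seed: int | None = None,
) -> ComparisonMatrix:
    """All-pairs two-sided comparison with Bonferroni two-tier flags.

    Groups with fewer than 2 values stay in the matrix but are flagged
    ``insufficient-n`` with NaN p-values rather than being dropped.
    The comparison count m (and hence the corrected threshold) counts
    every unordered pair of groups, testable or not, matching the
    "given m comparisons" convention of the knockout panels.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    if method not in ("welch", "student", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    m, threshold = bonferroni_threshold(alpha, len(groups))
    rng = np.random.default_rng(seed)

    p = pd.DataFrame(np.nan, index=labels, columns=labels)
    f = pd.DataFrame("", index=labels, columns=labels)
    for ga, gb in itertools.combinations(groups, 2):
        if not (ga.testable and gb.testable):
            f.loc[ga.label, gb.label] = f.loc[gb.label, ga.label] = FLAG_UNTESTABLE
            continue
        if method == "welch":
            pv = _welch_p(ga.values, gb.values)
        elif method == "student":
            pv = _student_p(ga.values, gb.values)
        else:
            pv = _permutation_p(ga.values, gb.values, rng)
        flag = (FLAG_DOUBLE if pv < threshold
                else FLAG_SINGLE if pv < alpha else FLAG_NS)
        p.loc[ga.label, gb.label] = p.loc[gb.label, ga.label] = pv
        f.loc[ga.label, gb.label] = f.loc[gb.label, ga.label] = flag
    return ComparisonMatrix(labels, p, f, alpha, m, threshold, method)


def compare_metric_table(
    metrics: pd.DataFrame,
    metric: str = "max_rate",
    group_col: str = "strain",
    method: str = "welch",
    alpha: float = 0.05,
    seed: int | None = None,
) -> ComparisonMatrix:
    """Convenience wrapper: build groups from a per-replicate metrics
    table (as produced by :func:`phenox.kinetics.summarize_replicates`)."""
    groups = [
        GroupMetrics(label, grp[metric].dropna().to_numpy())
        for label, grp in metrics.groupby(group_col, sort=False)
    ]
    return pairwise_compare(groups, method=method, alpha=alpha, seed=seed)


@dataclass
class TypeIErrorReport:
    """Observed family-wise error of the corrected comparison stage."""

    n_sims: int
    n_false_families: int
    rate: float
    mc_standard_error: float
    alpha: float
    threshold: float


def type_i_error_check(
    method: str = "welch",
    n_per_group: int = 3,
    n_groups: int = 4,
    n_sims: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> TypeIErrorReport:
    """All-null simulation of the comparison stage.

    Draws every group from the same standard normal, applies the pairwise
    test plus Bonferroni correction, and reports the fraction of
    simulated families with at least one double-flagged cell.  For the
    Welch default the t statistics are computed vectorized across
    simulations.
    """
    m, threshold = bonferroni_threshold(alpha, n_groups)
    if n_sims <= 0:
        return TypeIErrorReport(0, 0, float("nan"), float("nan"), alpha, threshold)
    rng = np.random.default_rng(seed)
    if method == "welch":
        data = rng.standard_normal((n_sims, n_groups, n_per_group))
        means = data.mean(axis=2)
        var = data.var(axis=2, ddof=1)
        any_hit = np.zeros(n_sims, dtype=bool)
        for i, j in itertools.combinations(range(n_groups), 2):
            se2_i = var[:, i] / n_per_group
            se2_j = var[:, j] / n_per_group
            denom = np.sqrt(se2_i + se2_j)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = (means[:, i] - means[:, j]) / denom
                df = (se2_i + se2_j) ** 2 / (
                    se2_i**2 / (n_per_group - 1) + se2_j**2 / (n_per_group - 1)
                )
            pv = 2.0 * sps.t.sf(np.abs(tstat), df)
            pv = np.where(np.isfinite(pv), pv, 1.0)
            any_hit |= pv < threshold
        n_false = int(any_hit.sum())
    else:
        n_false = 0
        for _ in range(n_sims):
            groups = [
                GroupMetrics(f"g{k}", rng.standard_normal(n_per_group))
                for k in range(n_groups)
            ]
            cm = pairwise_compare(groups, method=method, alpha=alpha,
                                  seed=int(rng.integers(2**31)))
            if (cm.flags.values == FLAG_DOUBLE).any():
                n_false += 1
    rate = n_false / n_sims
    se = math.sqrt(max(rate * (1 - rate), 1e-12) / n_sims)
    return TypeIErrorReport(n_sims, n_false, rate, se, alpha, threshold)
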