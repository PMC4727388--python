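"""Differential expression testing with two-stage FDR screening.

The DEG-calling engine is a per-gene two-sample test on log2(value + 1),
Benjamini–Hochberg corrected across genes.  The default is a moderated
t-test: per-gene pooled variances are shrunk toward a common prior
variance estimated across all genes by empirical Bayes (the scaled
inverse-chi-square moment estimator of the limma lineage), which is the
standard remedy for the unstable variance estimates triplicate designs
produce.  A plain Welch t-test is available via ``method="welch"``.

Thresholds follow the two-stage convention of the analysis this package
supports: initial testing at α = 0.05 with allowed FDR 0.05, then a
stricter screen at FDR 0.01; only the 0.01 screen gates downstream gene
sets.

Fold changes for display are computed without a pseudocount so that a
gene undetected in the baseline group reports an infinite log2 fold
change, as the printed candidate table does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .simulate import ExpressionMatrix

__all__ = [
    "ComparisonSpec",
    "Thresholds",
    "DEGTable",
    "InsufficientReplicatesError",
    "log2_fold_change",
    "benjamini_hochberg",
    "moderated_ttest",
    "test_differential_expression",
]

_ZERO_VAR = 1e-12
_MAX_DF = 1e6  # treat larger prior df as effectively normal


class InsufficientReplicatesError(ValueError):
    """Raised for groups without enough replicates to test (Day 18–36)."""


@dataclass(frozen=True)
class ComparisonSpec:
    """One two-group comparison: fold changes are B relative to A."""

    label: str
    group_a: tuple  # (condition, day)
    group_b: tuple

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")


@dataclass(frozen=True)
class Thresholds:
    alpha: float = 0.05
    fdr_initial: float = 0.05
    fdr_screen: float = 0.01


@dataclass
class DEGTable:
    """Per-gene results of one comparison.

    ``records`` columns: gene_id, log2fc (±inf allowed), p_raw, q_bh,
    significant (bool, q < fdr_screen), direction ("up"/"down"/"none").
    """

    comparison: ComparisonSpec
    records: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)

    def significant_genes(self, direction: str | None = None) -> set:
        mask = self.records["significant"]
        if direction is not None:
            mask = mask & (self.records["direction"] == direction)
        return set(self.records.loc[mask, "gene_id"])

    @property
    def gene_universe(self) -> set:
        return set(self.records["gene_id"])


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.0) -> float:
    """log2((mean_b + pc) / (mean_a + pc)); ±inf when a zero mean and pc=0.

    Both means zero with no pseudocount is undefined and returns NaN.
    """
    if mean_a < 0 or mean_b < 0 or pseudocount < 0:
        raise ValueError("means and pseudocount must be nonnegative")
    a, b = mean_a + pseudocount, mean_b + pseudocount
    if a == 0 and b == 0:
        return math.nan
    if a == 0:
        return math.inf
    if b == 0:
        return -math.inf
    return math.log2(b / a)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted q-values, in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to 1, where p_(1..m) are
    the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0)."""
    if y <= special.polygamma(1, _MAX_DF):
        return _MAX_DF
    return optimize.brentq(lambda x: special.polygamma(1, x) - y, 1e-6, _MAX_DF)


def _estimate_variance_prior(s2: np.ndarray, df: float):
    """Empirical-Bayes prior (d0, s0²) for gene-wise sample variances.

    Moment estimator on log variances: with s²_g ~ s0²·F(df, d0), the
    log-variance residuals have variance trigamma(df/2) + trigamma(d0/2).
    Returns ``d0 = inf`` when the observed spread is no wider than the
    sampling spread (variances effectively common).
    """
    s2 = s2[s2 > _ZERO_VAR]
    if s2.size < 2:
        return math.inf, float(s2.mean()) if s2.size else 1.0
    e = np.log(s2) - special.digamma(df / 2) + math.log(df / 2)
    var_e = float(e.var(ddof=1))
    excess = var_e - special.polygamma(1, df / 2)
    if excess <= 0:
        return math.inf, float(np.exp(e.mean()))
    x0 = _trigamma_inverse(excess)
    d0 = 2 * x0
    log_s0 = float(e.mean()) + special.digamma(x0) - math.log(x0)
    return d0, float(np.exp(log_s0))


def moderated_ttest(la: np.ndarray, lb: np.ndarray):
    """Two-sample moderated t-test per gene (rows), pooled variances.

    Gene-wise pooled variances are shrunk toward the empirical-Bayes
    prior; the t statistic uses the shrunk variance with df + d0 degrees
    of freedom.  Returns ``(t, p, d0, s0_sq)``.
    """
    n1, n2 = la.shape[1], lb.shape[1]
    df = n1 + n2 - 2
    var_a = la.var(axis=1, ddof=1)
    var_b = lb.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * var_a + (n2 - 1) * var_b) / df
    d0, s0_sq = _estimate_variance_prior(s2, df)
    if math.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = _MAX_DF
    else:
        s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    diff = lb.mean(axis=1) - la.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df=min(df_total, _MAX_DF))
    return t, p, d0, s0_sq


def test_differential_expression(
    matrix: ExpressionMatrix,
    spec: ComparisonSpec,
    thresholds: Thresholds = Thresholds(),
    method: str = "moderated",
) -> DEGTable:
    """Per-gene two-sample test on log2(value+1), BH-corrected.

    ``method`` is "moderated" (empirical-Bayes shrunk variances, the
    default) or "welch".  Both groups must have ≥ 2 replicates —
    singleton Day 18–36 samples are refused.  Genes with (numerically)
    zero variance in both groups are untestable and get p = 1,
    direction "none".
    """
    a = matrix.select(*spec.group_a)
    b = matrix.select(*spec.group_b)
    for name, grp in (("group_a", a), ("group_b", b)):
        if grp.shape[1] < 2:
            raise InsufficientReplicatesError(
                f"{spec.label}: {name} {spec.__getattribute__(name)} has "
                f"{grp.shape[1]} sample(s); need at least 2"
            )
    la = np.log2(a.to_numpy(dtype=float) + 1.0)
    lb = np.log2(b.to_numpy(dtype=float) + 1.0)
    if method == "moderated":
        _, p, _, _ = moderated_ttest(la, lb)
    elif method == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    var_a = la.var(axis=1, ddof=1)
    var_b = lb.var(axis=1, ddof=1)
    untestable = (var_a < _ZERO_VAR) & (var_b < _ZERO_VAR)
    p = np.where(untestable | np.isnan(p), 1.0, p)
    q = benjamini_hochberg(p)

    mean_a = a.mean(axis=1).to_numpy()
    mean_b = b.mean(axis=1).to_numpy()
    log2fc = np.array(
        [log2_fold_change(x, y, pseudocount=0.0) for x, y in zip(mean_a, mean_b)]
    )
    significant = (q < thresholds.fdr_screen) & ~untestable
    direction = np.where(
        ~significant, "none", np.where(log2fc > 0, "up", "down")
    )
    records = pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "log2fc": log2fc,
            "p_raw": p,
            "q_bh": q,
            "significant": significant,
            "direction": direction,
        }
    ).reset_index(drop=True)
    return DEGTable(comparison=spec, records=records, thresholds=thresholds)
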