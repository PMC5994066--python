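"""Exact and rank-based statistical tests shared by the analysis modules.

Conventions fixed here so every downstream table is comparable:

* Fisher's exact test (2x2) is two-sided by the point-probability rule —
  the p value sums hypergeometric probabilities of all tables with the
  observed margins whose probability does not exceed that of the observed
  table.  This is the convention scipy implements and the one that
  reproduces the dominance-contingency values the pipeline reports.
* Pearson chi-square carries no Yates continuity correction.
* Wilcoxon signed-rank drops zero differences (no Pratt correction);
  a fully degenerate comparison (all differences zero) is reported as
  p = 1 with a warning rather than an error, because prevalence-filtered
  genus scans routinely produce identical paired vectors.
* Benjamini–Hochberg q values come from the standard step-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "FdrResult",
    "fisher_exact_2x2",
    "chi_square_rxc",
    "two_sample_test",
    "correlation",
    "bh_fdr",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test or correlation."""

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    alternative: str = "two-sided"
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": "/".join(str(k) for k in self.n),
            "alternative": self.alternative,
        }


@dataclass(frozen=True)
class FdrResult:
    """Benjamini–Hochberg adjusted p values with significance flags."""

    p_values: np.ndarray
    q_values: np.ndarray
    flags: np.ndarray
    q_threshold: float = field(default=0.05)

    @property
    def n_significant(self) -> int:
        return int(self.flags.sum())


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> TestResult:
    """Fisher's exact test on the 2x2 table ``[[a, b], [c, d]]``.

    Two-sided p follows the point-probability rule (sum of hypergeometric
    probabilities of tables, with the observed margins, no more probable
    than the observed table).
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("all-zero 2x2 table")
    odds, p = sps.fisher_exact(table, alternative=alternative)
    return TestResult(
        statistic=float(odds),
        p_value=float(p),
        method="fisher_exact",
        n=(int(a + b), int(c + d)),
        alternative=alternative,
    )


def chi_square_rxc(table) -> TestResult:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction, (r-1)(c-1) degrees of freedom."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        method=f"chi_square_df{dof}",
        n=(int(obs.sum()),),
        alternative="two-sided",
    )


def _drop_paired_missing(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def two_sample_test(x, y=None, mode: str = "mann_whitney", *, groups=None) -> TestResult:
    """Dispatch to the standard two-sample / paired / k-group tests.

    ``mode`` is one of ``wilcoxon_signed_rank``, ``mann_whitney``,
    ``welch_t``, ``paired_t``, ``kruskal_wallis``.  Paired modes drop
    pairs with a missing value; Mann-Whitney is exact for combined
    n <= 20 and tie-free data, normal-approximated with tie correction
    otherwise.
    """
    if mode == "kruskal_wallis":
        gs = [np.asarray(g, dtype=float) for g in (groups if groups is not None else x)]
        gs = [g[~np.isnan(g)] for g in gs]
        if len(gs) < 2:
            raise ValueError("kruskal_wallis needs >= 2 groups")
        stat, p = sps.kruskal(*gs)
        return TestResult(float(stat), float(p), "kruskal_wallis",
                          tuple(len(g) for g in gs))

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    if mode in ("wilcoxon_signed_rank", "paired_t"):
        if len(x) != len(y):
            raise ValueError("paired modes require equal-length vectors")
        x, y = _drop_paired_missing(x, y)

    if mode == "wilcoxon_signed_rank":
        diffs = x - y
        nz = diffs[diffs != 0]
        if len(nz) == 0:
            warnings.warn("all paired differences are zero; p reported as 1")
            return TestResult(0.0, 1.0, "wilcoxon_signed_rank", (len(x),),
                              warning="degenerate: all differences zero")
        stat, p = sps.wilcoxon(x, y, zero_method="wilcox")
        return TestResult(float(stat), float(p), "wilcoxon_signed_rank", (len(x),))

    if mode == "paired_t":
        stat, p = sps.ttest_rel(x, y)
        return TestResult(float(stat), float(p), "paired_t", (len(x),))

    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]

    if mode == "mann_whitney":
        exact = (len(x) + len(y)) <= 20
        method = "exact" if exact else "asymptotic"
        try:
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        except ValueError:
            # exact method refuses ties; fall back to tie-corrected normal
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")
        return TestResult(float(stat), float(p), "mann_whitney", (len(x), len(y)))

    if mode == "welch_t":
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        return TestResult(float(stat), float(p), "welch_t", (len(x), len(y)))

    raise ValueError(f"unknown mode {mode!r}")


def correlation(x, y, mode: str = "spearman") -> TestResult:
    """Pearson or Spearman correlation on pairwise-complete observations.

    Spearman uses mid-ranks for ties; for n <= 9 tie-free data the p value
    is from the exact permutation distribution.  A zero-variance input
    yields a NaN coefficient flagged in the result, never a silent 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    x, y = _drop_paired_missing(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(np.nan, np.nan, mode, (n,),
                          warning="zero variance: correlation undefined")
    if mode == "pearson":
        r, p = sps.pearsonr(x, y)
    elif mode == "spearman":
        r, p = sps.spearmanr(x, y)
        if n <= 9:
            # exact permutation p on the rank statistic
            res = sps.permutation_test(
                (x,), lambda xs: sps.spearmanr(xs, y).statistic,
                permutation_type="pairings", n_resamples=np.inf,
                alternative="two-sided",
            )
            p = res.pvalue
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(float(r), float(p), mode, (n,))


def bh_fdr(p, q_threshold: float = 0.05) -> FdrResult:
    """Benjamini–Hochberg step-up: q_i = min over j with p_(j) >= p_(i)
    of min(1, m p_(j) / j), flagged at q <= q_threshold."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return FdrResult(p, p.copy(), np.zeros(0, dtype=bool), q_threshold)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    flags = q <= q_threshold
    return FdrResult(p, q, flags, q_threshold)
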