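"""Paired inference for matched binary endpoints and paired deltas.

Implements the complete battery: exact McNemar on discordant pairs, matched
odds ratio with 0.5 continuity correction and Wald CI on the log scale,
paired risk difference, exact two-sided sign test, Wilcoxon signed-rank
(zeros dropped; exact tie-aware null by enumeration for small n, otherwise a
tie-corrected normal approximation with continuity correction), seeded
percentile bootstrap CI for the median, and Holm step-down adjustment.

Conventions (pinned, see package docs):

* two-sided exact binomial p-values are the doubled smaller tail capped at 1;
* the bootstrap CI is the percentile method over replicate medians, one
  seeded generator drawing n indices per replicate, replicates in order;
* Wilcoxon drops zero differences (Wilcoxon's original handling, not Pratt).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PairedTable",
    "MatchedOrResult",
    "PairedDeltaSummary",
    "build_paired_table",
    "matched_odds_ratio",
    "mcnemar_exact",
    "sign_test",
    "wilcoxon_signed_rank",
    "bootstrap_median_ci",
    "holm_adjust",
    "delta_summary",
]

Z_95 = 1.959963984540054  # Phi^-1(0.975); the CI formula specifies 1.96
_CI_Z = 1.96


@dataclass(frozen=True)
class PairedTable:
    """Paired 2x2 counts; first index = clinician outcome, second = LLM (1 = event)."""

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        for name in ("n00", "n01", "n10", "n11"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")

    @property
    def n(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def discordant(self) -> int:
        return self.n01 + self.n10

    @property
    def clin_events(self) -> int:
        return self.n10 + self.n11

    @property
    def llm_events(self) -> int:
        return self.n01 + self.n11

    def transpose(self) -> "PairedTable":
        """Swap the two arms (n01 <-> n10)."""
        return PairedTable(self.n00, self.n10, self.n01, self.n11)


@dataclass(frozen=True)
class MatchedOrResult:
    """Matched OR with Wald CI, risk difference and exact McNemar p."""

    or_hat: float
    ci_low: float
    ci_high: float
    rd: float
    p_exact: float


@dataclass(frozen=True)
class PairedDeltaSummary:
    """Summary of a paired-delta vector with sign/Wilcoxon tests and optional bootstrap CI."""

    n: int
    n_neg: int
    n_pos: int
    n_zero: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float
    p_wilcoxon: float
    p_sign: float
    ci_median_low: float | None = None
    ci_median_high: float | None = None


def build_paired_table(pairs: Sequence[tuple[int, int]]) -> PairedTable:
    """Tally (clinician, LLM) binary outcome pairs into a :class:`PairedTable`."""
    counts = [0, 0, 0, 0]
    for clin, llm in pairs:
        if clin not in (0, 1) or llm not in (0, 1):
            raise ValidationError(f"outcomes must be binary, got ({clin!r}, {llm!r})")
        counts[2 * clin + llm] += 1
    return PairedTable(n00=counts[0], n01=counts[1], n10=counts[2], n11=counts[3])


def matched_odds_ratio(table: PairedTable) -> MatchedOrResult:
    """Matched OR = (n01 + 0.5)/(n10 + 0.5) with Wald 95% CI on the log scale.

    The risk difference is the LLM-minus-clinician event-rate difference,
    (n01 - n10)/N.  Raises on an empty table (RD undefined).
    """
    if table.n == 0:
        raise ValidationError("risk difference undefined for an empty paired table")
    a = table.n01 + 0.5
    b = table.n10 + 0.5
    or_hat = a / b
    se = math.sqrt(1.0 / a + 1.0 / b)
    ci_low = math.exp(math.log(or_hat) - _CI_Z * se)
    ci_high = math.exp(math.log(or_hat) + _CI_Z * se)
    rd = (table.n01 - table.n10) / table.n
    return MatchedOrResult(
        or_hat=or_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        rd=rd,
        p_exact=mcnemar_exact(table),
    )


def mcnemar_exact(table: PairedTable) -> float:
    """Two-sided exact McNemar p: doubled smaller binomial tail, capped at 1.

    With d = n01 + n10 discordant pairs and k = min(n01, n10),
    p = min(1, 2 * P[X <= k]) for X ~ Binomial(d, 1/2); p = 1 when d = 0.
    """
    d = table.discordant
    if d == 0:
        return 1.0
    k = min(table.n01, table.n10)
    return min(1.0, 2.0 * float(sps.binom.cdf(k, d, 0.5)))


def sign_test(deltas: Sequence[float]) -> tuple[float, int, int, int]:
    """Exact two-sided sign test on non-tied pairs.

    Returns ``(p, n_neg, n_pos, n_zero)``.  Zeros are excluded; with
    m = n_neg + n_pos informative pairs and k = min(n_neg, n_pos),
    p = min(1, 2 * P[X <= k]) for X ~ Binomial(m, 1/2).  p = 1 (with a
    warning) when there are no informative pairs.
    """
    arr = np.asarray(deltas, dtype=float)
    n_neg = int(np.sum(arr < 0))
    n_pos = int(np.sum(arr > 0))
    n_zero = int(np.sum(arr == 0))
    m = n_neg + n_pos
    if m == 0:
        warnings.warn("sign test: all pairs tied; no information", stacklevel=2)
        return 1.0, n_neg, n_pos, n_zero
    k = min(n_neg, n_pos)
    p = min(1.0, 2.0 * float(sps.binom.cdf(k, m, 0.5)))
    return p, n_neg, n_pos, n_zero


def _wilcoxon_exact_p(ranks: np.ndarray, signs: np.ndarray) -> float:
    """Exact two-sided p by sign-flip enumeration with midranks.

    Midranks are multiples of 0.5, so doubling makes them exact integers and
    the 2^m enumeration collapses into an integer-support convolution.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    # dist[s] = number of sign assignments with doubled positive-rank sum s
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    w2 = int(np.rint(2.0 * float(ranks[signs > 0].sum())))
    lo = min(w2, total - w2)
    hi = max(w2, total - w2)
    n_assign = dist.sum()
    p = (dist[: lo + 1].sum() + dist[hi:].sum()) / n_assign
    return min(1.0, float(p))


def wilcoxon_signed_rank(deltas: Sequence[float], exact_limit: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value, zeros dropped, midranks for ties.

    Exact sign-flip null when the nonzero count is <= *exact_limit*;
    otherwise a normal approximation with tie-corrected variance
    (Var W+ = sum(r_i^2)/4) and 0.5 continuity correction.

    Raises :class:`DegenerateInputError` for all-zero input.
    """
    arr = np.asarray(deltas, dtype=float)
    nonzero = arr[arr != 0]
    if nonzero.size == 0:
        raise DegenerateInputError("wilcoxon signed-rank: all deltas are zero")
    ranks = sps.rankdata(np.abs(nonzero))
    signs = np.sign(nonzero)
    if nonzero.size <= exact_limit:
        return _wilcoxon_exact_p(ranks, signs)
    w_plus = float(ranks[signs > 0].sum())
    mu = float(ranks.sum()) / 2.0
    sigma = math.sqrt(float(np.sum(ranks**2)) / 4.0)
    if sigma == 0:
        return 1.0
    diff = w_plus - mu
    cc = 0.5 * math.copysign(1.0, diff) if diff != 0 else 0.0
    z = (diff - cc) / sigma
    return min(1.0, 2.0 * float(sps.norm.sf(abs(z))))


def bootstrap_median_ci(
    deltas: Sequence[float], n_boot: int = 5000, seed: int = 7
) -> tuple[float, float]:
    """Percentile 95% CI for the median by resampling with replacement.

    One seeded generator draws n indices per replicate, replicates in order,
    so the interval is deterministic given (input order, n_boot, seed).
    """
    arr = np.asarray(deltas, dtype=float)
    if arr.size == 0:
        raise ValidationError("bootstrap_median_ci: empty input")
    rng = np.random.default_rng(seed)
    # A single row-major draw is stream-identical to per-replicate draws of n.
    indices = rng.integers(0, arr.size, size=(n_boot, arr.size))
    medians = np.median(arr[indices], axis=1)
    low, high = np.percentile(medians, [2.5, 97.5])
    return float(low), float(high)


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the original order."""
    ps = np.asarray(p_values, dtype=float)
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValidationError(f"p-values must lie in [0, 1], got {list(ps)}")
    m = ps.size
    order = np.argsort(ps, kind="stable")
    scaled = ps[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return [float(x) for x in adjusted]


def delta_summary(
    deltas: Sequence[float],
    with_bootstrap: bool = False,
    n_boot: int = 5000,
    seed: int = 7,
) -> PairedDeltaSummary:
    """Full paired-delta summary: location, spread, sign pattern, and tests.

    Quartiles use linear interpolation (type-7); SD is the sample (n-1)
    standard deviation.  When every delta is zero the Wilcoxon statistic is
    degenerate and its p-value is reported as 1.0 by convention (the
    standalone :func:`wilcoxon_signed_rank` raises instead).
    """
    arr = np.asarray(deltas, dtype=float)
    if arr.size == 0:
        raise ValidationError("delta_summary: empty input")
    p_sign, n_neg, n_pos, n_zero = sign_test(arr)
    if n_neg + n_pos == 0:
        p_wilcoxon = 1.0
    else:
        p_wilcoxon = wilcoxon_signed_rank(arr)
    ci_low = ci_high = None
    if with_bootstrap:
        ci_low, ci_high = bootstrap_median_ci(arr, n_boot=n_boot, seed=seed)
    return PairedDeltaSummary(
        n=arr.size,
        n_neg=n_neg,
        n_pos=n_pos,
        n_zero=n_zero,
        median=float(np.median(arr)),
        q1=float(np.percentile(arr, 25)),
        q3=float(np.percentile(arr, 75)),
        mean=float(np.mean(arr)),
        sd=float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
        p_wilcoxon=p_wilcoxon,
        p_sign=p_sign,
        ci_median_low=ci_low,
        ci_median_high=ci_high,
    )
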