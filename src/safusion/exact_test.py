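"""Exact multinomial tail test for an excess (or deficit) of SA-fusions.

Given observed counts of SA-, AA- and SS-fusions in a clade and the null
fusion-type probabilities implied by its karyotype, the p-value for "at
least this many SA-fusions" is the multinomial tail

    P(X_SA >= k) = sum_{i=k}^{n} sum_{j=0}^{n-i}
        n! / (i! j! (n-i-j)!) p_sa^i p_aa^j p_ss^(n-i-j),

where n is the total fusion count.  Because the inner sum marginalizes the
AA/SS split, the tail also equals the binomial tail of X_SA ~ Bin(n, p_sa);
both forms are computed here and required to agree, which guards against
bookkeeping errors in either.  All mass terms are accumulated in log space
so that p-values far below 1e-5 are exact to full double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln
from scipy.stats import binom

from .null_model import FusionProbabilities, Karyotype, SexBias, probabilities

__all__ = [
    "FusionCounts",
    "TailResult",
    "multinomial_point",
    "sa_tail_probability",
    "test_counts",
]

_PROB_SUM_TOL = 1e-9
_FORM_AGREEMENT_RTOL = 1e-12
_DOUBLE_SUM_MAX_N = 500


@dataclass(frozen=True)
class FusionCounts:
    """Observed tallies of the three fusion classes."""

    n_sa: int
    n_aa: int
    n_ss: int

    def __post_init__(self) -> None:
        for name in ("n_sa", "n_aa", "n_ss"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_sa + self.n_aa + self.n_ss


@dataclass(frozen=True)
class TailResult:
    """Outcome of the exact SA-fusion tail test."""

    p_value: float
    n: int
    k_min: int
    null_probs: FusionProbabilities
    tail: str = "upper"

    def as_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "n": self.n,
            "k_min": self.k_min,
            "tail": self.tail,
            "null_probs": self.null_probs.as_dict(),
        }


def _check_probs(probs: FusionProbabilities) -> None:
    total = probs.p_sa + probs.p_aa + probs.p_ss
    if abs(total - 1.0) > _PROB_SUM_TOL:
        raise ValueError(
            f"fusion probabilities must sum to 1 (got {total!r}); "
            f"construct them with safusion.null_model.probabilities"
        )
    for name, p in probs.as_dict().items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} = {p} is not a probability")


def _log_pmf(i: int, j: int, k: int, probs: FusionProbabilities) -> float:
    """Log multinomial mass of the outcome (i SA, j AA, k SS)."""
    n = i + j + k
    out = gammaln(n + 1) - gammaln(i + 1) - gammaln(j + 1) - gammaln(k + 1)
    for count, p in ((i, probs.p_sa), (j, probs.p_aa), (k, probs.p_ss)):
        if count > 0:
            if p == 0.0:
                return -math.inf
            out += count * math.log(p)
    return float(out)


def multinomial_point(
    n_sa: int, n_aa: int, n_ss: int, probs: FusionProbabilities
) -> float:
    """Exact multinomial point mass of an (n_sa, n_aa, n_ss) outcome."""
    counts = FusionCounts(n_sa, n_aa, n_ss)
    _check_probs(probs)
    return math.exp(_log_pmf(counts.n_sa, counts.n_aa, counts.n_ss, probs))


def _tail_double_sum(k_min: int, n: int, probs: FusionProbabilities) -> float:
    """Upper tail by explicit double sum over all AA/SS splits."""
    if k_min <= 0:
        return 1.0
    if k_min > n:
        return 0.0
    logs = [
        _log_pmf(i, j, n - i - j, probs)
        for i in range(k_min, n + 1)
        for j in range(0, n - i + 1)
    ]
    finite = [x for x in logs if x > -math.inf]
    if not finite:
        return 0.0
    m = max(finite)
    return math.exp(m) * sum(math.exp(x - m) for x in finite)


def sa_tail_probability(
    k_min: int, n: int, probs: FusionProbabilities, tail: str = "upper"
) -> TailResult:
    """Exact tail probability of the SA-fusion count.

    ``tail="upper"`` gives P(X_SA >= k_min) (the excess test);
    ``tail="lower"`` gives P(X_SA <= k_min) (the deficit direction).
    The multinomial double sum and the marginal binomial form are both
    evaluated and must agree to 12 significant digits.
    """
    if n < 0:
        raise ValueError(f"total fusion count must be >= 0, got {n}")
    if not (0 <= k_min <= n + 1):
        raise ValueError(f"k_min={k_min} outside [0, n+1] for n={n}")
    _check_probs(probs)
    if tail not in ("upper", "lower"):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")

    if tail == "upper":
        marginal = float(binom.sf(k_min - 1, n, probs.p_sa))
    else:
        marginal = float(binom.cdf(k_min, n, probs.p_sa))

    # Cross-check the marginal form against the explicit double sum.  The
    # sum has O(n^2) terms, so it is verified up to a size cutoff well
    # beyond any observed fusion tally; above it the marginal binomial
    # (an exact identity, not an approximation) stands alone.
    if n <= _DOUBLE_SUM_MAX_N:
        if tail == "upper":
            double = _tail_double_sum(k_min, n, probs)
        else:
            # deficit direction: P(X <= k_min) = 1 - P(X >= k_min + 1)
            double = 1.0 - _tail_double_sum(k_min + 1, n, probs)
        scale = max(abs(double), abs(marginal), 1e-300)
        if abs(double - marginal) > _FORM_AGREEMENT_RTOL * scale + 1e-300:
            raise ArithmeticError(
                f"multinomial double sum ({double!r}) and marginal binomial "
                f"({marginal!r}) disagree beyond 12 significant digits"
            )
    return TailResult(
        p_value=min(1.0, max(0.0, marginal)),
        n=n,
        k_min=k_min,
        null_probs=probs,
        tail=tail,
    )


def test_counts(
    counts: FusionCounts,
    k: Karyotype,
    b: SexBias | float | None = None,
    tail: str = "upper",
) -> TailResult:
    """Exact test of observed fusion counts against a karyotype's null.

    The observed AA/SS split only sets the total ``n``; the tail is taken
    over the SA count at ``k_min = n_sa``.
    """
    n = counts.total
    if n == 0:
        raise ValueError("no fusions observed; the test is undefined for n = 0")
    probs = probabilities(k, b)
    return sa_tail_probability(counts.n_sa, n, probs, tail=tail)
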