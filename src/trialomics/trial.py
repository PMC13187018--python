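"""Exact single-arm phase II statistics.

Response tabulation under RECIST best-response categories, exact
Clopper-Pearson binomial confidence intervals, and the A'Hern single-stage
design (the exact-binomial modification of Fleming's one-stage design):
the smallest responder count r such that P(X >= r | n, p0) <= alpha, with
attained type-I error and exact power computed by direct tail summation —
no normal approximation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import beta as beta_dist
from scipy.stats import binom

from .io import ClinicalTable

__all__ = [
    "ResponseSummary",
    "ExactInterval",
    "AhernDesign",
    "tabulate_responses",
    "clopper_pearson",
    "ahern_min_responses",
    "exact_power",
    "round_percent",
]


@dataclass(frozen=True)
class ResponseSummary:
    """Best-response category counts with ORR (CR+PR) and DCR (CR+PR+SD).

    NE (no assessment) patients count toward ``n_total`` but toward neither
    the objective-response nor the disease-control numerator, so reported
    rates use the full intention-to-treat denominator.
    """

    n_total: int
    n_CR: int
    n_PR: int
    n_SD: int
    n_PD: int
    n_NE: int

    def __post_init__(self) -> None:
        parts = self.n_CR + self.n_PR + self.n_SD + self.n_PD + self.n_NE
        if parts != self.n_total:
            raise ValueError(f"category counts sum to {parts}, expected {self.n_total}")

    @property
    def orr_count(self) -> int:
        return self.n_CR + self.n_PR

    @property
    def dcr_count(self) -> int:
        return self.n_CR + self.n_PR + self.n_SD

    def orr_interval(self, confidence: float = 0.95) -> "ExactInterval":
        return clopper_pearson(self.orr_count, self.n_total, confidence)

    def dcr_interval(self, confidence: float = 0.95) -> "ExactInterval":
        return clopper_pearson(self.dcr_count, self.n_total, confidence)


@dataclass(frozen=True)
class ExactInterval:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval."""

    x: int
    n: int
    confidence: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.x / self.n

    def as_percent(self, decimals: int = 1) -> tuple[float, float]:
        """Bounds in percent, rounded half-away-from-zero."""
        return (
            round_percent(self.lower, decimals),
            round_percent(self.upper, decimals),
        )


@dataclass(frozen=True)
class AhernDesign:
    """An exact single-stage design: reject H0 (p <= p0) iff X >= r_min.

    ``r_min = n + 1`` flags an infeasible design (no responder count in
    0..n controls the type-I error at the requested alpha).
    """

    n: int
    p0: float
    alpha: float
    r_min: int
    attained_alpha: float
    p1: float | None = None
    attained_power: float | None = None

    @property
    def feasible(self) -> bool:
        return self.r_min <= self.n


def round_percent(proportion: float, decimals: int = 1) -> float:
    """Render a proportion as percent with round-half-away-from-zero.

    Python's builtin round is banker's rounding; clinical tables round
    halves away from zero (e.g. 0.10125 -> 10.1%... 0.655 -> 65.5%).
    """
    scaled = proportion * 100 * 10**decimals
    # nudge by a relative epsilon so values that are exactly representable
    # halves round away from zero, while ties from float noise are untouched
    import math

    floor = math.floor(abs(scaled))
    frac = abs(scaled) - floor
    if abs(frac - 0.5) < 1e-9:
        out = floor + 1
    else:
        out = math.floor(abs(scaled) + 0.5)
    return math.copysign(out, scaled) / 10**decimals


def tabulate_responses(clinical: ClinicalTable) -> ResponseSummary:
    """Tabulate best-response categories for a clinical table."""
    counts = clinical.data["best_response"].value_counts()
    return ResponseSummary(
        n_total=len(clinical),
        n_CR=int(counts.get("CR", 0)),
        n_PR=int(counts.get("PR", 0)),
        n_SD=int(counts.get("SD", 0)),
        n_PD=int(counts.get("PD", 0)),
        n_NE=int(counts.get("NE", 0)),
    )


def clopper_pearson(x: int, n: int, confidence: float = 0.95) -> ExactInterval:
    """Exact binomial confidence interval from beta quantiles.

    lower = Beta(alpha/2; x, n-x+1) quantile (0 when x = 0);
    upper = Beta(1-alpha/2; x+1, n-x) quantile (1 when x = n).
    """
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"require 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    alpha = 1.0 - confidence
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return ExactInterval(x=x, n=n, confidence=confidence, lower=lower, upper=upper)


def _upper_tail(r: int, n: int, p: float) -> float:
    """P(X >= r) for X ~ Binomial(n, p), by exact summation."""
    if r <= 0:
        return 1.0
    if r > n:
        return 0.0
    return float(binom.sf(r - 1, n, p))


def ahern_min_responses(
    n: int, p0: float, alpha: float = 0.05, p1: float | None = None
) -> AhernDesign:
    """Smallest r with exact binomial tail P(X >= r | n, p0) <= alpha.

    Scans r = 0..n; returns the sentinel r = n + 1 (attained alpha 0) when
    even r = n leaves the tail above alpha, signalling an infeasible design.
    When ``p1`` is given the exact power at the threshold is attached.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if p1 is not None and p1 <= p0:
        raise ValueError("p1 must exceed p0")
    r_min = n + 1
    attained = 0.0
    for r in range(n + 1):
        tail = _upper_tail(r, n, p0)
        if tail <= alpha:
            r_min = r
            attained = tail
            break
    power = exact_power(n, r_min, p1) if (p1 is not None and r_min <= n) else None
    return AhernDesign(
        n=n, p0=p0, alpha=alpha, r_min=r_min, attained_alpha=attained,
        p1=p1, attained_power=power,
    )


def exact_power(n: int, r: int, p1: float) -> float:
    """P(X >= r | n, p1): exact probability of meeting the design threshold."""
    if not 0 <= r <= n + 1:
        raise ValueError(f"require 0 <= r <= n+1, got r={r}, n={n}")
    if not 0 <= p1 <= 1:
        raise ValueError("p1 must be in [0, 1]")
    return _upper_tail(r, n, p1)
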