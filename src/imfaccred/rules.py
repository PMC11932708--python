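"""Industry rules-based accreditation test.

The industry standard accredits an IMF% device when at least 67% of its
deviations from laboratory values fall within ±1 IMF% and at least 95%
within ±2 IMF% (equivalently, fewer than 5% beyond ±2 IMF%).  Applied to a
finite sample these percentage rules become integer count thresholds, and
how fractional counts are rounded materially changes the test at small n.
Two counting conventions are therefore shipped:

``TABLE1`` (default)
    The convention that reproduces the published minimum-count table:
    the within-one percentage is rounded to the nearest percent
    (half-up) before comparison, and the beyond-two allowance is
    ``floor(0.05 n)`` (exactly 5% is allowed).

``STRICT``
    Exact fractions: within-one requires ``k/n >= 0.67`` and beyond-two
    requires strictly fewer than 5% of the sample (``m/n < 0.05``).

All counting is done in exact rational arithmetic, so no floating-point
rounding can flip a verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "RuleThresholds",
    "RulesConvention",
    "RulesVerdict",
    "QuarterRulesReport",
    "TABLE1",
    "STRICT",
    "classify_deviation",
    "min_within_one",
    "max_beyond_two",
    "evaluate_rules",
    "evaluate_rules_by_quarter",
    "minimum_count_table",
]

_WITHIN_POLICIES = ("nearest_percent", "exact_fraction")
_BEYOND_POLICIES = ("floor_allowance", "strict_fraction")


@dataclass(frozen=True)
class RuleThresholds:
    """Accuracy thresholds of the accreditation standard.

    ``frac_within_one`` of deviations must fall within ``band_one`` IMF% of
    the laboratory value and ``frac_within_two`` within ``band_two`` IMF%.
    """

    frac_within_one: float = 0.67
    frac_within_two: float = 0.95
    band_one: float = 1.0
    band_two: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.frac_within_one < self.frac_within_two <= 1):
            raise ValueError("require 0 < frac_within_one < frac_within_two <= 1")
        if not (0 < self.band_one < self.band_two):
            raise ValueError("require 0 < band_one < band_two")

    @property
    def frac_beyond_two(self) -> Fraction:
        """Maximum tolerated fraction beyond the outer band (exact rational)."""
        return 1 - _as_fraction(self.frac_within_two)


def _as_fraction(x: float) -> Fraction:
    # str() round-trips the decimal the user typed (0.67 -> 67/100), which
    # is what the percentage rules mean; Fraction(float) would embed the
    # binary representation error into the rule itself.
    return Fraction(str(x))


@dataclass(frozen=True)
class RulesConvention:
    """Counting policy for converting percentage rules into count thresholds."""

    within_rule: str = "nearest_percent"
    beyond_rule: str = "floor_allowance"

    def __post_init__(self) -> None:
        if self.within_rule not in _WITHIN_POLICIES:
            raise ValueError(f"within_rule must be one of {_WITHIN_POLICIES}")
        if self.beyond_rule not in _BEYOND_POLICIES:
            raise ValueError(f"beyond_rule must be one of {_BEYOND_POLICIES}")

    @property
    def name(self) -> str:
        if self == TABLE1:
            return "table1"
        if self == STRICT:
            return "strict"
        return f"{self.within_rule}/{self.beyond_rule}"


TABLE1 = RulesConvention("nearest_percent", "floor_allowance")
STRICT = RulesConvention("exact_fraction", "strict_fraction")


def get_convention(spec: "str | RulesConvention") -> RulesConvention:
    """Resolve a convention given by name ('table1' or 'strict') or instance."""
    if isinstance(spec, RulesConvention):
        return spec
    if spec == "table1":
        return TABLE1
    if spec == "strict":
        return STRICT
    raise ValueError(f"unknown rules convention {spec!r}")


def classify_deviation(residual: float, thresholds: RuleThresholds | None = None) -> str:
    """Band of one deviation by absolute size.

    ``|r| <= band_one`` -> ``'within_one'``; ``|r| <= band_two`` ->
    ``'between'``; otherwise ``'beyond_two'``.  Band edges count as inside
    the band.
    """
    thresholds = thresholds or RuleThresholds()
    if not np.isfinite(residual):
        raise ValueError(f"residual must be finite, got {residual}")
    a = abs(residual)
    if a <= thresholds.band_one:
        return "within_one"
    if a <= thresholds.band_two:
        return "between"
    return "beyond_two"


def min_within_one(n: int, convention: RulesConvention = TABLE1,
                   thresholds: RuleThresholds | None = None) -> int:
    """Smallest count of deviations within ±1 IMF% that passes the 67% rule.

    Under ``nearest_percent`` the requirement is that ``100 k / n`` rounded
    half-up to the nearest percent reaches the threshold percentage; under
    ``exact_fraction`` that ``k / n`` reaches the threshold fraction.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    thresholds = thresholds or RuleThresholds()
    f = _as_fraction(thresholds.frac_within_one)
    if convention.within_rule == "exact_fraction":
        # smallest k with k/n >= f
        return math.ceil(f * n)
    # nearest_percent: smallest k with round_half_up(100 k / n) >= 100 f,
    # i.e. 100 k / n >= 100 f - 1/2
    target = 100 * f - Fraction(1, 2)
    return max(0, math.ceil(target * n / 100))


def max_beyond_two(n: int, convention: RulesConvention = TABLE1,
                   thresholds: RuleThresholds | None = None) -> int:
    """Largest count of deviations beyond ±2 IMF% that still passes.

    ``floor_allowance`` permits ``floor(0.05 n)`` (exactly 5% passes);
    ``strict_fraction`` requires the fraction beyond to be strictly below
    5%.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    thresholds = thresholds or RuleThresholds()
    f = thresholds.frac_beyond_two  # exact rational, e.g. 1/20
    if convention.beyond_rule == "floor_allowance":
        return math.floor(f * n)
    # strict: largest m with m/n < f
    limit = f * n
    return int(limit) - 1 if limit.denominator == 1 else math.floor(limit)


@dataclass(frozen=True)
class RulesVerdict:
    """Outcome of the rules-based test on one residual sample."""

    n: int
    n_within_one: int
    n_between: int
    n_beyond_two: int
    pass_one: bool
    pass_two: bool
    convention: str = TABLE1.name

    def __post_init__(self) -> None:
        if self.n_within_one + self.n_between + self.n_beyond_two != self.n:
            raise ValueError("band counts must sum to n")

    @property
    def pass_overall(self) -> bool:
        return self.pass_one and self.pass_two

    @property
    def quadrant(self) -> str:
        """Fig-2 style quadrant: Q4 both rules pass, Q2 only the ±1 rule,
        Q3 only the ±2 rule, Q1 neither."""
        if self.pass_one and self.pass_two:
            return "Q4"
        if self.pass_one:
            return "Q2"
        if self.pass_two:
            return "Q3"
        return "Q1"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_within_one": self.n_within_one,
            "n_between": self.n_between,
            "n_beyond_two": self.n_beyond_two,
            "pct_within_one": 100.0 * self.n_within_one / self.n,
            "pct_within_two": 100.0 * (self.n - self.n_beyond_two) / self.n,
            "pass_one": self.pass_one,
            "pass_two": self.pass_two,
            "pass_overall": self.pass_overall,
            "quadrant": self.quadrant,
            "convention": self.convention,
        }


def band_counts(residuals: np.ndarray, thresholds: RuleThresholds) -> tuple[int, int, int]:
    a = np.abs(np.asarray(residuals, dtype=float))
    n_within = int(np.count_nonzero(a <= thresholds.band_one))
    n_beyond = int(np.count_nonzero(a > thresholds.band_two))
    return n_within, a.size - n_within - n_beyond, n_beyond


def evaluate_rules(residuals: Sequence[float],
                   thresholds: RuleThresholds | None = None,
                   convention: RulesConvention = TABLE1) -> RulesVerdict:
    """Apply both counting rules to a residual sample and return the verdict."""
    thresholds = thresholds or RuleThresholds()
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("cannot evaluate rules on an empty residual vector")
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite")
    n_within, n_between, n_beyond = band_counts(r, thresholds)
    n = r.size
    return RulesVerdict(
        n=n,
        n_within_one=n_within,
        n_between=n_between,
        n_beyond_two=n_beyond,
        pass_one=n_within >= min_within_one(n, convention, thresholds),
        pass_two=n_beyond <= max_beyond_two(n, convention, thresholds),
        convention=convention.name,
    )


@dataclass
class QuarterRulesReport:
    """Rules verdicts per quarter; overall pass requires all four quarters."""

    verdicts: dict[int, RulesVerdict | None]
    convention: str
    diagnostics: dict[int, str]

    @property
    def all_quarters_pass(self) -> bool:
        return all(v is not None and v.pass_overall for v in self.verdicts.values())

    # the rules-based test has no separate bracket criterion; alias for
    # symmetry with the regression report
    @property
    def overall_pass(self) -> bool:
        return self.all_quarters_pass

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "quarters": {
                str(q): (v.to_dict() if v is not None else None)
                for q, v in self.verdicts.items()
            },
            "diagnostics": {str(q): m for q, m in self.diagnostics.items()},
            "all_quarters_pass": self.all_quarters_pass,
        }


def evaluate_rules_by_quarter(residuals: Sequence[float],
                              quarter_labels: Sequence[int],
                              thresholds: RuleThresholds | None = None,
                              convention: RulesConvention = TABLE1) -> QuarterRulesReport:
    """Rules test within each quarter; overall pass iff every quarter passes.

    An empty quarter cannot demonstrate the accuracy standard, so it fails
    with an "insufficient sampling" diagnostic rather than raising.
    """
    thresholds = thresholds or RuleThresholds()
    r = np.asarray(residuals, dtype=float)
    q = np.asarray(quarter_labels, dtype=int)
    if r.shape != q.shape:
        raise ValueError("residuals and quarter labels must align")
    verdicts: dict[int, RulesVerdict | None] = {}
    diagnostics: dict[int, str] = {}
    for quarter in range(4):
        sub = r[q == quarter]
        if sub.size == 0:
            verdicts[quarter] = None
            diagnostics[quarter] = "insufficient sampling: quarter is empty"
        else:
            verdicts[quarter] = evaluate_rules(sub, thresholds, convention)
    return QuarterRulesReport(verdicts=verdicts, convention=convention.name,
                              diagnostics=diagnostics)


def minimum_count_table(sample_sizes: Sequence[int],
                        convention: RulesConvention = TABLE1,
                        thresholds: RuleThresholds | None = None):
    """Minimum/maximum band counts needed to pass, per sample size.

    Reproduces the published minimum-count table under the default
    convention: columns are the minimum count within ±1 IMF%, the implied
    count in the 1–2 IMF% band, and the maximum count allowed beyond
    ±2 IMF%.
    """
    import pandas as pd

    rows = []
    for n in sample_sizes:
        k = min_within_one(n, convention, thresholds)
        m = max_beyond_two(n, convention, thresholds)
        rows.append(
            {
                "n": n,
                "min_within_one": k,
                "max_between": n - k - m,
                "max_beyond_two": m,
                "pct_within_one": round(100 * k / n, 1),
                "pct_beyond_two": round(100 * m / n, 1),
            }
        )
    return pd.DataFrame(rows)
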