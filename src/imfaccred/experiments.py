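"""Monte-Carlo pass-rate studies comparing the two accreditation tests.

Each study simulates many accreditation attempts from a theoretical device
of known accuracy and records how often the device passes.  Datasets are
generated once per replicate at the largest requested size and truncated by
the prefix protocol for smaller sizes, so pass-rate curves are smooth in n.

The harness allocates observations to quarters by the simulation design
itself (laboratory values drawn per quarter of the fixed 0.5–9.5 IMF%
range), which gives exactly ``n`` observations per quarter — the balanced
per-quarter sizes the pass-rate studies are expressed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accredit import MIN_QUARTER_COUNT, resolve_alpha
from .bayes import DEFAULT_N_DRAWS, PriorSpec, posterior, predictive_draws, build_design
from .rules import TABLE1, STRICT, RulesConvention, RuleThresholds, evaluate_rules, min_within_one, max_beyond_two, band_counts
from .simulate import DEFAULT_RANGE, SimulationSpec, get_device, simulate_device_dataset

__all__ = [
    "PassRateCurve",
    "QuadrantResult",
    "pass_rate_curve",
    "quadrant_experiment",
    "quadrant_probabilities",
    "large_sample_experiment",
]


@dataclass
class PassRateCurve:
    """Pass rate per per-quarter sample size for one device and method."""

    method: str
    device: str
    error_sd: float
    sizes: list[int]
    n_reps: int
    pass_rate: list[float]
    prior_scheme: str | float | None
    g: float | None
    n_draws: int | None
    convention: str | None
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        meta = {
            "method": self.method,
            "device": self.device,
            "error_sd": self.error_sd,
            "reps": self.n_reps,
            "prior_scheme": self.prior_scheme,
            "g": self.g,
            "n_draws": self.n_draws,
            "convention": self.convention,
            "seed": self.seed,
        }
        return pd.DataFrame(
            [{"size_per_quarter": s, "pass_rate": r, **meta}
             for s, r in zip(self.sizes, self.pass_rate)]
        )


def _regression_pass(resid: np.ndarray, labels: np.ndarray, g: float,
                     alpha_scheme, thresholds: RuleThresholds,
                     n_draws: int, rng: np.random.Generator) -> bool:
    """One regression assessment on a balanced labelled sample."""
    counts = np.bincount(labels, minlength=4)
    if (counts <= MIN_QUARTER_COUNT).any():
        return False
    alpha = resolve_alpha(alpha_scheme, resid.size, counts)
    system = build_design(resid, labels)
    post = posterior(system, PriorSpec(g=g, alpha=alpha, delta=alpha))
    X_new = np.zeros((4, 4))
    X_new[:, 0] = 1.0
    X_new[1, 1] = X_new[2, 2] = X_new[3, 3] = 1.0
    pred = predictive_draws(post, X_new, n_draws=n_draws, seed=rng)
    frac1 = pred.fraction_within(thresholds.band_one)
    frac2 = pred.fraction_within(thresholds.band_two)
    return bool(np.all(frac1 > thresholds.frac_within_one)
                and np.all(frac2 > thresholds.frac_within_two))


def _rules_pass(resid: np.ndarray, labels: np.ndarray,
                thresholds: RuleThresholds, convention: RulesConvention) -> bool:
    for quarter in range(4):
        sub = resid[labels == quarter]
        if sub.size == 0:
            return False
        n_within, _, n_beyond = band_counts(sub, thresholds)
        if n_within < min_within_one(sub.size, convention, thresholds):
            return False
        if n_beyond > max_beyond_two(sub.size, convention, thresholds):
            return False
    return True


def pass_rate_curve(device, method: str, sizes, n_reps: int = 1000,
                    prior_scheme="0.25n", g: float = 1.0,
                    thresholds: RuleThresholds | None = None,
                    convention: RulesConvention = TABLE1,
                    n_draws: int = DEFAULT_N_DRAWS,
                    value_range: tuple[float, float] = DEFAULT_RANGE,
                    seed: int | None = None) -> PassRateCurve:
    """Monte-Carlo pass rate versus per-quarter sample size.

    Parameters
    ----------
    device : str, float or DeviceSpec
        Device label ('A'–'D'), a custom error sd, or a full spec.
    method : {'rules', 'regression'}
    sizes : sequence of int
        Ascending per-quarter sample sizes.
    n_reps : int
        Replicated accreditation attempts per size; each replicate draws
        one maximal dataset and prefixes it down the size grid.
    prior_scheme : regression only; a number for ``alpha = delta`` or one
        of ``'smallest_quarter'``, ``'0.25n'``, ``'0.5n'``, ``'n'``, ``'2n'``
        (fractions of the total sample size at each grid point).
    """
    dev = get_device(device)
    sizes = sorted(int(s) for s in sizes)
    if not sizes or sizes[0] < 1:
        raise ValueError("sizes must be positive integers")
    if method not in ("rules", "regression"):
        raise ValueError("method must be 'rules' or 'regression'")
    thresholds = thresholds or RuleThresholds()
    max_size = sizes[-1]
    passes = np.zeros((len(sizes), n_reps), dtype=bool)
    ss = np.random.SeedSequence(seed)
    for r, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        spec = SimulationSpec(device=dev, n_per_stratum=max_size,
                              value_range=value_range, stratify="quarter")
        data = simulate_device_dataset(spec, rng)
        resid_full = data.residuals
        # interleaved generation: row 4i+q sits in quarter q
        labels_full = np.tile(np.arange(4), max_size)
        for i, s in enumerate(sizes):
            resid = resid_full[: 4 * s]
            labels = labels_full[: 4 * s]
            if method == "rules":
                passes[i, r] = _rules_pass(resid, labels, thresholds, convention)
            else:
                passes[i, r] = _regression_pass(resid, labels, g, prior_scheme,
                                                thresholds, n_draws, rng)
    return PassRateCurve(
        method=method,
        device=dev.label,
        error_sd=dev.error_sd,
        sizes=sizes,
        n_reps=n_reps,
        pass_rate=passes.mean(axis=1).tolist(),
        prior_scheme=prior_scheme if method == "regression" else None,
        g=g if method == "regression" else None,
        n_draws=n_draws if method == "regression" else None,
        convention=convention.name if method == "rules" else None,
        seed=seed,
    )


@dataclass
class QuadrantResult:
    """Tally of rule outcomes over repeated samples from one error law."""

    n_sims: int
    n: int
    sd: float
    counts: dict[str, int]
    convention: str
    seed: int | None

    @property
    def pass_one_count(self) -> int:
        return self.counts["Q2"] + self.counts["Q4"]

    @property
    def pass_two_count(self) -> int:
        return self.counts["Q3"] + self.counts["Q4"]

    @property
    def both_pass_count(self) -> int:
        return self.counts["Q4"]

    def to_dict(self) -> dict:
        return {
            "n_sims": self.n_sims, "n": self.n, "sd": self.sd,
            "quadrants": self.counts,
            "pass_one_count": self.pass_one_count,
            "pass_two_count": self.pass_two_count,
            "both_pass_count": self.both_pass_count,
            "convention": self.convention, "seed": self.seed,
        }


def quadrant_experiment(n_sims: int = 100, n: int = 100, sd: float = 1.0,
                        thresholds: RuleThresholds | None = None,
                        convention: RulesConvention = STRICT,
                        seed: int | None = None) -> QuadrantResult:
    """Repeatedly sample deviations from ``N(0, sd^2)`` and tally rule outcomes.

    Each simulation is one hypothetical accreditation sample; quadrants
    classify which of the ±1 and ±2 IMF% rules it passed.
    """
    thresholds = thresholds or RuleThresholds()
    rng = np.random.default_rng(seed)
    counts = {"Q1": 0, "Q2": 0, "Q3": 0, "Q4": 0}
    for _ in range(n_sims):
        verdict = evaluate_rules(rng.normal(0.0, sd, n), thresholds, convention)
        counts[verdict.quadrant] += 1
    return QuadrantResult(n_sims=n_sims, n=n, sd=sd, counts=counts,
                          convention=convention.name, seed=seed)


def quadrant_probabilities(n: int = 100, sd: float = 1.0,
                           thresholds: RuleThresholds | None = None,
                           convention: RulesConvention = STRICT) -> dict[str, float]:
    """Exact quadrant probabilities by multinomial enumeration.

    The band counts of an n-sample from ``N(0, sd^2)`` are multinomial with
    cell probabilities given by the normal CDF; summing the multinomial pmf
    over all (within, beyond) count pairs gives the exact probability of
    each rule outcome — the analytic oracle for
    :func:`quadrant_experiment`.
    """
    thresholds = thresholds or RuleThresholds()
    p_within = 2 * stats.norm.cdf(thresholds.band_one / sd) - 1
    p_beyond = 2 * stats.norm.sf(thresholds.band_two / sd)
    p_mid = 1 - p_within - p_beyond
    k_min = min_within_one(n, convention, thresholds)
    m_max = max_beyond_two(n, convention, thresholds)

    # log-pmf of the trinomial over the (within, beyond) grid
    from scipy.special import gammaln

    w = np.arange(n + 1)
    probs = {"Q1": 0.0, "Q2": 0.0, "Q3": 0.0, "Q4": 0.0}
    logs = np.log([max(p_within, 1e-300), max(p_beyond, 1e-300), max(p_mid, 1e-300)])
    for wi in w:
        b = np.arange(n - wi + 1)
        mid = n - wi - b
        logp = (gammaln(n + 1) - gammaln(wi + 1) - gammaln(b + 1) - gammaln(mid + 1)
                + wi * logs[0] + b * logs[1] + mid * logs[2])
        pmf = np.exp(logp)
        pass_one = wi >= k_min
        pass_two = b <= m_max
        probs["Q4"] += pmf[pass_two].sum() if pass_one else 0.0
        probs["Q2"] += pmf[~pass_two].sum() if pass_one else 0.0
        probs["Q3"] += 0.0 if pass_one else pmf[pass_two].sum()
        probs["Q1"] += 0.0 if pass_one else pmf[~pass_two].sum()
    return probs


def large_sample_experiment(sd_list=(0.95, 1.05), n: int = 20_000,
                            n_sims: int = 10_000,
                            thresholds: RuleThresholds | None = None,
                            convention: RulesConvention = TABLE1,
                            seed: int | None = None) -> pd.DataFrame:
    """Distribution of within-band percentages for very large samples.

    At n = 20,000 the sample percentages concentrate tightly around the
    population band probabilities, so a device with error sd just inside
    the standard passes essentially always and one just outside essentially
    never — the separation the percentage rules cannot deliver at small n.

    Returns a tidy frame with one row per (sd, simulation).
    """
    thresholds = thresholds or RuleThresholds()
    rng = np.random.default_rng(seed)
    k_min = min_within_one(n, convention, thresholds)
    m_max = max_beyond_two(n, convention, thresholds)
    records = []
    for sd in sd_list:
        for sim in range(n_sims):
            draws = rng.normal(0.0, sd, n)
            n_within, _, n_beyond = band_counts(draws, thresholds)
            records.append({
                "sd": sd,
                "sim": sim,
                "pct_within_one": 100.0 * n_within / n,
                "pct_within_two": 100.0 * (n - n_beyond) / n,
                "pass": (n_within >= k_min) and (n_beyond <= m_max),
            })
    return pd.DataFrame.from_records(records)
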