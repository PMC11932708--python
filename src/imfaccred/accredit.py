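"""Full device assessments: Bayesian predictive test and rules-based test.

The regression assessment partitions the accredited range into quarters,
fits the conjugate quarter regression to the residuals, simulates future
residuals from the predictive posterior for each quarter and passes a
quarter when strictly more than 67% of the simulated values fall within
±1 IMF%, strictly more than 95% within ±2 IMF%, and the quarter holds more
than 19 observations.  The rules-based assessment applies the industry
count rules quarter by quarter.  Both produce serialisable reports with
full provenance (seed, prior, convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .bayes import (
    DEFAULT_N_DRAWS,
    BayesianQuarterRegression,
    PriorSpec,
    posterior,
    predictive_draws,
)
from .data import AccreditationDataset, QuarterPartition, UnitBracketCensus, unit_bracket_census
from .rules import (
    TABLE1,
    QuarterRulesReport,
    RulesConvention,
    RuleThresholds,
    evaluate_rules_by_quarter,
)

__all__ = [
    "QuarterAssessment",
    "AccreditationReport",
    "StandardRegressionReport",
    "RegressionAccreditor",
    "RulesAccreditor",
    "assess_regression",
    "assess_rules",
    "standard_regression_report",
    "MIN_QUARTER_COUNT",
]

#: A quarter must hold strictly more observations than this.
MIN_QUARTER_COUNT = 19

PRIOR_SCHEMES = ("smallest_quarter", "0.25n", "0.5n", "n", "2n")


def resolve_alpha(scheme, n_total: int, quarter_counts: np.ndarray) -> float:
    """Translate a prior scheme into a numeric ``alpha = delta`` value.

    Accepted schemes: a positive number (used as-is), ``'smallest_quarter'``
    (the occupancy of the least-sampled quarter), or the sample-size
    multiples ``'0.25n'``, ``'0.5n'``, ``'n'``, ``'2n'``.
    """
    if scheme is None:
        scheme = "0.25n"
    if isinstance(scheme, (int, float)) and not isinstance(scheme, bool):
        if scheme <= 0:
            raise ValueError("alpha must be positive")
        return float(scheme)
    if scheme == "smallest_quarter":
        smallest = int(quarter_counts[quarter_counts > 0].min()) if np.any(quarter_counts > 0) else 1
        return float(max(smallest, 1))
    multipliers = {"0.25n": 0.25, "0.5n": 0.5, "n": 1.0, "2n": 2.0}
    if scheme in multipliers:
        return multipliers[scheme] * n_total
    raise ValueError(f"unknown prior scheme {scheme!r}; use a number or one of {PRIOR_SCHEMES}")


@dataclass
class QuarterAssessment:
    """Predictive-posterior verdict for one quarter of the range."""

    quarter: int                    # 1-based, as reported to users
    range: tuple[float, float]
    count: int
    fitted_mean: float | None
    fitted_sd: float | None
    pct_within_one: float | None
    pct_within_two: float | None
    pass_count_rule: bool
    pass_bands: bool
    diagnostic: str = ""

    @property
    def passed(self) -> bool:
        return self.pass_count_rule and self.pass_bands

    def to_dict(self) -> dict:
        return {
            "quarter": self.quarter,
            "range_lower": self.range[0],
            "range_upper": self.range[1],
            "count": self.count,
            "fitted_mean": self.fitted_mean,
            "fitted_sd": self.fitted_sd,
            "pct_within_one": self.pct_within_one,
            "pct_within_two": self.pct_within_two,
            "pass_count_rule": self.pass_count_rule,
            "pass_bands": self.pass_bands,
            "pass": self.passed,
            "diagnostic": self.diagnostic,
        }


@dataclass
class AccreditationReport:
    """Outcome of a regression-based accreditation assessment.

    ``all_quarters_pass`` is the pass-rate quantity of the simulation
    studies (every quarter meets the predictive band and count criteria);
    ``overall_pass`` additionally requires every 1-IMF% unit bracket of the
    accredited range to hold at least 20 observations, mirroring the
    industry sampling-density requirement.
    """

    quarters: list[QuarterAssessment]
    census: UnitBracketCensus
    prior: dict
    n_draws: int
    seed: int | None
    n_used: int
    n_excluded: int
    partition: dict
    provenance: dict = field(default_factory=dict)

    @property
    def all_quarters_pass(self) -> bool:
        return all(q.passed for q in self.quarters)

    @property
    def brackets_pass(self) -> bool:
        return self.census.all_pass

    @property
    def overall_pass(self) -> bool:
        return self.all_quarters_pass and self.brackets_pass

    def to_dict(self) -> dict:
        return {
            "quarters": [q.to_dict() for q in self.quarters],
            "unit_brackets": {
                "counts": self.census.counts.tolist(),
                "edges": self.census.edges.tolist(),
                "min_count": self.census.min_count,
                "insufficient": self.census.flags.tolist(),
            },
            "all_quarters_pass": self.all_quarters_pass,
            "brackets_pass": self.brackets_pass,
            "overall_pass": self.overall_pass,
            "prior": self.prior,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "partition": self.partition,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self):
        """Flat per-quarter table mirroring the regression-analysis report."""
        import pandas as pd

        return pd.DataFrame([q.to_dict() for q in self.quarters])


@dataclass
class StandardRegressionReport:
    """Classical device-vs-laboratory regression summary for reports."""

    intercept: float
    slope: float
    rmsep: float
    r_squared: float
    n: int
    residual_mean: float
    residual_sd: float

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "rmsep": self.rmsep,
            "r_squared": self.r_squared,
            "n": self.n,
            "residual_mean": self.residual_mean,
            "residual_sd": self.residual_sd,
        }


def standard_regression_report(dataset: AccreditationDataset) -> StandardRegressionReport:
    """Least-squares fit of device on laboratory IMF% with RMSEP and R².

    RMSEP is the root mean squared residual of this regression; R² is the
    squared correlation between device and laboratory values.
    """
    if len(dataset) < 3:
        raise ValueError("standard regression needs at least 3 observations")
    lab, device = dataset.lab, dataset.device
    if np.var(lab) == 0:
        raise ValueError("laboratory values are degenerate (zero variance)")
    fit = stats.linregress(lab, device)
    fitted = fit.intercept + fit.slope * lab
    resid = device - fitted
    return StandardRegressionReport(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        rmsep=float(np.sqrt(np.mean(resid**2))),
        r_squared=float(fit.rvalue**2),
        n=len(dataset),
        residual_mean=float(np.mean(resid)),
        residual_sd=float(np.std(resid, ddof=1)),
    )


def _validate_xy(X, y) -> AccreditationDataset:
    lab = np.asarray(X, dtype=float)
    if lab.ndim == 2:
        if lab.shape[1] != 1:
            raise ValueError("X must be laboratory values of shape (n,) or (n, 1)")
        lab = lab.ravel()
    device = np.asarray(y, dtype=float).ravel()
    return AccreditationDataset(lab=lab, device=device)


class RegressionAccreditor(BaseEstimator):
    """Bayesian predictive accreditation assessment as an estimator.

    ``fit(X, y)`` takes laboratory values ``X`` and device predictions
    ``y``; the fitted object exposes the quarter partition, the conjugate
    posterior and the :class:`AccreditationReport`.

    Parameters
    ----------
    lower, upper : float, optional
        Accreditation range; defaults to the observed extremes of the
        partition basis values.  Observations outside an explicit range are
        excluded from assessment and counted in the report.
    basis : {'device', 'lab'}, default 'device'
        Values that drive quarter allocation.
    g : float, default 1.0
        Prior precision weight.
    alpha : float or str, optional
        ``alpha = delta`` hyperparameter, or a scheme name
        (``'smallest_quarter'``, ``'0.25n'``, ``'0.5n'``, ``'n'``,
        ``'2n'``).  Default ``'0.25n'``.
    thresholds : RuleThresholds, optional
        Accuracy bands and fractions.
    n_draws : int, default 50000
        Predictive posterior sample size per assessment.
    random_state : int or numpy Generator, optional
        Seed for the predictive draws.
    """

    def __init__(self, lower: float | None = None, upper: float | None = None,
                 basis: str = "device", g: float = 1.0, alpha=None,
                 thresholds: RuleThresholds | None = None,
                 n_draws: int = DEFAULT_N_DRAWS, min_bracket_count: int = 20,
                 random_state=None):
        self.lower = lower
        self.upper = upper
        self.basis = basis
        self.g = g
        self.alpha = alpha
        self.thresholds = thresholds
        self.n_draws = n_draws
        self.min_bracket_count = min_bracket_count
        self.random_state = random_state

    def fit(self, X, y):
        dataset = _validate_xy(X, y)
        thresholds = self.thresholds or RuleThresholds()
        basis_values = dataset._basis_values(self.basis)
        lo = float(np.min(basis_values)) if self.lower is None else float(self.lower)
        hi = float(np.max(basis_values)) if self.upper is None else float(self.upper)
        part = QuarterPartition(lo, hi, self.basis)
        labels = part.assign(basis_values)
        included = labels >= 0

        resid = dataset.residuals[included]
        q = labels[included]
        counts = np.bincount(q, minlength=4)
        n_used = int(included.sum())
        alpha = resolve_alpha(self.alpha, n_used, counts)
        prior = PriorSpec(g=float(self.g), alpha=alpha, delta=alpha)

        occupied = counts > 0
        quarters: list[QuarterAssessment] = []
        model = None
        if occupied.all():
            model = BayesianQuarterRegression(g=self.g, alpha=alpha, delta=alpha)
            model.fit(q, resid)
            pred = model.predictive_draws(quarters=(0, 1, 2, 3),
                                          n_draws=self.n_draws, seed=self.random_state)
            frac1 = pred.fraction_within(thresholds.band_one)
            frac2 = pred.fraction_within(thresholds.band_two)
            for j in range(4):
                draws_j = pred.draws[:, j]
                pct1 = 100.0 * frac1[j]
                pct2 = 100.0 * frac2[j]
                quarters.append(QuarterAssessment(
                    quarter=j + 1,
                    range=part.quarter_range(j),
                    count=int(counts[j]),
                    fitted_mean=float(np.mean(draws_j)),
                    fitted_sd=float(np.std(draws_j, ddof=1)),
                    pct_within_one=float(pct1),
                    pct_within_two=float(pct2),
                    pass_count_rule=bool(counts[j] > MIN_QUARTER_COUNT),
                    pass_bands=bool(pct1 > 100.0 * thresholds.frac_within_one
                                    and pct2 > 100.0 * thresholds.frac_within_two),
                ))
        else:
            # Rank-deficient design: assess the occupied quarters with a
            # reduced design (intercept absorbs the first occupied quarter),
            # fail the empty ones with a diagnostic — never crash.
            from .bayes import DesignSystem

            occ = [int(j) for j in np.flatnonzero(occupied)]
            Xr = np.column_stack(
                [np.ones(resid.size)] + [(q == orig).astype(float) for orig in occ[1:]]
            )
            system = DesignSystem(y=resid, X=Xr)
            post = posterior(system, PriorSpec(g=float(self.g), alpha=alpha, delta=alpha))
            rows = np.zeros((len(occ), Xr.shape[1]))
            rows[:, 0] = 1.0
            for i, orig in enumerate(occ[1:], start=1):
                rows[i, i] = 1.0
            pred = predictive_draws(post, rows, n_draws=self.n_draws,
                                    seed=self.random_state)
            frac1 = pred.fraction_within(thresholds.band_one)
            frac2 = pred.fraction_within(thresholds.band_two)
            col = {orig: i for i, orig in enumerate(occ)}
            for j in range(4):
                if occupied[j]:
                    i = col[j]
                    pct1 = 100.0 * frac1[i]
                    pct2 = 100.0 * frac2[i]
                    quarters.append(QuarterAssessment(
                        quarter=j + 1, range=part.quarter_range(j),
                        count=int(counts[j]),
                        fitted_mean=float(np.mean(pred.draws[:, i])),
                        fitted_sd=float(np.std(pred.draws[:, i], ddof=1)),
                        pct_within_one=float(pct1), pct_within_two=float(pct2),
                        pass_count_rule=bool(counts[j] > MIN_QUARTER_COUNT),
                        pass_bands=bool(pct1 > 100.0 * thresholds.frac_within_one
                                        and pct2 > 100.0 * thresholds.frac_within_two),
                    ))
                else:
                    quarters.append(QuarterAssessment(
                        quarter=j + 1, range=part.quarter_range(j), count=0,
                        fitted_mean=None, fitted_sd=None,
                        pct_within_one=None, pct_within_two=None,
                        pass_count_rule=False, pass_bands=False,
                        diagnostic="insufficient samples: quarter is empty",
                    ))
        census = unit_bracket_census(basis_values[included], lo, hi,
                                     min_count=self.min_bracket_count)
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None
        report = AccreditationReport(
            quarters=quarters,
            census=census,
            prior={"g": float(self.g), "alpha": alpha, "delta": alpha,
                   "scheme": self.alpha if isinstance(self.alpha, str) else None},
            n_draws=self.n_draws,
            seed=seed,
            n_used=n_used,
            n_excluded=int(len(dataset) - n_used),
            partition={"lower": lo, "upper": hi, "basis": self.basis,
                       "boundaries": part.boundaries.tolist()},
            provenance={"method": "regression", "band_rule": "strict_fraction_of_draws"},
        )
        self.dataset_ = dataset
        self.partition_ = part
        self.labels_ = labels
        self.model_ = model
        self.report_ = report
        self.passed_ = report.all_quarters_pass
        return self

    def predict(self, X=None) -> bool:
        """Overall verdict on the fitted data (all quarters pass)."""
        self._check_fitted()
        return self.passed_

    def _check_fitted(self) -> None:
        if not hasattr(self, "report_"):
            raise AttributeError("accreditor is not fitted; call fit(lab, device) first")


class RulesAccreditor(BaseEstimator):
    """Industry rules-based assessment as an estimator.

    ``fit(X, y)`` with laboratory values ``X`` and device predictions ``y``
    partitions the range into quarters and applies the count rules within
    each; the device passes when every quarter passes both rules.
    """

    def __init__(self, lower: float | None = None, upper: float | None = None,
                 basis: str = "device", thresholds: RuleThresholds | None = None,
                 convention: RulesConvention = TABLE1):
        self.lower = lower
        self.upper = upper
        self.basis = basis
        self.thresholds = thresholds
        self.convention = convention

    def fit(self, X, y):
        dataset = _validate_xy(X, y)
        basis_values = dataset._basis_values(self.basis)
        lo = float(np.min(basis_values)) if self.lower is None else float(self.lower)
        hi = float(np.max(basis_values)) if self.upper is None else float(self.upper)
        part = QuarterPartition(lo, hi, self.basis)
        labels = part.assign(basis_values)
        included = labels >= 0
        report = evaluate_rules_by_quarter(
            dataset.residuals[included], labels[included],
            thresholds=self.thresholds, convention=self.convention,
        )
        self.dataset_ = dataset
        self.partition_ = part
        self.labels_ = labels
        self.report_ = report
        self.passed_ = report.all_quarters_pass
        return self

    def predict(self, X=None) -> bool:
        if not hasattr(self, "report_"):
            raise AttributeError("accreditor is not fitted; call fit(lab, device) first")
        return self.passed_


def assess_regression(dataset: AccreditationDataset, g: float = 1.0, alpha=None,
                      thresholds: RuleThresholds | None = None,
                      n_draws: int = DEFAULT_N_DRAWS,
                      lower: float | None = None, upper: float | None = None,
                      basis: str = "device", seed=None) -> AccreditationReport:
    """Run the Bayesian predictive assessment and return its report."""
    acc = RegressionAccreditor(lower=lower, upper=upper, basis=basis, g=g,
                               alpha=alpha, thresholds=thresholds,
                               n_draws=n_draws, random_state=seed)
    acc.fit(dataset.lab, dataset.device)
    return acc.report_


def assess_rules(dataset: AccreditationDataset,
                 thresholds: RuleThresholds | None = None,
                 convention: RulesConvention = TABLE1,
                 lower: float | None = None, upper: float | None = None,
                 basis: str = "device") -> QuarterRulesReport:
    """Run the rules-based assessment and return its per-quarter report."""
    acc = RulesAccreditor(lower=lower, upper=upper, basis=basis,
                          thresholds=thresholds, convention=convention)
    acc.fit(dataset.lab, dataset.device)
    return acc.report_
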