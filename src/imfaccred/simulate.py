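"""Synthetic device-accreditation datasets.

Laboratory IMF% values are drawn uniformly over the accreditation range
0.5–9.5 IMF% (sheep meat), stratified either over 1-IMF% unit brackets
({0.5–1.5, ..., 8.5–9.5}) or over the four quarters of the range.  Device
predictions add Gaussian error, so the residual ``lab - device`` is
``N(-error_mean, error_sd^2)`` — for the mean-zero theoretical devices the
residual is simply ``N(0, sd^2)``.

Four theoretical devices span the accreditation boundary:

=======  =========  ==========================================
Device   error sd   relation to the standard (sd 1.03 boundary)
=======  =========  ==========================================
A        0.80       comfortably inside
B        0.95       just inside
C        1.05       just outside
D        1.10       clearly outside
=======  =========  ==========================================

Strata are generated interleaved (round-robin), so the first ``4k`` rows of
a quarter-stratified dataset contain exactly ``k`` observations per
quarter.  Taking the first *n* rows of one maximal simulation ("prefix
sampling") is the protocol used by the pass-rate studies; it keeps curves
across sample sizes smooth because consecutive sizes share their data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AccreditationDataset

__all__ = [
    "DeviceSpec",
    "SimulationSpec",
    "DEVICES",
    "simulate_lab_values",
    "simulate_device_dataset",
    "prefix",
]

DEFAULT_RANGE = (0.5, 9.5)


@dataclass(frozen=True)
class DeviceSpec:
    """A theoretical device defined by its Gaussian prediction error."""

    label: str
    error_sd: float
    error_mean: float = 0.0

    def __post_init__(self) -> None:
        if not self.error_sd >= 0:
            raise ValueError("error_sd must be non-negative")


#: The four theoretical devices of the simulation study.
DEVICES: dict[str, DeviceSpec] = {
    "A": DeviceSpec("A", 0.80),
    "B": DeviceSpec("B", 0.95),
    "C": DeviceSpec("C", 1.05),
    "D": DeviceSpec("D", 1.10),
}


def get_device(spec: "str | DeviceSpec | float") -> DeviceSpec:
    """Resolve a device by label ('A'–'D'), error sd, or spec instance."""
    if isinstance(spec, DeviceSpec):
        return spec
    if isinstance(spec, str):
        try:
            return DEVICES[spec.upper()]
        except KeyError:
            raise ValueError(
                f"unknown device {spec!r}; use one of {sorted(DEVICES)} or a DeviceSpec"
            ) from None
    return DeviceSpec(label=f"sd={float(spec):g}", error_sd=float(spec))


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic accreditation dataset.

    ``n_per_stratum`` lab values are drawn per stratum; with
    ``stratify='quarter'`` (the pass-rate-study default) the strata are the
    four quarters of the range, with ``stratify='bracket'`` they are the
    1-IMF% unit brackets.
    """

    device: DeviceSpec
    n_per_stratum: int
    value_range: tuple[float, float] = DEFAULT_RANGE
    stratify: str = "quarter"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_stratum < 1:
            raise ValueError("n_per_stratum must be >= 1")
        lo, hi = self.value_range
        if not hi > lo:
            raise ValueError("range upper bound must exceed lower bound")
        if self.stratify not in ("quarter", "bracket", "none"):
            raise ValueError("stratify must be 'quarter', 'bracket' or 'none'")

    @property
    def n_total(self) -> int:
        return self.n_per_stratum * self.n_strata

    @property
    def n_strata(self) -> int:
        if self.stratify == "none":
            return 1
        if self.stratify == "quarter":
            return 4
        lo, hi = self.value_range
        return int(np.ceil(round(hi - lo, 9)))


def _stratum_edges(spec: SimulationSpec) -> np.ndarray:
    lo, hi = spec.value_range
    if spec.stratify == "none":
        return np.array([lo, hi])
    if spec.stratify == "quarter":
        return np.linspace(lo, hi, 5)
    edges = np.append(np.arange(lo, hi, 1.0), hi)
    return edges


def simulate_lab_values(spec: SimulationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Stratified-uniform laboratory IMF% values, in interleaved order.

    Row ``4i + q`` of a quarter-stratified draw lies in quarter ``q``, so
    every prefix of length ``4k`` holds exactly ``k`` values per quarter.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    edges = _stratum_edges(spec)
    n_strata = edges.size - 1
    # one uniform per stratum per round, emitted round-robin
    u = rng.random((spec.n_per_stratum, n_strata))
    values = edges[:-1] + u * np.diff(edges)
    return values.ravel()


def simulate_device_dataset(spec: SimulationSpec,
                            rng: np.random.Generator | None = None) -> AccreditationDataset:
    """Full synthetic dataset: ``device_i = lab_i + e_i`` with Gaussian errors.

    Lab values and errors come from a single seeded generator sequence, so
    a given spec always yields the identical dataset and its prefixes.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lab = simulate_lab_values(spec, rng)
    errors = rng.normal(spec.device.error_mean, spec.device.error_sd, lab.size)
    return AccreditationDataset(lab=lab, device=lab + errors)


def prefix(dataset: AccreditationDataset, n: int) -> AccreditationDataset:
    """First ``n`` records in generation order (the prefix-sampling protocol)."""
    return dataset.prefix(n)
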