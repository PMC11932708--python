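"""Core data containers for device-accreditation analysis.

The accreditation problem compares a device's intramuscular-fat predictions
(IMF%, per carcass) against destructive laboratory reference values (Soxhlet
extraction).  Everything downstream works on the paired values, their
residuals ``lab - device``, and an equal-width four-quarter partition of the
accredited IMF% range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementPair",
    "AccreditationDataset",
    "QuarterPartition",
    "UnitBracketCensus",
    "compute_residuals",
    "partition_quarters",
    "unit_bracket_census",
]

#: Plausible IMF% window used to flag (not drop) suspicious inputs.
DEFAULT_PLAUSIBLE_RANGE = (0.0, 60.0)

#: Minimum carcass count required in every 1-IMF% increment of the
#: accredited range.
MIN_BRACKET_COUNT = 20


@dataclass(frozen=True)
class MeasurementPair:
    """One carcass: laboratory reference IMF% and device-predicted IMF%."""

    lab_imf: float
    device_imf: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lab_imf) and np.isfinite(self.device_imf)):
            raise ValueError(
                f"measurement pair must be finite, got "
                f"(lab={self.lab_imf}, device={self.device_imf})"
            )

    @property
    def residual(self) -> float:
        """Laboratory minus device IMF% for this carcass."""
        return self.lab_imf - self.device_imf

    def in_plausible_range(self, lower: float = DEFAULT_PLAUSIBLE_RANGE[0],
                           upper: float = DEFAULT_PLAUSIBLE_RANGE[1]) -> bool:
        return (lower <= self.lab_imf <= upper) and (lower <= self.device_imf <= upper)


class AccreditationDataset:
    """Ordered collection of paired lab/device IMF% measurements.

    Residuals ``y_i = lab_i - device_i`` are recomputed from the stored
    arrays on every access, so they can never drift from the pairs.

    Parameters
    ----------
    lab : array-like of float
        Laboratory (Soxhlet) IMF% values.
    device : array-like of float
        Device-predicted IMF% values, same length and order.
    """

    def __init__(self, lab: Sequence[float], device: Sequence[float]):
        lab_arr = np.asarray(lab, dtype=float)
        device_arr = np.asarray(device, dtype=float)
        if lab_arr.ndim != 1 or device_arr.ndim != 1:
            raise ValueError("lab and device must be one-dimensional")
        if lab_arr.shape != device_arr.shape:
            raise ValueError(
                f"lab and device lengths differ: {lab_arr.size} vs {device_arr.size}"
            )
        bad = ~(np.isfinite(lab_arr) & np.isfinite(device_arr))
        if bad.any():
            rows = np.flatnonzero(bad)[:10]
            raise ValueError(f"non-finite measurement(s) at row(s) {rows.tolist()}")
        self._lab = lab_arr
        self._device = device_arr

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self._lab.size

    def __getitem__(self, i: int) -> MeasurementPair:
        return MeasurementPair(float(self._lab[i]), float(self._device[i]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AccreditationDataset):
            return NotImplemented
        return np.array_equal(self._lab, other._lab) and np.array_equal(
            self._device, other._device
        )

    @property
    def lab(self) -> np.ndarray:
        return self._lab.copy()

    @property
    def device(self) -> np.ndarray:
        return self._device.copy()

    @property
    def residuals(self) -> np.ndarray:
        """``lab - device``, recomputed on access (never cached)."""
        return self._lab - self._device

    @property
    def pairs(self) -> list[MeasurementPair]:
        return [self[i] for i in range(len(self))]

    def prefix(self, n: int) -> "AccreditationDataset":
        """First ``n`` records in generation/storage order."""
        if n > len(self):
            raise ValueError(f"prefix length {n} exceeds dataset size {len(self)}")
        if n < 0:
            raise ValueError("prefix length must be non-negative")
        return AccreditationDataset(self._lab[:n], self._device[:n])

    def out_of_range_mask(self, lower: float, upper: float,
                          basis: str = "device") -> np.ndarray:
        """Boolean mask of observations outside ``[lower, upper]``.

        Flagged observations are excluded from assessment and reported,
        never silently dropped.
        """
        values = self._basis_values(basis)
        return (values < lower) | (values > upper)

    def _basis_values(self, basis: str) -> np.ndarray:
        if basis == "device":
            return self._device
        if basis == "lab":
            return self._lab
        raise ValueError(f"basis must be 'device' or 'lab', got {basis!r}")

    def implausible_mask(self, lower: float = DEFAULT_PLAUSIBLE_RANGE[0],
                         upper: float = DEFAULT_PLAUSIBLE_RANGE[1]) -> np.ndarray:
        """Flag rows where either value leaves the plausible IMF% window."""
        return ~(
            (self._lab >= lower) & (self._lab <= upper)
            & (self._device >= lower) & (self._device <= upper)
        )

    def to_frame(self, lab_column: str = "lab", device_column: str = "device") -> pd.DataFrame:
        return pd.DataFrame({lab_column: self._lab, device_column: self._device})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AccreditationDataset(n={len(self)})"


def compute_residuals(dataset: AccreditationDataset) -> np.ndarray:
    """Residual vector ``y_i = lab_i - device_i`` (IMF%), order preserved.

    Raises
    ------
    ValueError
        If the dataset is empty.
    """
    if len(dataset) == 0:
        raise ValueError("cannot compute residuals of an empty dataset")
    return dataset.residuals


@dataclass(frozen=True)
class QuarterPartition:
    """Four equal-width quarters of the accredited IMF% range.

    Quarters are half-open ``[a, b)`` with the top quarter closed
    ``[a, b]``, so every value in ``[lower, upper]`` belongs to exactly one
    quarter.  ``assignment_basis`` records whether device or laboratory
    values drive the allocation.
    """

    lower: float
    upper: float
    assignment_basis: str = "device"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("partition bounds must be finite")
        if self.upper <= self.lower:
            raise ValueError(
                f"degenerate range: upper ({self.upper}) must exceed lower ({self.lower})"
            )
        if self.assignment_basis not in ("device", "lab"):
            raise ValueError("assignment_basis must be 'device' or 'lab'")

    @property
    def boundaries(self) -> np.ndarray:
        """Five ascending, equally spaced cut points."""
        return np.linspace(self.lower, self.upper, 5)

    @property
    def width(self) -> float:
        return (self.upper - self.lower) / 4.0

    def quarter_range(self, q: int) -> tuple[float, float]:
        b = self.boundaries
        return float(b[q]), float(b[q + 1])

    def assign(self, values: Sequence[float]) -> np.ndarray:
        """Quarter index (0..3) per value; -1 marks out-of-range values."""
        v = np.asarray(values, dtype=float)
        idx = np.floor((v - self.lower) / self.width).astype(int)
        idx = np.clip(idx, 0, 3)  # upper boundary belongs to the top quarter
        out = (v < self.lower) | (v > self.upper)
        idx[out] = -1
        return idx

    def counts(self, values: Sequence[float]) -> np.ndarray:
        """Observation count per quarter (out-of-range values ignored)."""
        labels = self.assign(values)
        return np.bincount(labels[labels >= 0], minlength=4)


def partition_quarters(values: Sequence[float], lower: float | None = None,
                       upper: float | None = None,
                       assignment_basis: str = "device") -> tuple[QuarterPartition, np.ndarray]:
    """Build a quarter partition over ``values`` and assign each of them.

    ``lower``/``upper`` default to the observed extremes, matching the way
    uploaded data are allocated to quarter ranges.

    Returns
    -------
    (QuarterPartition, ndarray)
        The partition and the per-observation quarter labels (0..3).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot partition an empty value vector")
    lo = float(np.min(v)) if lower is None else float(lower)
    hi = float(np.max(v)) if upper is None else float(upper)
    part = QuarterPartition(lo, hi, assignment_basis)
    return part, part.assign(v)


@dataclass
class UnitBracketCensus:
    """Counts of observations per 1-IMF% increment of the accredited range.

    Accreditation requires at least :data:`MIN_BRACKET_COUNT` carcasses in
    every increment.  Brackets are anchored at ``lower`` (``[lower,
    lower+1), [lower+1, lower+2), ...``); the top bracket may be narrower
    than one unit and is closed at ``upper``.
    """

    edges: np.ndarray
    counts: np.ndarray
    min_count: int = MIN_BRACKET_COUNT
    flags: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.flags = self.counts < self.min_count

    @property
    def n_brackets(self) -> int:
        return self.counts.size

    @property
    def all_pass(self) -> bool:
        return not bool(self.flags.any())

    def bracket_range(self, i: int) -> tuple[float, float]:
        return float(self.edges[i]), float(self.edges[i + 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bracket_lower": self.edges[:-1],
                "bracket_upper": self.edges[1:],
                "count": self.counts,
                "sufficient": ~self.flags,
            }
        )


def unit_bracket_census(values: Sequence[float], lower: float, upper: float,
                        min_count: int = MIN_BRACKET_COUNT) -> UnitBracketCensus:
    """Count observations in each 1-IMF% bracket of ``[lower, upper]``.

    Brackets with fewer than ``min_count`` observations are flagged; counts
    over the brackets sum to the number of in-range observations.
    """
    if upper <= lower:
        raise ValueError("upper must exceed lower")
    v = np.asarray(values, dtype=float)
    inner = np.arange(lower, upper, 1.0)
    edges = np.append(inner, upper)
    if edges.size < 2:  # range narrower than one unit
        edges = np.array([lower, upper])
    in_range = v[(v >= lower) & (v <= upper)]
    counts, _ = np.histogram(in_range, bins=edges)
    return UnitBracketCensus(edges=edges, counts=counts, min_count=min_count)
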