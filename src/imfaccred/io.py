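"""CSV input/output and run configuration.

The upload format is a headed, comma-separated, UTF-8 file with one column
of laboratory IMF% estimates and one of device estimates per carcass.
Malformed rows are reported with their line numbers; nothing is silently
dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AccreditationDataset

__all__ = ["read_dataset", "write_dataset", "RunConfig", "config_hash"]

DEFAULT_LAB_COLUMN = "lab"
DEFAULT_DEVICE_COLUMN = "device"


def read_dataset(path, lab_column: str = DEFAULT_LAB_COLUMN,
                 device_column: str = DEFAULT_DEVICE_COLUMN) -> AccreditationDataset:
    """Read paired lab/device IMF% values from a CSV file.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        Distinct messages for an empty file, a missing column, or
        non-numeric/blank cells (with 1-based data row numbers).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"input file is empty: {path}") from None
    if frame.empty:
        raise ValueError(f"input file has a header but no data rows: {path}")
    for col in (lab_column, device_column):
        if col not in frame.columns:
            raise ValueError(
                f"column {col!r} not found in {path}; available columns: "
                f"{list(frame.columns)}"
            )
    lab = pd.to_numeric(frame[lab_column], errors="coerce")
    device = pd.to_numeric(frame[device_column], errors="coerce")
    bad = ~(np.isfinite(lab.to_numpy()) & np.isfinite(device.to_numpy()))
    if bad.any():
        rows = (np.flatnonzero(bad) + 1).tolist()  # 1-based data rows
        shown = ", ".join(map(str, rows[:20])) + (" ..." if len(rows) > 20 else "")
        raise ValueError(
            f"non-numeric or blank IMF% value(s) in {path} at data row(s): {shown}"
        )
    return AccreditationDataset(lab=lab.to_numpy(), device=device.to_numpy())


def write_dataset(dataset: AccreditationDataset, path,
                  lab_column: str = DEFAULT_LAB_COLUMN,
                  device_column: str = DEFAULT_DEVICE_COLUMN) -> None:
    """Write a dataset as the two-column CSV the assessment consumes.

    Values round-trip at full float precision.
    """
    frame = dataset.to_frame(lab_column, device_column)
    frame.to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Validated configuration for an assessment run.

    The hyperparameter limits mirror the interactive App: ``g`` within
    [0.25, 5.00], ``alpha = delta`` within [0.05 N, N] for total sample
    size N, and at least 1,000 predictive draws.  (The research-grade
    experiment harness is not bound by these interactive limits.)
    """

    g: float = 1.0
    alpha: float | None = None     # None -> 0.25 * N
    draws: int = 50_000
    seed: int | None = None
    lower: float | None = None
    upper: float | None = None
    basis: str = "device"
    lab_column: str = DEFAULT_LAB_COLUMN
    device_column: str = DEFAULT_DEVICE_COLUMN
    convention: str = "table1"

    def validate(self, n_total: int) -> None:
        if not (0.25 <= self.g <= 5.0):
            raise ValueError(f"g must lie in [0.25, 5.00], got {self.g}")
        if self.alpha is not None and not (0.05 * n_total <= self.alpha <= n_total):
            raise ValueError(
                f"alpha = delta must lie in [0.05 N, N] = "
                f"[{0.05 * n_total:g}, {n_total}], got {self.alpha}"
            )
        if self.draws < 1000:
            raise ValueError(f"draws must be >= 1000, got {self.draws}")
        if self.basis not in ("device", "lab"):
            raise ValueError("basis must be 'device' or 'lab'")

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: dict) -> str:
    """Stable short hash embedded in every output for reproducibility."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
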