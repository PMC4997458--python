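"""Space-time observation panels: unit x year matrices with centered time codes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpaceTimePanel:
    """Annual observations for a set of geographic units.

    Parameters
    ----------
    values
        ``(n_units, n_years)`` array of concentrations (μg/m³). No missing
        entries are allowed at fit time; impute upstream.
    years
        Strictly increasing integer year labels, one per column.
    unit_ids
        Integer labels, one per row; defaults to ``1..n``.
    """

    values: np.ndarray
    years: np.ndarray
    unit_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("panel values must be 2-D (units x years)")
        if self.years.shape != (self.values.shape[1],):
            raise ValueError("years length must match number of columns")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.unit_ids is None:
            self.unit_ids = np.arange(1, self.values.shape[0] + 1)
        else:
            self.unit_ids = np.asarray(self.unit_ids, dtype=int)
            if self.unit_ids.shape != (self.values.shape[0],):
                raise ValueError("unit_ids length must match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel contains non-finite values; impute first")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]

    @property
    def tstar(self) -> np.ndarray:
        """Centered time codes t* = year - mean(year); mean exactly 0."""
        t = self.years.astype(float)
        return t - t.mean()

    def to_csv(self, path) -> None:
        """Write tidy CSV with columns unit_id, year, value."""
        n, T = self.values.shape
        df = pd.DataFrame(
            {
                "unit_id": np.repeat(self.unit_ids, T),
                "year": np.tile(self.years, n),
                "value": self.values.ravel(),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpaceTimePanel":
        df = pd.read_csv(path)
        required = {"unit_id", "year", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"panel CSV must have columns {sorted(required)}")
        wide = df.pivot(index="unit_id", columns="year", values="value")
        wide = wide.sort_index()
        if wide.isna().any().any():
            raise ValueError("panel CSV has missing unit/year combinations")
        return cls(
            values=wide.to_numpy(),
            years=wide.columns.to_numpy(dtype=int),
            unit_ids=wide.index.to_numpy(dtype=int),
        )
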