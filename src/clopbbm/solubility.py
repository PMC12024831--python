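"""pH-dependent solubility lookup and dose-number classification.

Clopidogrel hydrogen sulfate is a weak base (pKa 4.55) whose aqueous
solubility falls by more than four orders of magnitude between gastric and
intestinal pH.  The simulator consumes solubility as tabulated (pH, S)
points with interpolation; because S spans >4 decades, the default
interpolation is linear in log10(S) versus pH (a plain linear rule would be
dominated by the acidic value).  Outside the tabulated range the nearest
endpoint is used.

The dose number D0 = D / (V0 * C0) (dose over the amount dissolvable in a
250 mL reference volume) classifies solubility: D0 <= 1 highly soluble,
D0 > 1 poorly soluble.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SolubilityTable",
    "SolubilityClass",
    "interpolate_solubility",
    "dose_number",
    "solubility_class",
    "REFERENCE_VOLUME_ML",
]

#: Biowaiver reference volume of fluid (mL) used in the dose number.
REFERENCE_VOLUME_ML = 250.0


class SolubilityClass(str, Enum):
    highly_soluble = "highly_soluble"
    poorly_soluble = "poorly_soluble"


@dataclass(frozen=True)
class SolubilityTable:
    """Tabulated solubility: strictly increasing pH, S in mg/mL (> 0)."""

    points: tuple[tuple[float, float], ...]
    interpolation: str = "log-linear"  # or "linear"

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("solubility table needs at least 2 points")
        ph = np.array([p for p, _ in self.points], dtype=float)
        s = np.array([s for _, s in self.points], dtype=float)
        if np.any(np.diff(ph) <= 0):
            raise ValueError("pH values must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("solubility values must be > 0")
        if self.interpolation not in ("log-linear", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[Sequence[float]], interpolation: str = "log-linear"
    ) -> "SolubilityTable":
        return cls(tuple((float(p), float(s)) for p, s in pairs), interpolation)

    @property
    def ph(self) -> np.ndarray:
        return np.array([p for p, _ in self.points], dtype=float)

    @property
    def s(self) -> np.ndarray:
        return np.array([s for _, s in self.points], dtype=float)


def interpolate_solubility(table: SolubilityTable, pH) -> np.ndarray | float:
    """Solubility (mg/mL) at the given pH value(s).

    Tabulated pH values return the tabulated S exactly; between points the
    table's interpolation rule applies; outside the range the nearest
    endpoint value is returned (clamped).
    """
    ph_arr = np.asarray(pH, dtype=float)
    scalar = ph_arr.ndim == 0
    ph_arr = np.atleast_1d(ph_arr)
    if table.interpolation == "log-linear":
        out = 10.0 ** np.interp(ph_arr, table.ph, np.log10(table.s))
    else:
        out = np.interp(ph_arr, table.ph, table.s)
    # exact at the knots and under clamping (no log10/10** round-trip noise)
    out[ph_arr <= table.ph[0]] = table.s[0]
    out[ph_arr >= table.ph[-1]] = table.s[-1]
    for i, p in enumerate(table.ph):
        out[ph_arr == p] = table.s[i]
    return float(out[0]) if scalar else out


def dose_number(D: float, V0: float = REFERENCE_VOLUME_ML, C0: float | None = None) -> float:
    """Dose number D0 = D / (V0 * C0).

    D in mg, V0 in mL (default 250), C0 in mg/mL.  All inputs must be > 0.
    """
    if C0 is None:
        raise TypeError("C0 (solubility, mg/mL) is required")
    if D <= 0 or V0 <= 0 or C0 <= 0:
        raise ValueError("dose_number requires D, V0, C0 > 0")
    return D / (V0 * C0)


def solubility_class(D0: float) -> SolubilityClass:
    """D0 <= 1 -> highly soluble; D0 > 1 -> poorly soluble.

    The boundary D0 == 1 is assigned to highly_soluble (the classification
    is defined by strict inequalities either side; the boundary convention
    is documented here and covered by a test).
    """
    if D0 < 0:
        raise ValueError("dose number cannot be negative")
    return SolubilityClass.highly_soluble if D0 <= 1.0 else SolubilityClass.poorly_soluble
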