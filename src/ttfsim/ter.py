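"""Therapeutic enhancement ratio (TER) dose-response model.

TER quantifies the effect of an alternating electric field on tumor growth:
TER > 0 means reduced growth, TER = 1 complete growth arrest, TER > 1
shrinkage. The model is a cubic fitted to in vitro glioma dose-response
measurements, valid on the measured field range [1.10, 2.40] V/cm and
capped outside it:

    TER(E) = 0.4057 E^3 - 1.713 E^2 + 2.941 E - 1.542   (E in V/cm)

with TER = 0 below 1.10 V/cm and TER = TER(2.40) above 2.40 V/cm. The
function is therefore discontinuous at the lower bound (the cubic is about
0.16 there); the boundary convention is closed on the right: TER(1.10)
takes the cubic's value. The cubic is strictly increasing on the capped
interval, so the inverse (field for a given TER) is unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from .solver import FieldSolution

#: Cubic coefficients, highest degree first.
DEFAULT_COEFFS = (0.4057, -1.713, 2.941, -1.542)
DEFAULT_E_LOW = 1.10
DEFAULT_E_HIGH = 2.40

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class TERPolynomial:
    """Capped cubic TER(E), E in V/cm."""

    coeffs: Tuple[float, float, float, float] = DEFAULT_COEFFS
    e_low: float = DEFAULT_E_LOW
    e_high: float = DEFAULT_E_HIGH

    def __post_init__(self) -> None:
        if not 0 <= self.e_low < self.e_high:
            raise ValueError("require 0 <= e_low < e_high")
        # strict monotonicity on [e_low, e_high]
        a3, a2, a1, _ = self.coeffs
        grid = np.linspace(self.e_low, self.e_high, 257)
        deriv = 3 * a3 * grid**2 + 2 * a2 * grid + a1
        if not (deriv > 0).all():
            raise ValueError("cubic must be strictly increasing on [e_low, e_high]")

    @property
    def cap(self) -> float:
        """TER value at and above the upper field bound."""
        return float(np.polyval(self.coeffs, self.e_high))

    def __call__(self, e_field: ArrayLike) -> ArrayLike:
        return self.ter_of_field(e_field)

    def ter_of_field(self, e_field: ArrayLike) -> ArrayLike:
        """Evaluate TER at field strength E (V/cm); E must be >= 0."""
        e = np.asarray(e_field, dtype=float)
        if (e < 0).any():
            raise ValueError("field strength must be non-negative")
        e_eval = np.clip(e, None, self.e_high)
        val = np.polyval(self.coeffs, e_eval)
        out = np.where(e < self.e_low, 0.0, val)
        return float(out) if np.isscalar(e_field) else out

    def field_for_ter(self, ter: float) -> float:
        """Field strength E (V/cm) with TER(E) = ter, on the cubic's domain.

        Defined for 0 < ter < cap; unique by monotonicity. Found by
        bracketed root finding to 1e-10.
        """
        if not 0.0 < ter < self.cap:
            raise ValueError(
                f"TER must be in (0, {self.cap:.6g}) to invert, got {ter}"
            )
        lo_val = float(np.polyval(self.coeffs, self.e_low))
        if ter <= lo_val:
            # the jump at e_low: fields just at the lower bound already give
            # the cubic's value there, so the threshold field is e_low
            return self.e_low
        return float(
            brentq(
                lambda e: np.polyval(self.coeffs, e) - ter,
                self.e_low,
                self.e_high,
                xtol=1e-10,
                rtol=8.9e-16,
            )
        )

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = json.dumps(
            {"coeffs": list(self.coeffs), "e_low": self.e_low, "e_high": self.e_high},
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: Union[str, Path]) -> "TERPolynomial":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(tuple(d["coeffs"]), d["e_low"], d["e_high"])


@dataclass
class TERMap:
    """Per-element TER values for one field solution."""

    values: np.ndarray
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.values)


def ter_of_field(e_field: ArrayLike, poly: TERPolynomial | None = None) -> ArrayLike:
    return (poly or TERPolynomial()).ter_of_field(e_field)


def field_for_ter(ter: float, poly: TERPolynomial | None = None) -> float:
    return (poly or TERPolynomial()).field_for_ter(ter)


def map_field_to_ter(
    field: FieldSolution, poly: TERPolynomial | None = None
) -> TERMap:
    """Elementwise TER for a field solution's magnitudes."""
    poly = poly or TERPolynomial()
    return TERMap(values=poly.ter_of_field(field.magnitude), source_name=field.name)


def refit_polynomial(
    points: Sequence[Tuple[float, float]], degree: int = 3
) -> TERPolynomial:
    """Least-squares cubic refit to user-supplied (E, TER) data.

    The caps are set from the data's field range. Intended for alternative
    in vitro datasets; the default coefficients are authoritative otherwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (E, TER) pairs")
    if len(pts) < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for a degree-{degree} fit")
    e, t = pts[:, 0], pts[:, 1]
    if np.unique(e).size < degree + 1:
        raise ValueError("rank-deficient fit: too few distinct field values")
    coeffs = np.polyfit(e, t, degree)
    return TERPolynomial(tuple(coeffs), float(e.min()), float(e.max()))
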