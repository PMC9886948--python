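"""Tissue labels and conductivities for the synthetic head models.

Conductivities are effective values at TTF carrier frequencies (~200 kHz),
isotropic by default, in S/m. The resection cavity is CSF-filled and takes
the CSF value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

#: Integer codes used as cell data in mesh files.
TISSUE_IDS: Dict[str, int] = {
    "skin": 1,
    "skull_compact": 2,
    "skull_spongy": 3,
    "csf": 4,
    "gm": 5,
    "wm": 6,
    "eye": 7,
    "muscle": 8,
    "tumor_shell": 9,
    "tumor_core": 10,
    "resection": 11,
}

ID_TO_TISSUE: Dict[int, str] = {v: k for k, v in TISSUE_IDS.items()}

#: Labels that make up brain tissue proper; tumors may only displace these.
BRAIN_LABELS = ("gm", "wm")

#: Labels retained when a head model is reduced to its intracranial part.
INTRACRANIAL_LABELS = ("csf", "gm", "wm", "tumor_shell", "tumor_core", "resection")

TUMOR_LABELS = ("tumor_shell", "tumor_core")

_DEFAULTS: Dict[str, float] = {
    "skin": 0.465,
    "skull_compact": 0.007,
    "skull_spongy": 0.025,
    "csf": 1.65,
    "gm": 0.276,
    "wm": 0.126,
    "eye": 1.5,
    "muscle": 0.4,
    "tumor_shell": 0.24,
    "tumor_core": 1.0,
    "resection": 1.65,  # CSF-filled cavity
}


@dataclass(frozen=True)
class TissueConductivityTable:
    """Map from tissue label to isotropic conductivity in S/m.

    All values must be strictly positive. ``default()`` returns the
    literature table used throughout; ``overridden`` builds a copy with
    selected labels replaced.
    """

    values: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULTS))

    def __post_init__(self) -> None:
        for label, sigma in self.values.items():
            if label not in TISSUE_IDS:
                raise ValueError(f"unknown tissue label {label!r}")
            if not sigma > 0:
                raise ValueError(
                    f"conductivity for {label!r} must be strictly positive, got {sigma}"
                )

    @classmethod
    def default(cls) -> "TissueConductivityTable":
        return cls(dict(_DEFAULTS))

    def overridden(self, **overrides: float) -> "TissueConductivityTable":
        merged = dict(self.values)
        merged.update(overrides)
        return TissueConductivityTable(merged)

    def __getitem__(self, label: str) -> float:
        try:
            return self.values[label]
        except KeyError:
            raise KeyError(f"no conductivity for tissue label {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.values

    def require(self, labels: Iterable[str]) -> None:
        """Raise if any of *labels* is missing from the table."""
        for label in labels:
            if label not in self.values:
                raise KeyError(f"no conductivity for tissue label {label!r}")
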