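"""Closed-form potentials for point-current electrodes on concentric spheres.

Independent verification oracle for the FEM: the potential of a point
current source on the outer surface of a concentric multilayer sphere is a
Legendre series in (r, gamma), with per-degree radial coefficients obtained
from the interface continuity conditions (potential and normal current
density) and the Neumann boundary condition at the outer surface. For a
bipolar source/sink pair the two series are superposed; the monopole term
cancels.

For a homogeneous sphere the series sums to the classical closed form,
which is exposed separately as a cross-check.

Lengths in mm at the interface, converted to meters internally;
conductivities in S/m; currents in A; potentials in V; fields in V/cm.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence, Tuple

import numpy as np
from scipy.special import eval_legendre

MM_TO_M = 1e-3
V_PER_M_TO_V_PER_CM = 1e-2

DEFAULT_SERIES_ORDER = 200


class SeriesConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SphereModel:
    """Concentric-sphere conductor: radii (mm, strictly decreasing outer ->
    inner) and per-layer isotropic conductivities (S/m)."""

    radii: Tuple[float, ...]
    conductivities: Tuple[float, ...]
    series_order: int = DEFAULT_SERIES_ORDER

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.conductivities):
            raise ValueError("one conductivity per layer required")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if any(b >= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly decreasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.series_order < 50:
            raise ValueError("series order must be at least 50")

    @property
    def outer_radius(self) -> float:
        return self.radii[0]

    @classmethod
    def homogeneous(
        cls, radius: float, sigma: float, series_order: int = DEFAULT_SERIES_ORDER
    ) -> "SphereModel":
        return cls((radius,), (sigma,), series_order)


@lru_cache(maxsize=16)
def _radial_coefficients(model: SphereModel, n_max: int) -> np.ndarray:
    """Per-degree layer coefficients for a unit point source at the surface.

    Layers are indexed inner -> outer (layer 0 contains the center). In
    layer k spanning [r_in, r_out] the radial factor is written in the
    overflow-safe normalized form

        R_k(r) = alpha_k (r / r_out)^n + beta_k (r / r_in)^{-(n+1)},

    with beta_0 = 0 in the innermost layer. Returns coefficients
    (n_max, L, 2) for I = 1 A; multiply the resulting potential by I.
    """
    radii_m = np.asarray(model.radii[::-1], dtype=float) * MM_TO_M  # inner->outer bounds
    sigmas = np.asarray(model.conductivities[::-1], dtype=float)
    L = len(sigmas)
    R = radii_m[-1]
    # layer k in [lower_k, upper_k]; innermost lower bound is 0 (we normalize
    # its inverse term away since beta_0 = 0)
    uppers = radii_m
    lowers = np.concatenate([[np.nan], radii_m[:-1]])

    out = np.zeros((n_max + 1, L, 2))
    for n in range(1, n_max + 1):
        size = 2 * L - 1  # beta_0 eliminated
        A = np.zeros((size, size))
        rhs = np.zeros(size)

        def col_alpha(k: int) -> int:
            return 2 * k - 1 if k > 0 else 0

        def col_beta(k: int) -> int:
            return 2 * k  # valid for k >= 1

        # interface conditions between layer k and k+1 at r = uppers[k]
        row = 0
        for k in range(L - 1):
            a = uppers[k]
            # radial factor and derivative of layer k at its upper bound
            # alpha term: (r/upper_k)^n -> value 1, deriv n/a
            # beta term: (r/lower_k)^{-(n+1)} -> value (a/lower_k)^{-(n+1)},
            #            deriv -(n+1)/a * value
            # layer k+1 at r=a: alpha: (a/upper_{k+1})^n ; beta: (a/lower_{k+1})^{-(n+1)} = 1
            up1 = uppers[k + 1]
            val_a_k = 1.0
            der_a_k = n / a
            A[row, col_alpha(k)] += val_a_k
            A[row + 1, col_alpha(k)] += sigmas[k] * der_a_k
            if k >= 1:
                vb = (a / lowers[k]) ** (-(n + 1))
                A[row, col_beta(k)] += vb
                A[row + 1, col_beta(k)] += sigmas[k] * (-(n + 1) / a) * vb
            va1 = (a / up1) ** n
            A[row, col_alpha(k + 1)] -= va1
            A[row + 1, col_alpha(k + 1)] -= sigmas[k + 1] * (n / a) * va1
            vb1 = 1.0  # (a / lowers[k+1])^{-(n+1)} with lowers[k+1] = a
            A[row, col_beta(k + 1)] -= vb1
            A[row + 1, col_beta(k + 1)] -= sigmas[k + 1] * (-(n + 1) / a) * vb1
            row += 2

        # outer Neumann condition at r = R (layer L-1):
        # sigma dV/dr = (2n+1) / (4 pi R^2)   for I = 1 A
        A[row, col_alpha(L - 1)] += sigmas[L - 1] * n / R
        if L - 1 >= 1:
            vb = (R / lowers[L - 1]) ** (-(n + 1))
            A[row, col_beta(L - 1)] += sigmas[L - 1] * (-(n + 1) / R) * vb
        else:
            pass
        rhs[row] = (2 * n + 1) / (4.0 * np.pi * R**2)

        sol = np.linalg.solve(A, rhs)
        out[n, 0, 0] = sol[0]
        for k in range(1, L):
            out[n, k, 0] = sol[col_alpha(k)]
            out[n, k, 1] = sol[col_beta(k)]
    return out


def _layer_index(model: SphereModel, r_m: float) -> int:
    """Index (inner -> outer) of the layer containing radius r (meters)."""
    radii_m = np.asarray(model.radii[::-1], dtype=float) * MM_TO_M
    for k, upper in enumerate(radii_m):
        if r_m <= upper + 1e-15:
            return k
    return len(radii_m) - 1


def _series_terms(
    model: SphereModel, probe: np.ndarray, source: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """Radial factors, derivatives and Legendre inputs for one point source."""
    coeffs = _radial_coefficients(model, model.series_order)
    r = float(np.linalg.norm(probe)) * MM_TO_M
    radii_m = np.asarray(model.radii[::-1], dtype=float) * MM_TO_M
    k = _layer_index(model, r)
    upper = radii_m[k]
    lower = radii_m[k - 1] if k >= 1 else np.nan

    n = np.arange(model.series_order + 1)
    alpha = coeffs[:, k, 0]
    beta = coeffs[:, k, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_a = np.where(n >= 1, (r / upper) ** n, 0.0)
        radial = alpha * t_a
        dradial = alpha * np.where(r > 0, n * t_a / max(r, 1e-300), 0.0)
        if k >= 1 and r > 0:
            t_b = (r / lower) ** (-(n + 1.0))
            radial = radial + beta * t_b
            dradial = dradial + beta * (-(n + 1.0)) * t_b / r
    cosg_den = np.linalg.norm(probe) * np.linalg.norm(source)
    cosg = float(np.dot(probe, source) / cosg_den) if cosg_den > 0 else 1.0
    cosg = float(np.clip(cosg, -1.0, 1.0))
    pn = eval_legendre(n, cosg)
    return radial, dradial, pn, cosg, n.astype(float), np.asarray([r])


def _check_tail(terms: np.ndarray, total: float) -> None:
    tail = np.abs(terms[-10:]).sum()
    if tail > 1e-3 * max(abs(total), 1e-12):
        raise SeriesConvergenceError(
            "Legendre series not converged at this probe; increase the series "
            "order or move the probe away from the electrodes"
        )


def _potential_single(model: SphereModel, probe: np.ndarray, source: np.ndarray) -> float:
    radial, _, pn, _, _, _ = _series_terms(model, probe, source)
    terms = radial * pn
    total = float(terms[1:].sum())
    _check_tail(terms, total)
    return total


def analytic_potential(
    model: SphereModel,
    source: Sequence[float],
    sink: Sequence[float],
    current: float,
    probe: Sequence[float],
) -> float:
    """Series potential (V) at an interior probe for a surface source/sink
    pair carrying current I (A). Positions in mm."""
    probe = np.asarray(probe, dtype=float)
    source = np.asarray(source, dtype=float)
    sink = np.asarray(sink, dtype=float)
    if np.allclose(source, sink):
        raise ValueError("source and sink must differ")
    if np.linalg.norm(probe) >= model.outer_radius:
        raise ValueError("probe must be strictly inside the outer radius")
    if current == 0.0:
        return 0.0
    v = _potential_single(model, probe, source) - _potential_single(
        model, probe, sink
    )
    return current * v


def _field_single(model: SphereModel, probe: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Gradient of the single-source series, term by term. Returns -grad V
    in V/m for I = 1 A."""
    radial, dradial, pn, cosg, n, r_arr = _series_terms(model, probe, source)
    r = float(r_arr[0])
    rhat = probe / np.linalg.norm(probe)
    shat = source / np.linalg.norm(source)
    sing = float(np.sqrt(max(0.0, 1.0 - cosg**2)))

    # dPn/dgamma = -sin(gamma) Pn'(cos gamma); use the stable recurrence
    # (1 - x^2) Pn'(x) = n (P_{n-1}(x) - x Pn(x))
    x = cosg
    pn_prev = np.concatenate([[0.0], pn[:-1]])
    if 1.0 - x**2 > 1e-14:
        pn_deriv = n * (pn_prev - x * pn) / (1.0 - x**2)
    else:
        pn_deriv = np.zeros_like(pn)

    dv_dr = float((dradial * pn)[1:].sum())
    dv_dgam = float((radial * (-sing) * pn_deriv)[1:].sum())
    _check_tail(dradial * pn, dv_dr)

    if sing > 1e-12:
        ghat = (x * rhat - shat) / sing
    else:
        ghat = np.zeros(3)
    grad = dv_dr * rhat + (dv_dgam / max(r, 1e-300)) * ghat
    return -grad


def analytic_field(
    model: SphereModel,
    source: Sequence[float],
    sink: Sequence[float],
    current: float,
    probe: Sequence[float],
) -> np.ndarray:
    """Series electric field vector (V/cm) at an interior probe. Antisymmetric
    under source/sink exchange; linear in I."""
    probe = np.asarray(probe, dtype=float)
    source = np.asarray(source, dtype=float)
    sink = np.asarray(sink, dtype=float)
    if np.allclose(source, sink):
        raise ValueError("source and sink must differ")
    if np.linalg.norm(probe) >= model.outer_radius:
        raise ValueError("probe must be strictly inside the outer radius")
    if current == 0.0:
        return np.zeros(3)
    e = _field_single(model, probe, source) - _field_single(model, probe, sink)
    return current * e * V_PER_M_TO_V_PER_CM


def homogeneous_potential_closed_form(
    radius: float,
    sigma: float,
    source: Sequence[float],
    sink: Sequence[float],
    current: float,
    probe: Sequence[float],
) -> float:
    """Classical closed form for a homogeneous sphere (cross-check for the
    series): for a unit point source on the surface,

        V = I / (4 pi sigma R) * [ 2/sqrt(1 - 2 t x + t^2) - 2
            + ln( 2 / (1 - t x + sqrt(1 - 2 t x + t^2)) ) ],

    with t = r/R and x = cos(gamma); the bipolar potential is the source
    minus sink superposition. Positions in mm, output in V.
    """
    R = radius * MM_TO_M
    probe = np.asarray(probe, dtype=float) * MM_TO_M
    r = np.linalg.norm(probe)
    t = r / R

    def _single(pos_mm: Sequence[float]) -> float:
        pos = np.asarray(pos_mm, dtype=float) * MM_TO_M
        den = r * np.linalg.norm(pos)
        x = float(np.dot(probe, pos) / den) if den > 0 else 1.0
        x = float(np.clip(x, -1, 1))
        w = np.sqrt(max(1e-300, 1.0 - 2.0 * t * x + t * t))
        return (2.0 / w - 2.0) + np.log(2.0 / (1.0 - t * x + w))

    return current / (4.0 * np.pi * sigma * R) * (_single(source) - _single(sink))
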