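"""Steady-state membrane Gβγ profiles around receptors and hotspots.

Free Gβγ released at the membrane diffuses laterally (D ~ 0.2 µm² s⁻¹)
and is removed by first-order re-sequestration (k ~ 1 s⁻¹), so its
steady-state surface density obeys

    D ∇²C(r) + s(r) − k C(r) = 0

in the membrane plane, decaying over the characteristic length
λ = sqrt(D/k). Three solution routes are provided:

* an analytic modified-Bessel kernel for a single receptor represented
  as a flux through a small circle of radius r0 (C = A·K0(r/λ));
* an analytic infinite-domain solution for a uniform disk source, used
  as an independent oracle;
* an axisymmetric second-order finite-difference solver for the disk
  ("hotspot") problem with a zero-concentration far boundary, the
  configuration used for quantitative predictions.

Units: r in µm, C in molecules µm⁻², s in molecules µm⁻² s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.special import i0, i1, k0, k1

from .units import GeometryParams, InvalidParameterError, density_to_concentration


class DomainError(ValueError):
    pass


class ResolutionError(RuntimeError):
    pass


@dataclass
class RadialProfile:
    """Radial steady-state concentration profile C(r)."""

    r: np.ndarray              # µm, strictly increasing
    C: np.ndarray              # molecules µm⁻²
    lam: float                 # characteristic length sqrt(D/k), µm
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self, layer_thickness: float = 80.0) -> pd.DataFrame:
        return pd.DataFrame({
            "r_um": self.r,
            "C_per_um2": self.C,
            "C_uM": [density_to_concentration(max(c, 0.0), layer_thickness) * 1e6
                     for c in self.C],
        })

    def interpolate(self, r: float) -> float:
        return float(np.interp(r, self.r, self.C))


def perimeter_flux(turnover: float, r0: float) -> float:
    """Inward flux per unit perimeter for a point source inside a circle.

    A single receptor generating ``turnover`` Gβγ s⁻¹ inside a circle of
    radius r0 corresponds to turnover / (2π r0) molecules µm⁻¹ s⁻¹
    through its perimeter (15.9 for 1 s⁻¹ through r0 = 0.01 µm).
    """
    if r0 <= 0:
        raise InvalidParameterError(f"r0 must be positive, got {r0}")
    if turnover < 0:
        raise InvalidParameterError(f"turnover must be non-negative, got {turnover}")
    return turnover / (2.0 * math.pi * r0)


def point_source_profile(
    geometry: GeometryParams,
    turnover: float = 1.0,
    r_grid: Sequence[float] | None = None,
) -> RadialProfile:
    """Analytic Gβγ profile around a single receptor.

    Solves D∇²C − kC = 0 outside r0 with the inward-flux boundary
    condition −D C'(r0) = turnover/(2π r0) and C(∞) = 0; the decaying
    solution is C(r) = A·K0(r/λ) with A = flux·λ / (D·K1(r0/λ)).
    """
    lam = geometry.characteristic_length
    r0 = geometry.inner_radius
    if r_grid is None:
        r_grid = np.geomspace(r0, max(10.0 * lam, 20.0 * r0), 400)
    r = np.asarray(r_grid, dtype=float)
    if np.any(r < r0 * (1 - 1e-12)):
        raise DomainError("grid points must satisfy r >= r0")
    flux = perimeter_flux(turnover, r0)
    A = flux * lam / (geometry.D * k1(r0 / lam))
    C = A * k0(r / lam)
    return RadialProfile(
        r=r, C=C, lam=lam,
        metadata={"kind": "point_source", "turnover": turnover, "r0": r0,
                  "flux_per_um": flux, "amplitude": A,
                  "D": geometry.D, "k_decay": geometry.k_decay},
    )


def disk_center_closed_form(s: float, k: float, D: float, R: float) -> float:
    """Center concentration of a uniform disk source on an infinite membrane.

    C(0) = (s/k)·[1 − (R/λ)·K1(R/λ)], λ = sqrt(D/k). Serves as the
    independent oracle for the numerical hotspot solver.
    """
    lam = math.sqrt(D / k)
    x = R / lam
    return (s / k) * (1.0 - x * float(k1(x)))


def disk_profile_closed_form(s: float, k: float, D: float, R: float,
                             r: np.ndarray) -> np.ndarray:
    """Full infinite-domain disk-source solution (inside: I0, outside: K0)."""
    lam = math.sqrt(D / k)
    x = R / lam
    r = np.asarray(r, dtype=float)
    C = np.where(
        r <= R,
        (s / k) * (1.0 - x * k1(x) * i0(r / lam)),
        (s / k) * x * i1(x) * k0(r / lam),
    )
    return C


def _graded_mesh(R: float, outer: float, n: int) -> np.ndarray:
    """Radial mesh refined inside the disk and near its rim."""
    n_in = max(n // 3, 20)
    n_rim = max(n // 6, 10)
    n_out = max(n - n_in - n_rim, 20)
    inner = np.linspace(0.0, 0.9 * R, n_in, endpoint=False)
    rim = np.linspace(0.9 * R, 1.1 * min(R, outer / 2), n_rim, endpoint=False)
    # geometric stretch from the rim out to the far boundary
    start = rim[-1] + (rim[1] - rim[0])
    out = np.geomspace(start, outer, n_out)
    mesh = np.concatenate([inner, rim, out])
    mesh[-1] = outer
    return mesh


def disk_source_profile_numeric(
    geometry: GeometryParams,
    r_grid: Sequence[float] | None = None,
    mesh_size: int = 1200,
    source_radius: float | None = None,
    source_inner_radius: float = 0.0,
    s: float | None = None,
) -> RadialProfile:
    """Numerical steady-state profile for a uniform disk (hotspot) source.

    Solves the axisymmetric two-point boundary-value problem

        D (C'' + C'/r) + s·1[r_in <= r <= R] − k C = 0,
        C'(0) = 0,   C(outer_radius) = 0

    with second-order finite differences on a graded mesh (finer inside
    and near the disk rim) and a banded direct solve. ``source_inner_radius``
    > 0 turns the disk into an annulus (used to cross-check against the
    point-source kernel).

    Returns the profile on the mesh, or interpolated onto ``r_grid``.
    """
    if mesh_size < 200:
        raise ResolutionError(f"mesh_size must be >= 200, got {mesh_size}")
    R = geometry.hotspot_radius if source_radius is None else source_radius
    outer = geometry.far_boundary
    if not R < outer:
        raise DomainError("source radius must be smaller than the outer boundary")
    s_val = geometry.source_strength if s is None else s
    D, k = geometry.D, geometry.k_decay
    lam = geometry.characteristic_length

    rm = _graded_mesh(R, outer, mesh_size)
    n = len(rm)
    h = np.diff(rm)

    # banded system: ab[0]=super, ab[1]=diag, ab[2]=sub
    ab = np.zeros((3, n))
    rhs = np.zeros(n)

    # r = 0: symmetry; C ~ C0 + C''(0) r²/2 so (C'' + C'/r) → 2C'' ≈ 4(C1−C0)/h0²
    src0 = s_val if source_inner_radius <= 0.0 else 0.0
    ab[1, 0] = -4.0 * D / h[0] ** 2 - k
    ab[0, 1] = 4.0 * D / h[0] ** 2
    rhs[0] = -src0

    hm, hp = h[:-1], h[1:]
    ri = rm[1:-1]
    denom = hm * hp * (hm + hp)
    # C'' and C' on a non-uniform three-point stencil
    a_sub = 2.0 * hp / denom - hp ** 2 / denom / ri      # coeff of C_{i-1}
    a_diag = -2.0 * (hm + hp) / denom + (hp ** 2 - hm ** 2) / denom / ri
    a_sup = 2.0 * hm / denom + hm ** 2 / denom / ri      # coeff of C_{i+1}
    ab[2, 0:n - 2] = D * a_sub
    ab[1, 1:n - 1] = D * a_diag - k
    ab[0, 2:n] = D * a_sup
    in_src = (ri >= source_inner_radius) & (ri <= R)
    rhs[1:n - 1] = np.where(in_src, -s_val, 0.0)

    # far boundary: C = 0
    ab[1, n - 1] = 1.0
    rhs[n - 1] = 0.0

    C = solve_banded((1, 1), ab, rhs)
    profile_meta = {
        "kind": "disk_source", "s": s_val, "R": R, "outer_radius": outer,
        "mesh_size": n, "D": D, "k_decay": k,
        "source_inner_radius": source_inner_radius,
    }
    if r_grid is not None:
        r = np.asarray(r_grid, dtype=float)
        if np.any(r < 0) or np.any(r > outer):
            raise DomainError("requested grid extends outside [0, outer_radius]")
        C = np.interp(r, rm, C)
        return RadialProfile(r=r, C=C, lam=lam, metadata=profile_meta)
    return RadialProfile(r=rm, C=C, lam=lam, metadata=profile_meta)


def center_concentration(geometry: GeometryParams, mesh_size: int = 1200) -> float:
    """C(0) for the hotspot disk problem (numerical solve)."""
    prof = disk_source_profile_numeric(geometry, mesh_size=mesh_size)
    return float(prof.C[0])


def center_concentration_vs_radius(
    geometry: GeometryParams,
    radii: Sequence[float],
    mesh_size: int = 1200,
) -> pd.DataFrame:
    """Hotspot-center Gβγ density as a function of hotspot radius.

    Receptor density (hence s) is held fixed, so larger disks hold more
    receptors; C(0) rises monotonically toward the well-mixed limit s/k.
    Returns a DataFrame (R_um, C0_per_um2).
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) < 0):
        raise DomainError("radii must be positive and sorted ascending")
    rows = []
    for R in radii:
        geo = geometry.replace(
            hotspot_radius=R,
            outer_radius=max(10.0 * geometry.characteristic_length, 10.0 * R),
        )
        rows.append((R, center_concentration(geo, mesh_size=mesh_size)))
    return pd.DataFrame(rows, columns=["R_um", "C0_per_um2"])


def receptors_in_disk(density: float, R: float) -> float:
    """Expected receptor count in a disk: π R² × density (≈14 for the
    default 0.3 µm hotspot at 50 µm⁻²)."""
    if density < 0 or R < 0:
        raise InvalidParameterError("density and radius must be non-negative")
    return math.pi * R * R * density


def equivalent_area_radius_factor(area_ratio: float) -> float:
    """Radius scale factor giving a circle of ``area_ratio`` times the area
    (10× the area ↔ 3.16× the radius)."""
    if area_ratio <= 0:
        raise InvalidParameterError(f"area ratio must be positive, got {area_ratio}")
    return math.sqrt(area_ratio)


def ode_residual(profile: RadialProfile, D: float, k: float,
                 s: float = 0.0, source_radius: float = 0.0) -> np.ndarray:
    """Pointwise residual D(C'' + C'/r) + s·1[r<=R] − kC on the interior of
    the profile grid (diagnostic for analytic solutions)."""
    r, C = profile.r, profile.C
    dC = np.gradient(C, r, edge_order=2)
    d2C = np.gradient(dC, r, edge_order=2)
    src = np.where(r <= source_radius, s, 0.0)
    return D * (d2C + dC / r) + src - k * C


def global_balance_error(profile: RadialProfile) -> float:
    """Relative mismatch between total generation and total removal
    (decay integral + outward flux at the far boundary) for a numeric
    disk solution."""
    md = profile.metadata
    r, C = profile.r, profile.C
    R, s, k, D = md["R"], md["s"], md["k_decay"], md["D"]
    r_in = md.get("source_inner_radius", 0.0)
    generation = s * math.pi * (R ** 2 - r_in ** 2)
    decay = float(np.trapezoid(k * C * 2.0 * math.pi * r, r))
    # outward flux at the far boundary
    dC_end = (C[-1] - C[-2]) / (r[-1] - r[-2])
    boundary_flux = -D * dC_end * 2.0 * math.pi * r[-1]
    return abs(generation - (decay + boundary_flux)) / generation
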