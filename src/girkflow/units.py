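"""Parameter registry and unit conversions for membrane signaling models.

The kinetic and spatial models work in two-dimensional membrane units
(molecules µm⁻² for densities, µm² molecule⁻¹ s⁻¹ for bimolecular rate
constants), while the literature reports most rate constants in molar
units. The two systems are interconverted through a thin sub-membrane
layer of configurable thickness (default 80 Å): one molecule µm⁻²
dissolved in that slab corresponds to ≈ 0.2 µM.

All conversions use the exact Avogadro-based layer factor rather than
the rounded 0.2 µM figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

AVOGADRO = 6.02214076e23  # molecules per mole (exact, SI 2019)

#: Default sub-membrane layer thickness, Ångström.
DEFAULT_LAYER_THICKNESS_A = 80.0

# Fields of ParameterSet that are bimolecular (2D units µm² molecule⁻¹ s⁻¹).
BIMOLECULAR_KEYS = ("k12", "k45", "k56")
RATE_KEYS = ("k12", "k21", "k23", "k32", "k34", "k43", "k45", "k54", "k56", "k65")


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its domain constraints."""


def _layer_volume_liters(thickness_angstrom: float) -> float:
    # 1 µm² × thickness: (1e-6 m)² × (thickness × 1e-10 m) = thickness × 1e-22 m³
    return thickness_angstrom * 1e-22 * 1e3  # m³ → L


def molar_per_molecule_per_um2(thickness_angstrom: float = DEFAULT_LAYER_THICKNESS_A) -> float:
    """Molar concentration equivalent of one molecule µm⁻² in the layer.

    For the default 80 Å layer this is 2.0755e-7 M (≈ 0.2 µM).
    """
    if thickness_angstrom <= 0:
        raise InvalidParameterError(f"layer thickness must be positive, got {thickness_angstrom}")
    return 1.0 / (AVOGADRO * _layer_volume_liters(thickness_angstrom))


def density_to_concentration(density: float, thickness_angstrom: float = DEFAULT_LAYER_THICKNESS_A) -> float:
    """Convert a surface density (molecules µm⁻²) to molar concentration.

    Parameters
    ----------
    density : molecules µm⁻², must be >= 0.
    thickness_angstrom : sub-membrane layer thickness in Å, must be > 0.

    Returns
    -------
    Concentration in mol/L. Exactly linear in ``density``.
    """
    if density < 0:
        raise InvalidParameterError(f"density must be non-negative, got {density}")
    return density * molar_per_molecule_per_um2(thickness_angstrom)


def concentration_to_density(concentration: float, thickness_angstrom: float = DEFAULT_LAYER_THICKNESS_A) -> float:
    """Inverse of :func:`density_to_concentration` (molar → molecules µm⁻²)."""
    if concentration < 0:
        raise InvalidParameterError(f"concentration must be non-negative, got {concentration}")
    return concentration / molar_per_molecule_per_um2(thickness_angstrom)


def bimolecular_rate_to_2d(k3d: float, thickness_angstrom: float = DEFAULT_LAYER_THICKNESS_A) -> float:
    """Convert a 3D bimolecular rate constant (M⁻¹ s⁻¹) to 2D units.

    The 2D constant (µm² molecule⁻¹ s⁻¹) is the 3D constant multiplied by
    the molar value of one molecule µm⁻² in the sub-membrane layer, so
    1 µM⁻¹ s⁻¹ ≈ 0.2 µm² molecule⁻¹ s⁻¹ at 80 Å.
    """
    if k3d < 0:
        raise InvalidParameterError(f"rate constant must be non-negative, got {k3d}")
    return k3d * molar_per_molecule_per_um2(thickness_angstrom)


def bimolecular_rate_to_3d(k2d: float, thickness_angstrom: float = DEFAULT_LAYER_THICKNESS_A) -> float:
    """Convert a 2D bimolecular rate constant back to M⁻¹ s⁻¹ (round-trip inverse)."""
    if k2d < 0:
        raise InvalidParameterError(f"rate constant must be non-negative, got {k2d}")
    return k2d / molar_per_molecule_per_um2(thickness_angstrom)


def derive_k54(k45: float, kd: float) -> float:
    """Off-rate of the Gα(GDP)·Gβγ trimer from its on-rate and K_d.

    k_off = k_on × K_d; with k45 = 0.7e6 M⁻¹ s⁻¹ and K_d = 3 nM this gives
    0.0021 s⁻¹ (tabulated as 0.002 to one significant figure).

    ``kd = 0`` is allowed and returns 0 (irreversible binding).
    """
    if k45 <= 0:
        raise InvalidParameterError(f"k45 must be positive, got {k45}")
    if kd < 0:
        raise InvalidParameterError(f"Kd must be non-negative, got {kd}")
    return k45 * kd


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants of the G-protein turnover cycle and GIRK binding.

    All bimolecular constants (k12, k45, k56) are stored in canonical 2D
    units, µm² molecule⁻¹ s⁻¹; unimolecular constants in s⁻¹. ``mu`` is
    the dimensionless cooperativity factor applied per successive Gβγ to
    the GIRK unbinding rate (later sites dissociate more slowly).
    """

    k12: float   # receptor–trimer association, µm² molecule⁻¹ s⁻¹
    k21: float   # receptor–trimer dissociation, s⁻¹
    k23: float   # nucleotide exchange + dissociation (Gβγ generation), s⁻¹
    k34: float   # GTP hydrolysis, s⁻¹
    k45: float   # Gα(GDP)–Gβγ re-association, µm² molecule⁻¹ s⁻¹
    k54: float   # trimer dissociation, s⁻¹
    k56: float   # GIRK–Gβγ association (per site), µm² molecule⁻¹ s⁻¹
    k65: float   # GIRK–Gβγ dissociation (first site), s⁻¹
    mu: float    # cooperativity factor, dimensionless, 0 < mu <= 1
    k32: float = 0.0   # reverse of exchange step; irreversible
    k43: float = 0.0   # reverse of hydrolysis; irreversible
    n_sites: int = 4   # Gβγ binding sites on GIRK

    def __post_init__(self) -> None:
        for key in RATE_KEYS:
            v = getattr(self, key)
            if v < 0:
                raise InvalidParameterError(f"{key} must be non-negative, got {v}")
        if self.k32 != 0.0 or self.k43 != 0.0:
            raise InvalidParameterError("k32 and k43 are fixed at 0 (irreversible steps)")
        if not 0 < self.mu <= 1:
            raise InvalidParameterError(f"mu must be in (0, 1], got {self.mu}")
        if self.n_sites != 4:
            raise InvalidParameterError(f"n_sites is fixed at 4, got {self.n_sites}")

    def replace(self, **changes) -> "ParameterSet":
        d = asdict(self)
        d.update(changes)
        return ParameterSet(**d)


@dataclass(frozen=True)
class GeometryParams:
    """Membrane geometry, densities and transport parameters.

    ``s_source`` (Gβγ generation density inside a hotspot, molecules
    µm⁻² s⁻¹) defaults to receptor_density × 1 Gβγ s⁻¹ per receptor when
    left as None. ``outer_radius`` (zero-concentration far boundary)
    defaults to max(10 λ, 10 × hotspot_radius) with λ = sqrt(D/k_decay).
    """

    layer_thickness: float = DEFAULT_LAYER_THICKNESS_A  # Å
    receptor_density: float = 50.0    # molecules µm⁻² inside a hotspot
    trimer_density: float = 100.0     # Gα(GDP)βγ, molecules µm⁻²
    girk_density: float = 1.0         # channels µm⁻² (probe-level; not stated in the source data)
    D: float = 0.2                    # Gβγ diffusion coefficient, µm² s⁻¹
    k_decay: float = 1.0              # Gβγ decay (re-sequestration) constant, s⁻¹
    s_source: float | None = None     # molecules µm⁻² s⁻¹; None → receptor_density × 1/s
    hotspot_radius: float = 0.3       # µm
    inner_radius: float = 0.01        # µm, point-source near boundary r0
    outer_radius: float | None = None  # µm; None → max(10 λ, 10 hotspot_radius)

    def __post_init__(self) -> None:
        positive = {
            "layer_thickness": self.layer_thickness,
            "receptor_density": self.receptor_density,
            "trimer_density": self.trimer_density,
            "girk_density": self.girk_density,
            "D": self.D,
            "k_decay": self.k_decay,
            "hotspot_radius": self.hotspot_radius,
            "inner_radius": self.inner_radius,
        }
        for name, v in positive.items():
            if v <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {v}")
        if self.s_source is not None and self.s_source < 0:
            raise InvalidParameterError(f"s_source must be >= 0, got {self.s_source}")
        if self.outer_radius is not None:
            if not (self.inner_radius < self.hotspot_radius < self.outer_radius):
                raise InvalidParameterError(
                    "radii must satisfy inner_radius < hotspot_radius < outer_radius"
                )

    @property
    def characteristic_length(self) -> float:
        """λ = sqrt(D / k_decay), µm."""
        return (self.D / self.k_decay) ** 0.5

    @property
    def source_strength(self) -> float:
        """Hotspot Gβγ generation, molecules µm⁻² s⁻¹."""
        if self.s_source is not None:
            return self.s_source
        return self.receptor_density * 1.0

    @property
    def far_boundary(self) -> float:
        """Zero-Dirichlet outer radius, µm."""
        if self.outer_radius is not None:
            return self.outer_radius
        return max(10.0 * self.characteristic_length, 10.0 * self.hotspot_radius)

    def replace(self, **changes) -> "GeometryParams":
        d = asdict(self)
        d.update(changes)
        return GeometryParams(**d)


# Tabulated 3D-unit constants of the Gi-coupled (M2R-like) reference cycle.
_TABLE_3D = {
    "k12": 1.0e6,    # M⁻¹ s⁻¹ (1 µM⁻¹ s⁻¹)
    "k21": 1.0,      # s⁻¹
    "k23": 1.0,      # s⁻¹
    "k32": 0.0,
    "k34": 2.0,      # s⁻¹
    "k43": 0.0,
    "k45": 0.7e6,    # M⁻¹ s⁻¹
    "k54": 0.002,    # s⁻¹
    "k56": 1.0e7,    # M⁻¹ s⁻¹
    "k65": 600.0,    # s⁻¹
    "mu": 0.3,
}

RECEPTOR_CLASSES = ("Gi-coupled", "Gs-coupled")


def default_parameters(
    receptor_class: str = "Gi-coupled",
    thickness_angstrom: float = DEFAULT_LAYER_THICKNESS_A,
) -> ParameterSet:
    """Reference rate constants in canonical 2D units.

    "Gi-coupled" is the M2R-like cycle; "Gs-coupled" (β2AR-like) is
    identical except k12 is tenfold smaller, the single parameter that
    carries Gβγ-signaling specificity in this model.
    """
    if receptor_class not in RECEPTOR_CLASSES:
        raise InvalidParameterError(
            f"unknown receptor class {receptor_class!r}; expected one of {RECEPTOR_CLASSES}"
        )
    factor = molar_per_molecule_per_um2(thickness_angstrom)
    k12 = _TABLE_3D["k12"] * factor
    if receptor_class == "Gs-coupled":
        k12 /= 10.0
    return ParameterSet(
        k12=k12,
        k21=_TABLE_3D["k21"],
        k23=_TABLE_3D["k23"],
        k34=_TABLE_3D["k34"],
        k45=_TABLE_3D["k45"] * factor,
        k54=_TABLE_3D["k54"],
        k56=_TABLE_3D["k56"] * factor,
        k65=_TABLE_3D["k65"],
        mu=_TABLE_3D["mu"],
    )


def save_parameters(params: ParameterSet, path: str | Path,
                    thickness_angstrom: float = DEFAULT_LAYER_THICKNESS_A) -> None:
    """Write a ParameterSet as JSON with an explicit units block."""
    payload = {key: getattr(params, key) for key in RATE_KEYS}
    payload["mu"] = params.mu
    payload["units"] = {
        key: ("2d" if key in BIMOLECULAR_KEYS else "per_second") for key in RATE_KEYS
    }
    payload["units"]["layer_thickness_angstrom"] = thickness_angstrom
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a ParameterSet from JSON, converting any 3D-unit constants.

    The "units" block declares each bimolecular constant as "2d"
    (µm² molecule⁻¹ s⁻¹) or "3d" (M⁻¹ s⁻¹); 3D values are converted with
    the layer thickness given in the block (default 80 Å).
    """
    payload = json.loads(Path(path).read_text())
    units = payload.get("units", {})
    thickness = units.get("layer_thickness_angstrom", DEFAULT_LAYER_THICKNESS_A)
    factor = molar_per_molecule_per_um2(thickness)
    values = {}
    for key in RATE_KEYS:
        v = float(payload[key])
        if key in BIMOLECULAR_KEYS and units.get(key, "2d") == "3d":
            v *= factor
        values[key] = v
    return ParameterSet(mu=float(payload["mu"]), **values)
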