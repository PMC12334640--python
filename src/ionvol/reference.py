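"""Shared physical reference models: pure-water density, the Debye-Hückel
volume slope, solute registry, and unit conversions.

All densities are in g/cm³, temperatures in °C, molalities in mol/kg and
molar volumes in cm³/mol unless stated otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AVOGADRO_SCALE",
    "ION_CHARGES",
    "ION_ORDER",
    "ReferenceContext",
    "SaltSpec",
    "SALTS",
    "aa3_to_cm3mol",
    "cm3mol_to_aa3",
    "av_slope_table",
    "d0_ref",
    "d0_ref_tanaka",
    "default_context",
    "study_context",
    "load_context",
    "valence_factor",
]

#: N_A x 1e-24 — converts Å³/molecule to cm³/mol.
AVOGADRO_SCALE = 6.02214076e23 * 1e-24


def d0_ref(T: float | np.ndarray) -> float | np.ndarray:
    """Density of air-free liquid water at atmospheric pressure.

    Kell's (1975) rational polynomial, valid 0–60 °C here (the
    parameterization itself extends to 150 °C).  d0_ref(20) = 0.998204,
    d0_ref(25) = 0.997045 g/cm³.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0.0) or np.any(T > 60.0):
        raise ValueError("d0_ref: temperature outside validity range 0-60 °C")
    num = (
        999.83952
        + 16.945176 * T
        - 7.9870401e-3 * T**2
        - 46.170461e-6 * T**3
        + 105.56302e-9 * T**4
        - 280.54253e-12 * T**5
    )
    out = num / (1.0 + 16.87985e-3 * T) / 1000.0
    return float(out) if out.ndim == 0 else out


def d0_ref_tanaka(T: float | np.ndarray) -> float | np.ndarray:
    """Independent cross-check water density (Tanaka et al. 2001, SMOW).

    Agrees with :func:`d0_ref` to < 3e-6 g/cm³ on 20-40 °C; used only to
    validate the primary parameterization.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0.0) or np.any(T > 60.0):
        raise ValueError("d0_ref_tanaka: temperature outside validity range")
    a1, a2, a3, a4, a5 = -3.983035, 301.797, 522528.9, 69.34881, 999.974950
    out = a5 * (1.0 - (T + a1) ** 2 * (T + a2) / (a3 * (T + a4))) / 1000.0
    return float(out) if out.ndim == 0 else out


def _av_quadratic(T: float, scale: float = 1.0) -> float:
    # Smooth parameterization of the Pitzer-convention volumetric
    # Debye-Hückel slope, anchored at Av(0)=1.504 and Av(25)=1.875
    # cm³·kg^1/2·mol^-3/2; increasing on 0-60 °C.
    return scale * (1.504 + 1.2565e-2 * T + 9.1e-5 * T**2)


def av_slope_table(T_min: float = 10.0, T_max: float = 50.0,
                   step: float = 5.0, scale: float = 1.0) -> dict[float, float]:
    """Tabulate the Debye-Hückel volume slope at regular knots.

    ``scale=1`` gives the standard Pitzer-convention values (1.875 at
    25 °C); ``scale=1.65/1.875`` gives the study-consistent table that
    reproduces the printed dilute-limit contributions.
    """
    knots = np.arange(T_min, T_max + step / 2, step)
    return {float(t): _av_quadratic(float(t), scale) for t in knots}


def valence_factor(components: Iterable[tuple[str, int, int]]) -> float:
    """Valence factor ω = ½ Σ nᵢzᵢ² of an electroneutral salt.

    ``components`` is an iterable of (ion name, stoichiometric count,
    charge).  Raises ``ValueError`` for a non-electroneutral composition.
    """
    comps = list(components)
    net = sum(n * z for _, n, z in comps)
    if net != 0:
        raise ValueError(f"composition is not electroneutral (Σ n·z = {net})")
    return 0.5 * sum(n * z * z for _, n, z in comps)


def aa3_to_cm3mol(v: float | np.ndarray) -> float | np.ndarray:
    """Convert a molecular volume in Å³ to a molar volume in cm³/mol."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    out = v * AVOGADRO_SCALE
    return float(out) if out.ndim == 0 else out


def cm3mol_to_aa3(v: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`aa3_to_cm3mol`."""
    out = np.asarray(v, dtype=float) / AVOGADRO_SCALE
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Solute registry

#: Documented ion ordering used by every design matrix and report.
ION_ORDER: tuple[str, ...] = (
    "Li+", "Na+", "K+", "Mg2+", "Cl-", "Br-", "I-", "SO4-2",
)

ION_CHARGES: dict[str, int] = {
    "H+": 1, "Li+": 1, "Na+": 1, "K+": 1, "Mg2+": 2,
    "Cl-": -1, "Br-": -1, "I-": -1, "SO4-2": -2,
}


@dataclass(frozen=True)
class SaltSpec:
    """Identity of a dissociable solute.

    ``components`` lists (ion, stoichiometric count, charge); ``M`` is the
    molar mass in g/mol.  Electroneutrality is enforced at construction
    and ω = ½ Σ nᵢzᵢ² is derived, never stored independently.
    """

    name: str
    components: tuple[tuple[str, int, int], ...]
    M: float

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        valence_factor(self.components)  # raises if not electroneutral

    @property
    def omega(self) -> float:
        return valence_factor(self.components)

    @property
    def ions(self) -> tuple[str, ...]:
        return tuple(ion for ion, _, _ in self.components)

    def counts(self, ion_order: Sequence[str] = ION_ORDER) -> np.ndarray:
        """Stoichiometric counts as a row aligned with ``ion_order``.

        Ions absent from ``ion_order`` (e.g. H⁺) are omitted — callers
        handle constrained ions separately.
        """
        row = np.zeros(len(ion_order))
        for ion, n, _ in self.components:
            if ion in ion_order:
                row[list(ion_order).index(ion)] += n
        return row


def _salt(name: str, components, M: float) -> SaltSpec:
    comps = tuple((ion, n, ION_CHARGES[ion]) for ion, n in components)
    return SaltSpec(name, comps, M)


#: The 16 studied salts + HCl.  Masses are the published experimental
#: values where the source study printed them (note the study's Na2SO4
#: mass, 142.37 g/mol, exceeds the IUPAC value 142.04 — stored verbatim);
#: the remainder come from IUPAC 2021 atomic weights.
SALTS: dict[str, SaltSpec] = {
    s.name: s
    for s in [
        _salt("LiCl", [("Li+", 1), ("Cl-", 1)], 42.394),
        _salt("NaCl", [("Na+", 1), ("Cl-", 1)], 58.44),
        _salt("KCl", [("K+", 1), ("Cl-", 1)], 74.555),
        _salt("MgCl2", [("Mg2+", 1), ("Cl-", 2)], 95.211),
        _salt("LiBr", [("Li+", 1), ("Br-", 1)], 86.844),
        _salt("NaBr", [("Na+", 1), ("Br-", 1)], 102.894),
        _salt("KBr", [("K+", 1), ("Br-", 1)], 119.002),
        _salt("MgBr2", [("Mg2+", 1), ("Br-", 2)], 184.113),
        _salt("LiI", [("Li+", 1), ("I-", 1)], 133.844),
        _salt("NaI", [("Na+", 1), ("I-", 1)], 149.894),
        _salt("KI", [("K+", 1), ("I-", 1)], 166.003),
        _salt("MgI2", [("Mg2+", 1), ("I-", 2)], 278.114),
        _salt("Li2SO4", [("Li+", 2), ("SO4-2", 1)], 109.936),
        _salt("Na2SO4", [("Na+", 2), ("SO4-2", 1)], 142.37),
        _salt("K2SO4", [("K+", 2), ("SO4-2", 1)], 174.259),
        _salt("MgSO4", [("Mg2+", 1), ("SO4-2", 1)], 120.36),
        _salt("HCl", [("H+", 1), ("Cl-", 1)], 36.45),
    ]
}


# --------------------------------------------------------------------------
# Reference context

@dataclass
class ReferenceContext:
    """Bundle of reference models consumed by the density pipeline.

    Parameters
    ----------
    d0_model : callable T -> g/cm³, pure-water density.
    av_table : mapping T -> Av (cm³·kg^1/2·mol^-3/2); linearly
        interpolated between knots, hard error outside.
    b : Pitzer denominator, (kg/mol)^1/2.  Default 1.2.
    avogadro_scale : Å³/molecule -> cm³/mol conversion factor.
    T_ref : reference temperature for thermal-expansion models.
    """

    d0_model: Callable[[float], float] = d0_ref
    av_table: Mapping[float, float] = field(default_factory=av_slope_table)
    b: float = 1.2
    avogadro_scale: float = AVOGADRO_SCALE
    T_ref: float = 25.0

    def d0(self, T: float | np.ndarray) -> float | np.ndarray:
        return self.d0_model(T)

    def av(self, T: float | np.ndarray) -> float | np.ndarray:
        """Debye-Hückel volume slope at T, by linear interpolation."""
        knots = np.array(sorted(self.av_table))
        vals = np.array([self.av_table[t] for t in knots])
        T = np.asarray(T, dtype=float)
        if np.any(T < knots[0] - 1e-9) or np.any(T > knots[-1] + 1e-9):
            raise ValueError(
                f"Av slope requested at {T} °C, outside the configured "
                f"table [{knots[0]}, {knots[-1]}] °C"
            )
        out = np.interp(T, knots, vals)
        return float(out) if out.ndim == 0 else out


def default_context() -> ReferenceContext:
    """Standard Pitzer-convention context (Av(25 °C) = 1.875)."""
    return ReferenceContext()


def study_context() -> ReferenceContext:
    """Context with the study-consistent Debye-Hückel slope table.

    The densimetric study's Av source is an external compilation whose
    values are not printed; back-deriving from its stated dilute-limit
    contributions (0.26 / 1.25 / 1.90 cm³/mol at ω = 1/3/4, m = 0.03
    mol/kg) gives Av(25 °C) ≈ 1.65, ~12% below the standard Pitzer
    convention.  This context scales the default table accordingly.
    """
    return ReferenceContext(av_table=av_slope_table(scale=1.65 / 1.875))


def load_context(path: str | Path) -> ReferenceContext:
    """Build a context from a YAML or JSON config file.

    Recognized keys (all optional): ``av_table`` (mapping T -> Av),
    ``av_scale`` (scale factor on the default table), ``b``, ``T_ref``.
    """
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    cfg = cfg or {}
    kwargs: dict = {}
    if "av_table" in cfg:
        kwargs["av_table"] = {float(k): float(v) for k, v in cfg["av_table"].items()}
    elif "av_scale" in cfg:
        kwargs["av_table"] = av_slope_table(scale=float(cfg["av_scale"]))
    for key in ("b", "T_ref"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    return ReferenceContext(**kwargs)
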