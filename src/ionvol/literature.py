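"""Published dilute-solution densimetry results for the 17 solutes and the
self-consistent single-ion volume set derived from them.

These printed values serve two roles: as the observed input of the
ionic-additivity decomposition (the study's raw densities are not public),
and as ground truth for the synthetic-data generators.

Conventions: V is the partial molar volume at 25 °C in cm³/mol with its
standard error; ``alpha`` is the first temperature derivative at 25 °C in
cm³/mol/K; ``beta`` is the quadratic coefficient of the 25 °C-referenced
parabola in cm³/mol/K² (the published second-derivative row stores this
quadratic coefficient, as its proton entry −0.17·10⁻³ — the Marcus
polynomial's own quadratic coefficient — confirms).
"""

from __future__ import annotations

from .density import ThermalVolumeModel
from .reference import ION_ORDER

__all__ = [
    "SALT_VOLUMES_25C",
    "ION_VOLUMES",
    "ION_VOLUMES_BY_T",
    "salt_values_25c",
    "ion_truth_models",
]

#: Quadratic-model estimates at 25 °C: name -> (V, SE, alpha, SE, beta, SE).
#: alpha/beta and their SEs are in cm³/mol/K and cm³/mol/K².
SALT_VOLUMES_25C: dict[str, tuple[float, float, float, float, float, float]] = {
    "LiCl":   (17.89, 0.10,  13e-3, 20e-3, -1.6e-3, 1.8e-3),
    "NaCl":   (16.43, 0.12,  87e-3, 25e-3, -2.6e-3, 2.2e-3),
    "KCl":    (27.22, 0.18,  66e-3, 36e-3,  0.0e-3, 3.1e-3),
    "MgCl2":  (18.06, 0.20,  -4e-3, 41e-3, -0.5e-3, 3.5e-3),
    "LiBr":   (24.03, 0.09,  26e-3, 18e-3, -0.6e-3, 1.6e-3),
    "NaBr":   (23.21, 0.18, 106e-3, 37e-3, -1.5e-3, 3.2e-3),
    "KBr":    (33.54, 0.21,  83e-3, 43e-3, -0.2e-3, 3.7e-3),
    "MgBr2":  (33.15, 0.12,  55e-3, 24e-3, -1.6e-3, 2.1e-3),
    "LiI":    (35.75, 0.09,  50e-3, 18e-3, -1.8e-3, 1.6e-3),
    "NaI":    (35.90, 0.13, 123e-3, 26e-3, -1.5e-3, 2.2e-3),
    "KI":     (44.71, 0.12, 113e-3, 24e-3, -2.2e-3, 2.1e-3),
    "MgI2":   (54.72, 0.16, 129e-3, 32e-3, -4.1e-3, 2.7e-3),
    "Li2SO4": (11.89, 0.11,  60e-3, 22e-3, -2.4e-3, 1.9e-3),
    "Na2SO4": (11.30, 0.25, 221e-3, 52e-3, -5.5e-3, 4.5e-3),
    "K2SO4":  (33.32, 0.14, 145e-3, 28e-3, -0.1e-3, 2.5e-3),
    "MgSO4":  (-4.71, 0.11,  73e-3, 25e-3, -1.5e-3, 2.2e-3),
    "HCl":    (17.69, 0.07,  21e-3, 13e-3, -1.7e-3, 1.2e-3),
}

#: Self-consistent ionic set: ion -> (V25, SE, dV/dT at 25 °C, SE,
#: quadratic coefficient, SE).  Units as in SALT_VOLUMES_25C.
ION_VOLUMES: dict[str, tuple[float, float, float, float, float, float]] = {
    "Li+":   (-5.56, 0.21, -31.8e-3,  5.5e-3,  0.56e-3, 0.49e-3),
    "Na+":   (-5.91, 0.22,  44.7e-3,  5.9e-3, -0.30e-3, 0.51e-3),
    "K+":    ( 4.48, 0.22,  17.1e-3,  5.9e-3,  1.31e-3, 0.51e-3),
    "Mg2+":  (-27.26, 0.40, -57.6e-3, 10.6e-3, 1.49e-3, 0.93e-3),
    "Cl-":   (22.85, 0.16,  35.8e-3,  4.3e-3, -1.50e-3, 0.38e-3),
    "Br-":   (29.96, 0.21,  57.2e-3,  5.6e-3, -1.47e-3, 0.50e-3),
    "I-":    (41.06, 0.21,  89.9e-3,  5.6e-3, -2.62e-3, 0.49e-3),
    "SO4-2": (23.24, 0.41, 124.4e-3, 11.1e-3, -3.61e-3, 0.97e-3),
}

#: Ionic volumes (value, SE) at each measured temperature, cm³/mol.
ION_VOLUMES_BY_T: dict[int, dict[str, tuple[float, float]]] = {
    20: {"Li+": (-5.44, 0.22), "Na+": (-6.20, 0.24), "K+": (4.32, 0.24),
         "Mg2+": (-27.07, 0.43), "Cl-": (22.67, 0.18), "Br-": (29.68, 0.23),
         "I-": (40.59, 0.23), "SO4-2": (22.63, 0.45)},
    25: {"Li+": (-5.56, 0.21), "Na+": (-5.91, 0.22), "K+": (4.48, 0.22),
         "Mg2+": (-27.26, 0.40), "Cl-": (22.85, 0.16), "Br-": (29.96, 0.21),
         "I-": (41.06, 0.21), "SO4-2": (23.24, 0.41)},
    30: {"Li+": (-5.72, 0.20), "Na+": (-5.74, 0.22), "K+": (4.52, 0.22),
         "Mg2+": (-27.59, 0.39), "Cl-": (23.03, 0.16), "Br-": (30.25, 0.21),
         "I-": (41.48, 0.21), "SO4-2": (23.81, 0.41)},
    35: {"Li+": (-5.90, 0.21), "Na+": (-5.57, 0.22), "K+": (4.65, 0.22),
         "Mg2+": (-27.86, 0.41), "Cl-": (23.09, 0.17), "Br-": (30.41, 0.22),
         "I-": (41.75, 0.22), "SO4-2": (24.28, 0.42)},
    40: {"Li+": (-5.91, 0.25), "Na+": (-5.32, 0.26), "K+": (5.01, 0.26),
         "Mg2+": (-27.81, 0.47), "Cl-": (23.07, 0.19), "Br-": (30.51, 0.25),
         "I-": (41.83, 0.25), "SO4-2": (24.30, 0.49)},
}


def salt_values_25c() -> dict[str, tuple[float, float]]:
    """(V, SE) at 25 °C for all 17 solutes — decomposition input."""
    return {name: (v[0], v[1]) for name, v in SALT_VOLUMES_25C.items()}


def ion_truth_models(T_ref: float = 25.0) -> dict[str, ThermalVolumeModel]:
    """Published ionic set as thermal-volume models (generator truth)."""
    if T_ref != 25.0:
        raise ValueError("published ionic coefficients are referenced to 25 °C")
    return {
        ion: ThermalVolumeModel(V_ref=v, alpha=a, beta=b, T_ref=25.0)
        for ion, (v, _, a, _, b, _) in ION_VOLUMES.items()
    }


assert set(ION_VOLUMES) == set(ION_ORDER)
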