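"""Synthetic-data generators emulating the study's two data sources.

The density generator reproduces the statistical structure of a
vibrating-tube densimetry campaign on dilute electrolytes: serial
dilutions on a geometric molality grid (1e-3 to 3e-2 mol/kg), 20-40 °C in
5 °C steps, Gaussian instrument noise of 7e-6 g/cm³ and a small
per-(series, temperature) solvent-density offset (truncated below
2e-5 g/cm³ in magnitude), with densities produced by the closed-form
model of :mod:`ionvol.density`.

The solvation generator emits ion-centered snapshot frames of rigid
three-site waters in a 25 Å periodic cube: an isotropic ideal-gas mode,
a hard-core (excluded-volume) Poisson mode for calibrating the V(N)
intercept estimator, and shell-structured cation-like / anion-like /
bulk-like modes whose first-shell orientation statistics mimic the
qualitative hydration picture (oxygen toward cations, one hydrogen
toward anions, donor/acceptor split in bulk water).  It targets the
statistics the estimators consume, not real-water correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np

from .density import DensityRecord, ThermalVolumeModel, predict_density
from .ions import IonVolumeSet, hplus_model
from .md import SolvationSnapshot
from .reference import ION_ORDER, ReferenceContext, SaltSpec, SALTS, default_context

__all__ = [
    "DensityDesign",
    "SolvationDesign",
    "ShellSpec",
    "gen_density_dataset",
    "gen_full_study",
    "gen_solvation_snapshots",
    "salt_truth_from_ions",
]

# TIP3P-like rigid water geometry
OH_BOND = 0.9572          # Å
HOH_ANGLE = 104.52        # degrees
_Q_DIST = OH_BOND * math.cos(math.radians(HOH_ANGLE / 2))   # O -> H midpoint
_HH_HALF = OH_BOND * math.sin(math.radians(HOH_ANGLE / 2))


@dataclass
class DensityDesign:
    """Design of a synthetic densimetry campaign (defaults = study design)."""

    molalities: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-3, 3e-2, 8))
    temperatures: np.ndarray = field(
        default_factory=lambda: np.arange(20.0, 41.0, 5.0))
    n_series: int = 3
    noise_sd: float = 7e-6
    delta_d0_sd: float = 1e-5
    delta_d0_max: float = 2e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.molalities) == 0 or len(self.temperatures) == 0:
            raise ValueError("empty design grid")
        if self.noise_sd < 0 or self.delta_d0_sd < 0:
            raise ValueError("noise levels must be non-negative")


def _truncated_normal(rng, sd, bound, size):
    if sd == 0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) >= bound
    while bad.any():
        out[bad] = rng.normal(0.0, sd, bad.sum())
        bad = np.abs(out) >= bound
    return out


def gen_density_dataset(
    salt: SaltSpec,
    truth: ThermalVolumeModel,
    design: DensityDesign | None = None,
    ctx: ReferenceContext | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[DensityRecord], dict]:
    """Simulate dilution series for one solute.

    Returns the records and a ground-truth sidecar (injected parameters
    and the drawn per-cell offsets) for recovery tests.
    """
    design = design or DensityDesign()
    ctx = ctx or default_context()
    rng = rng or np.random.default_rng(design.seed)
    records: list[DensityRecord] = []
    offsets: dict[str, float] = {}
    for s in range(design.n_series):
        sid = f"{salt.name}-s{s + 1}"
        for T in design.temperatures:
            dd0 = float(_truncated_normal(rng, design.delta_d0_sd,
                                          design.delta_d0_max, 1)[0])
            offsets[f"{sid}@{T:g}C"] = dd0
            d_true = predict_density(design.molalities, T, truth, salt, dd0, ctx)
            d_obs = d_true + rng.normal(0.0, design.noise_sd,
                                        len(design.molalities))
            for m, d in zip(design.molalities, d_obs):
                records.append(DensityRecord(salt.name, sid, float(T),
                                             float(m), float(d)))
    sidecar = {
        "solute": salt.name,
        "truth": {"V_ref": truth.V_ref, "alpha": truth.alpha,
                  "beta": truth.beta, "T_ref": truth.T_ref},
        "delta_d0": offsets,
        "design": {"n_series": design.n_series,
                   "molalities": list(map(float, design.molalities)),
                   "temperatures": list(map(float, design.temperatures)),
                   "noise_sd": design.noise_sd, "seed": design.seed},
    }
    return records, sidecar


def salt_truth_from_ions(
    salt: SaltSpec, ion_models: Mapping[str, ThermalVolumeModel],
) -> ThermalVolumeModel:
    """Additive salt-level truth: coefficients sum ion-wise (common T_ref)."""
    V = a = b = 0.0
    T_ref = None
    for ion, n, _ in salt.components:
        mod = hplus_model() if ion == "H+" else ion_models[ion]
        if ion == "H+":
            # re-reference the proton polynomial to the ions' T_ref
            tr = next(iter(ion_models.values())).T_ref
            mod = ThermalVolumeModel(
                V_ref=float(mod.value_at(tr)), alpha=mod.derivative_at(tr),
                beta=mod.beta, T_ref=tr)
        if T_ref is None:
            T_ref = mod.T_ref
        elif mod.T_ref != T_ref:
            raise ValueError("ion models must share T_ref")
        V += n * mod.V_ref; a += n * mod.alpha; b += n * mod.beta
    return ThermalVolumeModel(V_ref=V, alpha=a, beta=b, T_ref=T_ref)


def gen_full_study(
    ion_models: Mapping[str, ThermalVolumeModel] | IonVolumeSet,
    design: DensityDesign | None = None,
    ctx: ReferenceContext | None = None,
    registry: Mapping[str, SaltSpec] = SALTS,
) -> tuple[list[DensityRecord], dict]:
    """Simulate the complete campaign: 16 salts + HCl from an ionic truth."""
    if isinstance(ion_models, IonVolumeSet):
        ion_models = ion_models.models
    missing = set(ION_ORDER) - set(ion_models)
    if missing:
        raise ValueError(f"ion truth missing: {sorted(missing)}")
    design = design or DensityDesign()
    ctx = ctx or default_context()
    rng = np.random.default_rng(design.seed)
    records: list[DensityRecord] = []
    sidecars = {}
    for name, spec in registry.items():
        truth = salt_truth_from_ions(spec, ion_models)
        recs, side = gen_density_dataset(spec, truth, design, ctx, rng)
        records.extend(recs)
        sidecars[name] = side
    truth_tab = {ion: {"V_ref": m.V_ref, "alpha": m.alpha, "beta": m.beta}
                 for ion, m in ion_models.items()}
    return records, {"ions": truth_tab, "salts": sidecars}


# --------------------------------------------------------------------------
# Solvation snapshots

@dataclass
class ShellSpec:
    """One Gaussian radial shell with a preferred water orientation."""

    radius: float            # Å, shell center
    width: float             # Å, radial standard deviation
    occupancy: int           # waters per frame
    theta_mean: float        # degrees, preferred ion-O-Q angle
    theta_sd: float = 15.0   # degrees, angular spread


_MODE_SHELLS: dict[str, list[ShellSpec]] = {
    # first/second shells mimicking the qualitative hydration picture
    "cation-like": [ShellSpec(2.1, 0.12, 6, 165.0, 12.0),
                    ShellSpec(4.2, 0.30, 16, 140.0, 30.0)],
    "anion-like": [ShellSpec(3.2, 0.18, 7, 60.0, 15.0),
                   ShellSpec(5.0, 0.35, 18, 80.0, 35.0)],
    "bulk-like": [ShellSpec(2.8, 0.15, 2, 150.0, 15.0),   # H-bond donors
                  ShellSpec(2.8, 0.15, 2, 40.0, 20.0)],   # acceptors
}


@dataclass
class SolvationDesign:
    """Design of a synthetic snapshot trajectory (defaults = study setup)."""

    box_edge: float = 25.0
    n_waters: int = 507
    n_frames: int = 10_000
    mode: Literal["isotropic", "hard-core", "cation-like",
                  "anion-like", "bulk-like"] = "isotropic"
    r_ex: float = 0.0
    shells: list[ShellSpec] | None = None
    count_distribution: Literal["fixed", "poisson"] = "fixed"
    #: If set, overrides ``n_waters`` via mean count = density * free volume
    #: (kept exact, not integer-rounded, in poisson mode) so several fluids
    #: with different cores can share one far-field density exactly.
    target_density: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_ex >= self.box_edge / 4:
            raise ValueError("r_ex must be below a quarter of the box edge")
        if self.shells is None and self.mode in _MODE_SHELLS:
            self.shells = list(_MODE_SHELLS[self.mode])
        if self.target_density is not None:
            self.n_waters = int(round(self.target_density * self.free_volume))
        shells = self.shells or []
        if sum(s.occupancy for s in shells) > self.n_waters:
            raise ValueError("shell occupancies exceed the water budget")

    @property
    def free_volume(self) -> float:
        """Box volume outside the excluded core, Å³."""
        return self.box_edge**3 - (4.0 / 3.0) * math.pi * self.r_ex**3

    @property
    def mean_count(self) -> float:
        if self.target_density is not None:
            return self.target_density * self.free_volume
        return float(self.n_waters)

    @property
    def density(self) -> float:
        """Implied far-field number density, Å^-3."""
        return self.mean_count / self.free_volume


def _random_units(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _orient_waters(rng, O, to_ion_unit, theta_deg):
    """Build rigid waters whose ion-O-Q angle equals ``theta_deg``.

    The O->Q axis is placed at the requested angle from O->ion with a
    uniform azimuth; the H-H axis gets a uniform spin about O->Q.
    """
    n = len(O)
    # orthonormal frame around the O->ion direction
    a = to_ion_unit
    helper = np.where(np.abs(a[:, :1]) < 0.9,
                      np.tile([1.0, 0, 0], (n, 1)),
                      np.tile([0, 1.0, 0], (n, 1)))
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(a, e1)
    phi = rng.uniform(0, 2 * math.pi, n)[:, None]
    th = np.radians(theta_deg)[:, None]
    q_dir = (np.cos(th) * a
             + np.sin(th) * (np.cos(phi) * e1 + np.sin(phi) * e2))
    Q = O + _Q_DIST * q_dir
    # H-H axis: unit vector perpendicular to q_dir, random spin
    psi = rng.uniform(0, 2 * math.pi, n)[:, None]
    f1 = np.cross(q_dir, e1)
    norm = np.linalg.norm(f1, axis=1, keepdims=True)
    degen = norm[:, 0] < 1e-9
    if degen.any():
        f1[degen] = np.cross(q_dir[degen], e2[degen])
        norm = np.linalg.norm(f1, axis=1, keepdims=True)
    f1 /= norm
    f2 = np.cross(q_dir, f1)
    hh = np.cos(psi) * f1 + np.sin(psi) * f2
    H1 = Q + _HH_HALF * hh
    H2 = Q - _HH_HALF * hh
    return H1, H2


def _sample_theta(rng, n, mean_deg, sd_deg):
    # truncated-normal angle peak (von-Mises-like for small spread)
    th = rng.normal(mean_deg, sd_deg, n)
    bad = (th < 0) | (th > 180)
    while bad.any():
        th[bad] = rng.normal(mean_deg, sd_deg, bad.sum())
        bad = (th < 0) | (th > 180)
    return th


def gen_solvation_snapshots(
    design: SolvationDesign,
) -> Iterator[SolvationSnapshot]:
    """Lazily generate snapshot frames for the configured mode.

    Ion sits at the box center.  ``isotropic``: uniform positions,
    orientation uniform in cos(theta).  ``hard-core``: same but no
    oxygen within ``r_ex`` of the ion (Poisson-count option for exact
    ideal-gas statistics).  Shell modes add Gaussian radial shells with
    peaked theta distributions; the remaining waters behave like the
    hard-core mode beyond the outermost shell.
    """
    rng = np.random.default_rng(design.seed)
    L = design.box_edge
    ion = np.full(3, L / 2.0)
    shells = design.shells or []
    n_shell = sum(s.occupancy for s in shells)
    core = design.r_ex
    if shells and core == 0.0:
        # structured first shell displaces bulk water: unoriented bulk
        # starts just beyond the innermost shell (its g(r) minimum)
        core = min(s.radius for s in shells) + 1.0

    for _ in range(design.n_frames):
        n_total = design.n_waters
        if design.count_distribution == "poisson":
            n_total = int(rng.poisson(design.mean_count))
        n_bulk = max(n_total - n_shell, 0)
        O_parts, th_parts = [], []
        for sh in shells:
            r = rng.normal(sh.radius, sh.width, sh.occupancy)
            r = np.abs(r)
            O_parts.append(ion + r[:, None] * _random_units(rng, sh.occupancy))
            th_parts.append(_sample_theta(rng, sh.occupancy,
                                          sh.theta_mean, sh.theta_sd))
        # bulk: uniform in the box, rejecting the excluded core
        O_bulk = np.empty((0, 3))
        while len(O_bulk) < n_bulk:
            cand = rng.uniform(0, L, (max(n_bulk - len(O_bulk), 16), 3))
            if core > 0:
                keep = np.linalg.norm(cand - ion, axis=1) > core
                cand = cand[keep]
            O_bulk = np.vstack([O_bulk, cand])
        O_bulk = O_bulk[:n_bulk]
        # isotropic orientation: theta uniform in cos
        th_bulk = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n_bulk)))
        O = np.vstack([*O_parts, O_bulk]) if O_parts else O_bulk
        theta = np.concatenate([*th_parts, th_bulk]) if th_parts else th_bulk
        to_ion = ion - O
        dist = np.linalg.norm(to_ion, axis=1)
        H1, H2 = _orient_waters(rng, O, to_ion / dist[:, None], theta)
        yield SolvationSnapshot(box_edge=L, ion_position=ion.copy(),
                                O=O, H1=H1, H2=H2)
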