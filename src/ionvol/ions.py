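"""Single-ion partial molar volumes from salt-level data.

Ionic additivity, V2(XnYm) = n*V2(X) + m*V2(Y), turns the 16 binary-salt
volumes into a linear system in 8 ionic unknowns.  That system is rank
deficient: its null space is spanned by the ionic charge vector, the
algebraic face of the fact that only electroneutral combinations are ever
measured.  Adding HCl and pinning the aqueous proton to the Marcus
polynomial V2(H+, T) = -5.1 - 0.008*T - 1.7e-4*T**2 restores full rank.

Two estimation routes are provided: a per-temperature weighted least
squares on salt-level volumes, and a grand nonlinear fit of all raw
density records with per-ion quadratic thermal-expansion parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .density import DensityRecord, ThermalVolumeModel
from .reference import (ION_CHARGES, ION_ORDER, ReferenceContext, SaltSpec,
                        SALTS, default_context)

__all__ = [
    "AdditivitySystem",
    "IonVolumeSet",
    "build_system",
    "curvature_contrast",
    "decompose_at_T",
    "global_ionic_fit",
    "hplus_model",
    "hplus_volume",
]

CATIONS = ("Li+", "Na+", "K+", "Mg2+")
ANIONS = ("Cl-", "Br-", "I-", "SO4-2")


def hplus_volume(T: float | np.ndarray) -> float | np.ndarray:
    """Marcus polynomial for the aqueous proton volume, cm³/mol (T in °C)."""
    T = np.asarray(T, dtype=float)
    out = -5.1 - 0.008 * T - 1.7e-4 * T**2
    return float(out) if out.ndim == 0 else out


def hplus_model() -> ThermalVolumeModel:
    """The proton constraint as a thermal-volume model (T_ref = 0 °C)."""
    return ThermalVolumeModel(V_ref=-5.1, alpha=-0.008, beta=-1.7e-4, T_ref=0.0)


@dataclass
class AdditivitySystem:
    """Linear additivity system over the documented ion ordering.

    ``design`` holds stoichiometric counts (rows = solutes, columns =
    :data:`~ionvol.reference.ION_ORDER`); the HCl row, when present, has
    the fixed proton contribution already moved to the observation side.
    """

    salts: list[SaltSpec]
    values: np.ndarray
    ses: np.ndarray
    design: np.ndarray
    ions: tuple[str, ...] = ION_ORDER
    constraint: dict | None = None

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.design))

    def null_space(self, rtol: float = 1e-10) -> np.ndarray:
        """Orthonormal basis of the design's null space (columns)."""
        _, s, vt = np.linalg.svd(self.design)
        null_mask = np.zeros(vt.shape[0], dtype=bool)
        null_mask[len(s):] = True
        null_mask[: len(s)] |= s < rtol * (s[0] if len(s) else 1.0)
        return vt[null_mask].T

    def report(self) -> dict:
        return {
            "ions": {ion: i for i, ion in enumerate(self.ions)},
            "rank": self.rank,
            "n_rows": len(self.salts),
            "null_space": self.null_space().tolist(),
            "constraint": self.constraint,
        }


def build_system(
    salt_values: Mapping[str, tuple[float, float]],
    T: float = 25.0,
    registry: Mapping[str, SaltSpec] = SALTS,
    include_hcl: bool = True,
    ions: Sequence[str] | None = None,
) -> AdditivitySystem:
    """Assemble the additivity system from salt-level (V, SE) pairs.

    Solutes containing H+ are kept only when ``include_hcl`` and enter
    with the proton pinned to :func:`hplus_volume`(T) (substitution form:
    the fixed contribution is subtracted from the observed value).  With
    ``ions=None`` the columns are the documented ordering restricted to
    ions actually present; an explicit ion list demands full coverage.
    """
    rows, vals, ses, kept = [], [], [], []
    constraint = None
    for name, (v, se) in salt_values.items():
        spec = registry[name]
        has_h = any(ion == "H+" for ion, _, _ in spec.components)
        if has_h and not include_hcl:
            continue
        val = float(v)
        if has_h:
            nh = sum(n for ion, n, _ in spec.components if ion == "H+")
            val -= nh * float(hplus_volume(T))
            constraint = {"ion": "H+", "T": T, "value": float(hplus_volume(T))}
        vals.append(val); ses.append(float(se)); kept.append(spec)
    if not kept:
        raise ValueError("no usable solutes")
    present = {ion for spec in kept for ion in spec.ions if ion != "H+"}
    if ions is None:
        ion_order = tuple(i for i in ION_ORDER if i in present)
        ion_order += tuple(sorted(present - set(ion_order)))
    else:
        ion_order = tuple(ions)
        missing = set(ion_order) - present
        if missing:
            raise ValueError(f"ions never observed in any solute: {sorted(missing)}")
    design = np.array([spec.counts(ion_order) for spec in kept])
    return AdditivitySystem(
        salts=kept, values=np.array(vals), ses=np.array(ses),
        design=design, ions=ion_order, constraint=constraint,
    )


def decompose_at_T(system: AdditivitySystem) -> dict:
    """Weighted least squares solution of a (constrained) additivity system.

    Weights are 1/SE²; the covariance is the weighted normal-equations
    inverse scaled by the reduced chi-square.  Raises on rank deficiency
    (build the system with HCl + the proton constraint to avoid it).
    """
    A, y, se = system.design, system.values, system.ses
    if system.rank < len(system.ions):
        ns = system.null_space()
        raise np.linalg.LinAlgError(
            f"additivity system has rank {system.rank} < {len(system.ions)}; "
            f"null direction ~ {np.round(ns[:, 0] / ns[np.argmax(np.abs(ns[:, 0])), 0], 3).tolist()}"
        )
    w = 1.0 / se**2
    Aw = A * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    cov_unit = np.linalg.inv(Aw.T @ Aw)
    est = cov_unit @ Aw.T @ yw
    resid = y - A @ est
    dof = len(y) - len(system.ions)
    chi2 = float(np.sum(w * resid**2))
    # Scale by reduced chi-square so SEs reflect actual scatter (floor at
    # 1 keeps stated input SEs authoritative for consistent systems).
    s2 = max(chi2 / dof, 1.0) if dof > 0 else 1.0
    cov = cov_unit * s2
    return {
        "ions": dict(zip(system.ions, est)),
        "se": dict(zip(system.ions, np.sqrt(np.diag(cov)))),
        "covariance": cov,
        "residuals": {s.name: float(r) for s, r in zip(system.salts, resid)},
        "chi2": chi2,
        "dof": dof,
        "constraint": system.constraint,
    }


# --------------------------------------------------------------------------
# Grand fit on raw densities

@dataclass
class IonVolumeSet:
    """Self-consistent per-ion thermal-volume models plus the proton pin."""

    models: dict[str, ThermalVolumeModel]
    hplus: ThermalVolumeModel = field(default_factory=hplus_model)
    method: str = "global"
    covariance: np.ndarray | None = None  # 24x24, ion-major (V, alpha, beta)
    residual_sd: float | None = None
    n_obs: int | None = None

    def volume(self, ion: str, T: float) -> float:
        if ion == "H+":
            return float(self.hplus.value_at(T))
        return float(self.models[ion].value_at(T))

    def salt_volume(self, salt: SaltSpec, T: float) -> float:
        return sum(n * self.volume(ion, T) for ion, n, _ in salt.components)

    def table(self, temperatures: Sequence[float] = (20, 25, 30, 35, 40)) -> "pd.DataFrame":
        """Ions x temperatures table with derivative rows and T_extr."""
        import pandas as pd

        from .density import extremum_temperature

        cols = ("H+",) + tuple(self.models)
        rows = {}
        for T in temperatures:
            rows[f"{T:g} C"] = [self.volume(ion, T) for ion in cols]
        rows["dV/dT(25) x1e-3"] = [
            1e3 * (self.hplus if ion == "H+" else self.models[ion]).derivative_at(25.0)
            for ion in cols]
        rows["beta x1e-3"] = [
            1e3 * (self.hplus if ion == "H+" else self.models[ion]).beta
            for ion in cols]
        textr = []
        for ion in cols:
            mod = self.hplus if ion == "H+" else self.models[ion]
            ext = extremum_temperature(mod)
            textr.append(float("nan") if ext is None else ext[0])
        rows["T_extr"] = textr
        return pd.DataFrame(rows, index=cols).T


def global_ionic_fit(
    records: Sequence[DensityRecord],
    registry: Mapping[str, SaltSpec] = SALTS,
    ctx: ReferenceContext | None = None,
    T_ref: float = 25.0,
) -> IonVolumeSet:
    """One nonlinear least squares over every solute's raw densities.

    Parameters: (V_ref, alpha, beta) for each of the 8 ions, plus one
    solvent-density offset per (solute, series, temperature) cell.  Each
    record's predicted density is built from the additive salt volume
    (with H+ fixed to the Marcus polynomial) plus the Debye-Hückel term.
    """
    ctx = ctx or default_context()
    records = list(records)
    if len({r.T for r in records}) < 3:
        raise ValueError("unidentifiable beta: need >= 3 temperatures")

    n_ion = len(ION_ORDER)
    m = np.array([r.m for r in records])
    T = np.array([r.T for r in records])
    dobs = np.array([r.d for r in records])
    specs = [registry[r.solute] for r in records]
    C = np.array([s.counts(ION_ORDER) for s in specs])          # counts
    if not (C.sum(axis=0) > 0).all():
        missing = [ion for ion, tot in zip(ION_ORDER, C.sum(axis=0)) if tot == 0]
        raise ValueError(f"unidentifiable ions (never observed): {missing}")
    nH = np.array([sum(n for ion, n, _ in s.components if ion == "H+")
                   for s in specs])
    if not nH.any():
        # no HCl rows: check the charge direction is actually constrained
        raise np.linalg.LinAlgError(
            "rank-deficient ionic design: without an H+-containing solute the "
            "charge vector direction is unidentifiable"
        )
    Mmass = np.array([s.M for s in specs])
    omega = np.array([s.omega for s in specs])
    cells = sorted({(r.solute, r.series_id, r.T) for r in records})
    cix = {c: i for i, c in enumerate(cells)}
    idx = np.array([cix[(r.solute, r.series_id, r.T)] for r in records])
    n_cells = len(cells)

    d0T = np.asarray(ctx.d0(T), dtype=float)
    avT = np.asarray(ctx.av(T), dtype=float)
    dh = avT * omega * np.log1p(ctx.b * np.sqrt(omega * m)) / ctx.b
    dT = T - T_ref
    vH = np.asarray(hplus_volume(T), dtype=float) * nH

    def resid(p):
        V, a, b = p[:n_ion], p[n_ion:2 * n_ion], p[2 * n_ion:3 * n_ion]
        vsalt = C @ V + (C @ a) * dT + (C @ b) * dT**2 + vH
        d0p = d0T + p[3 * n_ion:][idx]
        denom = 1.0 - m * (Mmass - d0p * (vsalt + dh)) / 1e3
        return d0p / denom - dobs

    # start from per-record apparent volumes solved ion-wise by ordinary LS
    from .density import apparent_rhs
    vpsi0 = apparent_rhs(dobs, d0T, m, Mmass) - dh - vH
    start, *_ = np.linalg.lstsq(C, vpsi0, rcond=None)
    p0 = np.zeros(3 * n_ion + n_cells)
    p0[:n_ion] = start
    sol = optimize.least_squares(resid, p0, method="lm", xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12, max_nfev=200000)
    if not sol.success:
        raise RuntimeError(f"global ionic fit did not converge: {sol.message}")
    n, k = len(records), len(p0)
    rss = float(np.sum(sol.fun**2))
    jtj = sol.jac.T @ sol.jac
    sv = np.linalg.svd(jtj, compute_uv=False)
    if sv[-1] < 1e-12 * sv[0]:
        raise np.linalg.LinAlgError("rank-deficient global ionic design")
    s2 = rss / max(n - k, 1)
    cov_full = np.linalg.inv(jtj) * s2

    models = {}
    order = np.empty(3 * n_ion, dtype=int)
    for i, ion in enumerate(ION_ORDER):
        sel = [i, n_ion + i, 2 * n_ion + i]
        order[3 * i: 3 * i + 3] = sel
        models[ion] = ThermalVolumeModel(
            V_ref=float(sol.x[i]), alpha=float(sol.x[n_ion + i]),
            beta=float(sol.x[2 * n_ion + i]), T_ref=T_ref,
            covariance=cov_full[np.ix_(sel, sel)],
        )
    cov_ion = cov_full[np.ix_(order, order)]
    return IonVolumeSet(models=models, method="global", covariance=cov_ion,
                        residual_sd=math.sqrt(s2), n_obs=n)


def per_t_ionic_fit(
    salt_fits: Mapping[str, "SaltFitResult"],
    temperatures: Sequence[float] = (20.0, 25.0, 30.0, 35.0, 40.0),
    registry: Mapping[str, SaltSpec] = SALTS,
    T_ref: float = 25.0,
) -> IonVolumeSet:
    """Two-stage route: per-temperature decompositions + quadratic refit.

    At each temperature the fitted salt models are evaluated (with
    propagated SEs) and decomposed by weighted least squares; each ion's
    volumes across temperatures are then refitted with the quadratic
    thermal-expansion law.  Agrees with :func:`global_ionic_fit` within
    statistical scatter on additive data.
    """
    per_t: dict[float, dict] = {}
    for T in temperatures:
        values = {}
        for name, fit in salt_fits.items():
            mod = fit.model
            dT = T - mod.T_ref
            g = np.array([1.0, dT, dT * dT])
            var = float(g @ mod.covariance @ g) if mod.covariance is not None else 0.0
            values[name] = (float(mod.value_at(T)), math.sqrt(max(var, 1e-12)))
        per_t[T] = decompose_at_T(build_system(values, T=T, registry=registry))
    models = {}
    for ion in ION_ORDER:
        Ts = np.array(list(per_t))
        y = np.array([per_t[T]["ions"][ion] for T in per_t])
        se = np.array([per_t[T]["se"][ion] for T in per_t])
        dT = Ts - T_ref
        X = np.column_stack([np.ones_like(dT), dT, dT**2])
        w = 1.0 / se**2
        Xw = X * np.sqrt(w)[:, None]
        cov = np.linalg.inv(Xw.T @ Xw)
        coef = cov @ Xw.T @ (y * np.sqrt(w))
        models[ion] = ThermalVolumeModel(
            V_ref=float(coef[0]), alpha=float(coef[1]), beta=float(coef[2]),
            T_ref=T_ref, covariance=cov)
    return IonVolumeSet(models=models, method="per-T")


def curvature_contrast(
    betas: Mapping[str, tuple[float, float]] | IonVolumeSet,
    cations: Sequence[str] = CATIONS,
    anions: Sequence[str] = ANIONS,
    method: Literal["z", "welch"] = "z",
) -> dict:
    """Contrast of V2(T) curvature between cations and anions.

    Accepts either a mapping ion -> (beta, SE) or an
    :class:`IonVolumeSet`.  Default is a two-sided z-test on the
    inverse-variance-weighted group means of the quadratic coefficients
    (the study names no test; this is a reconstruction).  ``welch`` runs
    an unweighted Welch t-test on the coefficients instead.
    """
    if isinstance(betas, IonVolumeSet):
        bmap = {}
        for ion, mod in betas.models.items():
            se = mod.se()
            bmap[ion] = (mod.beta, se[2] if se else float("nan"))
        betas = bmap
    if len(cations) < 2 or len(anions) < 2:
        raise ValueError("need >= 2 ions per group")
    bc = np.array([betas[i][0] for i in cations])
    sc = np.array([betas[i][1] for i in cations])
    ba = np.array([betas[i][0] for i in anions])
    sa = np.array([betas[i][1] for i in anions])
    if np.any(sc <= 0) or np.any(sa <= 0):
        raise ValueError("degenerate test: zero/negative SE input")
    signs = {
        "cations_positive": int(np.sum(bc > 0)),
        "anions_negative": int(np.sum(ba < 0)),
        "n_cations": len(bc),
        "n_anions": len(ba),
    }
    if method == "z":
        wc, wa = 1.0 / sc**2, 1.0 / sa**2
        mc, ma = np.sum(wc * bc) / np.sum(wc), np.sum(wa * ba) / np.sum(wa)
        se_diff = math.sqrt(1.0 / np.sum(wc) + 1.0 / np.sum(wa))
        z = (mc - ma) / se_diff
        p = 2.0 * float(stats.norm.sf(abs(z)))
        return {"method": "weighted-z", "statistic": float(z), "p": p,
                "mean_cation_beta": float(mc), "mean_anion_beta": float(ma),
                "signs": signs}
    t, p = stats.ttest_ind(bc, ba, equal_var=False)
    return {"method": "welch-t", "statistic": float(t), "p": float(p),
            "mean_cation_beta": float(np.mean(bc)),
            "mean_anion_beta": float(np.mean(ba)), "signs": signs}
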