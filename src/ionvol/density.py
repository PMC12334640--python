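"""Dilute-electrolyte density model and the global per-salt fit.

The measured side of the working equation is the apparent molar volume

    V_phi(m, T) = M/d0 - 1e3/(d*d0) * (d - d0)/m

which the Pitzer-type Debye-Hückel correction maps onto the
infinite-dilution volume:

    V2(T) + Av(T) * omega * ln(1 + b*sqrt(omega*m)) / b = V_phi(m, T)

with a quadratic thermal expansion V2(T) = V_ref + alpha*(T-T_ref) +
beta*(T-T_ref)^2.  Solving for d gives the closed-form density predictor
used both for fitting and for the synthetic generator.  Each dilution
series at each temperature carries a local solvent-density offset
delta_d0, fitted jointly with the three global parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .reference import ReferenceContext, SaltSpec, default_context

__all__ = [
    "DensityRecord",
    "ThermalVolumeModel",
    "SaltFitResult",
    "apparent_rhs",
    "dh_term",
    "extremum_temperature",
    "fit_salt",
    "predict_density",
    "read_density_csv",
    "records_to_frame",
    "write_density_csv",
]

#: Declared densimeter precision, g/cm³ (diagnostic yardstick).
INSTRUMENT_SD = 7e-6
#: Reported ceiling on per-series solvent-density offsets, g/cm³.
DELTA_D0_CEILING = 2e-5

CSV_COLUMNS = ["solute", "series_id", "temperature_C",
               "molality_mol_kg", "density_g_cm3"]


@dataclass(frozen=True)
class DensityRecord:
    """One densimeter observation."""

    solute: str
    series_id: str
    T: float
    m: float
    d: float

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"{self.solute}/{self.series_id}: molality must be > 0")
        if self.d <= 0:
            raise ValueError(f"{self.solute}/{self.series_id}: density must be > 0")
        if not 20.0 <= self.T <= 40.0:
            warnings.warn(
                f"record at {self.T} °C is outside the 20-40 °C study range",
                stacklevel=2,
            )


@dataclass
class ThermalVolumeModel:
    """Quadratic temperature dependence of a partial molar volume.

    ``value_at(T) = V_ref + alpha*(T - T_ref) + beta*(T - T_ref)**2``;
    ``covariance`` (3x3, order V_ref/alpha/beta) is optional.
    """

    V_ref: float
    alpha: float = 0.0
    beta: float = 0.0
    T_ref: float = 25.0
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.covariance is not None:
            c = np.asarray(self.covariance, dtype=float)
            if c.shape != (3, 3) or not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("covariance must be a symmetric 3x3 matrix")
            if np.min(np.linalg.eigvalsh((c + c.T) / 2)) < -1e-8 * max(1.0, np.trace(c)):
                raise ValueError("covariance must be positive semidefinite")
            self.covariance = c

    def value_at(self, T: float | np.ndarray) -> float | np.ndarray:
        dT = np.asarray(T, dtype=float) - self.T_ref
        out = self.V_ref + self.alpha * dT + self.beta * dT**2
        return float(out) if out.ndim == 0 else out

    def derivative_at(self, T: float) -> float:
        return self.alpha + 2.0 * self.beta * (T - self.T_ref)

    def se(self) -> tuple[float, float, float] | None:
        if self.covariance is None:
            return None
        return tuple(np.sqrt(np.diag(self.covariance)))


def extremum_temperature(
    model: ThermalVolumeModel, T_range: tuple[float, float] = (20.0, 40.0)
) -> tuple[float, bool] | None:
    """Vertex of the V2(T) parabola, or None when the model is linear.

    Returns ``(T_extr, extrapolated)`` where the flag marks a vertex
    outside ``T_range`` (an extrapolation beyond the measurements).
    """
    if model.beta == 0.0:
        return None
    T = model.T_ref - model.alpha / (2.0 * model.beta)
    return T, not (T_range[0] <= T <= T_range[1])


def dh_term(
    m: float | np.ndarray,
    omega: float,
    T: float | np.ndarray,
    ctx: ReferenceContext | None = None,
) -> float | np.ndarray:
    """Debye-Hückel volume correction Av*omega*ln(1 + b*sqrt(omega*m))/b."""
    ctx = ctx or default_context()
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("molality must be non-negative")
    if omega < 1:
        raise ValueError("valence factor must be >= 1")
    av = ctx.av(T)
    out = av * omega * np.log1p(ctx.b * np.sqrt(omega * m)) / ctx.b
    return float(out) if np.ndim(out) == 0 else out


def apparent_rhs(
    d: float | np.ndarray, d0: float | np.ndarray,
    m: float | np.ndarray, M: float,
) -> float | np.ndarray:
    """Measured side of the working equation: M/d0 - 1e3*(d-d0)/(d*d0*m)."""
    d = np.asarray(d, float); d0 = np.asarray(d0, float); m = np.asarray(m, float)
    if np.any(m == 0):
        raise ZeroDivisionError("apparent molar volume is singular at m = 0")
    if np.any(d <= 0) or np.any(d0 <= 0):
        raise ValueError("densities must be positive")
    out = M / d0 - 1e3 / (d * d0) * (d - d0) / m
    return float(out) if out.ndim == 0 else out


def predict_density(
    m: float | np.ndarray,
    T: float | np.ndarray,
    model: ThermalVolumeModel,
    salt: SaltSpec,
    delta_d0: float | np.ndarray = 0.0,
    ctx: ReferenceContext | None = None,
) -> float | np.ndarray:
    """Closed-form inversion of the working equation to solution density.

    d = d0' / (1 - m*(M - d0'*V_psi)/1e3) with d0' = d0_ref(T) + delta_d0
    and V_psi = V2(T) + dh_term(m).  Exact inverse of
    :func:`apparent_rhs`; returns d0' at m = 0.
    """
    ctx = ctx or default_context()
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("molality must be non-negative")
    d0p = np.asarray(ctx.d0(T), dtype=float) + delta_d0
    vpsi = model.value_at(T) + dh_term(m, salt.omega, T, ctx)
    denom = 1.0 - m * (salt.M - d0p * vpsi) / 1e3
    if np.any(denom <= 0):
        raise ValueError("nonphysical parameters: density denominator <= 0")
    out = d0p / denom
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Global per-salt fit

@dataclass
class SaltFitResult:
    """Outcome of the joint fit of one solute across series and temperatures."""

    salt: SaltSpec
    model: ThermalVolumeModel
    model_linear: ThermalVolumeModel
    delta_d0: dict[tuple[str, float], float]
    residual_sd: float
    n_obs: int
    aic_linear: float
    aic_quadratic: float
    f_test_p: float
    selected_order: Literal["linear", "quadratic"]
    delta_d0_flags: list[tuple[str, float]] = field(default_factory=list)

    def report(self) -> dict:
        """JSON-serializable fit report."""
        se = self.model.se()
        return {
            "solute": self.salt.name,
            "selected_order": self.selected_order,
            "V_ref": self.model.V_ref,
            "alpha": self.model.alpha,
            "beta": self.model.beta,
            "T_ref": self.model.T_ref,
            "se": list(se) if se else None,
            "covariance": (self.model.covariance.tolist()
                           if self.model.covariance is not None else None),
            "delta_d0": {f"{s}@{t:g}C": v for (s, t), v in self.delta_d0.items()},
            "delta_d0_flagged": [f"{s}@{t:g}C" for s, t in self.delta_d0_flags],
            "residual_sd": self.residual_sd,
            "instrument_sd": INSTRUMENT_SD,
            "n_obs": self.n_obs,
            "aic": {"linear": self.aic_linear, "quadratic": self.aic_quadratic},
            "f_test_p_beta": self.f_test_p,
        }


def records_to_frame(records: Iterable[DensityRecord]) -> pd.DataFrame:
    rows = [(r.solute, r.series_id, r.T, r.m, r.d) for r in records]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def read_density_csv(path: str | Path) -> list[DensityRecord]:
    """Read observations from the tidy CSV dialect (header required)."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"density CSV missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(DensityRecord(
                solute=str(row["solute"]), series_id=str(row["series_id"]),
                T=float(row["temperature_C"]), m=float(row["molality_mol_kg"]),
                d=float(row["density_g_cm3"]),
            ))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return out


def write_density_csv(records: Iterable[DensityRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _design(records: Sequence[DensityRecord]):
    """Arrays + (series, T) cell indexing for a single solute."""
    m = np.array([r.m for r in records])
    T = np.array([r.T for r in records])
    cells = sorted({(r.series_id, r.T) for r in records})
    cell_ix = {c: i for i, c in enumerate(cells)}
    idx = np.array([cell_ix[(r.series_id, r.T)] for r in records])
    d = np.array([r.d for r in records])
    return m, T, d, idx, cells


def _check_identifiable(records, cells, order):
    temps = sorted({r.T for r in records})
    per_cell = {}
    for r in records:
        per_cell.setdefault((r.series_id, r.T), set()).add(r.m)
    thin = [c for c, ms in per_cell.items() if len(ms) < 2]
    if thin:
        raise ValueError(
            "unidentifiable delta_d0: cells with fewer than two molalities: "
            f"{thin[:3]}"
        )
    if order in ("linear", "quadratic") and len(temps) < 2:
        raise ValueError("unidentifiable alpha: need >= 2 temperatures")
    if order == "quadratic" and len(temps) < 3:
        raise ValueError("unidentifiable beta: need >= 3 temperatures")


def _fit_order(m, T, d, idx, n_cells, salt, ctx, T_ref, order):
    n_glob = 2 if order == "linear" else 3
    d0T = np.asarray(ctx.d0(T), dtype=float)
    avT = np.asarray(ctx.av(T), dtype=float)
    dh = avT * salt.omega * np.log1p(ctx.b * np.sqrt(salt.omega * m)) / ctx.b
    dT = T - T_ref

    def resid(p):
        v2 = p[0] + p[1] * dT + (p[2] * dT**2 if n_glob == 3 else 0.0)
        d0p = d0T + p[n_glob:][idx]
        denom = 1.0 - m * (salt.M - d0p * (v2 + dh)) / 1e3
        return d0p / denom - d

    # two-point start for V_ref from the extreme molalities at one cell
    j_lo, j_hi = int(np.argmin(m)), int(np.argmax(m))
    v0 = float(np.mean(apparent_rhs(d[[j_lo, j_hi]], d0T[[j_lo, j_hi]],
                                    m[[j_lo, j_hi]], salt.M) - dh[[j_lo, j_hi]]))
    p0 = np.zeros(n_glob + n_cells)
    p0[0] = v0
    sol = optimize.least_squares(resid, p0, method="lm", xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12, max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"{salt.name}: {order} fit did not converge: {sol.message}")
    n, k = len(d), n_glob + n_cells
    rss = float(np.sum(sol.fun**2))
    jtj = sol.jac.T @ sol.jac
    sv = np.linalg.svd(jtj, compute_uv=False)
    if sv[-1] < 1e-12 * sv[0]:
        raise ValueError(f"{salt.name}: rank-deficient design in {order} fit")
    s2 = rss / max(n - k, 1)
    cov = np.linalg.inv(jtj) * s2
    aic = n * math.log(rss / n) + 2 * k
    return sol.x, cov, rss, aic, n_glob


def fit_salt(
    records: Sequence[DensityRecord],
    salt: SaltSpec,
    ctx: ReferenceContext | None = None,
    model_order: Literal["linear", "quadratic", "auto"] = "auto",
    T_ref: float = 25.0,
) -> SaltFitResult:
    """Joint nonlinear least squares for one solute.

    Global parameters (V_ref, alpha[, beta]) are shared across all
    dilution series and temperatures; one solvent-density offset
    delta_d0 is fitted per (series, temperature) cell.  Linear and
    quadratic thermal-expansion variants are both fitted; ``auto``
    selects the quadratic model when both the AIC and the extra
    sum-of-squares F-test (alpha = 0.05) favor it.
    """
    ctx = ctx or default_context()
    records = list(records)
    if not records:
        raise ValueError("no records")
    solutes = {r.solute for r in records}
    if solutes != {salt.name}:
        raise ValueError(f"records mention {sorted(solutes)}, expected {salt.name}")
    m, T, d, idx, cells = _design(records)
    _check_identifiable(records, cells,
                        "quadratic" if model_order != "linear" else "linear")
    n_cells = len(cells)
    n = len(records)

    p_lin, cov_lin, rss_lin, aic_lin, _ = _fit_order(
        m, T, d, idx, n_cells, salt, ctx, T_ref, "linear")
    p_quad, cov_quad, rss_quad, aic_quad, _ = _fit_order(
        m, T, d, idx, n_cells, salt, ctx, T_ref, "quadratic")

    k_quad = 3 + n_cells
    df_den = n - k_quad
    f_stat = max(rss_lin - rss_quad, 0.0) / (rss_quad / df_den)
    f_p = float(stats.f.sf(f_stat, 1, df_den))

    if model_order == "auto":
        selected = "quadratic" if (aic_quad < aic_lin and f_p < 0.05) else "linear"
    else:
        selected = model_order

    def pack(p, cov, n_glob):
        cov3 = np.zeros((3, 3))
        cov3[:n_glob, :n_glob] = cov[:n_glob, :n_glob]
        model = ThermalVolumeModel(
            V_ref=float(p[0]), alpha=float(p[1]),
            beta=float(p[2]) if n_glob == 3 else 0.0,
            T_ref=T_ref, covariance=cov3)
        dd0 = {c: float(p[n_glob + i]) for i, c in enumerate(cells)}
        return model, dd0

    model_lin, dd0_lin = pack(p_lin, cov_lin, 2)
    model_quad, dd0_quad = pack(p_quad, cov_quad, 3)
    if selected == "quadratic":
        model, dd0, rss, k = model_quad, dd0_quad, rss_quad, k_quad
    else:
        model, dd0, rss, k = model_lin, dd0_lin, rss_lin, 2 + n_cells

    flags = [c for c, v in dd0.items() if abs(v) > DELTA_D0_CEILING]
    return SaltFitResult(
        salt=salt, model=model, model_linear=model_lin, delta_d0=dd0,
        residual_sd=math.sqrt(rss / max(n - k, 1)), n_obs=n,
        aic_linear=aic_lin, aic_quadratic=aic_quad, f_test_p=f_p,
        selected_order=selected, delta_d0_flags=flags,
    )
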