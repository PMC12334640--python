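"""Solvation-shell analysis of ion-centered water snapshots.

Works on multi-frame XYZ (or multi-MODEL PDB) files holding one ion and
rigid three-site waters in a cubic periodic box.  Provides per-water
orientation records (d, theta), 2D distance-angle density maps (raw and
Jacobian-corrected), cumulative sphere-volume curves V(N), and the
global-slope intercept estimator of ionic partial molar volume: with the
35 waters nearest the ion excluded, mean sphere volume grows linearly in
the enclosed water count N; the shared slope is the bulk molecular volume
of water and each ion's intercept estimates its own partial molar volume.

All coordinates are in Å; angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "SolvationSnapshot",
    "VNCurve",
    "density_map",
    "fit_vn_global",
    "min_image",
    "orientation_records",
    "read_snapshots",
    "vn_curve",
    "write_xyz",
]


def min_image(vec: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image displacement(s) in a cubic periodic box."""
    return vec - box_edge * np.round(vec / box_edge)


@dataclass
class SolvationSnapshot:
    """One frame: ion (reference-atom) position plus rigid waters."""

    box_edge: float
    ion_position: np.ndarray           # (3,)
    O: np.ndarray                      # (n, 3) water oxygens
    H1: np.ndarray                     # (n, 3)
    H2: np.ndarray                     # (n, 3)
    reference_atom_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    @property
    def n_waters(self) -> int:
        return len(self.O)

    def validate(self) -> None:
        """Check coordinate sanity and O-H bond lengths (minimum-image)."""
        for arr in (self.ion_position, self.O, self.H1, self.H2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite coordinates")
        for H in (self.H1, self.H2):
            r = np.linalg.norm(min_image(H - self.O, self.box_edge), axis=1)
            if np.any((r < 0.8) | (r > 1.3)):
                bad = int(np.argmax((r < 0.8) | (r > 1.3)))
                raise ValueError(
                    f"water {bad}: O-H distance {r[bad]:.3f} Å outside (0.8, 1.3)")


# --------------------------------------------------------------------------
# I/O — simple text exchange formats

def write_xyz(snapshots: Iterable[SolvationSnapshot], path: str | Path,
              ion_label: str = "ION") -> None:
    """Write frames as multi-frame XYZ; box edge goes in the comment line."""
    with open(path, "w") as fh:
        for snap in snapshots:
            fh.write(f"{1 + 3 * snap.n_waters}\n")
            fh.write(f"box={snap.box_edge:.6f}\n")
            x, y, z = snap.ion_position
            fh.write(f"{ion_label} {x:.6f} {y:.6f} {z:.6f}\n")
            for o, h1, h2 in zip(snap.O, snap.H1, snap.H2):
                fh.write(f"OW {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
                fh.write(f"HW1 {h1[0]:.6f} {h1[1]:.6f} {h1[2]:.6f}\n")
                fh.write(f"HW2 {h2[0]:.6f} {h2[1]:.6f} {h2[2]:.6f}\n")


def _frame_from_atoms(atoms, box_edge, frame_no, validate):
    ion = None
    O, H1, H2 = [], [], []
    pending_h = 0
    for label, xyz in atoms:
        lab = label.upper()
        if lab in ("OW", "O"):
            if pending_h:
                raise ValueError(f"frame {frame_no}: unpaired hydrogens before {lab}")
            O.append(xyz); pending_h = 2
        elif lab in ("HW1", "HW2", "H"):
            if pending_h == 0:
                raise ValueError(f"frame {frame_no}: hydrogen without an oxygen")
            (H1 if pending_h == 2 else H2).append(xyz)
            pending_h -= 1
        else:
            if ion is not None:
                raise ValueError(f"frame {frame_no}: multiple ion records")
            ion = xyz
    if pending_h:
        raise ValueError(f"frame {frame_no}: unpaired hydrogens at end of frame")
    if ion is None:
        raise ValueError(f"frame {frame_no}: no ion record found")
    snap = SolvationSnapshot(
        box_edge=box_edge, ion_position=np.asarray(ion),
        O=np.array(O).reshape(-1, 3), H1=np.array(H1).reshape(-1, 3),
        H2=np.array(H2).reshape(-1, 3))
    if validate:
        snap.validate()
    return snap


def read_snapshots(
    path: str | Path,
    fmt: Literal["xyz", "pdb-multimodel"] = "xyz",
    validate: bool = True,
) -> Iterator[SolvationSnapshot]:
    """Lazily yield validated snapshots from a trajectory file.

    XYZ dialect: count line; comment line carrying ``box=<edge>``;
    then ``<label> x y z`` records where labels are the ion (anything
    that is not OW/HW1/HW2) and OW/HW1/HW2 triplets.  The PDB reader
    takes the box edge from CRYST1 and frames from MODEL/ENDMDL.
    """
    if fmt == "xyz":
        yield from _read_xyz(path, validate)
    elif fmt == "pdb-multimodel":
        yield from _read_pdb(path, validate)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _read_xyz(path, validate):
    with open(path) as fh:
        frame_no = 0
        while True:
            header = fh.readline()
            if not header.strip():
                return
            n_atoms = int(header)
            comment = fh.readline()
            box = None
            for token in comment.split():
                if token.startswith("box="):
                    box = float(token[4:])
            if box is None:
                raise ValueError(
                    f"frame {frame_no}: comment line lacks 'box=<edge>'")
            atoms = []
            for _ in range(n_atoms):
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise ValueError(f"frame {frame_no}: truncated atom record")
                atoms.append((parts[0], np.array([float(p) for p in parts[1:4]])))
            yield _frame_from_atoms(atoms, box, frame_no, validate)
            frame_no += 1


def _read_pdb(path, validate):
    box = None
    atoms: list = []
    frame_no = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "CRYST1":
                box = float(line[6:15])
            elif rec == "MODEL":
                in_model, atoms = True, []
            elif rec in ("ATOM", "HETATM"):
                name = line[12:16].strip()
                xyz = np.array([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
                atoms.append((name, xyz))
            elif rec == "ENDMDL":
                if box is None:
                    raise ValueError("PDB lacks a CRYST1 box record")
                yield _frame_from_atoms(atoms, box, frame_no, validate)
                frame_no += 1
                in_model = False
    if atoms and in_model:
        raise ValueError(f"frame {frame_no}: MODEL without ENDMDL")


# --------------------------------------------------------------------------
# Orientation records and maps

def orientation_records(
    snapshot: SolvationSnapshot,
    r_max: float = 12.5,
    q_mode: Literal["h-midpoint", "com"] = "h-midpoint",
) -> np.ndarray:
    """Per-water (d, theta) orientation records within ``r_max`` of the ion.

    ``d`` is the minimum-image ion-oxygen distance; ``theta`` the angle at
    the oxygen vertex between O->ion and O->Q, where Q is the hydrogen
    midpoint (``h-midpoint``, default) or the molecular center of mass
    (``com``).  Returns a structured array with fields ``d``, ``theta``.
    """
    if r_max > snapshot.box_edge / 2 + 1e-9:
        raise ValueError(
            f"r_max={r_max} exceeds half the box edge "
            f"({snapshot.box_edge / 2}); minimum image is ambiguous")
    L = snapshot.box_edge
    ref = snapshot.ion_position + snapshot.reference_atom_offset
    to_ion = min_image(ref - snapshot.O, L)        # O -> ion
    d = np.linalg.norm(to_ion, axis=1)
    sel = d <= r_max
    to_ion, d = to_ion[sel], d[sel]
    h1 = min_image(snapshot.H1[sel] - snapshot.O[sel], L)
    h2 = min_image(snapshot.H2[sel] - snapshot.O[sel], L)
    if q_mode == "h-midpoint":
        to_q = 0.5 * (h1 + h2)
    else:  # O + H + H center of mass relative to O
        to_q = (1.00784 * (h1 + h2)) / (15.999 + 2 * 1.00784)
    cosang = np.einsum("ij,ij->i", to_ion, to_q) / (
        d * np.linalg.norm(to_q, axis=1))
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    out = np.empty(len(d), dtype=[("d", float), ("theta", float)])
    out["d"], out["theta"] = d, theta
    return out


def density_map(
    records: np.ndarray,
    d_bins: np.ndarray,
    theta_bins: np.ndarray,
    corrected: bool = False,
    farfield_fraction: float = 2.0 / 3.0,
) -> np.ndarray:
    """2D histogram of (d, theta) records, optionally Jacobian-corrected.

    Raw mode returns counts.  Corrected mode divides each bin by its
    integrated isotropic-gas measure, (d2³ - d1³)/3 · (cos t1 - cos t2),
    and rescales so the mean over occupied far-field bins (lower d edge
    >= ``farfield_fraction`` of the outermost edge) equals 1 — a flat
    corrected map means ideal-gas-like water at that distance.
    """
    if len(records) == 0:
        raise ValueError("no orientation records")
    d_bins = np.asarray(d_bins, float)
    theta_bins = np.asarray(theta_bins, float)
    for edges, name in ((d_bins, "d_bins"), (theta_bins, "theta_bins")):
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    counts, _, _ = np.histogram2d(records["d"], records["theta"],
                                  bins=[d_bins, theta_bins])
    if not corrected:
        return counts
    dvol = np.diff(d_bins**3) / 3.0
    avol = np.cos(np.radians(theta_bins[:-1])) - np.cos(np.radians(theta_bins[1:]))
    jac = np.outer(dvol, avol)
    dens = np.where(jac > 0, counts / np.where(jac > 0, jac, 1.0), np.nan)
    far = d_bins[:-1] >= farfield_fraction * d_bins[-1]
    ref_cells = dens[far][(counts[far] > 0) & np.isfinite(dens[far])]
    scale = np.mean(ref_cells) if len(ref_cells) else 1.0
    return dens / scale


# --------------------------------------------------------------------------
# V(N) curves and the global intercept estimator

@dataclass
class VNCurve:
    """Mean sphere volume vs. enclosed water count, aggregated over frames."""

    N: np.ndarray
    V_mean: np.ndarray       # Å³
    V_se: np.ndarray
    n_frames: int
    mean_radius: np.ndarray  # Å, mean d_(N) across frames
    box_edge: float


def vn_curve(
    snapshots: Iterable[SolvationSnapshot],
    N_max: int | None = None,
) -> VNCurve:
    """Cumulative-volume curve: V_N = (4/3)π d_(N)³ per frame, averaged.

    ``d_(N)`` is the Nth-smallest minimum-image ion-oxygen distance.  The
    curve runs to ``N_max``, capped at the smallest per-frame count of
    waters within the minimum-image-valid radius (box/2); exceeding that
    cap raises with the admissible maximum.
    """
    sum_v = sumsq_v = sum_d = None
    n_frames = 0
    min_valid = None
    box = None
    for snap in snapshots:
        box = snap.box_edge
        ref = snap.ion_position + snap.reference_atom_offset
        d = np.sort(np.linalg.norm(min_image(ref - snap.O, box), axis=1))
        n_valid = int(np.searchsorted(d, box / 2, side="right"))
        min_valid = n_valid if min_valid is None else min(min_valid, n_valid)
        cap = N_max if N_max is not None else min_valid
        if len(d) < cap:
            raise ValueError(
                f"frame {n_frames}: only {len(d)} waters, N_max={cap} unreachable")
        v = (4.0 / 3.0) * math.pi * d[:cap] ** 3
        if sum_v is None:
            k = cap
            sum_v, sumsq_v, sum_d = (np.zeros(k) for _ in range(3))
        k = min(len(sum_v), cap)
        sum_v, sumsq_v, sum_d = sum_v[:k], sumsq_v[:k], sum_d[:k]
        sum_v += v[:k]; sumsq_v += v[:k] ** 2; sum_d += d[:k]
        n_frames += 1
    if n_frames == 0:
        raise ValueError("no snapshots")
    if N_max is not None and N_max > min_valid:
        raise ValueError(
            f"N_max={N_max} exceeds the minimum-image-valid water count; "
            f"admissible maximum is {min_valid}")
    mean = sum_v / n_frames
    var = np.maximum(sumsq_v / n_frames - mean**2, 0.0)
    se = np.sqrt(var / max(n_frames - 1, 1))
    k = len(mean)
    return VNCurve(N=np.arange(1, k + 1), V_mean=mean, V_se=se,
                   n_frames=n_frames, mean_radius=sum_d / n_frames,
                   box_edge=box)


def fit_vn_global(
    curves: Mapping[str, VNCurve],
    N_skip: int = 35,
    N_max: int | None = None,
) -> dict:
    """Joint linear fit V = a·N + c_ion with one shared slope.

    Points with N <= ``N_skip`` (perturbed solvation shells) and points
    whose mean radius reaches half the box edge are excluded.  Returns
    the shared slope (bulk water molecular volume, Å³), per-ion
    intercepts (ionic volume estimates, Å³) and their SEs from the
    unweighted normal-equations covariance, plus per-ion diagnostics.
    """
    names = list(curves)
    rows_x, rows_y, ion_ix = [], [], []
    for j, name in enumerate(names):
        c = curves[name]
        use = (c.N > N_skip) & (c.mean_radius < c.box_edge / 2)
        if N_max is not None:
            use &= c.N <= N_max
        if use.sum() < 5:
            raise ValueError(f"{name}: fewer than 5 usable points above N_skip")
        rows_x.append(c.N[use]); rows_y.append(c.V_mean[use])
        ion_ix.append(np.full(use.sum(), j))
    N = np.concatenate(rows_x); V = np.concatenate(rows_y)
    ion_ix = np.concatenate(ion_ix)
    n_pts, n_par = len(N), 1 + len(names)
    if n_pts <= n_par:
        raise np.linalg.LinAlgError("fewer points than parameters in V(N) fit")
    X = np.zeros((n_pts, n_par))
    X[:, 0] = N
    X[np.arange(n_pts), 1 + ion_ix] = 1.0
    coef, _, rank, _ = np.linalg.lstsq(X, V, rcond=None)
    if rank < n_par:
        raise np.linalg.LinAlgError("rank-deficient V(N) design")
    resid = V - X @ coef
    s2 = float(resid @ resid) / (n_pts - n_par)
    cov = np.linalg.inv(X.T @ X) * s2
    se = np.sqrt(np.diag(cov))
    diagnostics = {}
    for j, name in enumerate(names):
        sel = ion_ix == j
        ss_res = float(resid[sel] @ resid[sel])
        ss_tot = float(np.sum((V[sel] - V[sel].mean()) ** 2))
        diagnostics[name] = {
            "n_points": int(sel.sum()),
            "rmsd": math.sqrt(ss_res / sel.sum()),
            "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        }
    return {
        "slope": float(coef[0]),
        "slope_se": float(se[0]),
        "intercepts": {n: float(coef[1 + j]) for j, n in enumerate(names)},
        "intercept_se": {n: float(se[1 + j]) for j, n in enumerate(names)},
        "n_points": n_pts,
        "residual_sd": math.sqrt(s2),
        "diagnostics": diagnostics,
    }
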