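"""Sphere-probe pore-radius profiling along a channel axis.

At each slice along the axis the profiler finds the in-plane center that
maximizes the clearance r(c) = min_i(|c - x_i| - vdw_i) over all atoms,
i.e. the radius of the largest sphere centred in the slice plane that fits
without overlapping any atom's vdW sphere.  The search combines a coarse
in-plane grid around the previous slice's center with seeded random
restarts and Nelder-Mead polishing, which dominates random sampling on all
tested geometries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .model_io import Structure

__all__ = [
    "PoreProfile",
    "PoreMinimum",
    "profile_pore",
    "min_pore",
    "pore_region_points",
    "channel_anchor_z",
]


@dataclass(frozen=True)
class PoreProfile:
    z: np.ndarray          # (n,) channel coordinate, strictly increasing, Å
    centers: np.ndarray    # (n, 3) sphere centers
    radius: np.ndarray     # (n,) Å
    step: float
    anchor_z: float = 0.0  # absolute z of the Z=0 reference (e.g. Q436 CA)
    flagged: np.ndarray | None = None  # samples with discontinuous radius

    def __len__(self) -> int:
        return len(self.z)

    def to_csv(self, path: str | Path, landmarks: dict[str, float] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pore profile, step={self.step} A, anchor_z={self.anchor_z}\n")
            if landmarks:
                fh.write(f"# landmarks: {json.dumps(landmarks)}\n")
            fh.write("z,x_center,y_center,z_center,radius\n")
            for zi, c, r in zip(self.z, self.centers, self.radius):
                fh.write(f"{zi:.4f},{c[0]:.4f},{c[1]:.4f},{c[2]:.4f},{r:.4f}\n")


@dataclass(frozen=True)
class PoreMinimum:
    z_min: float
    r_min: float

    @property
    def diameter(self) -> float:
        return 2.0 * self.r_min


def channel_anchor_z(structure: Structure, chain: str = "A", residue: int = 436) -> float:
    """Absolute z of the CA atom anchoring the channel coordinate Z=0."""
    for i in structure.residue_atoms(chain, residue):
        if structure.atoms[i].atom_name == "CA":
            return float(structure.atoms[i].coords[2])
    raise ValueError(f"no CA atom for residue {chain}/{residue}")


def _clearance(center: np.ndarray, coords: np.ndarray, radii: np.ndarray) -> float:
    d = np.sqrt(np.sum((coords - center) ** 2, axis=1))
    return float(np.min(d - radii))


def profile_pore(
    structure: Structure,
    seed_point: Sequence[float],
    z_range: tuple[float, float],
    step: float = 0.25,
    *,
    max_radius: float = 15.0,
    n_restarts: int = 8,
    seed: int = 0,
    discontinuity: float = 5.0,
) -> PoreProfile:
    """Profile the pore radius along +z from ``z_range[0]`` to ``z_range[1]``.

    ``seed_point`` must lie inside the pathway (positive clearance).  The
    slice center walk starts at the slice nearest the seed point and moves
    outward in both directions, each slice warm-started from its neighbor.
    """
    coords = structure.coords
    radii = np.array([a.vdw_radius for a in structure.atoms])
    seed_point = np.asarray(seed_point, dtype=float)
    if _clearance(seed_point, coords, radii) <= 0:
        raise ValueError("seed point lies inside an atom (clearance <= 0)")
    rng = np.random.default_rng(seed)

    lo, hi = z_range
    zs = np.arange(lo, hi + 1e-9, step)
    n = len(zs)
    start = int(np.argmin(np.abs(zs - seed_point[2])))

    centers = np.zeros((n, 3))
    rads = np.zeros(n)

    def optimize_slice(z: float, guess_xy: np.ndarray) -> tuple[np.ndarray, float]:
        # restrict to atoms that can constrain a sphere in this slice
        zdist = np.abs(coords[:, 2] - z)
        near = zdist - radii < max_radius
        c_near, r_near = coords[near], radii[near]
        if len(c_near) == 0:
            return np.array([guess_xy[0], guess_xy[1], z]), max_radius

        def neg_clearance(xy):
            return -_clearance(np.array([xy[0], xy[1], z]), c_near, r_near)

        # triage candidate starts by direct evaluation, polish the best few
        offsets = np.array(
            [(dx, dy) for dx in (-1.0, -0.5, 0.0, 0.5, 1.0)
             for dy in (-1.0, -0.5, 0.0, 0.5, 1.0)]
        )
        starts = np.vstack([
            guess_xy + offsets,
            guess_xy + rng.uniform(-3.0, 3.0, size=(n_restarts, 2)),
        ])
        pts3 = np.column_stack([starts, np.full(len(starts), z)])
        d = np.sqrt(
            ((pts3[:, None, :] - c_near[None, :, :]) ** 2).sum(axis=2)
        )
        clear = (d - r_near).min(axis=1)
        order = np.argsort(clear)[::-1][:3]
        best_xy, best_val = None, np.inf
        for s in starts[order]:
            res = minimize(neg_clearance, s, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 250})
            if res.fun < best_val:
                best_val, best_xy = res.fun, res.x
        r = min(-best_val, max_radius)
        return np.array([best_xy[0], best_xy[1], z]), r

    # warm-started walk from the seed slice outward
    guess = seed_point[:2].copy()
    for i in range(start, n):
        centers[i], rads[i] = optimize_slice(zs[i], guess)
        guess = centers[i][:2].copy()
    guess = centers[start][:2].copy()
    for i in range(start - 1, -1, -1):
        centers[i], rads[i] = optimize_slice(zs[i], guess)
        guess = centers[i][:2].copy()

    flagged = np.zeros(n, dtype=bool)
    if n > 1:
        jumps = np.abs(np.diff(rads)) > discontinuity
        flagged[1:] |= jumps
        flagged[:-1] |= jumps
    if np.any(rads <= 0):
        bad = zs[rads <= 0]
        raise ValueError(
            f"non-positive pore radius at z={bad[:5]}: pathway blocked or "
            "seed point outside the pore"
        )
    return PoreProfile(z=zs, centers=centers, radius=rads, step=step,
                       flagged=flagged)


def min_pore(
    profile: PoreProfile, z_window: tuple[float, float] | None = None
) -> PoreMinimum:
    """Exact minimum radius over profile samples within a z-window."""
    mask = np.ones(len(profile), dtype=bool)
    if z_window is not None:
        mask = (profile.z >= z_window[0]) & (profile.z <= z_window[1])
    if not np.any(mask):
        raise ValueError(f"no profile samples inside window {z_window}")
    i = int(np.argmin(np.where(mask, profile.radius, np.inf)))
    return PoreMinimum(z_min=float(profile.z[i]), r_min=float(profile.radius[i]))


def pore_region_points(
    structure: Structure,
    profile: PoreProfile,
    grid_spacing: float = 0.5,
    protein_clearance: float = 2.5,
) -> np.ndarray:
    """Grid points inside the profiled pore volume but > 2.5 Å from protein.

    A point belongs to the pore volume if its distance in the slice plane
    from the center of the nearest-z profile sample is at most that sample's
    radius, and it is farther than ``protein_clearance`` from every protein
    atom center.
    """
    coords = structure.coords
    z_lo, z_hi = profile.z[0], profile.z[-1]
    r_max = float(profile.radius.max())
    cx_lo = profile.centers[:, 0].min() - r_max
    cx_hi = profile.centers[:, 0].max() + r_max
    cy_lo = profile.centers[:, 1].min() - r_max
    cy_hi = profile.centers[:, 1].max() + r_max
    xs = np.arange(cx_lo, cx_hi + 1e-9, grid_spacing)
    ys = np.arange(cy_lo, cy_hi + 1e-9, grid_spacing)
    zs = np.arange(z_lo, z_hi + 1e-9, grid_spacing)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    slice_idx = np.clip(
        np.round((pts[:, 2] - profile.z[0]) / profile.step).astype(int),
        0, len(profile) - 1,
    )
    c = profile.centers[slice_idx]
    r = profile.radius[slice_idx]
    in_pore = np.hypot(pts[:, 0] - c[:, 0], pts[:, 1] - c[:, 1]) <= r
    pts = pts[in_pore]
    if len(pts) == 0:
        return pts
    # chunked distance test against all atoms
    keep = np.ones(len(pts), dtype=bool)
    for i0 in range(0, len(pts), 4096):
        chunk = pts[i0:i0 + 4096]
        d2 = np.min(
            np.sum((chunk[:, None, :] - coords[None, :, :]) ** 2, axis=2), axis=1
        )
        keep[i0:i0 + 4096] = d2 > protein_clearance**2
    return pts[keep]
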