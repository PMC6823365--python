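"""Finite-difference linearized Poisson-Boltzmann electrostatics with a
membrane-slab dielectric model.

The solver works in Gaussian-style units: charges in elementary charges,
lengths in Å, and the reduced potential phi~ satisfies

    div(eps grad phi~) - eps_w kappa^2 s(x) phi~ = -4 pi rho_e

where s(x) = 1 in ion-accessible water.  Potentials are reported in
kcal/(mol e): phi = 332.0637 * phi~ (the Coulomb constant e^2/(4 pi eps0)
expressed in kcal Å/(mol e^2)), so a unit charge in a uniform dielectric
gives phi = 332.0637 q/(eps r), and with salt the screened Coulomb form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants

from .model_io import Structure
from .pore import PoreProfile

logger = logging.getLogger(__name__)

__all__ = [
    "MembraneDielectricSpec",
    "EPGrid",
    "EPProfile",
    "debye_kappa",
    "build_maps",
    "solve_lpbe",
    "ep_profile",
    "ep_isorange_surface",
    "write_dx",
]

COULOMB_KCAL = 332.0637  # kcal Å / (mol e^2)

#: Formal charges used when a plain PDB (no PQR charges) is supplied.
FORMAL_CHARGES: dict[str, float] = {"ASP": -1.0, "GLU": -1.0, "LYS": +1.0, "ARG": +1.0, "HIS": 0.0}
ION_CHARGES: dict[str, float] = {"CA": +2.0, "ZN": +2.0, "MG": +2.0, "NA": +1.0, "K": +1.0, "CL": -1.0}


@dataclass(frozen=True)
class MembraneDielectricSpec:
    """Dielectric/ion-accessibility model: protein eps 2, 26 Å slab core
    eps 2, 8 Å headgroup bands eps 30, water eps 80, an 18 Å-radius
    water-filled cylinder through the slab about the pore axis (ion
    accessible), 150 mM monovalent salt excluded from membrane and protein.
    """

    eps_protein: float = 2.0
    eps_core: float = 2.0
    eps_head: float = 30.0
    eps_water: float = 80.0
    core_thickness: float = 26.0
    headgroup_thickness: float = 8.0
    hole_radius: float = 18.0
    ionic_strength_mM: float = 150.0
    temperature: float = 298.0
    membrane_center_z: float = 0.0
    include_membrane: bool = True

    def __post_init__(self) -> None:
        if self.core_thickness <= 0 or self.headgroup_thickness <= 0:
            raise ValueError("slab thicknesses must be > 0")
        for e in (self.eps_protein, self.eps_core, self.eps_head, self.eps_water):
            if e < 1.0:
                raise ValueError("dielectric constants must be >= 1")


@dataclass
class EPGrid:
    origin: np.ndarray        # (3,)
    spacing: float
    shape: tuple[int, int, int]
    eps: np.ndarray           # node-centred dielectric map
    kappa2: np.ndarray        # eps_w * kappa^2 where ions are present, else 0
    charge: np.ndarray        # e per node
    phi: np.ndarray | None = None  # kcal/(mol e)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.shape[i])
            for i in range(3)
        )

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of phi at Cartesian points."""
        if self.phi is None:
            raise ValueError("phi not solved yet")
        from scipy.ndimage import map_coordinates

        pts = (np.asarray(points, dtype=float) - self.origin) / self.spacing
        return map_coordinates(self.phi, pts.T, order=1, mode="nearest")


@dataclass(frozen=True)
class EPProfile:
    z: np.ndarray             # channel coordinate, decreasing = EC -> IC
    phi: np.ndarray           # kcal/(mol e)
    landmarks: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# electrostatic potential along the pore axis\n")
            if self.landmarks:
                import json

                fh.write(f"# landmarks: {json.dumps(self.landmarks)}\n")
            fh.write("z,phi_kcal_mol_e\n")
            for zi, p in zip(self.z, self.phi):
                fh.write(f"{zi:.4f},{p:.6f}\n")


def debye_kappa(ionic_strength_mM: float, eps: float = 80.0, temperature: float = 298.0) -> float:
    """Inverse Debye length (1/Å) for a monovalent salt solution."""
    # number density of each ion species (1:1 salt), m^-3
    n = ionic_strength_mM * 1e-3 * 1e3 * constants.N_A  # mol/L -> mol/m^3 -> m^-3
    kappa2 = (2 * n * constants.e**2) / (
        eps * constants.epsilon_0 * constants.k * temperature
    )
    return float(np.sqrt(kappa2) * 1e-10)  # 1/m -> 1/Å


def build_maps(
    structure: Structure,
    spec: MembraneDielectricSpec,
    *,
    spacing: float = 0.8,
    padding: float = 15.0,
    pore_axis_xy: Sequence[float] | None = None,
    box: tuple[np.ndarray, np.ndarray] | None = None,
) -> EPGrid:
    """Populate dielectric, screening and charge maps for a structure.

    Region precedence at a grid node: protein (vdW-inflated atoms) >
    membrane cylinder hole (water, ion-accessible) > slab bands > bulk
    water.  Ions are present only in water-dielectric regions outside the
    protein and outside the slab bands (the cylindrical hole is ion
    accessible).
    """
    coords = structure.coords
    radii = np.array([a.vdw_radius for a in structure.atoms])
    charges = np.array([
        a.partial_charge if a.partial_charge is not None
        else _fallback_charge(a)
        for a in structure.atoms
    ])
    if box is None:
        lo = coords.min(axis=0) - padding
        hi = coords.max(axis=0) + padding
    else:
        lo, hi = np.asarray(box[0], float), np.asarray(box[1], float)
    if spacing > 1.5:
        logger.warning("grid spacing %.2f Å is coarse (> 1.5 Å)", spacing)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    grid = EPGrid(
        origin=lo,
        spacing=spacing,
        shape=shape,
        eps=np.full(shape, spec.eps_water),
        kappa2=np.zeros(shape),
        charge=np.zeros(shape),
    )
    X, Y, Z = np.meshgrid(*grid.axes(), indexing="ij")

    in_membrane_band = np.zeros(shape, dtype=bool)
    in_hole = np.zeros(shape, dtype=bool)
    if spec.include_membrane:
        zc = spec.membrane_center_z
        half_core = spec.core_thickness / 2
        dz = np.abs(Z - zc)
        core = dz <= half_core
        head = (dz > half_core) & (dz <= half_core + spec.headgroup_thickness)
        if pore_axis_xy is None:
            pore_axis_xy = coords[:, :2].mean(axis=0)
        ax, ay = float(pore_axis_xy[0]), float(pore_axis_xy[1])
        in_hole = (
            (np.hypot(X - ax, Y - ay) <= spec.hole_radius) & (core | head)
        )
        grid.eps[core] = spec.eps_core
        grid.eps[head] = spec.eps_head
        grid.eps[in_hole] = spec.eps_water
        in_membrane_band = (core | head) & ~in_hole
        if not np.any((coords[:, 2] > zc - half_core) & (coords[:, 2] < zc + half_core)):
            logger.warning("protein does not intersect the membrane slab")

    # protein interior: vdW-inflated atoms
    in_protein = np.zeros(shape, dtype=bool)
    axes = grid.axes()
    for xyz, r in zip(coords, radii):
        if r <= 1e-3:
            continue  # bare point charges: uniform-dielectric limit systems
        _mark_sphere(in_protein, axes, xyz, r)
    grid.eps[in_protein] = spec.eps_protein

    kappa = debye_kappa(spec.ionic_strength_mM, spec.eps_water, spec.temperature)
    ion_ok = ~in_protein & ~in_membrane_band & (grid.eps == spec.eps_water)
    grid.kappa2[ion_ok] = spec.eps_water * kappa**2

    _spread_charges(grid, coords, charges)
    return grid


def _fallback_charge(atom) -> float:
    """Minimal formal-charge model for structures without PQR charges."""
    if atom.element in ION_CHARGES and atom.is_hetero:
        return ION_CHARGES[atom.element]
    if atom.residue_name in FORMAL_CHARGES:
        carrier = {"ASP": "CG", "GLU": "CD", "LYS": "NZ", "ARG": "CZ"}.get(atom.residue_name)
        if carrier and atom.atom_name == carrier:
            return FORMAL_CHARGES[atom.residue_name]
    return 0.0


def _mark_sphere(mask: np.ndarray, axes, center: np.ndarray, r: float) -> None:
    sl = []
    for i in range(3):
        ax = axes[i]
        j0 = np.searchsorted(ax, center[i] - r)
        j1 = np.searchsorted(ax, center[i] + r, side="right")
        if j0 >= len(ax) or j1 <= 0:
            return
        sl.append((max(j0, 0), min(j1, len(ax))))
    xs = axes[0][sl[0][0]:sl[0][1]] - center[0]
    ys = axes[1][sl[1][0]:sl[1][1]] - center[1]
    zs = axes[2][sl[2][0]:sl[2][1]] - center[2]
    d2 = xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
    mask[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]] |= d2 <= r * r


def _spread_charges(grid: EPGrid, coords: np.ndarray, charges: np.ndarray) -> None:
    """Trilinear assignment of point charges onto grid nodes."""
    frac = (coords - grid.origin) / grid.spacing
    base = np.floor(frac).astype(int)
    w = frac - base
    nx, ny, nz = grid.shape
    for (i, j, k), (wx, wy, wz), q in zip(base, w, charges):
        if q == 0.0:
            continue
        if not (0 <= i < nx - 1 and 0 <= j < ny - 1 and 0 <= k < nz - 1):
            raise ValueError("charge outside grid interior")
        for di, fx in ((0, 1 - wx), (1, wx)):
            for dj, fy in ((0, 1 - wy), (1, wy)):
                for dk, fz in ((0, 1 - wz), (1, wz)):
                    grid.charge[i + di, j + dj, k + dk] += q * fx * fy * fz


def _boundary_phi(grid: EPGrid, coords, charges, eps_w, kappa) -> np.ndarray:
    """Debye-screened Coulomb superposition evaluated on the grid faces."""
    phi = np.zeros(grid.shape)
    axes = grid.axes()
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    face = np.zeros(grid.shape, dtype=bool)
    face[0, :, :] = face[-1, :, :] = True
    face[:, 0, :] = face[:, -1, :] = True
    face[:, :, 0] = face[:, :, -1] = True
    pts = np.column_stack([X[face], Y[face], Z[face]])
    vals = np.zeros(len(pts))
    for xyz, q in zip(coords, charges):
        if q == 0.0:
            continue
        r = np.linalg.norm(pts - xyz, axis=1)
        r = np.maximum(r, grid.spacing)
        vals += q * np.exp(-kappa * r) / (eps_w * r)
    phi[face] = vals
    return phi


def solve_lpbe(
    grid: EPGrid,
    tolerance: float = 1e-6,
    max_iter: int = 20000,
    omega: float | None = None,
    structure: Structure | None = None,
) -> EPGrid:
    """Solve the LPBE on the grid by red-black SOR; fills ``grid.phi``.

    Face dielectrics are harmonic means of the node values; the boundary
    condition is the screened-Coulomb superposition of all charges.
    Raises on non-convergence with the residual history attached.
    """
    h = grid.spacing
    eps = grid.eps
    nx, ny, nz = grid.shape
    if omega is None:
        omega = 2.0 / (1.0 + np.pi / max(nx, ny, nz))

    # face dielectric (harmonic mean) for the 6 neighbors
    def hmean(a, b):
        return 2.0 * a * b / (a + b)

    exm = np.ones_like(eps); exp_ = np.ones_like(eps)
    eym = np.ones_like(eps); eyp = np.ones_like(eps)
    ezm = np.ones_like(eps); ezp = np.ones_like(eps)
    exm[1:, :, :] = hmean(eps[1:, :, :], eps[:-1, :, :])
    exp_[:-1, :, :] = hmean(eps[:-1, :, :], eps[1:, :, :])
    eym[:, 1:, :] = hmean(eps[:, 1:, :], eps[:, :-1, :])
    eyp[:, :-1, :] = hmean(eps[:, :-1, :], eps[:, 1:, :])
    ezm[:, :, 1:] = hmean(eps[:, :, 1:], eps[:, :, :-1])
    ezp[:, :, :-1] = hmean(eps[:, :, :-1], eps[:, :, 1:])

    source = 4.0 * np.pi * grid.charge / h  # -4 pi rho, integrated: q/h
    diag = exm + exp_ + eym + eyp + ezm + ezp + grid.kappa2 * h * h

    # boundary condition
    kappa_eff = 0.0
    if grid.kappa2.max() > 0:
        eps_w = float(eps.max())
        kappa_eff = float(np.sqrt(grid.kappa2.max() / eps_w))
    else:
        eps_w = float(eps.max())
    # recover source charges for the BC from the spread charge map
    axes = grid.axes()
    nzi = np.argwhere(grid.charge != 0)
    bc_coords = np.array([[axes[0][i], axes[1][j], axes[2][k]] for i, j, k in nzi]) \
        if len(nzi) else np.zeros((0, 3))
    bc_charges = np.array([grid.charge[tuple(ijk)] for ijk in nzi])
    phi = _boundary_phi(grid, bc_coords, bc_charges, eps_w, kappa_eff)

    interior = np.zeros(grid.shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    I, J, K = np.indices(grid.shape)
    red = ((I + J + K) % 2 == 0) & interior
    black = ((I + J + K) % 2 == 1) & interior

    history = []
    for it in range(max_iter):
        max_update = 0.0
        for mask in (red, black):
            nbr = (
                exm * np.roll(phi, 1, axis=0)
                + exp_ * np.roll(phi, -1, axis=0)
                + eym * np.roll(phi, 1, axis=1)
                + eyp * np.roll(phi, -1, axis=1)
                + ezm * np.roll(phi, 1, axis=2)
                + ezp * np.roll(phi, -1, axis=2)
            )
            new = (nbr + source) / diag
            delta = omega * (new - phi)
            phi_masked = np.where(mask, phi + delta, phi)
            max_update = max(max_update, float(np.max(np.abs(np.where(mask, delta, 0.0)))))
            phi = phi_masked
        history.append(max_update)
        scale = max(float(np.max(np.abs(phi))), 1e-30)
        if max_update / scale < tolerance:
            logger.debug("SOR converged in %d sweeps", it + 1)
            break
    else:
        err = RuntimeError(
            f"LPBE solver did not converge in {max_iter} sweeps "
            f"(last update {history[-1]:.3e})"
        )
        err.residual_history = history  # type: ignore[attr-defined]
        raise err

    grid.phi = phi * COULOMB_KCAL
    return grid


def ep_profile(
    grid: EPGrid,
    profile: PoreProfile,
    landmarks: dict | None = None,
    channel_offset: float = 0.0,
) -> EPProfile:
    """Potential along the pore-axis centers, ordered EC -> IC
    (decreasing channel coordinate)."""
    if grid.phi is None:
        raise ValueError("solve the grid before profiling")
    axes = grid.axes()
    for c in profile.centers:
        if np.any(c < grid.origin) or any(
            c[i] > axes[i][-1] for i in range(3)
        ):
            raise ValueError("pore axis exits the potential grid")
    vals = grid.interpolate(profile.centers)
    z = profile.z - channel_offset
    order = np.argsort(z)[::-1]
    return EPProfile(z=z[order], phi=vals[order], landmarks=landmarks or {})


def ep_isorange_surface(
    grid: EPGrid,
    mask_points: np.ndarray,
    vrange: tuple[float, float] = (-1.0, 1.0),
) -> np.ndarray:
    """Masked grid potentials clipped to ``vrange``: (n, 4) x,y,z,phi rows."""
    if grid.phi is None:
        raise ValueError("solve the grid first")
    if len(mask_points) == 0:
        logger.info("empty pore-region mask: nothing to export")
        return np.zeros((0, 4))
    vals = np.clip(grid.interpolate(mask_points), vrange[0], vrange[1])
    return np.column_stack([mask_points, vals])


def write_dx(grid: EPGrid, path) -> None:
    """Export phi as an OpenDX scalar field."""
    if grid.phi is None:
        raise ValueError("solve the grid first")
    try:
        from gridData import Grid

        g = Grid(grid.phi, origin=grid.origin,
                 delta=[grid.spacing] * 3)
        g.export(str(path), "DX")
    except ImportError:  # plain-text fallback writer
        nx, ny, nz = grid.shape
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write("origin %.6f %.6f %.6f\n" % tuple(grid.origin))
            fh.write(f"delta {grid.spacing} 0 0\ndelta 0 {grid.spacing} 0\n"
                     f"delta 0 0 {grid.spacing}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {nx*ny*nz} data follows\n"
            )
            flat = grid.phi.ravel()
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')
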