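"""Synthetic fixtures: two-state feature series, toy groove structures,
ring-built pore geometries, point-charge systems and kinetic traces.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_io import AtomRecord, Structure, TrajectoryFrame

__all__ = [
    "TwoStateSpec",
    "ToyGrooveSpec",
    "make_two_state_series",
    "make_toy_groove",
    "make_pore_toy",
    "make_point_charge_system",
    "make_trace_set",
]

#: Default mapping of toy residue slots onto the groove numbering used by
#: the feature metrics.  Each entry is (residue_number, residue_name).
DEFAULT_RESIDUES: tuple[tuple[int, str], ...] = (
    (302, "LEU"),
    (313, "GLU"),
    (318, "GLU"),
    (333, "THR"),
    (337, "VAL"),
    (343, "ILE"),
    (347, "LEU"),
    (381, "THR"),
    (432, "ARG"),
    (436, "GLN"),
    (439, "TYR"),
    (443, "THR"),
    (447, "VAL"),
)


@dataclass(frozen=True)
class TwoStateSpec:
    """Markov two-state emission model for feature time series."""

    k12: float  # open -> occluded rate, 1/frame
    k21: float  # occluded -> open rate, 1/frame
    mu_open: np.ndarray  # (5,) feature means, Å
    mu_occluded: np.ndarray
    noise_sd: np.ndarray  # (5,) per-feature Gaussian sd, Å
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_open", "mu_occluded", "noise_sd"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).ravel()
            )
        if self.k12 <= 0 or self.k21 <= 0:
            raise ValueError("rates must be > 0")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.mu_open.shape != self.mu_occluded.shape:
            raise ValueError("state mean vectors must have equal length")


def make_two_state_series(spec: TwoStateSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the hidden two-state chain and noisy feature emissions.

    The per-frame transition probabilities are the exact one-frame
    discretization of the continuous two-state exchange, so the state
    indicator has autocorrelation exp(-(k12+k21)*tau) at lag tau exactly
    in expectation.

    Returns ``(features, states)`` with shapes (T, d) and (T,);
    state 0 = open, 1 = occluded.
    """
    ktot = spec.k12 + spec.k21
    if spec.n_frames < 10.0 / ktot:
        warnings.warn(
            "n_frames < 10/(k12+k21): the slow mode is under-sampled",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    decay = np.exp(-ktot)
    p01 = (spec.k12 / ktot) * (1.0 - decay)  # P(open -> occluded | 1 frame)
    p10 = (spec.k21 / ktot) * (1.0 - decay)
    pi1 = spec.k12 / ktot  # stationary occupancy of state 1
    T = spec.n_frames
    states = np.empty(T, dtype=np.int64)
    states[0] = rng.random() < pi1
    u = rng.random(T - 1)
    for t in range(1, T):
        if states[t - 1] == 0:
            states[t] = u[t - 1] < p01
        else:
            states[t] = 1 - (u[t - 1] < p10)
    means = np.stack([spec.mu_open, spec.mu_occluded])  # (2, d)
    d = means.shape[1]
    features = means[states] + rng.standard_normal((T, d)) * spec.noise_sd
    return features, states


# ---------------------------------------------------------------------------
# Toy groove structures


@dataclass
class ToyGrooveSpec:
    """Layout of a toy groove structure with controllable placements.

    ``residue_positions`` places each numbered residue's anchor; residues get
    a CA at the anchor plus sidechain pseudo-atoms immediately next to it so
    that sidechain-based metrics have something to measure.  Waters and
    lipids are planted at exactly the requested coordinates.
    """

    residue_positions: dict[int, np.ndarray] = field(default_factory=dict)
    residues: tuple[tuple[int, str], ...] = DEFAULT_RESIDUES
    water_positions: Sequence[np.ndarray] = field(default_factory=list)
    lipid_chains: Sequence[dict] = field(default_factory=list)
    chain_id: str = "A"
    min_hetero_separation: float = 0.5


# sidechain heavy-atom names emitted for each toy residue type; enough to
# exercise the per-atom-class rules (carboxylate O on Glu, guanidinium N on
# Arg, hydroxyl O on Tyr/Thr) without full residue topologies.
_TOY_SIDECHAINS: dict[str, tuple[tuple[str, str], ...]] = {
    "GLY": (),
    "ALA": (("CB", "C"),),
    "VAL": (("CB", "C"), ("CG1", "C"), ("CG2", "C")),
    "LEU": (("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")),
    "ILE": (("CB", "C"), ("CG1", "C"), ("CG2", "C"), ("CD1", "C")),
    "THR": (("CB", "C"), ("OG1", "O"), ("CG2", "C")),
    "GLN": (("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("NE2", "N")),
    "GLU": (("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")),
    "TYR": (("CB", "C"), ("CG", "C"), ("OH", "O")),
    "ARG": (("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"),
            ("CZ", "C"), ("NH1", "N"), ("NH2", "N")),
}


def make_toy_groove(
    spec: ToyGrooveSpec,
) -> Structure:
    """Build a toy structure carrying groove residue numbering plus waters
    and lipid pseudo-residues at exactly the requested positions."""
    atoms: list[AtomRecord] = []
    serial = 1

    def add(name, resname, chain, resnum, xyz, element, hetero=False):
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial,
                atom_name=name,
                residue_name=resname,
                chain_id=chain,
                residue_number=resnum,
                coords=np.asarray(xyz, dtype=float),
                element=element,
                vdw_radius={"C": 1.7, "O": 1.52, "N": 1.55, "P": 1.8}.get(element, 1.7),
                is_hetero=hetero,
            )
        )
        serial += 1

    name_by_number = dict(spec.residues)
    for resnum, anchor in sorted(spec.residue_positions.items()):
        resname = name_by_number.get(resnum, "ALA")
        anchor = np.asarray(anchor, dtype=float)
        add("N", resname, spec.chain_id, resnum, anchor + [-0.8, -0.6, 0.0], "N")
        add("CA", resname, spec.chain_id, resnum, anchor, "C")
        add("C", resname, spec.chain_id, resnum, anchor + [0.9, -0.5, 0.0], "C")
        add("O", resname, spec.chain_id, resnum, anchor + [1.1, -1.4, 0.5], "O")
        for i, (aname, elem) in enumerate(_TOY_SIDECHAINS.get(resname, ())):
            # short ladder of sidechain atoms extending +y from the CA
            offset = np.array([0.0, 0.7 * (i + 1), 0.2 * (i % 2)])
            add(aname, resname, spec.chain_id, resnum, anchor + offset, elem)

    hetero_positions: list[np.ndarray] = []

    def check_clash(xyz):
        xyz = np.asarray(xyz, dtype=float)
        for p in hetero_positions:
            if np.linalg.norm(xyz - p) < spec.min_hetero_separation:
                raise ValueError(
                    f"hetero-atom placement clash (<{spec.min_hetero_separation} Å) at {xyz}"
                )
        hetero_positions.append(xyz)

    for i, pos in enumerate(spec.water_positions, start=1):
        check_clash(pos)
        add("O", "HOH", "W", i, pos, "O", hetero=True)

    for li, lipid in enumerate(spec.lipid_chains, start=1):
        resname = lipid.get("resname", "TOY")
        head = lipid.get("head", [])
        tail = lipid.get("tail", [])
        for j, pos in enumerate(head, start=1):
            check_clash(pos)
            add(f"P{j}" if j == 1 else f"OH{j}", resname, "L", li, pos,
                "P" if j == 1 else "O", hetero=True)
        for j, pos in enumerate(tail, start=1):
            check_clash(pos)
            add(f"C{j}T", resname, "L", li, pos, "C", hetero=True)

    return Structure(atoms, title="toy groove")


def make_groove_trajectory(
    spec: ToyGrooveSpec, occluded_script: Sequence[bool],
    open_sep: float = 12.0, occluded_sep: float = 7.0,
) -> tuple[Structure, list[TrajectoryFrame]]:
    """Toy trajectory whose V337/V447 CA separation follows a script.

    Frame t has CA separation ``occluded_sep`` when ``occluded_script[t]``
    is true, else ``open_sep``; residue 447 is translated along x.
    """
    base = make_toy_groove(spec)
    ref_sep = np.linalg.norm(
        spec.residue_positions[447] - spec.residue_positions[337]
    )
    idx447 = [i for i, a in enumerate(base.atoms)
              if a.residue_number == 447 and a.chain_id == spec.chain_id]
    direction = (spec.residue_positions[447] - spec.residue_positions[337]) / ref_sep
    frames = []
    for t, occ in enumerate(occluded_script):
        coords = base.coords
        target = occluded_sep if occ else open_sep
        coords[idx447] += (target - ref_sep) * direction
        frames.append(TrajectoryFrame(frame_index=t, coords=coords))
    return base, frames


# ---------------------------------------------------------------------------
# Pore toys


def make_pore_toy(
    shape: str,
    *,
    ring_radius: float = 6.0,
    waist_radius: float | None = None,
    atom_radius: float = 1.7,
    z_lo: float = -10.0,
    z_hi: float = 10.0,
    ring_spacing: float = 1.0,
    atoms_per_ring: int = 24,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Rings of pseudo-atoms about +z realizing a cylinder or hourglass.

    For a cylinder the analytic pore radius is ``ring_radius - atom_radius``
    at every z (in the densely-ringed limit).  For an hourglass the ring
    radius varies linearly from ``ring_radius`` at the ends to
    ``waist_radius`` at z = (z_lo+z_hi)/2.
    """
    if shape not in ("cylinder", "hourglass"):
        raise ValueError(f"unknown pore toy shape {shape!r}")
    if waist_radius is None:
        waist_radius = ring_radius / 2.0
    if min(ring_radius, waist_radius) <= atom_radius:
        raise ValueError("ring radii must exceed the atom radius")
    rng = np.random.default_rng(seed)
    zs = np.arange(z_lo, z_hi + 1e-9, ring_spacing)
    z_mid = 0.5 * (z_lo + z_hi)
    half = max(z_hi - z_mid, 1e-9)
    atoms: list[AtomRecord] = []
    serial = 1
    for zi, z in enumerate(zs):
        if shape == "cylinder":
            r = ring_radius
        else:
            frac = abs(z - z_mid) / half
            r = waist_radius + (ring_radius - waist_radius) * frac
        # stagger rings so the surface has no open seams
        phase = (zi % 2) * np.pi / atoms_per_ring
        for j in range(atoms_per_ring):
            theta = 2 * np.pi * j / atoms_per_ring + phase
            xyz = np.array([r * np.cos(theta), r * np.sin(theta), z])
            if jitter_sd > 0:
                xyz = xyz + rng.standard_normal(3) * jitter_sd
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name="C",
                    residue_name="TOY",
                    chain_id="P",
                    residue_number=zi + 1,
                    coords=xyz,
                    element="C",
                    vdw_radius=atom_radius,
                )
            )
            serial += 1
    return Structure(atoms, title=f"pore toy ({shape})")


# ---------------------------------------------------------------------------
# Point-charge systems for electrostatics limit tests


def make_point_charge_system(
    charges: Sequence[tuple[Sequence[float], float]],
    box: float = 40.0,
    salt_mM: float = 0.0,
    temperature: float = 298.0,
) -> Structure:
    """PQR-style structure of bare point charges centred in a cubic box.

    With ``salt_mM > 0`` every charge must sit at least two Debye lengths
    from each box face so that the analytic boundary condition is accurate.
    """
    from .electrostatics import debye_kappa

    margin = 0.0
    if salt_mM > 0:
        kappa = debye_kappa(salt_mM, eps=80.0, temperature=temperature)
        margin = 2.0 / kappa
    atoms = []
    for i, (pos, q) in enumerate(charges, start=1):
        pos = np.asarray(pos, dtype=float)
        if np.any(np.abs(pos) > box / 2 - margin):
            raise ValueError(
                f"charge {i} closer than 2 Debye lengths ({margin:.1f} Å) to a box face"
            )
        atoms.append(
            AtomRecord(
                serial=i,
                atom_name="Q",
                residue_name="ION",
                chain_id="Z",
                residue_number=i,
                coords=pos,
                element="C",
                vdw_radius=1e-3,  # negligible: uniform-dielectric limit tests
                partial_charge=float(q),
                is_hetero=True,
            )
        )
    return Structure(atoms, title="point charges")


# ---------------------------------------------------------------------------
# Fluorescence traces


def make_trace_set(
    param_table: Sequence["ScramblingParams"],
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list["FluorescenceTrace"]:
    """Noisy traces drawn from the closed-form scrambling model."""
    from .kinetics import simulate_trace

    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    return [
        simulate_trace(p, times, noise_sd=noise_sd,
                       seed=int(rng.integers(0, 2**31 - 1)))
        for p in param_table
    ]
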