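"""Per-frame groove metrics: the five feature distances, state labels,
hydration counts and lipid head/tail penetration fractions.

All metrics operate on heavy atoms by default (``include_hydrogens=True``
switches to the all-atom convention used for simulation frames), use
inclusive (<=) radius comparisons at region boundaries, and assume whole
(non-wrapped) coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import Structure, SelectionError, select

logger = logging.getLogger(__name__)

__all__ = [
    "GrooveFeatures",
    "GrooveStateLabel",
    "HydrationCount",
    "LipidPenetration",
    "GROOVE_LINING_RESIDUES",
    "GROOVE_INTERIOR_RESIDUES",
    "OCCLUSION_CUTOFF",
    "TM3_TM4_CUTOFF",
    "DIRECT_CONTACT_CUTOFF",
    "min_residue_distance",
    "glu_arg_distance",
    "feature_vector",
    "classify_groove",
    "count_region_waters",
    "lipid_penetration",
]

#: Residues whose sidechains define membership in the groove hydration shell
#: (water within 3 Å of any of their sidechain atoms).
GROOVE_LINING_RESIDUES: tuple[int, ...] = (
    302, 306, 310, 313, 333, 336, 337, 340, 341, 344, 348, 352, 367, 370,
    371, 374, 377, 378, 381, 382, 385, 432, 436, 439, 440, 444, 447, 451,
    455, 499, 501, 505, 509, 513,
)

#: Residues lining the groove interior used for the 5 Å lipid-penetration rule.
GROOVE_INTERIOR_RESIDUES: tuple[int, ...] = (
    377, 378, 381, 382, 385, 501, 505, 509, 513,
)

WATER_RADIUS = 3.0  # Å, inclusive
LIPID_RADIUS = 5.0  # Å, inclusive
OCCLUSION_CUTOFF = 8.5  # Å, V337-V447 CA-CA; boundary counts as occluded
TM3_TM4_CUTOFF = 3.5  # Å, minimal L302-I343 distance
DIRECT_CONTACT_CUTOFF = 2.5  # Å, minimal V337-V447 distance

#: Vestibule slab: between the z-planes of these residues' CA atoms.
SLAB_PLANE_RESIDUES: tuple[int, int] = (381, 436)

GLU_OXYGENS = ("OE1", "OE2")
GLU_BACKBONE_OXYGEN = ("O",)
ARG_NITROGENS = ("NE", "NH1", "NH2")


@dataclass(frozen=True)
class GrooveFeatures:
    """The five feature distances for one frame (Å)."""

    d_T333_Y439: float
    d_Y439_R432: float
    d_E313_R432: float
    d_E318_R432: float
    d_V337_V447_CA: float
    frame_index: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([
            self.d_T333_Y439,
            self.d_Y439_R432,
            self.d_E313_R432,
            self.d_E318_R432,
            self.d_V337_V447_CA,
        ])


@dataclass(frozen=True)
class GrooveStateLabel:
    occluded: bool          # d_V337_V447_CA <= 8.5 Å
    tm3_tm4_engaged: bool   # min L302-I343 distance <= 3.5 Å
    direct_contact: bool    # min V337-V447 distance < 2.5 Å


@dataclass(frozen=True)
class HydrationCount:
    n_groove_waters: int
    n_slab_waters: int
    region: str
    plane_residues: tuple[int, int] = SLAB_PLANE_RESIDUES


@dataclass(frozen=True)
class LipidPenetration:
    head_fraction: float
    tail_fraction: float
    per_lipid: tuple[tuple[str, int, float, float], ...]  # (chain, resnum, head, tail)


def _atom_class(include_hydrogens: bool) -> str:
    return "all" if include_hydrogens else "heavy"


def min_residue_distance(
    structure: Structure,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    atom_class: str = "heavy",
) -> float:
    """Minimum distance between any atom pair of two residues (Å)."""
    sel_a = select(structure, res_a[0], [res_a[1]], atom_class)
    sel_b = select(structure, res_b[0], [res_b[1]], atom_class)
    xa = np.array([structure.atoms[i].coords for i in sel_a.indices])
    xb = np.array([structure.atoms[i].coords for i in sel_b.indices])
    return float(cdist(xa, xb).min())


def _named_atom_coords(
    structure: Structure, chain: str, resnum: int, names: Sequence[str]
) -> np.ndarray:
    idx = structure.residue_atoms(chain, resnum)
    if not idx:
        raise SelectionError(f"residue {chain}/{resnum} not present")
    coords = [structure.atoms[i].coords for i in idx
              if structure.atoms[i].atom_name in names]
    if not coords:
        present = sorted({structure.atoms[i].atom_name for i in idx})
        raise SelectionError(
            f"residue {chain}/{resnum}: none of atoms {list(names)} present "
            f"(has {present}); sidechain may be truncated"
        )
    return np.array(coords)


def glu_arg_distance(
    structure: Structure,
    glu: tuple[str, int],
    arg: tuple[str, int],
    use_backbone_oxygen: bool = False,
) -> float:
    """Glu oxygen to Arg sidechain nitrogen distance (Å).

    Default oxygen set is the sidechain carboxylate pair (OE1/OE2);
    ``use_backbone_oxygen`` switches to the backbone carbonyl O.  The Arg
    set is NE/NH1/NH2; the minimum over all pairs is returned.
    """
    oxy_names = GLU_BACKBONE_OXYGEN if use_backbone_oxygen else GLU_OXYGENS
    xo = _named_atom_coords(structure, glu[0], glu[1], oxy_names)
    xn = _named_atom_coords(structure, arg[0], arg[1], ARG_NITROGENS)
    return float(cdist(xo, xn).min())


def _ca_distance(structure: Structure, chain: str, a: int, b: int) -> float:
    xa = _named_atom_coords(structure, chain, a, ("CA",))
    xb = _named_atom_coords(structure, chain, b, ("CA",))
    return float(np.linalg.norm(xa[0] - xb[0]))


def feature_vector(
    structure: Structure,
    chain: str = "A",
    frame_index: int = 0,
    include_hydrogens: bool = False,
    use_backbone_oxygen: bool = False,
) -> GrooveFeatures:
    """Compute the five feature distances for one frame.

    (1)-(2) are minimal inter-atom distances, (3)-(4) follow the
    Glu-O/Arg-N rule, (5) is the CA-CA distance.
    """
    ac = _atom_class(include_hydrogens)
    return GrooveFeatures(
        d_T333_Y439=min_residue_distance(structure, (chain, 333), (chain, 439), ac),
        d_Y439_R432=min_residue_distance(structure, (chain, 439), (chain, 432), ac),
        d_E313_R432=glu_arg_distance(structure, (chain, 313), (chain, 432),
                                     use_backbone_oxygen),
        d_E318_R432=glu_arg_distance(structure, (chain, 318), (chain, 432),
                                     use_backbone_oxygen),
        d_V337_V447_CA=_ca_distance(structure, chain, 337, 447),
        frame_index=frame_index,
    )


def classify_groove(
    features: GrooveFeatures,
    structure: Structure | None = None,
    chain: str = "A",
    include_hydrogens: bool = False,
) -> GrooveStateLabel:
    """State labels from the feature vector (plus frame for the contact
    metrics when a structure is supplied).

    The boundary value d = 8.5 Å classifies as occluded.
    """
    tm3_tm4 = False
    contact = False
    if structure is not None:
        ac = _atom_class(include_hydrogens)
        tm3_tm4 = (
            min_residue_distance(structure, (chain, 302), (chain, 343), ac)
            <= TM3_TM4_CUTOFF
        )
        contact = (
            min_residue_distance(structure, (chain, 337), (chain, 447), ac)
            < DIRECT_CONTACT_CUTOFF
        )
    return GrooveStateLabel(
        occluded=features.d_V337_V447_CA <= OCCLUSION_CUTOFF,
        tm3_tm4_engaged=tm3_tm4,
        direct_contact=contact,
    )


def _water_groups(structure: Structure) -> dict[tuple[str, int], list[int]]:
    groups: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.is_water:
            groups.setdefault((a.chain_id, a.residue_number), []).append(i)
    return groups


def _sidechain_coords(
    structure: Structure, chain: str, residues: Iterable[int],
    include_hydrogens: bool,
) -> np.ndarray:
    idx: list[int] = []
    missing: list[int] = []
    for r in residues:
        if not structure.has_residue(chain, r):
            missing.append(r)
            continue
        idx.extend(select(structure, chain, [r], "sidechain_heavy").indices)
    if missing:
        logger.warning(
            "lining residues %s missing from chain %s: counted over the "
            "remaining %d residues", missing, chain, len(residues) - len(missing)
        )
    if not idx:
        raise SelectionError(
            f"no lining residues of {list(residues)} present in chain {chain!r}"
        )
    return np.array([structure.atoms[i].coords for i in idx])


def count_region_waters(
    structure: Structure,
    region: str = "groove",
    chain: str = "A",
    radius: float = WATER_RADIUS,
    lining_residues: Sequence[int] = GROOVE_LINING_RESIDUES,
    include_hydrogens: bool = False,
) -> HydrationCount:
    """Count waters in the groove shell and/or the vestibule slab.

    A water belongs to the groove if ANY of its atoms is within ``radius``
    (inclusive) of any sidechain atom of the lining residues; to the slab if
    any atom's z lies between the CA z-planes of residues T381 and Q436
    (inclusive).  ``region`` selects which count is populated ("groove",
    "slab" or "both"; the other is reported as 0).
    """
    if region not in ("groove", "slab", "both"):
        raise ValueError(f"unknown region {region!r}")
    waters = _water_groups(structure)
    if not waters:
        logger.info("no water residues found in frame")
        return HydrationCount(0, 0, region)

    n_groove = 0
    n_slab = 0
    if region in ("groove", "both"):
        lining = _sidechain_coords(structure, chain, lining_residues,
                                   include_hydrogens)
        for idx in waters.values():
            wx = np.array([structure.atoms[i].coords for i in idx
                           if include_hydrogens or not structure.atoms[i].is_hydrogen])
            if cdist(wx, lining).min() <= radius:
                n_groove += 1
    if region in ("slab", "both"):
        z_lo_arr = _named_atom_coords(structure, chain, SLAB_PLANE_RESIDUES[0], ("CA",))
        z_hi_arr = _named_atom_coords(structure, chain, SLAB_PLANE_RESIDUES[1], ("CA",))
        z1, z2 = float(z_lo_arr[0, 2]), float(z_hi_arr[0, 2])
        z_lo, z_hi = min(z1, z2), max(z1, z2)
        for idx in waters.values():
            zs = np.array([structure.atoms[i].coords[2] for i in idx])
            if np.any((zs >= z_lo) & (zs <= z_hi)):
                n_slab += 1
    return HydrationCount(n_groove, n_slab, region)


#: Head/tail atom-name partitions by lipid residue name.  The head extends
#: down to the C21-O21 / C31-O32 carbonyls; everything else in the acyl
#: chains is tail.  Names follow common CHARMM lipid nomenclature.
_POPX_HEAD = (
    "N", "C12", "C13", "C14", "C15", "C11", "P", "O13", "O14", "O11", "O12",
    "C1", "C2", "C3", "O21", "C21", "O22", "O31", "C31", "O32",
    "OC2", "OC3", "HO2", "HO3",
)
_LIPID_PARTITIONS: dict[str, tuple[str, ...]] = {
    "POPE": _POPX_HEAD,
    "POPC": _POPX_HEAD,
    "POPG": _POPX_HEAD + ("C11", "C12", "C13", "O2", "O3"),
    # toy lipids from synthetic.make_toy_groove: P*/OH* head, C*T tail
    "TOY": tuple(),
}


def _split_head_tail(structure: Structure, idx: list[int]) -> tuple[list[int], list[int]]:
    a0 = structure.atoms[idx[0]]
    resname = a0.residue_name
    if resname == "TOY":
        head = [i for i in idx if not structure.atoms[i].atom_name.endswith("T")]
        tail = [i for i in idx if structure.atoms[i].atom_name.endswith("T")]
        return head, tail
    if resname not in _LIPID_PARTITIONS:
        raise ValueError(
            f"unknown lipid residue name {resname!r}; supported: "
            f"{sorted(_LIPID_PARTITIONS)}"
        )
    head_names = set(_LIPID_PARTITIONS[resname])
    head = [i for i in idx if structure.atoms[i].atom_name in head_names]
    tail = [i for i in idx if structure.atoms[i].atom_name not in head_names]
    return head, tail


def lipid_penetration(
    structure: Structure,
    chain: str = "A",
    radius: float = LIPID_RADIUS,
    interior_residues: Sequence[int] = GROOVE_INTERIOR_RESIDUES,
    lipid_resnames: Sequence[str] | None = None,
) -> LipidPenetration:
    """Head/tail penetration fractions of lipids into the groove interior.

    Fractions count non-hydrogen lipid atoms within ``radius`` (inclusive)
    of any sidechain atom of the interior residues, normalized by the total
    non-hydrogen atom count of the head (resp. tail) over all lipids.  The
    per-lipid breakdown identifies single penetrating lipids.
    """
    names = set(lipid_resnames) if lipid_resnames is not None else (
        set(_LIPID_PARTITIONS)
    )
    lipids: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.residue_name in names and not a.is_hydrogen:
            lipids.setdefault((a.chain_id, a.residue_number), []).append(i)
    if not lipids:
        return LipidPenetration(0.0, 0.0, tuple())
    interior = _sidechain_coords(structure, chain, interior_residues, False)

    tot_head = tot_tail = in_head = in_tail = 0
    per_lipid = []
    for (lchain, lres), idx in sorted(lipids.items()):
        head, tail = _split_head_tail(structure, idx)
        h_in = t_in = 0
        if head:
            hx = np.array([structure.atoms[i].coords for i in head])
            h_in = int(np.sum(cdist(hx, interior).min(axis=1) <= radius))
        if tail:
            tx = np.array([structure.atoms[i].coords for i in tail])
            t_in = int(np.sum(cdist(tx, interior).min(axis=1) <= radius))
        tot_head += len(head)
        tot_tail += len(tail)
        in_head += h_in
        in_tail += t_in
        per_lipid.append((
            lchain, lres,
            h_in / len(head) if head else 0.0,
            t_in / len(tail) if tail else 0.0,
        ))
    return LipidPenetration(
        head_fraction=in_head / tot_head if tot_head else 0.0,
        tail_fraction=in_tail / tot_tail if tot_tail else 0.0,
        per_lipid=tuple(per_lipid),
    )
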