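import numpy as np
import pytest

from groovekit import synthetic
from groovekit.synthetic import ToyGrooveSpec


def ring_layout(radius: float = 12.0, z_step: float = 2.5) -> dict[int, np.ndarray]:
    """Deterministic anchor positions for the default toy residues."""
    numbers = [n for n, _ in synthetic.DEFAULT_RESIDUES]
    positions = {}
    for i, n in enumerate(numbers):
        theta = 2 * np.pi * i / len(numbers)
        positions[n] = np.array(
            [radius * np.cos(theta), radius * np.sin(theta), (i % 5) * z_step]
        )
    return positions


@pytest.fixture
def groove_spec() -> ToyGrooveSpec:
    return ToyGrooveSpec(residue_positions=ring_layout())


@pytest.fixture
def groove_structure(groove_spec):
    return synthetic.make_toy_groove(groove_spec)


def brute_force_min_distance(structure, idx_a, idx_b) -> float:
    """O(n^2) all-pairs minimum distance oracle."""
    best = np.inf
    for i in idx_a:
        for j in idx_b:
            d = np.linalg.norm(structure.atoms[i].coords - structure.atoms[j].coords)
            best = min(best, d)
    return best


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent RMSD oracle via the Horn quaternion eigenvalue method."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = len(P)
    sq = (np.sum(P**2) + np.sum(Q**2) - 2 * lam_max) / n
    return float(np.sqrt(max(sq, 0.0)))
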