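"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from allocomm import StructureModel, make_synthetic_topology


def min_rmsd_by_rotation_search(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent superposition oracle: numeric minimization over rotations.

    Centers both sets (the optimal translation for any fixed rotation) and
    minimizes RMSD over the rotation-vector parameterization from many
    starting points, including a coarse grid of starts.  Deliberately avoids
    the closed-form solution used by the implementation.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    n = len(mob)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.sum((mob @ R.T - ref) ** 2) / n)

    best = np.inf
    starts = [np.zeros(3)]
    rng = np.random.default_rng(1234)
    starts += list(rng.uniform(-np.pi, np.pi, size=(30, 3)))
    for ang in (np.pi / 2, np.pi, 3 * np.pi / 2):
        for axis in np.eye(3):
            starts.append(ang * axis)
    for s in starts:
        res = minimize(rmsd_of, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return float(best)


def entropy_sum_coinformation(cov: np.ndarray, d_t: int, d_r: int, d_x: int) -> float:
    """Three-body co-information via the full seven-term entropy expansion.

    CI = H(T)+H(R)+H(X) - H(TR) - H(TX) - H(RX) + H(TRX), each entropy
    computed from a raw slogdet — an independent route from the package's
    MI-difference form.
    """
    ln2pie = np.log(2 * np.pi * np.e)

    def H(idx):
        sub = cov[np.ix_(idx, idx)]
        return 0.5 * (len(idx) * ln2pie + np.linalg.slogdet(sub)[1])

    t = list(range(d_t))
    r = list(range(d_t, d_t + d_r))
    x = list(range(d_t + d_r, d_t + d_r + d_x))
    return (H(t) + H(r) + H(x)) - (H(t + r) + H(t + x) + H(r + x)) + H(t + r + x)


@pytest.fixture
def helix_topology() -> StructureModel:
    """12-residue CA+CB helical topology, residues 1..12 (mature frame)."""
    return make_synthetic_topology(12)


@pytest.fixture
def kinase_like_topology() -> StructureModel:
    """Topology numbered like a mature kinase N-lobe (683-772) with glycines.

    Residues 695, 699 and 701 are glycines (Cα only) — the composition the
    P-loop region presents when Cα+Cβ selections are requested.
    """
    top = make_synthetic_topology(90, start_residue=683)
    glycines = {695, 699, 701}
    keep = np.ones(top.n_atoms, dtype=bool)
    res_names = top.residue_names.copy()
    for i in range(top.n_atoms):
        if int(top.residue_numbers[i]) in glycines:
            res_names[i] = "GLY"
            if top.atom_names[i] == "CB":
                keep[i] = False
    return StructureModel(
        atom_names=top.atom_names[keep],
        elements=top.elements[keep],
        residue_numbers=top.residue_numbers[keep],
        residue_names=res_names[keep],
        chain_ids=top.chain_ids[keep],
        coords=top.coords[keep],
        numbering_convention="mature",
    )
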