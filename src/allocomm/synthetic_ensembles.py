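"""Synthetic coordinate ensembles with analytically known information content.

Two generators provide ground truth for the estimator pipeline:

* :func:`make_gaussian_ensemble` draws i.i.d. (optionally AR(1)-correlated)
  frames from an explicitly constructed joint Gaussian over several atom
  "bodies" with controllable inter-body coordinate correlations, so the
  mutual information between any two bodies is known in closed form from the
  determinant identity.

* :func:`make_enm_ensemble` samples the Boltzmann ensemble of an isotropic
  Gaussian (elastic) network built on a structure's atoms: covariance
  kB*T/gamma times the Kirchhoff-matrix pseudo-inverse, Kronecker-expanded
  to Cartesian space.  Any two selections then have analytic MI through the
  same identity.

Both are fully reproducible under a fixed seed, and both emit their analytic
covariance alongside the frames so downstream tests never re-derive ground
truth by hand.  :func:`make_rigid_pair` provides rigid/noisy coordinate-set
pairs for superposition tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import EnsembleSpecError
from .nbit import KB_KCAL_PER_MOL_K, gaussian_mi_nats
from .structio import MATURE, BodySelection, Ensemble, StructureModel


def make_synthetic_topology(
    n_residues: int,
    atoms_per_residue: int = 2,
    start_residue: int = 1,
    convention: str = MATURE,
    residue_name: str = "ALA",
    chain_id: str = "A",
    helix_radius: float = 2.3,
    helix_rise: float = 1.5,
) -> StructureModel:
    """Protein-like topology on an ideal α-helical Cα trace.

    Each residue carries a Cα and, with ``atoms_per_residue=2``, a Cβ offset
    radially outward — the atom pair the NbIT bodies are built from.  The
    helical geometry keeps sequential neighbours within elastic-network
    cutoff distances.
    """
    if atoms_per_residue not in (1, 2):
        raise ValueError("atoms_per_residue must be 1 (CA) or 2 (CA+CB)")
    names, elements, res_ids, res_names, chains, coords = [], [], [], [], [], []
    turn = np.deg2rad(100.0)  # ~3.6 residues/turn
    for i in range(n_residues):
        theta = i * turn
        ca = np.array([helix_radius * np.cos(theta), helix_radius * np.sin(theta), i * helix_rise])
        positions = [("CA", ca)]
        if atoms_per_residue == 2:
            outward = np.array([np.cos(theta), np.sin(theta), 0.0])
            positions.append(("CB", ca + 1.53 * outward))
        for name, xyz in positions:
            names.append(name)
            elements.append("C")
            res_ids.append(start_residue + i)
            res_names.append(residue_name)
            chains.append(chain_id)
            coords.append(xyz)
    return StructureModel(
        atom_names=np.array(names),
        elements=np.array(elements),
        residue_numbers=np.array(res_ids),
        residue_names=np.array(res_names),
        chain_ids=np.array(chains),
        coords=np.array(coords),
        numbering_convention=convention,
    )


# ---------------------------------------------------------------------------
# Gaussian body ensembles
# ---------------------------------------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Specification of a multi-body jointly Gaussian coordinate ensemble.

    ``body_sizes`` are atom counts per body; ``per_pair_correlation`` is a
    scalar (applied to every body pair) or a symmetric matrix of coordinate
    correlations rho between bodies.  Coordinate j of body a is coupled to
    coordinate j of body b for j < ``n_coupled_pairs`` (default: all shared
    coordinates), each with correlation rho_ab; all other coordinates are
    independent.  ``base_variance`` (Å^2) sets the per-coordinate marginal
    variance; the default 0.25 Å^2 corresponds to ~0.5 Å positional
    fluctuations, typical of a well-ordered pocket.  ``ar1_phi`` adds AR(1)
    frame-to-frame correlation with the same stationary covariance, for
    exercising block-bootstrap error estimation.
    """

    body_sizes: list[int]
    per_pair_correlation: float | np.ndarray = 0.0
    base_variance: float = 0.25
    n_frames: int = 1000
    seed: int = 0
    n_coupled_pairs: int | None = None
    ar1_phi: float = 0.0
    atoms_per_residue: int = 2

    def correlation_matrix(self) -> np.ndarray:
        k = len(self.body_sizes)
        rho = np.asarray(self.per_pair_correlation, dtype=float)
        if rho.ndim == 0:
            mat = np.full((k, k), float(rho))
            np.fill_diagonal(mat, 1.0)
            return mat
        if rho.shape != (k, k) or not np.allclose(rho, rho.T):
            raise EnsembleSpecError("per_pair_correlation must be scalar or a symmetric k x k matrix")
        return rho

    def validate(self) -> None:
        if not self.body_sizes or any(s < 1 for s in self.body_sizes):
            raise EnsembleSpecError("body_sizes must be positive atom counts")
        if self.base_variance <= 0:
            raise EnsembleSpecError("base_variance must be positive")
        if self.n_frames < 1:
            raise EnsembleSpecError("n_frames must be >= 1")
        if not -1.0 < self.ar1_phi < 1.0:
            raise EnsembleSpecError("ar1_phi must lie in (-1, 1)")
        rho = self.correlation_matrix()
        off = rho[~np.eye(len(self.body_sizes), dtype=bool)]
        if np.any(np.abs(off) >= 1.0):
            raise EnsembleSpecError("|rho| must be < 1 for all body pairs")


@dataclass
class GaussianEnsembleResult:
    """Generated ensemble plus its analytic ground truth."""

    ensemble: Ensemble
    bodies: list[BodySelection]
    cov: np.ndarray  # joint covariance, coordinate order = bodies concatenated
    mi_nats: dict[tuple[int, int], float]
    spec: GaussianEnsembleSpec

    def analytic_mi_nats(self, i: int = 0, j: int = 1) -> float:
        return self.mi_nats[(min(i, j), max(i, j))]


def _build_joint_covariance(spec: GaussianEnsembleSpec) -> np.ndarray:
    dims = [3 * s for s in spec.body_sizes]
    offsets = np.concatenate([[0], np.cumsum(dims)])
    D = int(offsets[-1])
    C = np.eye(D)
    rho = spec.correlation_matrix()
    for a in range(len(dims)):
        for b in range(a + 1, len(dims)):
            r = rho[a, b]
            if r == 0.0:
                continue
            k = min(dims[a], dims[b])
            if spec.n_coupled_pairs is not None:
                k = min(k, spec.n_coupled_pairs)
            for j in range(k):
                C[offsets[a] + j, offsets[b] + j] = r
                C[offsets[b] + j, offsets[a] + j] = r
    return spec.base_variance * C


def _sample_gaussian_frames(
    cov: np.ndarray, n_frames: int, seed: int, ar1_phi: float = 0.0
) -> np.ndarray:
    """Frames (n, D) with stationary covariance ``cov``; AR(1) in time if requested."""
    eigval, eigvec = np.linalg.eigh(cov)
    if np.min(eigval) <= 0:
        raise EnsembleSpecError(
            f"constructed covariance is not positive definite (min eigenvalue {np.min(eigval):.3e})"
        )
    A = eigvec * np.sqrt(eigval)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_frames, cov.shape[0]))
    if ar1_phi != 0.0:
        scale = np.sqrt(1.0 - ar1_phi**2)
        for t in range(1, n_frames):
            Z[t] = ar1_phi * Z[t - 1] + scale * Z[t]
    return Z @ A.T


def make_gaussian_ensemble(spec: GaussianEnsembleSpec) -> GaussianEnsembleResult:
    """Draw a coordinate ensemble from the constructed joint Gaussian.

    The topology lays the bodies out as consecutive residues (CA+CB per
    residue by default) on a helical trace; fluctuations are added to those
    mean coordinates.  Analytic MI for every body pair comes from the
    determinant identity evaluated on the constructed covariance.
    """
    spec.validate()
    cov = _build_joint_covariance(spec)

    apr = spec.atoms_per_residue
    total_atoms = sum(spec.body_sizes)
    residues_per_body = [int(np.ceil(s / apr)) for s in spec.body_sizes]
    topology = make_synthetic_topology(sum(residues_per_body), atoms_per_residue=apr)
    # Bodies occupy whole residues; trim trailing atoms when size is not a
    # multiple of atoms_per_residue.
    bodies, atom_cursor, res_cursor = [], 0, 0
    for size, n_res in zip(spec.body_sizes, residues_per_body):
        res_atoms = np.arange(res_cursor * apr, res_cursor * apr + size)
        bodies.append(
            BodySelection(
                atom_indices=res_atoms,
                residue_numbers=list(range(res_cursor + 1, res_cursor + n_res + 1)),
                numbering_convention=topology.numbering_convention,
                atom_name_filter=("CA", "CB") if apr == 2 else ("CA",),
                role="channel",
            )
        )
        atom_cursor += size
        res_cursor += n_res
    keep = np.concatenate([b.atom_indices for b in bodies])
    if keep.size != topology.n_atoms:
        # Drop padding atoms of partially filled residues, reindex bodies.
        remap = {int(a): i for i, a in enumerate(np.sort(keep))}
        topology = StructureModel(
            atom_names=topology.atom_names[keep],
            elements=topology.elements[keep],
            residue_numbers=topology.residue_numbers[keep],
            residue_names=topology.residue_names[keep],
            chain_ids=topology.chain_ids[keep],
            coords=topology.coords[keep],
            hetero=topology.hetero[keep],
            numbering_convention=topology.numbering_convention,
        )
        for b in bodies:
            b.atom_indices = np.array([remap[int(a)] for a in b.atom_indices])
    assert topology.n_atoms == total_atoms

    fluct = _sample_gaussian_frames(cov, spec.n_frames, spec.seed, spec.ar1_phi)
    coords = topology.coords[None, :, :] + fluct.reshape(spec.n_frames, total_atoms, 3)
    ensemble = Ensemble(topology=topology, coords=coords, label=f"gaussian_seed{spec.seed}")

    dims = [3 * s for s in spec.body_sizes]
    offsets = np.concatenate([[0], np.cumsum(dims)])
    mi = {}
    for a in range(len(dims)):
        for b in range(a + 1, len(dims)):
            idx = np.concatenate(
                [np.arange(offsets[a], offsets[a + 1]), np.arange(offsets[b], offsets[b + 1])]
            )
            mi[(a, b)] = gaussian_mi_nats(cov[np.ix_(idx, idx)], dims[a], eigenvalue_floor=0.0)
    return GaussianEnsembleResult(ensemble=ensemble, bodies=bodies, cov=cov, mi_nats=mi, spec=spec)


def analytic_pair_mi_nats(rho: float, n_pairs: int) -> float:
    """Closed-form MI for n_pairs independently coupled coordinate pairs:
    -(n_pairs/2) ln(1 - rho^2)."""
    return -0.5 * n_pairs * float(np.log1p(-rho * rho))


# ---------------------------------------------------------------------------
# Elastic-network (isotropic Gaussian network) ensembles
# ---------------------------------------------------------------------------

@dataclass
class ENMSpec:
    """Isotropic Gaussian-network ensemble specification.

    Springs of stiffness ``spring_constant`` (kcal mol^-1 Å^-2) connect every
    atom pair of ``structure`` within ``cutoff`` Å.  The Boltzmann ensemble
    of this network is Gaussian with per-axis covariance
    kB*T/gamma * Kirchhoff^+; the three Cartesian axes are independent and
    identically distributed (isotropic network), so the full 3N covariance is
    the Kronecker product with the 3x3 identity.
    """

    structure: StructureModel
    cutoff: float = 8.0
    spring_constant: float = 1.0
    temperature: float = 310.0
    n_frames: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.structure.n_atoms < 10:
            raise EnsembleSpecError("elastic network needs >= 10 atoms")
        if self.cutoff <= 0 or self.spring_constant <= 0 or self.temperature <= 0:
            raise EnsembleSpecError("cutoff, spring_constant, and temperature must be positive")
        if self.n_frames < 1:
            raise EnsembleSpecError("n_frames must be >= 1")


@dataclass
class ENMEnsembleResult:
    """Generated ENM ensemble plus analytic covariance (3N x 3N, Å^2)."""

    ensemble: Ensemble
    cov: np.ndarray
    kirchhoff: np.ndarray
    spec: ENMSpec

    def analytic_mi_nats(self, body_a: BodySelection, body_b: BodySelection) -> float:
        """Analytic MI between two selections from the network covariance."""
        idx = np.concatenate(
            [
                (3 * body_a.atom_indices[:, None] + np.arange(3)).ravel(),
                (3 * body_b.atom_indices[:, None] + np.arange(3)).ravel(),
            ]
        )
        return gaussian_mi_nats(self.cov[np.ix_(idx, idx)], body_a.n_dims, eigenvalue_floor=0.0)


def _kirchhoff_matrix(coords: np.ndarray, cutoff: float, gamma: float) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    n = coords.shape[0]
    contact = squareform(pdist(coords)) <= cutoff
    np.fill_diagonal(contact, False)
    K = -gamma * contact.astype(float)
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def make_enm_ensemble(spec: ENMSpec) -> ENMEnsembleResult:
    """Sample the Boltzmann ensemble of an isotropic elastic network.

    The network's Kirchhoff matrix has one zero mode per connected component
    (uniform translation); a disconnected contact graph is rejected because
    inter-component covariance would be undefined.  The null space is removed
    by eigenvalue thresholding before pseudo-inversion.
    """
    from scipy.sparse.csgraph import connected_components

    spec.validate()
    coords0 = spec.structure.coords
    K = _kirchhoff_matrix(coords0, spec.cutoff, spec.spring_constant)
    adjacency = (K != 0) & ~np.eye(K.shape[0], dtype=bool)
    n_comp, _ = connected_components(adjacency, directed=False)
    if n_comp != 1:
        raise EnsembleSpecError(
            f"contact network is disconnected ({n_comp} components) at cutoff "
            f"{spec.cutoff} Å; inter-component fluctuations are unbounded"
        )

    eigval, eigvec = np.linalg.eigh(K)
    tol = max(1e-10, 1e-9 * eigval[-1])
    nonzero = eigval > tol
    inv_eig = np.where(nonzero, 1.0 / np.where(nonzero, eigval, 1.0), 0.0)
    kT = KB_KCAL_PER_MOL_K * spec.temperature
    cov_n = kT * (eigvec * inv_eig) @ eigvec.T  # per-axis covariance, Å^2

    n = coords0.shape[0]
    rng = np.random.default_rng(spec.seed)
    A = eigvec[:, nonzero] * np.sqrt(kT * inv_eig[nonzero])
    # Three i.i.d. Cartesian axes.
    fluct = np.empty((spec.n_frames, n, 3))
    for axis in range(3):
        fluct[:, :, axis] = rng.standard_normal((spec.n_frames, A.shape[1])) @ A.T
    ensemble = Ensemble(
        topology=spec.structure,
        coords=coords0[None, :, :] + fluct,
        label=f"enm_seed{spec.seed}",
    )
    cov = np.kron(cov_n, np.eye(3))
    return ENMEnsembleResult(ensemble=ensemble, cov=cov, kirchhoff=K, spec=spec)


# ---------------------------------------------------------------------------
# Rigid fixtures for superposition tests
# ---------------------------------------------------------------------------

@dataclass
class RigidPair:
    coords_a: np.ndarray
    coords_b: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray


def make_rigid_pair(
    n_atoms: int,
    rotation_euler_deg: tuple[float, float, float] = (25.0, -40.0, 60.0),
    translation: tuple[float, float, float] = (5.0, -3.0, 2.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> RigidPair:
    """Coordinate-set pair b = R a + t (+ isotropic noise) for superposition tests.

    With ``noise_sigma=0`` optimal superposition recovers R, t and RMSD 0.
    """
    if n_atoms < 4:
        raise ValueError("n_atoms must be >= 4")
    rng = np.random.default_rng(seed)
    a = rng.uniform(-10.0, 10.0, size=(n_atoms, 3))
    R = Rotation.from_euler("xyz", rotation_euler_deg, degrees=True).as_matrix()
    t = np.asarray(translation, dtype=float)
    b = a @ R.T + t
    if noise_sigma > 0:
        b = b + rng.normal(0.0, noise_sigma, size=b.shape)
    return RigidPair(coords_a=a, coords_b=b, rotation=R, translation=t)
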