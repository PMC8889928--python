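"""N-body information theory (NbIT) on Cartesian fluctuation ensembles.

The quasi-harmonic approximation treats equilibrium coordinate fluctuations
of a selected atom set as multivariate Gaussian, so configurational entropy
follows from the covariance matrix:

    H = (1/2) ln[(2 pi e)^d det Sigma]        (nats)

and the mutual information between two bodies T and R is

    MI(T;R) = H(T) + H(R) - H(T,R)
            = (1/2) ln[det Sigma_T det Sigma_R / det Sigma_joint]  >= 0.

The co-information of a candidate channel body X,

    CI(T;R;X) = MI(T;R) - MI(T;R | X),

is positive when X carries information shared between transmitter and
receiver, which is how mediating residues of an allosteric pathway are
ranked.  All determinants are evaluated as sums of log-eigenvalues with an
eigenvalue floor, never as raw determinants.

MI in nats is converted to kcal/mol with kB*T (kB = 0.0019872
kcal mol^-1 K^-1); the default temperature of 310 K matches physiological
simulation conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import RankDeficiencyError, SelectionError
from .geometry import superpose_frames
from .structio import BodySelection, Ensemble, select_body

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872
#: Simulation temperature (K) used for the nats -> kcal/mol conversion.
DEFAULT_TEMPERATURE = 310.0
#: Default eigenvalue floor (Å^2) for near-singular joint covariances.
DEFAULT_EIGENVALUE_FLOOR = 1e-8

_LN_2PIE = float(np.log(2.0 * np.pi * np.e))


def kcal_per_nat(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kcal/mol corresponding to one nat at the given temperature (kB*T)."""
    return KB_KCAL_PER_MOL_K * float(temperature)


@dataclass
class CovarianceModel:
    """Mean and covariance of a selection's Cartesian coordinate vector.

    ``cov`` is the raw (sample) covariance in Å^2; regularization — an
    eigenvalue floor plus optional shrinkage toward the diagonal — is
    recorded here and applied when eigenvalues are consumed.
    """

    mean: np.ndarray
    cov: np.ndarray
    n_frames: int
    selection: BodySelection | None = None
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR
    shrinkage: float = 0.0
    stride: int = 1

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        d = self.mean.size
        if self.cov.shape != (d, d):
            raise ValueError(f"covariance shape {self.cov.shape} inconsistent with mean length {d}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def n_dims(self) -> int:
        return self.mean.size

    def regularized_eigenvalues(self) -> np.ndarray:
        """Eigenvalues after shrinkage and the eigenvalue floor (ascending)."""
        return np.maximum(np.linalg.eigvalsh(_shrink(self.cov, self.shrinkage)), self.eigenvalue_floor)


def _shrink(cov: np.ndarray, shrinkage: float) -> np.ndarray:
    if shrinkage <= 0:
        return cov
    return (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))


def estimate_covariance(
    ensemble: Ensemble,
    selection: BodySelection,
    fit: BodySelection | None = None,
    stride: int = 1,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
    shrinkage: float = 0.0,
    superpose_iterations: int = 2,
) -> CovarianceModel:
    """Sample mean and covariance of a selection's coordinates.

    With a ``fit`` selection, every used frame is first superposed onto the
    iteratively refined mean structure of the fit atoms (two passes by
    default) so that rigid-body motion does not masquerade as internal
    correlation.  ``stride`` subsamples frames; the frames actually used are
    recorded on the returned model.

    Raises :class:`RankDeficiencyError` when fewer frames than coordinate
    dimensions are available and no shrinkage is requested.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    coords = ensemble.coords[::stride]
    n_used = coords.shape[0]
    d = selection.n_dims
    if n_used - 1 < d and shrinkage <= 0:
        raise RankDeficiencyError(
            f"{n_used} frames cannot support a full-rank {d}-dimensional covariance; "
            "increase frames, raise stride resolution, or enable shrinkage"
        )
    if fit is not None:
        coords = superpose_frames(coords, fit.atom_indices, n_iter=superpose_iterations)
    X = coords[:, selection.atom_indices].reshape(n_used, d)
    mean = X.mean(axis=0)
    Xc = X - mean
    denom = max(n_used - 1, 1)
    cov = (Xc.T @ Xc) / denom
    return CovarianceModel(
        mean=mean,
        cov=cov,
        n_frames=n_used,
        selection=selection,
        eigenvalue_floor=eigenvalue_floor,
        shrinkage=shrinkage,
        stride=stride,
    )


def gaussian_entropy(
    cov: CovarianceModel | np.ndarray,
    eigenvalue_floor: float | None = None,
) -> float:
    """Quasi-harmonic (Gaussian) entropy in nats: 0.5 * ln[(2 pi e)^d det Sigma].

    The log-determinant is the sum of log-eigenvalues clipped at the floor.
    """
    if isinstance(cov, CovarianceModel):
        eig = cov.regularized_eigenvalues()
        if eigenvalue_floor is not None:
            eig = np.maximum(eig, eigenvalue_floor)
    else:
        cov = np.asarray(cov, dtype=float)
        # LAPACK returns garbage (not NaN) eigenvalues for non-finite input
        if not np.all(np.isfinite(cov)):
            raise FloatingPointError("non-finite entries in covariance")
        floor = DEFAULT_EIGENVALUE_FLOOR if eigenvalue_floor is None else eigenvalue_floor
        eig = np.maximum(np.linalg.eigvalsh(0.5 * (cov + cov.T)), floor)
    if eig.size < 1:
        raise ValueError("entropy needs dimension >= 1")
    if not np.all(np.isfinite(eig)):
        raise FloatingPointError("non-finite eigenvalue in covariance")
    return float(0.5 * (eig.size * _LN_2PIE + np.sum(np.log(eig))))


# ---------------------------------------------------------------------------
# Closed-form expressions on explicit covariance matrices.  These operate on
# any ordered block covariance and back both the estimators below and the
# analytic sidecar values of the synthetic generators.
# ---------------------------------------------------------------------------

def gaussian_mi_nats(
    cov_joint: np.ndarray,
    d_first: int,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
) -> float:
    """MI (nats) between the first ``d_first`` coordinates and the rest of a joint covariance."""
    cov_joint = np.asarray(cov_joint, dtype=float)
    h_t = gaussian_entropy(cov_joint[:d_first, :d_first], eigenvalue_floor)
    h_r = gaussian_entropy(cov_joint[d_first:, d_first:], eigenvalue_floor)
    h_joint = gaussian_entropy(cov_joint, eigenvalue_floor)
    return h_t + h_r - h_joint


def gaussian_coinformation_nats(
    cov_joint: np.ndarray,
    d_t: int,
    d_r: int,
    d_x: int,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
) -> float:
    """CI(T;R;X) in nats from a joint covariance ordered as [T, R, X].

    CI = MI(T;R) - MI(T;R|X); the conditional term is expressed through
    entropies of the marginal blocks, H(TX) + H(RX) - H(X) - H(TRX), so the
    whole quantity reduces to seven entropy evaluations of submatrices.
    """
    cov_joint = np.asarray(cov_joint, dtype=float)
    if cov_joint.shape[0] != d_t + d_r + d_x:
        raise ValueError("block sizes inconsistent with joint covariance")
    sl_t = slice(0, d_t)
    sl_r = slice(d_t, d_t + d_r)
    sl_x = slice(d_t + d_r, d_t + d_r + d_x)

    def H(*slices):
        idx = np.concatenate([np.arange(s.start, s.stop) for s in slices])
        return gaussian_entropy(cov_joint[np.ix_(idx, idx)], eigenvalue_floor)

    mi_tr = H(sl_t) + H(sl_r) - H(sl_t, sl_r)
    mi_tr_given_x = H(sl_t, sl_x) + H(sl_r, sl_x) - H(sl_x) - H(sl_t, sl_r, sl_x)
    return mi_tr - mi_tr_given_x


# ---------------------------------------------------------------------------
# Ensemble-level estimators
# ---------------------------------------------------------------------------

@dataclass
class InformationResult:
    """Entropies and mutual information between a transmitter and receiver body.

    ``per_replica`` holds the per-trajectory MI values (kcal/mol) when
    several replicate ensembles are analyzed; ``spread`` is their standard
    deviation, the quantity shown as error bars on replicate-averaged MI.
    """

    h_transmitter: float
    h_receiver: float
    h_joint: float
    mi_nats: float
    mi_kcal: float
    temperature: float
    per_replica: list[float] = field(default_factory=list)
    spread: float | None = None
    n_frames: int = 0

    def to_dict(self) -> dict:
        return {
            "mi_kcal": self.mi_kcal,
            "mi_nats": self.mi_nats,
            "h_transmitter": self.h_transmitter,
            "h_receiver": self.h_receiver,
            "h_joint": self.h_joint,
            "temperature": self.temperature,
            "per_replica": list(self.per_replica),
            "spread": self.spread,
            "n_frames": self.n_frames,
        }


def _as_ensemble_list(ensembles) -> list[Ensemble]:
    if isinstance(ensembles, Ensemble):
        return [ensembles]
    out = list(ensembles)
    if not out:
        raise ValueError("at least one ensemble is required")
    return out


def _joint_selection(transmitter: BodySelection, receiver: BodySelection, *more) -> BodySelection:
    bodies = (transmitter, receiver) + more
    for i, a in enumerate(bodies):
        for b in bodies[i + 1:]:
            if a.overlaps(b):
                raise SelectionError(
                    f"selections must be disjoint; {a.role} and {b.role} share atoms"
                )
    return BodySelection(
        atom_indices=np.concatenate([b.atom_indices for b in bodies]),
        residue_numbers=sorted({r for b in bodies for r in b.residue_numbers}),
        numbering_convention=transmitter.numbering_convention,
        atom_name_filter=transmitter.atom_name_filter,
        role="channel",
    )


def _block_order(joint: BodySelection, bodies: tuple[BodySelection, ...]) -> np.ndarray:
    """Coordinate permutation mapping the sorted joint selection onto [body0, body1, ...]."""
    pos = {int(a): i for i, a in enumerate(joint.atom_indices)}
    atom_order = np.concatenate([[pos[int(a)] for a in b.atom_indices] for b in bodies])
    return (3 * atom_order[:, None] + np.arange(3)[None, :]).ravel()


def _mi_single(
    ensemble: Ensemble,
    transmitter: BodySelection,
    receiver: BodySelection,
    fit: BodySelection | None,
    stride: int,
    eigenvalue_floor: float,
    shrinkage: float,
) -> tuple[float, float, float, int]:
    """(h_t, h_r, h_joint) in nats plus frames used, from one joint covariance."""
    joint_sel = _joint_selection(transmitter, receiver)
    model = estimate_covariance(
        ensemble, joint_sel, fit=fit, stride=stride,
        eigenvalue_floor=eigenvalue_floor, shrinkage=shrinkage,
    )
    perm = _block_order(joint_sel, (transmitter, receiver))
    cov = _shrink(model.cov, shrinkage)[np.ix_(perm, perm)]
    d_t = transmitter.n_dims
    h_t = gaussian_entropy(cov[:d_t, :d_t], eigenvalue_floor)
    h_r = gaussian_entropy(cov[d_t:, d_t:], eigenvalue_floor)
    h_joint = gaussian_entropy(cov, eigenvalue_floor)
    return h_t, h_r, h_joint, model.n_frames


def mutual_information(
    ensembles: Ensemble | list[Ensemble],
    transmitter: BodySelection,
    receiver: BodySelection,
    fit: BodySelection | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    stride: int = 1,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
    shrinkage: float = 0.0,
    pool_frames: bool = False,
) -> InformationResult:
    """Quasi-harmonic mutual information between two disjoint bodies.

    With several replicate ensembles, MI is estimated per replica and
    averaged; ``spread`` is the cross-replica standard deviation.  With
    ``pool_frames=True`` all frames are concatenated into a single estimate
    instead (each replica must then share one topology).
    """
    reps = _as_ensemble_list(ensembles)
    if pool_frames and len(reps) > 1:
        pooled = Ensemble(
            topology=reps[0].topology,
            coords=np.concatenate([e.coords for e in reps], axis=0),
            label="+".join(e.label for e in reps),
        )
        reps = [pooled]

    kT = kcal_per_nat(temperature)
    per_nats, per_frames = [], []
    parts = []
    for ens in reps:
        h_t, h_r, h_j, n_used = _mi_single(
            ens, transmitter, receiver, fit, stride, eigenvalue_floor, shrinkage
        )
        parts.append((h_t, h_r, h_j))
        per_nats.append(h_t + h_r - h_j)
        per_frames.append(n_used)

    mi_nats = float(np.mean(per_nats))
    h_t, h_r, h_j = (float(np.mean([p[i] for p in parts])) for i in range(3))
    per_kcal = [m * kT for m in per_nats]
    spread = float(np.std(per_kcal, ddof=1)) if len(per_kcal) > 1 else None
    return InformationResult(
        h_transmitter=h_t,
        h_receiver=h_r,
        h_joint=h_j,
        mi_nats=mi_nats,
        mi_kcal=mi_nats * kT,
        temperature=temperature,
        per_replica=per_kcal,
        spread=spread,
        n_frames=int(np.sum(per_frames)),
    )


def coinformation(
    ensembles: Ensemble | list[Ensemble],
    transmitter: BodySelection,
    receiver: BodySelection,
    channel: BodySelection,
    fit: BodySelection | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    stride: int = 1,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
    shrinkage: float = 0.0,
) -> float:
    """Co-information CI(T;R;X) in kcal/mol, averaged over replicate ensembles.

    Positive CI means the channel body carries information shared between
    transmitter and receiver.
    """
    reps = _as_ensemble_list(ensembles)
    joint_sel = _joint_selection(transmitter, receiver, channel)
    perm = None
    values = []
    for ens in reps:
        model = estimate_covariance(
            ens, joint_sel, fit=fit, stride=stride,
            eigenvalue_floor=eigenvalue_floor, shrinkage=shrinkage,
        )
        if perm is None:
            perm = _block_order(joint_sel, (transmitter, receiver, channel))
        cov = _shrink(model.cov, shrinkage)[np.ix_(perm, perm)]
        values.append(
            gaussian_coinformation_nats(
                cov, transmitter.n_dims, receiver.n_dims, channel.n_dims, eigenvalue_floor
            )
        )
    return float(np.mean(values)) * kcal_per_nat(temperature)


@dataclass
class CoInformationProfile:
    """Per-residue co-information contributions, min-max normalized across conditions.

    ``values`` and ``normalized`` map each condition label to an array over
    ``residues``.  Normalization bounds are taken jointly over every residue
    of every condition supplied in one call, so profiles from different
    conditions are directly comparable.
    """

    residues: list[int]
    values: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    normalization_bounds: tuple[float, float]
    normalization_scope: str = "across all simulations"
    temperature: float = DEFAULT_TEMPERATURE

    def to_frame(self):
        import pandas as pd

        rows = []
        for label, vals in self.values.items():
            for res, raw, norm in zip(self.residues, vals, self.normalized[label]):
                rows.append(
                    {"condition": label, "residue": res, "coinformation_kcal": raw, "normalized": norm}
                )
        return pd.DataFrame(rows)


def _without_atoms(body: BodySelection, other: BodySelection) -> BodySelection:
    """Copy of ``body`` with any atoms shared with ``other`` removed."""
    keep = ~np.isin(body.atom_indices, other.atom_indices)
    if keep.all():
        return body
    if not keep.any():
        raise SelectionError(
            f"{body.role} body would be empty after removing channel atoms"
        )
    return BodySelection(
        atom_indices=body.atom_indices[keep],
        residue_numbers=body.residue_numbers,
        numbering_convention=body.numbering_convention,
        atom_name_filter=body.atom_name_filter,
        role=body.role,
    )


def per_residue_profile(
    ensembles: Ensemble | list[Ensemble],
    transmitter: BodySelection,
    receiver: BodySelection,
    candidate_residues: list[int],
    fit: BodySelection | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    stride: int = 1,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
    shrinkage: float = 0.0,
    channel_atoms: tuple[str, ...] = ("CA", "CB"),
    include_body_residues: bool = False,
) -> CoInformationProfile:
    """Scan candidate residues as channels and rank their co-information.

    Each candidate residue's Cα+Cβ atoms form the channel body; its
    CI(T;R;X) is computed per condition (ensemble), and the min-max
    normalization is taken jointly across every residue of every condition
    supplied in the call.  Candidates overlapping the transmitter or
    receiver are rejected unless ``include_body_residues`` is set.
    """
    reps = _as_ensemble_list(ensembles)
    if not candidate_residues:
        raise ValueError("candidate residue list is empty")
    body_res = set(transmitter.residue_numbers) | set(receiver.residue_numbers)
    if not include_body_residues:
        clash = [r for r in candidate_residues if r in body_res]
        if clash:
            raise SelectionError(
                f"candidate residues overlap transmitter/receiver bodies: {clash}; "
                "pass include_body_residues=True to scan them anyway"
            )

    labels = []
    values: dict[str, np.ndarray] = {}
    for k, ens in enumerate(reps):
        label = ens.label or f"condition_{k}"
        labels.append(label)
        ci = np.empty(len(candidate_residues))
        for j, res in enumerate(candidate_residues):
            channel = select_body(
                ens.topology, [res], atom_names=channel_atoms, role="channel"
            )
            # A candidate inside a body is scanned against that body minus
            # its own atoms, so no coordinate is counted twice.
            t_eff = _without_atoms(transmitter, channel)
            r_eff = _without_atoms(receiver, channel)
            ci[j] = coinformation(
                ens, t_eff, r_eff, channel, fit=fit, temperature=temperature,
                stride=stride, eigenvalue_floor=eigenvalue_floor, shrinkage=shrinkage,
            )
        values[label] = ci

    allvals = np.concatenate(list(values.values()))
    vmin, vmax = float(allvals.min()), float(allvals.max())
    if vmax - vmin <= 0:
        warnings.warn(
            "degenerate normalization: all per-residue co-information values are equal; "
            "normalized profile set to zeros",
            stacklevel=2,
        )
        normalized = {lab: np.zeros_like(v) for lab, v in values.items()}
    else:
        normalized = {lab: (v - vmin) / (vmax - vmin) for lab, v in values.items()}
    return CoInformationProfile(
        residues=list(candidate_residues),
        values=values,
        normalized=normalized,
        normalization_bounds=(vmin, vmax),
        temperature=temperature,
    )


def block_bootstrap_mi(
    ensemble: Ensemble,
    transmitter: BodySelection,
    receiver: BodySelection,
    fit: BodySelection | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    n_boot: int = 50,
    block_length: int | None = None,
    seed: int = 0,
    eigenvalue_floor: float = DEFAULT_EIGENVALUE_FLOOR,
) -> tuple[float, np.ndarray]:
    """Moving-block-bootstrap standard error of MI (kcal/mol) for one trajectory.

    MD frames are autocorrelated, so naive i.i.d. standard errors on MI are
    optimistic; resampling contiguous blocks (default length n_frames/50)
    preserves short-range correlation.  Returns (se, bootstrap samples).
    """
    n = ensemble.n_frames
    L = max(1, n // 50) if block_length is None else int(block_length)
    if L < 1 or L > n:
        raise ValueError("block length must be in [1, n_frames]")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / L))
    samples = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, n - L + 1, size=n_blocks)
        idx = np.concatenate([np.arange(s, s + L) for s in starts])[:n]
        boot = Ensemble(topology=ensemble.topology, coords=ensemble.coords[idx], label=ensemble.label)
        samples[b] = mutual_information(
            boot, transmitter, receiver, fit=fit, temperature=temperature,
            eigenvalue_floor=eigenvalue_floor,
        ).mi_kcal
    return float(np.std(samples, ddof=1)), samples


def mi_bias_bound_nats(d_t: int, d_r: int, n_frames: int, confidence: float = 0.999) -> float:
    """Upper bound on the plug-in MI estimate for truly independent Gaussian bodies.

    Under independence, 2n * MI_hat is asymptotically chi-square with
    d_t * d_r degrees of freedom; the bound is the requested quantile of that
    distribution divided by 2n.  Used to decide whether a small estimated MI
    is distinguishable from sampling noise.
    """
    from scipy.stats import chi2

    return float(chi2.ppf(confidence, d_t * d_r) / (2.0 * n_frames))
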