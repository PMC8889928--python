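"""Rigid-body superposition, RMSD series, and pocket-conformation metrics.

The optimal-rotation problem (Kabsch) is solved through
``scipy.spatial.transform.Rotation.align_vectors``, which returns a proper
rotation; this module wraps it with centroid handling, degeneracy checks,
weighted RMSD, and trajectory conveniences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, SelectionError
from .structio import BodySelection, Ensemble, StructureModel, convert_numbering

FIRST_FRAME = "first_frame"
MEAN_STRUCTURE = "mean_structure"


@dataclass
class SuperpositionResult:
    """Optimal rigid transform of a mobile set onto a reference set.

    The transform maps mobile coordinates x to ``rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_fit: int
    matched_residues: list[int] | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or abs(np.linalg.det(R) - 1) > 1e-8:
            raise GeometryError("rotation is not a proper orthonormal matrix")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the rigid transform to an (n, 3) coordinate array."""
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class MetricSeries:
    """A per-frame scalar metric (Å) with its defining selections."""

    name: str
    values: np.ndarray
    fit_selection: BodySelection | None = None
    measure_selection: BodySelection | None = None
    reference: str = FIRST_FRAME

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in metric series {self.name!r}")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def summary(self) -> dict:
        return {"name": self.name, "mean": self.mean, "sd": self.sd, "n_frames": len(self.values)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"frame": np.arange(len(self.values)), self.name: self.values})


def _weighted_rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None) -> float:
    d2 = np.sum((a - b) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(np.mean(d2)))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Requires >= 3 paired, non-collinear atoms.  The returned RMSD is the
    (weight-averaged) RMSD after applying the optimal transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError(
            f"coordinate sets must share shape (n, 3); got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"superposition needs >= 3 atoms, got {n}")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n,) or np.any(weights < 0) or not np.any(weights > 0):
            raise GeometryError("weights must be non-negative with positive sum, one per atom")

    w = np.ones(n) if weights is None else weights
    c_mob = np.average(mobile, axis=0, weights=w)
    c_ref = np.average(reference, axis=0, weights=w)
    mob_c = mobile - c_mob
    ref_c = reference - c_ref

    # Collinear (rank < 2) point sets leave a rotation axis undetermined.
    for pts in (mob_c, ref_c):
        s = np.linalg.svd(pts * w[:, None] ** 0.5, compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1.0):
            raise GeometryError("degenerate (collinear) coordinate set: superposition ill-defined")

    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    R = rot.as_matrix()
    t = c_ref - R @ c_mob
    rmsd = _weighted_rmsd(mobile @ R.T + t, reference, weights)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms_fit=n)


def superpose_frames(
    coords: np.ndarray,
    fit_indices: np.ndarray,
    reference: np.ndarray | None = None,
    n_iter: int = 2,
) -> np.ndarray:
    """Superpose every frame onto a reference using the fit atoms.

    With ``reference=None`` the reference is the iteratively refined mean
    structure: frames are first fit to frame 0, then re-fit to the mean of
    the fitted frames, ``n_iter`` times.  Returns a new coordinate array.
    """
    coords = np.asarray(coords, dtype=float)
    out = coords.copy()
    if reference is not None:
        ref_fit = np.asarray(reference, dtype=float)[fit_indices]
        for f in range(out.shape[0]):
            sup = kabsch_superpose(out[f, fit_indices], ref_fit)
            out[f] = sup.transform(out[f])
        return out
    ref_fit = coords[0, fit_indices]
    for _ in range(max(1, n_iter)):
        for f in range(out.shape[0]):
            sup = kabsch_superpose(out[f, fit_indices], ref_fit)
            out[f] = sup.transform(out[f])
        ref_fit = out[:, fit_indices].mean(axis=0)
    return out


def rmsd_series(
    ensemble: Ensemble,
    fit: BodySelection,
    measure: BodySelection,
    reference: str | StructureModel = FIRST_FRAME,
    weights: np.ndarray | None = None,
) -> MetricSeries:
    """Per-frame RMSD of the measure atoms after fitting on the fit atoms.

    ``reference`` is the first frame, the (superposed) mean structure, or an
    external StructureModel sharing the ensemble's topology atom order.
    """
    fit_idx = fit.atom_indices
    meas_idx = measure.atom_indices
    if isinstance(reference, StructureModel):
        if reference.n_atoms != ensemble.n_atoms:
            raise SelectionError("external reference must share the ensemble topology atom order")
        ref = reference.coords
        ref_name = "external_structure"
    elif reference == FIRST_FRAME:
        ref = ensemble.coords[0]
        ref_name = FIRST_FRAME
    elif reference == MEAN_STRUCTURE:
        ref = superpose_frames(ensemble.coords, fit_idx).mean(axis=0)
        ref_name = MEAN_STRUCTURE
    else:
        raise ValueError(f"unknown reference {reference!r}")

    values = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        sup = kabsch_superpose(ensemble.coords[f, fit_idx], ref[fit_idx], weights=weights)
        values[f] = _weighted_rmsd(sup.transform(ensemble.coords[f, meas_idx]), ref[meas_idx], None)
    return MetricSeries(
        name=f"rmsd_{ensemble.label or 'ensemble'}",
        values=values,
        fit_selection=fit,
        measure_selection=measure,
        reference=ref_name,
    )


def compare_structures(
    a: StructureModel,
    b: StructureModel,
    atom_names: tuple[str, ...] = ("CA",),
    chain_id: str | None = None,
) -> SuperpositionResult:
    """Optimal-superposition RMSD between two structures over matched atoms.

    Atoms are matched by (residue number, atom name) after converting b's
    numbering into a's convention; only residues present in both structures
    contribute.  The matched residue list is reported on the result.
    """
    def keyed(model: StructureModel, renumber: np.ndarray | None = None):
        nums = model.residue_numbers if renumber is None else renumber
        table = {}
        for i in range(model.n_atoms):
            if model.hetero[i] or model.atom_names[i] not in atom_names:
                continue
            if chain_id is not None and model.chain_ids[i] != chain_id:
                continue
            table[(int(nums[i]), str(model.atom_names[i]))] = i
        return table

    b_nums = np.asarray(
        convert_numbering(
            b.residue_numbers, b.numbering_convention, a.numbering_convention, b.signal_peptide_offset
        )
    )
    ta = keyed(a)
    tb = keyed(b, b_nums)
    common = sorted(set(ta) & set(tb))
    if len(common) < 3:
        raise SelectionError(
            f"only {len(common)} atoms matched between structures (need >= 3); "
            "check numbering conventions"
        )
    ia = [ta[k] for k in common]
    ib = [tb[k] for k in common]
    result = kabsch_superpose(b.coords[ib], a.coords[ia])
    result.matched_residues = sorted({k[0] for k in common})
    return result


def loop_shift_metric(
    ensemble: Ensemble,
    loop: BodySelection,
    reference_structure: StructureModel,
    fit: BodySelection,
    axis: np.ndarray | None = None,
) -> MetricSeries:
    """Per-frame displacement (Å) of the loop Cα centroid from its reference position.

    Frames are first superposed onto the reference structure using the fit
    (core) atoms, so the metric reports internal loop motion, not rigid-body
    drift.  With ``axis`` given, the signed projection of the displacement
    onto that (normalized) axis is returned instead of its norm — useful for
    directional statements such as the inward shift of a kinase N-lobe
    β3-β4 loop or the collapse of the glycine-rich P loop.
    """
    if reference_structure.n_atoms != ensemble.n_atoms:
        raise SelectionError("reference structure must share the ensemble topology atom order")
    ref_centroid = reference_structure.coords[loop.atom_indices].mean(axis=0)
    if axis is not None:
        axis = np.asarray(axis, dtype=float).reshape(3)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("axis must be non-zero")
        axis = axis / norm

    values = np.empty(ensemble.n_frames)
    ref_fit = reference_structure.coords[fit.atom_indices]
    for f in range(ensemble.n_frames):
        sup = kabsch_superpose(ensemble.coords[f, fit.atom_indices], ref_fit)
        centroid = sup.transform(ensemble.coords[f, loop.atom_indices]).mean(axis=0)
        disp = centroid - ref_centroid
        values[f] = float(disp @ axis) if axis is not None else float(np.linalg.norm(disp))
    return MetricSeries(
        name=f"loop_shift_{ensemble.label or 'ensemble'}",
        values=values,
        fit_selection=fit,
        measure_selection=loop,
        reference="external_structure",
    )
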