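"""Config-driven orchestration: structure comparison -> RMSD series -> MI -> profile.

A YAML (or dict) configuration declares inputs and selections; the pipeline
runs whichever stages its inputs support, writes tidy per-stage tables and a
JSON summary with a provenance block, and keeps partial outputs when a stage
fails.  Re-running an identical configuration reproduces identical summaries
(all stochastic stages embed their seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .errors import PipelineError
from .geometry import compare_structures, loop_shift_metric, rmsd_series
from .nbit import (
    DEFAULT_TEMPERATURE,
    mutual_information,
    per_residue_profile,
)
from .structio import (
    MATURE,
    Ensemble,
    ca_selection,
    load_trajectory,
    read_ensemble,
    read_structure,
    select_body,
)
from .synthetic_ensembles import GaussianEnsembleSpec, make_gaussian_ensemble

logger = logging.getLogger("allocomm.pipeline")


@dataclass
class AnalysisConfig:
    """Serializable description of one analysis run."""

    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    stride: int = 1
    output_dir: str = "allocomm_out"
    convention: str = MATURE
    structures: dict[str, Any] = field(default_factory=dict)
    ensembles: list[dict[str, Any]] = field(default_factory=list)
    selections: dict[str, Any] = field(default_factory=dict)
    pool_frames: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise PipelineError(f"configuration file {path} did not parse to a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "temperature": self.temperature,
            "stride": self.stride,
            "output_dir": self.output_dir,
            "convention": self.convention,
            "structures": self.structures,
            "ensembles": self.ensembles,
            "selections": self.selections,
            "pool_frames": self.pool_frames,
        }


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_condition(entry: dict, config: AnalysisConfig, hashes: dict) -> list[Ensemble]:
    """One condition = one label with >= 1 replicate ensembles."""
    label = entry.get("label", "condition")
    if "synthetic" in entry:
        syn = dict(entry["synthetic"])
        kind = syn.pop("kind", "gaussian")
        if kind != "gaussian":
            raise PipelineError(f"unknown synthetic ensemble kind {kind!r}")
        replicates = int(syn.pop("replicates", 1))
        base_seed = int(syn.pop("seed", config.seed))
        out = []
        for r in range(replicates):
            spec = GaussianEnsembleSpec(seed=base_seed + r, **syn)
            res = make_gaussian_ensemble(spec)
            res.ensemble.label = f"{label}/rep{r}" if replicates > 1 else label
            out.append(res.ensemble)
        return out
    paths = entry.get("trajectories") or ([entry["trajectory"]] if "trajectory" in entry else [])
    if not paths:
        raise PipelineError(f"condition {label!r} has neither synthetic spec nor trajectory paths")
    out = []
    for k, p in enumerate(paths):
        hashes[str(p)] = _file_sha256(p)
        if str(p).endswith(".pdb"):
            ens = read_ensemble(p, convention=config.convention)
        else:
            top = entry.get("topology")
            if top is None:
                raise PipelineError(f"binary trajectory {p} requires a 'topology' path")
            hashes[str(top)] = _file_sha256(top)
            ens = load_trajectory(p, top, convention=config.convention)
        ens.label = f"{label}/rep{k}" if len(paths) > 1 else label
        out.append(ens)
    return out


def _resolve_selections(topology, config: AnalysisConfig):
    sel = config.selections
    convention = sel.get("convention", config.convention)
    atoms = tuple(sel.get("atom_names", ("CA", "CB")))

    def body(key, role):
        if key not in sel:
            return None
        return select_body(topology, sel[key], convention=convention, atom_names=atoms, role=role)

    transmitter = body("transmitter", "transmitter")
    receiver = body("receiver", "receiver")
    loop = body("loop", "channel")
    if "fit" in sel:
        # fit: none disables core superposition (appropriate for synthetic
        # ensembles generated without rigid-body motion)
        if sel["fit"] in (None, "none"):
            fit = None
        else:
            fit = select_body(topology, sel["fit"], convention=convention,
                              atom_names=("CA",), role="fit")
    else:
        fit = ca_selection(topology)
    return transmitter, receiver, loop, fit, sel.get("candidates")


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage the configuration supports; return and write the summary.

    Stages: structure comparison (two structure paths), per-condition RMSD
    series and loop-shift metrics (ensembles present), transmitter-receiver
    MI and optional per-residue co-information profile (ensembles plus
    selections).  Stage failures are recorded with the stage name; completed
    stages keep their outputs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    hashes: dict[str, str] = {}
    summary: dict[str, Any] = {"stages": {}, "errors": {}}
    try:
        # Stage: structure comparison -------------------------------------
        if {"a", "b"} <= set(config.structures):
            try:
                atoms = tuple(config.structures.get("atom_names", ("CA",)))
                sa = read_structure(config.structures["a"], convention=config.convention)
                sb = read_structure(config.structures["b"], convention=config.convention)
                hashes[str(config.structures["a"])] = _file_sha256(config.structures["a"])
                hashes[str(config.structures["b"])] = _file_sha256(config.structures["b"])
                cmp_res = compare_structures(sa, sb, atom_names=atoms)
                summary["stages"]["structure_comparison"] = {
                    "rmsd": cmp_res.rmsd,
                    "n_atoms_fit": cmp_res.n_atoms_fit,
                    "n_matched_residues": len(cmp_res.matched_residues or []),
                    "atom_names": list(atoms),
                }
                logger.info("structure comparison RMSD %.3f Å over %d atoms",
                            cmp_res.rmsd, cmp_res.n_atoms_fit)
            except Exception as exc:
                summary["errors"]["structure_comparison"] = str(exc)
                logger.exception("structure comparison failed")

        # Stage: ensembles -------------------------------------------------
        conditions: dict[str, list[Ensemble]] = {}
        for entry in config.ensembles:
            label = entry.get("label", f"condition_{len(conditions)}")
            try:
                conditions[label] = _load_condition(entry, config, hashes)
            except Exception as exc:
                summary["errors"][f"load:{label}"] = str(exc)
                logger.exception("loading condition %s failed", label)

        if conditions:
            first = next(iter(conditions.values()))[0]
            transmitter, receiver, loop, fit, candidates = _resolve_selections(
                first.topology, config
            )

            # RMSD metrics always superpose, even when the covariance fit is
            # disabled; fall back to all-Cα for them.
            geom_fit = fit if fit is not None else ca_selection(first.topology)
            if geom_fit.n_atoms < 3:
                # tiny synthetic topologies: superpose on every atom instead
                from .structio import BodySelection

                geom_fit = BodySelection(
                    atom_indices=np.arange(first.topology.n_atoms),
                    residue_numbers=sorted(set(map(int, first.topology.residue_numbers))),
                    numbering_convention=first.topology.numbering_convention,
                    role="fit",
                )
            # RMSD series per condition
            rmsd_summaries = {}
            for label, reps in conditions.items():
                try:
                    measure = transmitter or ca_selection(first.topology)
                    rows = []
                    for ens in reps:
                        series = rmsd_series(ens, fit=geom_fit, measure=measure)
                        df = series.to_frame()
                        df.insert(0, "replicate", ens.label)
                        rows.append(df)
                        rmsd_summaries.setdefault(label, []).append(series.summary())
                    import pandas as pd

                    pd.concat(rows).to_csv(out_dir / f"rmsd_{_slug(label)}.csv", index=False)
                except Exception as exc:
                    summary["errors"][f"rmsd:{label}"] = str(exc)
                    logger.exception("rmsd stage failed for %s", label)
            if rmsd_summaries:
                summary["stages"]["rmsd"] = rmsd_summaries

            # Loop-shift metric (optional; needs loop selection)
            if loop is not None:
                shifts = {}
                for label, reps in conditions.items():
                    try:
                        vals = [
                            loop_shift_metric(ens, loop, ens.frame(0), geom_fit).summary()
                            for ens in reps
                        ]
                        shifts[label] = vals
                    except Exception as exc:
                        summary["errors"][f"loop_shift:{label}"] = str(exc)
                if shifts:
                    summary["stages"]["loop_shift"] = shifts

            # NbIT MI per condition
            if transmitter is not None and receiver is not None:
                mi_block = {}
                for label, reps in conditions.items():
                    try:
                        res = mutual_information(
                            reps, transmitter, receiver, fit=fit,
                            temperature=config.temperature, stride=config.stride,
                            pool_frames=config.pool_frames,
                        )
                        mi_block[label] = res.to_dict()
                        logger.info("MI(%s) = %.4f kcal/mol", label, res.mi_kcal)
                    except Exception as exc:
                        summary["errors"][f"nbit:{label}"] = str(exc)
                        logger.exception("nbit stage failed for %s", label)
                if mi_block:
                    summary["stages"]["mutual_information"] = mi_block

                # Per-residue co-information profile, normalized across all
                # conditions supplied in this run.
                if candidates:
                    try:
                        flat = [ens for reps in conditions.values() for ens in reps]
                        profile = per_residue_profile(
                            flat, transmitter, receiver, list(candidates), fit=fit,
                            temperature=config.temperature, stride=config.stride,
                        )
                        profile.to_frame().to_csv(out_dir / "coinformation_profile.csv", index=False)
                        summary["stages"]["coinformation_profile"] = {
                            "residues": profile.residues,
                            "normalization_bounds": list(profile.normalization_bounds),
                            "normalization_scope": profile.normalization_scope,
                        }
                    except Exception as exc:
                        summary["errors"]["profile"] = str(exc)
                        logger.exception("profile stage failed")

        summary["provenance"] = {
            "allocomm_version": __version__,
            "seed": config.seed,
            "temperature": config.temperature,
            "stride": config.stride,
            "input_hashes": hashes,
            "config": config.to_dict(),
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_jsonable)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
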