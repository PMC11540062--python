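"""Pipeline orchestration: simulate -> fwmap -> biomarkers -> associate -> compete.

A run is driven by a :class:`RunConfig` (usually loaded from YAML), writes
every intermediate artifact under the output directory, and finishes with
a JSON manifest listing inputs, stage seeds, wall times and a SHA-256 hash
of every output file.  A single master seed fans out deterministically to
per-stage seeds, so rerunning the same config reproduces every stochastic
stage exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .biomarkers import ROILabelMap, SignatureDefinition, build_biomarker_table
from .cohort import (BIOMARKER_COLUMNS, OUTCOME_COLUMNS, CohortTruth,
                     make_cohort, make_morphometry)
from .competitive import bootstrap_competitive
from .freewater import FitOptions, compute_fw_maps
from .models import biomarker_outcome_grid, results_to_frame, standardize_predictors
from .phantom import default_regions, make_dwi_phantom
from .protocol import default_protocol

__all__ = ["RunConfig", "validate_inputs", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "fwmap", "biomarkers", "associate", "compete")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (all stages)."""

    out_dir: str = "fwbio_run"
    seed: int = 0
    mode: str = "synthetic"  # "synthetic" or "files"
    stages: tuple = ALL_STAGES
    # synthetic imaging arm
    imaging_n: int = 3
    phantom_shape: tuple = (9, 9, 5)
    snr: float = 40.0
    noise_model: str = "rician"
    # synthetic cohort arm
    cohort_n: int = 150
    visit_schedule: tuple = (0.0, 1.5, 3.0, 5.0)
    diagnosis_fraction_mci: float = 0.40
    # statistics
    B: int = 200
    alpha: float = 0.05
    fdr_family: str = "grid"
    outcomes: tuple = OUTCOME_COLUMNS
    biomarkers: tuple = BIOMARKER_COLUMNS
    compete_outcomes: tuple = ("memory_composite",)
    longitudinal: bool = True
    fit_options: dict = field(default_factory=dict)
    # file mode inputs
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for key in ("stages", "visit_schedule", "outcomes", "biomarkers",
                    "compete_outcomes", "phantom_shape"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def _stage_seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(ALL_STAGES))
    return {stage: int(c.generate_state(1)[0] % (2**31 - 1))
            for stage, c in zip(ALL_STAGES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: RunConfig) -> dict:
    """Fail-fast consistency report: {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    if config.mode == "files":
        required = ("dwi", "bval", "bvec", "labels", "morphometry", "cohort")
        for key in required:
            p = config.paths.get(key)
            if not p:
                errors.append(f"files mode requires path {key!r}")
            elif not Path(p).exists():
                errors.append(f"missing input file for {key!r}: {p}")
        if not errors:
            sig, _ = fio.read_nifti(config.paths["dwi"])
            lab, _ = fio.read_nifti(config.paths["labels"])
            if sig.shape[:3] != lab.shape:
                errors.append(
                    f"DWI grid {sig.shape[:3]} and label grid {lab.shape} differ")
            cohort = pd.read_csv(config.paths["cohort"])
            if "participant_id" not in cohort.columns:
                errors.append("cohort table lacks participant_id")
            bm_path = config.paths.get("biomarkers")
            if bm_path and Path(bm_path).exists():
                bm = pd.read_csv(bm_path)
                missing = set(cohort["participant_id"]) - set(bm["participant_id"])
                for pid in sorted(missing):
                    warnings_.append(
                        f"participant {pid} in cohort but not biomarker table")
    elif config.mode == "synthetic":
        if config.cohort_n < 10:
            errors.append("synthetic cohort needs at least 10 participants")
        if config.imaging_n < 1:
            errors.append("synthetic imaging arm needs at least 1 participant")
    else:
        errors.append(f"unknown mode {config.mode!r}")
    return {"errors": errors, "warnings": warnings_}


def _phantom_label_map(label_grid) -> ROILabelMap:
    """Name the phantom regions after the ROIs the analysis expects.

    Region 1 plays the hippocampus, region 2 the signature cortex, region 3
    a high-FW periventricular area (used as a second signature region).
    """
    names = {1: "hippocampus", 2: "entorhinal", 3: "fusiform"}
    return ROILabelMap(labels=np.asarray(label_grid, dtype=int), names=names)


def _phantom_signatures() -> dict:
    """Signature definitions restricted to the phantom's two cortical regions."""
    thick = (("entorhinal", 1.0, "thickness"), ("fusiform", 1.0, "thickness"))
    return {
        "schwarz": SignatureDefinition("schwarz", thick),
        "mcevoy": SignatureDefinition(
            "mcevoy", thick + (("hippocampus", 1.0, "volume"),), zscore_terms=True),
    }


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the configured stages in order and write a manifest.

    Stage outputs land under ``out_dir``; the manifest (manifest.json)
    records per-stage seeds, wall times, row counts and output hashes.  On
    stage failure the manifest is still written, with the error recorded,
    before the exception propagates.
    """
    stages = tuple(stages if stages is not None else config.stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()},
                "seeds": seeds, "stages": {}, "outputs": {}}

    report = validate_inputs(config)
    manifest["validation"] = report
    if report["errors"]:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise ValueError("invalid configuration: " + "; ".join(report["errors"]))

    state = {}
    try:
        for stage in ALL_STAGES:
            if stage not in stages:
                manifest["stages"][stage] = {"skipped": True}
                continue
            t0 = time.perf_counter()
            files = _run_stage(stage, config, seeds[stage], out, state)
            manifest["stages"][stage] = {
                "skipped": False,
                "seed": seeds[stage],
                "wall_time_s": round(time.perf_counter() - t0, 3),
                "files": sorted(str(f) for f in files),
            }
    except Exception as err:
        manifest["error"] = {"stage": stage, "message": str(err)}
        _hash_outputs(out, manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    _hash_outputs(out, manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _hash_outputs(out: Path, manifest: dict) -> None:
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)


def _run_stage(stage, config: RunConfig, seed: int, out: Path, state: dict):
    if stage == "simulate":
        return _stage_simulate(config, seed, out, state)
    if stage == "fwmap":
        return _stage_fwmap(config, seed, out, state)
    if stage == "biomarkers":
        return _stage_biomarkers(config, seed, out, state)
    if stage == "associate":
        return _stage_associate(config, seed, out, state)
    if stage == "compete":
        return _stage_compete(config, seed, out, state)
    raise ValueError(f"unknown stage {stage!r}")


def _imaging_ids(config):
    return [f"P{i:04d}" for i in range(config.imaging_n)]


def _stage_simulate(config, seed, out, state):
    files = []
    img_dir = out / "imaging"
    if config.mode == "synthetic":
        rng = np.random.default_rng(seed)
        protocol = default_protocol()
        ids = _imaging_ids(config)
        for pid in ids:
            dwi, truth = make_dwi_phantom(
                shape=config.phantom_shape, regions=default_regions(),
                protocol=protocol, snr=config.snr,
                noise_model=config.noise_model,
                seed=int(rng.integers(0, 2**31 - 1)))
            paths = fio.write_dwi(dwi, img_dir / pid / "dwi")
            fio.write_nifti(truth.label_map.astype(np.int16),
                            img_dir / pid / "labels.nii.gz")
            truth_json = img_dir / pid / "truth.json"
            truth_json.write_text(json.dumps(
                {"f_mean_by_label": {
                    str(l): float(truth.f_true[truth.label_map == l].mean())
                    for l in np.unique(truth.label_map) if l > 0}}, indent=2))
            files += list(paths.values()) + [str(img_dir / pid / "labels.nii.gz"),
                                             str(truth_json)]
        morph = make_morphometry(ids, seed=seed + 1)
        morph_path = out / "morphometry.csv"
        morph.to_csv(morph_path, index=False)
        files.append(str(morph_path))

        cohort, biomarkers, truth = make_cohort(
            config.cohort_n, visit_schedule=config.visit_schedule,
            diagnosis_fraction_mci=config.diagnosis_fraction_mci, seed=seed + 2)
        cohort_path = out / "cohort.csv"
        bm_path = out / "biomarkers.csv"
        cohort.to_csv(cohort_path, index=False)
        biomarkers.to_csv(bm_path, index=False)
        truth_path = out / "cohort_truth.json"
        truth_path.write_text(json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(truth).items()}, indent=2))
        files += [str(cohort_path), str(bm_path), str(truth_path)]
        state["imaging_ids"] = ids
    else:
        state["imaging_ids"] = None  # provided via paths
    return files


def _stage_fwmap(config, seed, out, state):
    files = []
    opts = FitOptions(**config.fit_options)
    if config.mode == "synthetic":
        ids = state.get("imaging_ids") or _imaging_ids(config)
        fwmaps = {}
        for pid in ids:
            base = out / "imaging" / pid
            dwi = fio.read_dwi(base / "dwi.nii.gz", base / "dwi.bval",
                               base / "dwi.bvec", base / "dwi_mask.nii.gz")
            maps = compute_fw_maps(dwi, opts)
            paths = fio.write_fw_maps(maps, base, prefix="fw")
            fwmaps[pid] = maps
            files += list(paths.values())
        state["fwmaps"] = fwmaps
    else:
        dwi = fio.read_dwi(config.paths["dwi"], config.paths["bval"],
                           config.paths["bvec"], config.paths.get("mask"))
        maps = compute_fw_maps(dwi, opts)
        paths = fio.write_fw_maps(maps, out / "imaging", prefix="fw")
        state["fwmaps"] = maps
        files += list(paths.values())
    return files


def _stage_biomarkers(config, seed, out, state):
    morph = pd.read_csv(config.paths.get("morphometry", out / "morphometry.csv"))
    if config.mode == "synthetic":
        ids = state.get("imaging_ids") or _imaging_ids(config)
        lab_grid, _ = fio.read_nifti(out / "imaging" / ids[0] / "labels.nii.gz")
        labels = _phantom_label_map(lab_grid)
        fwmaps = state.get("fwmaps")
        if fwmaps is None:
            raise RuntimeError("biomarkers stage requires the fwmap stage")
        signatures = _phantom_signatures()
    else:
        signatures = None
        lab_grid, _ = fio.read_nifti(config.paths["labels"])
        names = config.paths.get("label_names") or {}
        labels = ROILabelMap(np.asarray(lab_grid, dtype=int),
                             {int(k): v for k, v in names.items()})
        fwmaps = state["fwmaps"]
    table = build_biomarker_table(fwmaps, labels, morph, signatures=signatures)
    path = out / "biomarkers_imaging.csv"
    table.to_csv(path, index=False)
    state["biomarkers_imaging"] = table
    return [str(path)]


def _merged_cohort(config, out):
    cohort = pd.read_csv(config.paths.get("cohort", out / "cohort.csv"))
    bm = pd.read_csv(config.paths.get("biomarkers", out / "biomarkers.csv"))
    merged = cohort.merge(bm, on="participant_id", how="inner")
    merged = standardize_predictors(merged, list(config.biomarkers))
    return merged


def _stage_associate(config, seed, out, state):
    merged = _merged_cohort(config, out)
    files = []
    res = biomarker_outcome_grid(merged, config.biomarkers, config.outcomes,
                                 mode="baseline", fdr_family=config.fdr_family)
    path = out / "associations_baseline.csv"
    results_to_frame(res).to_csv(path, index=False)
    files.append(str(path))
    if config.longitudinal:
        res = biomarker_outcome_grid(merged, config.biomarkers, config.outcomes,
                                     mode="longitudinal",
                                     fdr_family=config.fdr_family)
        path = out / "associations_longitudinal.csv"
        results_to_frame(res).to_csv(path, index=False)
        files.append(str(path))
    return files


def _stage_compete(config, seed, out, state):
    merged = _merged_cohort(config, out)
    files = []
    frames = []
    pairwise = []
    for outcome in config.compete_outcomes:
        res = bootstrap_competitive(merged, config.biomarkers, outcome,
                                    mode="baseline_ols", B=config.B, seed=seed)
        frames.append(res.to_frame())
        pw = res.pairwise_p.reset_index(names="biomarker_i").melt(
            id_vars="biomarker_i", var_name="biomarker_j", value_name="p")
        pw.insert(0, "outcome", outcome)
        pairwise.append(pw.dropna(subset=["p"]))
    path = out / "competitive_baseline.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    files.append(str(path))
    path = out / "competitive_pairwise.csv"
    pd.concat(pairwise, ignore_index=True).to_csv(path, index=False)
    files.append(str(path))
    return files
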