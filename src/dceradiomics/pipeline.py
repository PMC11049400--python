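"""End-to-end orchestration: phantom cohort -> phase synchronization ->
per-phase feature extraction -> temporal screen -> clustering ->
phase-wise classification, driven by one YAML configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import ExtractionConfig, extract_all
from .io_core import load_config, logger, save_config
from .phantom import PhantomPatient, PhantomSpec, generate_cohort
from .phase_classifier import ClassifierConfig, classify_by_phase, roc_points
from .phase_sync import (PhaseSyncConfig, define_phases, median_enhancement_curve,
                         phase_volumes)
from .temporal_stats import (StatsConfig, cluster_profiles, linkage_to_nested,
                             screen_features, zscore_profile)

STAGES = ("simulate", "sync", "extract", "screen", "classify")


def default_config() -> dict:
    """A full run configuration with the pipeline defaults, mirroring every
    spec/config field so a user can edit any of them in one file."""
    return {
        "seed": 0,
        "phantom": asdict(PhantomSpec()),
        "phase_sync": asdict(PhaseSyncConfig()),
        "extraction": {"preset": "CT"},
        "stats": asdict(StatsConfig()),
        "classifier": {
            k: v for k, v in asdict(ClassifierConfig()).items()
        },
        "clusters": None,  # None -> cut at the largest relative merge-height gap
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def parse_config(cfg: dict):
    cfg = _merge(default_config(), cfg)
    phantom = dict(cfg["phantom"])
    phantom["seed"] = cfg.get("seed", phantom.get("seed", 0))
    for key in ("grid_shape", "spacing", "peak_time_range", "peak_amplitude_range",
                "texture_corr_lengths_mm"):
        if key in phantom and phantom[key] is not None:
            phantom[key] = tuple(phantom[key])
    spec = PhantomSpec(**phantom)
    sync = PhaseSyncConfig(**cfg["phase_sync"])
    extraction = dict(cfg["extraction"])
    preset = extraction.pop("preset", "CT")
    ecfg = ExtractionConfig.preset(preset)
    if extraction:
        fields = {f.name for f in dataclasses.fields(ExtractionConfig)}
        unknown = set(extraction) - fields
        if unknown:
            raise ValueError(f"unknown extraction options: {sorted(unknown)}")
        ecfg = dataclasses.replace(ecfg, **extraction)
    stats = StatsConfig(**cfg["stats"])
    clf = ClassifierConfig(**cfg["classifier"])
    return cfg, spec, sync, ecfg, stats, clf


def _section_hash(*sections) -> str:
    blob = json.dumps(sections, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def extract_cohort_table(patients: list[PhantomPatient], sync: PhaseSyncConfig,
                         ecfg: ExtractionConfig, rois=("tumor", "healthy")
                         ) -> pd.DataFrame:
    """Long-format feature table over patients x ROIs x the seven phases."""
    rows = []
    for pat in patients:
        curve = median_enhancement_curve(pat.series, pat.masks["vessel"])
        assignment = define_phases(curve, sync)
        for roi in rois:
            mask = pat.masks[roi]
            for phase_no, (vol, _label) in enumerate(phase_volumes(pat.series, assignment), 1):
                fv = extract_all(vol, mask, ecfg)
                for name, value in fv.values.items():
                    rows.append((pat.patient_id, 1, roi, phase_no, name, value,
                                 name in fv.flags))
    return pd.DataFrame(rows, columns=["subject", "visit", "roi", "phase",
                                       "feature", "value", "flag"])


def run_pipeline(config, outdir, stages=STAGES, seed: int | None = None) -> dict:
    """Run the requested stages and return the run manifest.

    Deterministic for a fixed configuration and master seed; the expensive
    feature-extraction stage is cached on a hash of the configuration
    sections it depends on, so statistics options can vary cheaply.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    if seed is not None:
        config = dict(config)
        config["seed"] = seed
    raw, spec, sync, ecfg, stats, clf = parse_config(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": raw,
        "seed": spec.seed,
        "stages": {},
    }
    last = max(STAGES.index(s) for s in stages)

    def stage_active(name):
        return STAGES.index(name) <= last

    patients: list[PhantomPatient] = []
    table: pd.DataFrame | None = None

    # --- simulate --------------------------------------------------------
    try:
        t0 = time.time()
        phantom_dir = outdir / "phantom"
        patients = generate_cohort(spec, out_dir=phantom_dir if "simulate" in stages else None)
        manifest["stages"]["simulate"] = {
            "n_patients": len(patients),
            "n_scans": len(patients[0].series),
            "path": str(phantom_dir),
            "seconds": round(time.time() - t0, 2),
        }
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    if not stage_active("sync"):
        _write_manifest(outdir, manifest)
        return manifest

    # --- sync ------------------------------------------------------------
    try:
        t0 = time.time()
        sync_rows = []
        for pat in patients:
            curve = median_enhancement_curve(pat.series, pat.masks["vessel"])
            assignment = define_phases(curve, sync)
            curve.to_frame().to_csv(outdir / f"curve_{pat.patient_id}.csv", index=False)
            adf = assignment.to_frame(curve.times)
            adf.insert(0, "patient_id", pat.patient_id)
            sync_rows.append(adf)
        sync_df = pd.concat(sync_rows, ignore_index=True)
        sync_df.to_csv(outdir / "phase_assignments.csv", index=False)
        manifest["stages"]["sync"] = {
            "path": str(outdir / "phase_assignments.csv"),
            "n_rows": len(sync_df),
            "seconds": round(time.time() - t0, 2),
        }
    except Exception as e:
        raise RuntimeError(f"stage 'sync' failed: {e}") from e

    if not stage_active("extract"):
        _write_manifest(outdir, manifest)
        return manifest

    # --- extract (cached) --------------------------------------------------
    try:
        t0 = time.time()
        feat_hash = _section_hash(asdict(spec), asdict(sync), asdict(ecfg))
        feat_path = outdir / "features.csv"
        hash_path = outdir / "features.hash"
        if feat_path.exists() and hash_path.exists() and hash_path.read_text() == feat_hash:
            table = pd.read_csv(feat_path)
            logger.info("extract: reusing cached feature table %s", feat_path)
        else:
            table = extract_cohort_table(patients, sync, ecfg)
            table.to_csv(feat_path, index=False)
            hash_path.write_text(feat_hash)
        per_roi = ecfg.n_image_sets * 86
        manifest["stages"]["extract"] = {
            "path": str(feat_path),
            "n_rows": len(table),
            "features_per_roi": per_roi,
            "expected_rows": per_roi * 7 * 2 * len(patients),
            "seconds": round(time.time() - t0, 2),
        }
    except Exception as e:
        raise RuntimeError(f"stage 'extract' failed: {e}") from e

    if not stage_active("screen"):
        _write_manifest(outdir, manifest)
        return manifest

    # --- screen ------------------------------------------------------------
    try:
        t0 = time.time()
        screen_info = {}
        for roi in ("tumor", "healthy"):
            res = screen_features(table, stats, roi=roi)
            sig = res.loc[res["significant"], "feature"].tolist()
            profiles = {}
            for feat in sig:
                prof, flagged = zscore_profile(table[table["roi"] == roi], feat)
                if not flagged:
                    profiles[feat] = prof
            if profiles:
                clusters, Z = cluster_profiles(profiles, k=raw.get("clusters"))
                res["cluster"] = res["feature"].map(clusters).astype("Int64")
                with open(outdir / f"linkage_{roi}.json", "w") as fh:
                    json.dump(linkage_to_nested(Z, list(profiles)), fh)
            else:
                res["cluster"] = pd.array([None] * len(res), dtype="Int64")
            res.to_csv(outdir / f"screen_{roi}.csv", index=False)
            screen_info[roi] = {
                "n_features": len(res),
                "n_significant": int(res["significant"].sum()),
                "n_excluded": int(res["excluded"].sum()),
            }
        manifest["stages"]["screen"] = {
            **screen_info,
            "seconds": round(time.time() - t0, 2),
        }
    except Exception as e:
        raise RuntimeError(f"stage 'screen' failed: {e}") from e

    if not stage_active("classify"):
        _write_manifest(outdir, manifest)
        return manifest

    # --- classify ------------------------------------------------------------
    try:
        t0 = time.time()
        aucs = classify_by_phase(table, clf)
        auc_df = pd.DataFrame(
            {
                "phase": [a.phase for a in aucs],
                "auc": [a.auc for a in aucs],
                "ci_low": [a.ci_low for a in aucs],
                "ci_high": [a.ci_high for a in aucs],
            }
        )
        auc_df.to_csv(outdir / "phase_auc.csv", index=False)
        prob_rows = []
        roc_rows = []
        for a in aucs:
            for p, y in zip(a.probabilities, a.labels):
                prob_rows.append((a.phase, float(p), int(y)))
            r = roc_points(a.probabilities, a.labels)
            r.insert(0, "phase", a.phase)
            roc_rows.append(r)
        pd.DataFrame(prob_rows, columns=["phase", "probability", "is_tumor"]).to_csv(
            outdir / "loo_probabilities.csv", index=False)
        pd.concat(roc_rows, ignore_index=True).to_csv(outdir / "roc_points.csv", index=False)
        manifest["stages"]["classify"] = {
            "path": str(outdir / "phase_auc.csv"),
            "auc_by_phase": {int(a.phase): round(a.auc, 4) for a in aucs},
            "seconds": round(time.time() - t0, 2),
        }
    except Exception as e:
        raise RuntimeError(f"stage 'classify' failed: {e}") from e

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
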