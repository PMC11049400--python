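"""Synthetic dynamic contrast-enhanced phantom cohorts.

The phantom emulates the acquisition this pipeline is built for: a CT
perfusion series of 26-33 scans, the first 20 at 1.5 s intervals and the
remainder at 3 s, with an arterial bolus whose peak arrives 15-26 s after
injection at 520-827 HU.  Each synthetic patient carries three disjoint
ROIs — a reference vessel following a jittered gamma-variate arterial input
function (AIF), plus a tumor and a healthy-tissue region following one-
compartment uptake kinetics — and a spatially correlated texture field
whose amplitude is partly coupled to enhancement, so that texture features
genuinely change with contrast phase and the ground truth is known.

Tumor and healthy tissue share the same pre-contrast baseline and the same
static texture amplitude: before bolus arrival the two classes are
statistically identical, and any downstream class separation must come
from contrast dynamics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import DynamicSeries, ImageVolume, RoiMask, write_mask, write_volume, logger


@dataclass
class PhantomSpec:
    """All simulation parameters for a phantom cohort.

    Rates are per second, intensities in HU, lengths in mm.  The AIF is a
    gamma-variate with shape ``alpha`` and timescale ``beta``; each patient
    draws a peak time uniformly from ``peak_time_range`` and a peak
    amplitude from ``peak_amplitude_range``.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_scans: int = 30
    fast_interval_s: float = 1.5   # first `n_fast` inter-scan intervals
    slow_interval_s: float = 3.0
    n_fast: int = 20               # scans acquired at the fast interval
    aif_alpha: float = 3.0
    aif_beta: float = 3.5
    peak_time_range: tuple[float, float] = (15.0, 26.0)
    peak_amplitude_range: tuple[float, float] = (520.0, 827.0)
    vessel_baseline: float = 40.0
    tissue_baseline: float = 45.0
    tumor_k_in: float = 0.010
    tumor_k_out: float = 0.025
    healthy_k_in: float = 0.003
    healthy_k_out: float = 0.015
    texture_corr_lengths_mm: tuple[float, ...] = (1.5, 4.0)  # multi-scale heterogeneity
    texture_amplitude: float = 25.0
    texture_enh_fraction: float = 0.25  # texture sd gained per HU of enhancement * this
    noise_sd: float = 20.0
    n_patients: int = 7
    seed: int = 0
    modality: str = "CT"

    def __post_init__(self) -> None:
        if self.n_scans < 10:
            raise ValueError("n_scans must be >= 10")
        for name in ("tumor_k_in", "tumor_k_out", "healthy_k_in", "healthy_k_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.aif_alpha <= 0 or self.aif_beta <= 0:
            raise ValueError("AIF alpha and beta must be positive")
        lo, hi = self.peak_time_range
        if not (0 < lo <= hi):
            raise ValueError("peak_time_range must be positive and ordered")
        if lo - self.aif_alpha * self.aif_beta <= 0:
            raise ValueError("earliest peak must leave a positive bolus-arrival time")
        alo, ahi = self.peak_amplitude_range
        if not (0 < alo <= ahi):
            raise ValueError("peak_amplitude_range must be positive and ordered")
        if self.noise_sd < 0 or self.texture_amplitude < 0 or self.texture_enh_fraction < 0:
            raise ValueError("noise and texture amplitudes must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    def scan_times(self) -> np.ndarray:
        """Acquisition times in seconds: first ``n_fast`` scans at the fast
        interval, the rest at the slow interval, starting at t=0."""
        dts = np.where(np.arange(self.n_scans - 1) < self.n_fast - 1,
                       self.fast_interval_s, self.slow_interval_s)
        return np.concatenate([[0.0], np.cumsum(dts)])


@dataclass
class PhantomPatient:
    """One simulated patient: the dynamic series, its three ROI masks and
    the noise-free ground truth used to verify downstream stages."""

    patient_id: str
    series: DynamicSeries
    masks: dict[str, RoiMask]
    ground_truth: dict

    def __post_init__(self) -> None:
        stack = np.zeros(self.series.shape, dtype=int)
        for m in self.masks.values():
            stack += m.voxels
        if (stack > 1).any():
            raise ValueError("ROI masks must be disjoint")
        for curve in self.ground_truth["curves"].values():
            if not np.all(np.isfinite(curve)):
                raise ValueError("ground-truth curves must be finite")


def gamma_variate_aif(t, t0: float, A: float, alpha: float, beta: float):
    """Gamma-variate bolus model.

    ``A * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)`` for
    ``t > t0`` and 0 before arrival; the peak value is exactly ``A`` at
    ``t = t0 + alpha*beta``.  First-pass only (no recirculation tail).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(t)
    pos = dt > 0
    out[pos] = A * (dt[pos] / (alpha * beta)) ** alpha * np.exp(alpha - dt[pos] / beta)
    return out if out.ndim else float(out)


def tissue_curve(aif, baseline: float, k_in: float, k_out: float, t,
                 dt_fine: float = 0.05):
    """One-compartment tissue enhancement.

    ``baseline + k_in * int_0^t aif(s) * exp(-k_out*(t-s)) ds`` evaluated by
    an exponential integrator on a fine grid (exact for piecewise-constant
    AIF, error O(dt^2)), then sampled at the scan times ``t``.
    """
    if k_in < 0 or k_out < 0:
        raise ValueError("rates must be >= 0")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if k_in == 0:
        out = np.full_like(t, float(baseline))
        return out if out.size > 1 else float(out[0])
    if k_out <= 0:
        raise ValueError("k_out must be > 0 when k_in > 0")
    t_end = float(t.max())
    n = max(int(np.ceil(t_end / dt_fine)), 1)
    grid = np.linspace(0.0, t_end, n + 1)
    dt = grid[1] - grid[0] if n > 0 else dt_fine
    a = np.asarray(aif(grid), dtype=float)
    decay = np.exp(-k_out * dt)
    gain = k_in * (1.0 - decay) / k_out
    c = np.zeros_like(grid)
    mid = 0.5 * (a[1:] + a[:-1])  # midpoint value of the piecewise-constant AIF
    for i in range(n):
        c[i + 1] = c[i] * decay + gain * mid[i]
    out = baseline + np.interp(t, grid, c)
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _sphere(shape, center, radius) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius**2


def _cylinder_z(shape, center_yx, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[1], : shape[2]]
    disk = (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2 <= radius**2
    return np.broadcast_to(disk, shape).copy()


def default_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Three disjoint ROIs scaled to the grid: two tissue spheres and a
    vessel cylinder running along the slice axis."""
    shape = spec.grid_shape
    r = max(2.0, min(shape) / 6.5)
    tumor = _sphere(shape, (shape[0] // 2, shape[1] // 4, shape[2] // 2), r)
    healthy = _sphere(shape, (shape[0] // 2, (3 * shape[1]) // 4, shape[2] // 2), r)
    vessel = _cylinder_z(shape, (shape[1] // 2, shape[2] // 8), max(1.5, min(shape) / 12.0))
    vessel &= ~(tumor | healthy)
    return {"tumor": tumor, "healthy": healthy, "vessel": vessel}


def _texture_field(rng: np.random.Generator, shape, spacing, corr_lengths_mm) -> np.ndarray:
    """Unit-variance Gaussian random field summing one smoothed-white-noise
    component per correlation length (multi-scale tissue heterogeneity)."""
    g = np.zeros(shape)
    for corr in corr_lengths_mm:
        white = rng.standard_normal(shape)
        sigmas = [corr / s for s in spacing]
        comp = ndimage.gaussian_filter(white, sigma=sigmas, mode="wrap")
        sd = comp.std()
        if sd > 0:
            g += comp / sd
    sd = g.std()
    if sd == 0:  # degenerate, e.g. correlation lengths >> grid
        return np.zeros(shape)
    return g / sd


# ---------------------------------------------------------------------------
# patient / cohort generation
# ---------------------------------------------------------------------------

def generate_patient(spec: PhantomSpec, patient_seed: int,
                     patient_id: str | None = None) -> PhantomPatient:
    """Simulate one patient; bit-identical for a fixed spec and seed."""
    rng = np.random.default_rng(patient_seed)
    times = spec.scan_times()

    peak_time = rng.uniform(*spec.peak_time_range)
    amplitude = rng.uniform(*spec.peak_amplitude_range)
    t0 = peak_time - spec.aif_alpha * spec.aif_beta

    def aif(t):
        return gamma_variate_aif(t, t0=t0, A=amplitude, alpha=spec.aif_alpha,
                                 beta=spec.aif_beta)

    vessel_curve = spec.vessel_baseline + aif(times)
    tumor = tissue_curve(aif, spec.tissue_baseline, spec.tumor_k_in,
                         spec.tumor_k_out, times)
    healthy = tissue_curve(aif, spec.tissue_baseline, spec.healthy_k_in,
                           spec.healthy_k_out, times)

    masks_vox = default_masks(spec)
    texture = _texture_field(rng, spec.grid_shape, spec.spacing,
                             spec.texture_corr_lengths_mm)

    n_t = len(times)
    shape = spec.grid_shape
    enh = {"tumor": tumor - spec.tissue_baseline, "healthy": healthy - spec.tissue_baseline}
    base_frame = np.full(shape, spec.tissue_baseline, dtype=np.float32)
    base_frame += (spec.texture_amplitude * texture).astype(np.float32)

    volumes = []
    for it in range(n_t):
        frame = base_frame.copy()
        for roi in ("tumor", "healthy"):
            m = masks_vox[roi]
            amp = spec.texture_amplitude + spec.texture_enh_fraction * enh[roi][it]
            frame[m] = (enh[roi][it] + spec.tissue_baseline + amp * texture[m]).astype(np.float32)
        frame[masks_vox["vessel"]] = np.float32(vessel_curve[it])
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)
        volumes.append(ImageVolume(voxels=frame.astype(np.float32), spacing=spec.spacing))

    series = DynamicSeries(volumes=volumes, acquisition_times=times, modality=spec.modality)
    masks = {
        label: RoiMask(voxels=vox, label=label, spacing=spec.spacing)
        for label, vox in masks_vox.items()
    }
    ground_truth = {
        "params": {
            "peak_time_s": float(peak_time),
            "peak_amplitude_hu": float(amplitude),
            "t0_s": float(t0),
            "tumor_k_in": spec.tumor_k_in,
            "tumor_k_out": spec.tumor_k_out,
            "healthy_k_in": spec.healthy_k_in,
            "healthy_k_out": spec.healthy_k_out,
            "texture_enh_fraction": spec.texture_enh_fraction,
        },
        "curves": {"vessel": vessel_curve, "tumor": tumor, "healthy": healthy},
        "peak_scan_index": int(np.argmax(vessel_curve)),
    }
    return PhantomPatient(
        patient_id=patient_id or f"P{patient_seed:04d}",
        series=series,
        masks=masks,
        ground_truth=ground_truth,
    )


def patient_seeds(spec: PhantomSpec) -> list[int]:
    """Independent per-patient integer seeds derived from the master seed."""
    ss = np.random.SeedSequence(spec.seed)
    state = ss.generate_state(spec.n_patients)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_cohort(spec: PhantomSpec, out_dir=None) -> list[PhantomPatient]:
    """Simulate ``spec.n_patients`` patients.

    If ``out_dir`` is given, writes per-patient NRRD series and masks plus a
    cohort manifest (CSV and JSON) listing paths, seeds and ground-truth
    parameters.  Two cohorts from the same master seed are identical.
    """
    seeds = patient_seeds(spec)
    patients = [
        generate_patient(spec, seed, patient_id=f"P{i:03d}")
        for i, seed in enumerate(seeds)
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        rows = []
        for pat, seed in zip(patients, seeds):
            pdir = out_dir / pat.patient_id
            pdir.mkdir(parents=True, exist_ok=True)
            for it, vol in enumerate(pat.series.volumes):
                write_volume(pdir / f"scan_{it:03d}.nrrd", vol)
            for label, mask in pat.masks.items():
                write_mask(pdir / f"mask_{label}.nrrd", mask)
            np.savetxt(pdir / "times_s.csv", pat.series.acquisition_times,
                       header="time_s", comments="", fmt="%.6g")
            rows.append({
                "patient_id": pat.patient_id,
                "seed": seed,
                "path": pat.patient_id,
                "n_scans": len(pat.series),
                **pat.ground_truth["params"],
            })
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out_dir / "cohort_manifest.csv", index=False)
        with open(out_dir / "cohort_manifest.json", "w") as fh:
            json.dump({"spec": asdict(spec), "patients": rows}, fh, indent=2, default=str)
        logger.info("wrote phantom cohort with %d patients to %s", len(patients), out_dir)
    return patients
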