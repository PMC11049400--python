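"""Image preprocessing and filter banks for feature extraction.

Order of operations mirrors the usual radiomics convention: optional
whole-volume intensity normalization (MR), isotropic resampling with
cubic-spline interpolation (nearest-neighbour for the mask), cropping to
the mask bounding box plus a pad margin, then filter banks applied to the
cropped volume.
"""

from __future__ import annotations

import numpy as np
import pywt
import SimpleITK as sitk
from scipy import ndimage

from ..io_core import ImageVolume, RoiMask
from .config import ExtractionConfig

#: sub-band labels in x,y,z filter order (L = low pass, H = high pass)
WAVELET_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _resample(volume: ImageVolume, mask: RoiMask, target: tuple[float, float, float]
              ) -> tuple[ImageVolume, RoiMask]:
    img = volume.to_sitk()
    msk = sitk.GetImageFromArray(mask.voxels.astype(np.uint8))
    msk.CopyInformation(img)

    old_size = np.array(img.GetSize(), dtype=float)          # (x, y, z)
    old_spacing = np.array(img.GetSpacing(), dtype=float)
    new_spacing = np.array(tuple(reversed(target)), dtype=float)
    new_size = np.maximum(np.ceil(old_size * old_spacing / new_spacing), 1).astype(int)

    def run(image, interp):
        rs = sitk.ResampleImageFilter()
        rs.SetOutputSpacing(tuple(new_spacing))
        rs.SetSize([int(s) for s in new_size])
        rs.SetOutputOrigin(image.GetOrigin())
        rs.SetOutputDirection(image.GetDirection())
        rs.SetInterpolator(interp)
        rs.SetDefaultPixelValue(0)
        return rs.Execute(image)

    new_img = run(img, sitk.sitkBSpline)
    new_msk = run(msk, sitk.sitkNearestNeighbor)
    vol = ImageVolume.from_sitk(new_img)
    mvox = sitk.GetArrayFromImage(new_msk) > 0
    if not mvox.any():
        raise ValueError("mask empty after resampling")
    return vol, RoiMask(voxels=mvox, label=mask.label, spacing=vol.spacing, origin=vol.origin)


def _crop(volume: ImageVolume, mask: RoiMask, pad: int) -> tuple[ImageVolume, RoiMask]:
    idx = np.nonzero(mask.voxels)
    lo = [max(int(i.min()) - pad, 0) for i in idx]
    hi = [min(int(i.max()) + pad + 1, s) for i, s in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    origin = tuple(o + a * s for o, a, s in zip(volume.origin, lo, volume.spacing))
    vol = ImageVolume(voxels=volume.voxels[sl].copy(), spacing=volume.spacing, origin=origin)
    msk = RoiMask(voxels=mask.voxels[sl].copy(), label=mask.label,
                  spacing=mask.spacing, origin=origin)
    return vol, msk


def preprocess(volume: ImageVolume, mask: RoiMask, cfg: ExtractionConfig
               ) -> tuple[ImageVolume, RoiMask]:
    """Normalize (MR), resample to the target spacing and crop around the ROI."""
    if not mask.geometry_equal(volume):
        raise ValueError("mask geometry does not match the volume")
    vox = np.asarray(volume.voxels, dtype=float)
    if cfg.normalize:
        sd = vox.std()
        if sd == 0:
            raise ValueError("zero-variance image cannot be normalized")
        vox = (vox - vox.mean()) / sd * cfg.normalize_scale
    vol = ImageVolume(voxels=vox, spacing=volume.spacing, origin=volume.origin)
    msk = mask
    if not np.allclose(vol.spacing, cfg.resampled_spacing, rtol=1e-6):
        vol, msk = _resample(vol, msk, tuple(cfg.resampled_spacing))
    return _crop(vol, msk, cfg.pad_distance)


def _log_kernels(sig_vox: float, truncate: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian and second-derivative-of-Gaussian 1D kernels.

    The derivative kernel is corrected to zero DC gain (its raw sampled sum
    is slightly nonzero), so the response to a constant image is exactly 0.
    """
    r = max(int(truncate * sig_vox + 0.5), 1)
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-0.5 * (x / sig_vox) ** 2)
    g /= g.sum()
    k2 = g * (x**2 - sig_vox**2) / sig_vox**4
    k2 -= k2.sum() * g
    return g, k2


def log_filter(volume: ImageVolume, sigma: float) -> ImageVolume:
    """Laplacian-of-Gaussian response at physical scale ``sigma`` (mm).

    The per-axis Gaussian sigma is ``sigma / spacing`` voxels and the
    second derivatives are taken per millimetre, so the response is
    independent of the sampling grid.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    vox = np.asarray(volume.voxels, dtype=float)
    kernels = [_log_kernels(sigma / s) for s in volume.spacing]
    out = np.zeros_like(vox)
    for axis in range(3):
        term = vox
        for ax2 in range(3):
            g, k2 = kernels[ax2]
            kern = k2 if ax2 == axis else g
            term = ndimage.correlate1d(term, kern, axis=ax2, mode="nearest")
        out += term / volume.spacing[axis] ** 2
    return ImageVolume(voxels=out, spacing=volume.spacing, origin=volume.origin)


def wavelet_subbands(volume: ImageVolume, wavelet: str = "coif1"
                     ) -> list[tuple[str, ImageVolume]]:
    """Single-level undecimated separable 3D wavelet decomposition.

    Returns the eight sub-bands labelled LLL..HHH (filter letters in
    x, y, z order), each the same size as the input so ROI masks apply
    unchanged.  With ``norm=True`` and an orthogonal wavelet the summed
    energy of the eight sub-bands equals the input energy (Parseval) for
    even-sized, periodically-extendable inputs.
    """
    vox = np.asarray(volume.voxels, dtype=float)
    pads = [(0, s % 2) for s in vox.shape]  # swt needs even axis lengths
    padded = np.pad(vox, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, norm=True, trim_approx=False)[0]
    crop = tuple(slice(0, s) for s in vox.shape)
    out = []
    for label in WAVELET_LABELS:
        # array axes are (z, y, x); swtn keys use 'a'/'d' per array axis
        key = "".join("a" if c == "L" else "d" for c in reversed(label))
        out.append((label, ImageVolume(voxels=coeffs[key][crop],
                                       spacing=volume.spacing, origin=volume.origin)))
    return out


def discretize(values, bin_width: float):
    """Fixed-bin-width gray levels anchored at the minimum:
    ``level(x) = floor((x - min) / bin_width) + 1``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    return np.floor((values - values.min()) / bin_width).astype(np.int64) + 1


def discretize_volume(voxels, mask, bin_width: float):
    """Discretize a volume over its ROI; voxels outside the mask get level 0."""
    voxels = np.asarray(voxels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    mn = voxels[mask].min()
    levels = np.floor((voxels - mn) / bin_width).astype(np.int64) + 1
    levels[~mask] = 0
    return levels
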