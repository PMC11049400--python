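"""Full-battery feature extraction for one volume/ROI pair."""

from __future__ import annotations

import numpy as np

from ..io_core import ImageVolume, RoiMask
from .config import ExtractionConfig, FeatureVector
from .firstorder import first_order_features
from .preprocessing import discretize_volume, log_filter, preprocess, wavelet_subbands
from .texture import glcm_features, texture_features

FEATURE_CLASSES = ("firstorder", "glcm", "gldm", "glrlm", "glszm")


def image_sets(volume: ImageVolume, cfg: ExtractionConfig
               ) -> list[tuple[str, ImageVolume]]:
    """The tagged image stack: original, LoG responses, wavelet sub-bands.

    Filters are applied to the already preprocessed (normalized, resampled,
    cropped) volume; the pad margin supplies filter context around the ROI.
    """
    sets: list[tuple[str, ImageVolume]] = [("original", volume)]
    for sigma in cfg.log_sigmas:
        sets.append((f"log-sigma-{sigma:g}-mm", log_filter(volume, sigma)))
    if cfg.wavelet:
        for label, sub in wavelet_subbands(volume, cfg.wavelet_name):
            sets.append((f"wavelet-{label}", sub))
    return sets


def _features_for_set(vol: ImageVolume, mask: RoiMask, cfg: ExtractionConfig
                      ) -> tuple[dict[str, float], set[str]]:
    mvox = mask.voxels
    values = vol.voxels[mvox]
    feats: dict[str, float] = {}
    flags: set[str] = set()

    fo, fo_flags = first_order_features(
        values, bin_width=cfg.bin_width, shift=cfg.voxel_array_shift,
        voxel_volume=vol.voxel_volume,
    )
    for k, v in fo.items():
        feats[f"firstorder_{k}"] = v
    flags.update(f"firstorder_{k}" for k in fo_flags)

    levels = discretize_volume(vol.voxels, mvox, cfg.bin_width)
    gl, gl_flags = glcm_features(levels, mvox)
    for k, v in gl.items():
        feats[f"glcm_{k}"] = v
    flags.update(f"glcm_{k}" for k in gl_flags)

    for kind in ("gldm", "glrlm", "glszm"):
        tx, tx_flags = texture_features(levels, mvox, kind)
        for k, v in tx.items():
            feats[f"{kind}_{k}"] = v
        flags.update(f"{kind}_{k}" for k in tx_flags)
    return feats, flags


def extract_all(volume: ImageVolume, mask: RoiMask,
                cfg: ExtractionConfig | None = None) -> FeatureVector:
    """Extract the complete battery: 86 features per image set.

    The CT preset yields 14 x 86 = 1204 entries, the MR preset
    13 x 86 = 1118, in a stable deterministic order (image sets in stack
    order, classes firstorder/glcm/gldm/glrlm/glszm, feature names
    alphabetical within a class).  Shape features are excluded by
    construction: the mask is identical across the dynamic series.
    """
    cfg = cfg or ExtractionConfig.ct_default()
    vol_p, mask_p = preprocess(volume, mask, cfg)
    values: dict[str, float] = {}
    flags: set[str] = set()
    for tag, img in image_sets(vol_p, cfg):
        feats, fl = _features_for_set(img, mask_p, cfg)
        for name, val in feats.items():
            values[f"{tag}_{name}"] = val
        flags.update(f"{tag}_{name}" for name in fl)
    expected = 86 * cfg.n_image_sets
    assert len(values) == expected, f"feature count {len(values)} != {expected}"
    return FeatureVector(values=values, flags=flags)
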