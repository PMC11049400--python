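"""Gray-level texture matrices (GLCM, GLDM, GLRLM, GLSZM) and their features.

All matrices are built on a 3D grid of positive integer gray levels with 0
marking voxels outside the ROI:

* GLCM — symmetric co-occurrence counts over the 13 unique direction
  offsets at Chebyshev distance 1, normalized per direction, with each of
  the 22 features averaged over directions.
* GLDM — 26-connected dependence counts with dependence threshold
  alpha = 0; the dependence size of a voxel is 1 (itself) plus the number
  of neighbours sharing its gray level.
* GLRLM — maximal same-level runs along each of the 13 directions,
  features averaged over directions.
* GLSZM — 26-connected iso-intensity zones (single matrix).

Degenerate inputs (single-voxel ROI, single gray level) return defined
sentinel values together with a per-feature flag instead of raising, so a
screening stage can treat them as missing.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

#: the 13 unique direction offsets of the 26-neighbourhood (z, y, x)
ANGLES_13 = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
)

OFFSETS_26 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "SumEntropy", "SumSquares",
)

GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)


def _shift(arr: np.ndarray, off, fill=0) -> np.ndarray:
    """out[v] = arr[v - off], with `fill` where v - off falls outside."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for o, size in zip(off, arr.shape):
        if o >= 0:
            dst.append(slice(o, size))
            src.append(slice(0, size - o))
        else:
            dst.append(slice(0, size + o))
            src.append(slice(-o, size))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(levels: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
    """One normalized symmetric co-occurrence matrix per direction with at
    least one voxel pair; levels are 1..Ng inside the mask, 0 outside."""
    ng = int(levels[mask].max())
    mats = []
    for off in ANGLES_13:
        nb_lv = _shift(levels, tuple(-o for o in off))   # level of voxel v+off
        nb_in = _shift(mask.astype(np.uint8), tuple(-o for o in off)) > 0
        valid = mask & nb_in
        if not valid.any():
            continue
        i = levels[valid]
        j = nb_lv[valid]
        counts = np.bincount((i - 1) * ng + (j - 1), minlength=ng * ng)
        c = counts.reshape(ng, ng).astype(float)
        c = c + c.T  # symmetric: count each pair in both orders
        mats.append(c / c.sum())
    return mats


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    lv = np.arange(1, ng + 1, dtype=float)
    i = lv[:, None]
    j = lv[None, :]
    px = p.sum(axis=1)
    ux = float(np.sum(px * lv))
    sigx = float(np.sqrt(np.sum(px * (lv - ux) ** 2)))

    k_diff = np.abs(i - j).astype(int)
    pd = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=ng)
    kd = np.arange(pd.size, dtype=float)
    da = float(np.sum(kd * pd))

    k_sum = (i + j).astype(int)
    ps = np.bincount(k_sum.ravel(), weights=p.ravel())
    ps_nz = ps[ps > 0]

    p_nz = p[p > 0]
    hxy = float(-np.sum(p_nz * np.log2(p_nz + _EPS)))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0] + _EPS)))
    pxpy = px[:, None] * px[None, :]
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))

    if sigx > 0:
        correlation = float(np.sum(p * (i - ux) * (j - ux))) / (sigx * sigx)
    else:
        correlation = 1.0  # single gray level: perfectly dependent
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))))

    inv_var = 0.0
    if ng > 1:
        off_diag = k_diff > 0
        inv_var = float(np.sum(p[off_diag] / (i - j)[off_diag] ** 2))

    return {
        "Autocorrelation": float(np.sum(p * i * j)),
        "ClusterProminence": float(np.sum(p * (i + j - 2 * ux) ** 4)),
        "ClusterShade": float(np.sum(p * (i + j - 2 * ux) ** 3)),
        "ClusterTendency": float(np.sum(p * (i + j - 2 * ux) ** 2)),
        "Contrast": float(np.sum(p * (i - j) ** 2)),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(pd[pd > 0] * np.log2(pd[pd > 0] + _EPS))),
        "DifferenceVariance": float(np.sum(pd * (kd - da) ** 2)),
        "Id": float(np.sum(pd / (1.0 + kd))),
        "Idm": float(np.sum(pd / (1.0 + kd**2))),
        "Idmn": float(np.sum(pd / (1.0 + (kd / ng) ** 2))),
        "Idn": float(np.sum(pd / (1.0 + kd / ng))),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-np.sum(ps_nz * np.log2(ps_nz + _EPS))),
        "SumSquares": float(np.sum(p * (i - ux) ** 2)),
    }


def glcm_features(levels: np.ndarray, mask: np.ndarray
                  ) -> tuple[dict[str, float], set[str]]:
    """The 22 co-occurrence features, averaged over the 13 directions.

    A ROI with no voxel pairs (e.g. a single voxel) yields NaN for every
    feature, each flagged; a single-gray-level ROI flags the
    correlation-type features and uses their documented fallbacks
    (Correlation = 1, InverseVariance = 0, Imc1 = 0).
    """
    mats = glcm_matrices(levels, mask)
    if not mats:
        return {name: float("nan") for name in GLCM_NAMES}, set(GLCM_NAMES)
    per_angle = [_glcm_single(p) for p in mats]
    feats = {name: float(np.mean([f[name] for f in per_angle])) for name in GLCM_NAMES}
    flags: set[str] = set()
    if int(levels[mask].max()) == int(levels[mask].min()):
        flags.update({"Correlation", "Imc1", "Imc2", "InverseVariance"})
    return feats, flags


# ---------------------------------------------------------------------------
# generic distribution statistics shared by GLDM / GLRLM / GLSZM
# ---------------------------------------------------------------------------

def _rl_stats(P: np.ndarray) -> dict[str, float]:
    """Statistics of a (gray level x size) count matrix with 1-based bins."""
    ns = P.sum()
    iv = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    jv = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    p = P / ns
    mu_i = float(np.sum(p * iv))
    mu_j = float(np.sum(p * jv))
    p_nz = p[p > 0]
    return {
        "small": float(np.sum(P / jv**2) / ns),
        "large": float(np.sum(P * jv**2) / ns),
        "gln": float(np.sum(P.sum(axis=1) ** 2) / ns),
        "glnn": float(np.sum(P.sum(axis=1) ** 2) / ns**2),
        "sn": float(np.sum(P.sum(axis=0) ** 2) / ns),
        "snn": float(np.sum(P.sum(axis=0) ** 2) / ns**2),
        "glv": float(np.sum(p * (iv - mu_i) ** 2)),
        "sv": float(np.sum(p * (jv - mu_j) ** 2)),
        "entropy": float(-np.sum(p_nz * np.log2(p_nz + _EPS))),
        "lgl": float(np.sum(P / iv**2) / ns),
        "hgl": float(np.sum(P * iv**2) / ns),
        "slgl": float(np.sum(P / (iv**2 * jv**2)) / ns),
        "shgl": float(np.sum(P * iv**2 / jv**2) / ns),
        "llgl": float(np.sum(P * jv**2 / iv**2) / ns),
        "lhgl": float(np.sum(P * iv**2 * jv**2) / ns),
        "n": float(ns),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(levels: np.ndarray, mask: np.ndarray, alpha: float = 0.0) -> np.ndarray:
    ng = int(levels[mask].max())
    dep = np.ones(levels.shape, dtype=np.int64)  # the centre voxel itself
    for off in OFFSETS_26:
        nb_lv = _shift(levels, tuple(-o for o in off))
        nb_in = _shift(mask.astype(np.uint8), tuple(-o for o in off)) > 0
        dep += (mask & nb_in & (np.abs(levels - nb_lv) <= alpha)).astype(np.int64)
    i = levels[mask] - 1
    j = dep[mask] - 1
    jmax = int(j.max()) + 1
    counts = np.bincount(i * jmax + j, minlength=ng * jmax)
    return counts.reshape(ng, jmax).astype(float)


def _gldm_features(levels, mask) -> tuple[dict[str, float], set[str]]:
    P = gldm_matrix(levels, mask)
    s = _rl_stats(P)
    feats = {
        "DependenceEntropy": s["entropy"],
        "DependenceNonUniformity": s["sn"],
        "DependenceNonUniformityNormalized": s["snn"],
        "DependenceVariance": s["sv"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelVariance": s["glv"],
        "HighGrayLevelEmphasis": s["hgl"],
        "LargeDependenceEmphasis": s["large"],
        "LargeDependenceHighGrayLevelEmphasis": s["lhgl"],
        "LargeDependenceLowGrayLevelEmphasis": s["llgl"],
        "LowGrayLevelEmphasis": s["lgl"],
        "SmallDependenceEmphasis": s["small"],
        "SmallDependenceHighGrayLevelEmphasis": s["shgl"],
        "SmallDependenceLowGrayLevelEmphasis": s["slgl"],
    }
    return feats, set()


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrices(levels: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
    """One run-length count matrix per direction.

    Runs are maximal sequences of in-mask voxels sharing a gray level along
    a direction; voxels outside the mask break runs.  Run lengths are found
    with a vectorized chain scan: ``length(v) = 1 + length(v + d)`` while
    the next voxel continues the run.
    """
    ng = int(levels[mask].max())
    maxlen = max(levels.shape)
    mats = []
    for off in ANGLES_13:
        back = tuple(-o for o in off)
        prev_lv = _shift(levels, off)
        prev_in = _shift(mask.astype(np.uint8), off) > 0
        same_prev = mask & prev_in & (levels == prev_lv)
        starts = mask & ~same_prev
        same_next = _shift(same_prev.astype(np.uint8), back) > 0
        length = np.ones(levels.shape, dtype=np.int32)
        for _ in range(maxlen - 1):
            nxt = 1 + np.where(same_next, _shift(length, back), 0)
            if np.array_equal(nxt, length):
                break
            length = nxt
        lv = levels[starts] - 1
        rl = length[starts] - 1
        rmax = int(rl.max()) + 1
        counts = np.bincount(lv * rmax + rl, minlength=ng * rmax)
        mats.append(counts.reshape(ng, rmax).astype(float))
    return mats


def _glrlm_features(levels, mask) -> tuple[dict[str, float], set[str]]:
    np_vox = float(mask.sum())
    per_dir = []
    for P in glrlm_matrices(levels, mask):
        s = _rl_stats(P)
        per_dir.append({
            "GrayLevelNonUniformity": s["gln"],
            "GrayLevelNonUniformityNormalized": s["glnn"],
            "GrayLevelVariance": s["glv"],
            "HighGrayLevelRunEmphasis": s["hgl"],
            "LongRunEmphasis": s["large"],
            "LongRunHighGrayLevelEmphasis": s["lhgl"],
            "LongRunLowGrayLevelEmphasis": s["llgl"],
            "LowGrayLevelRunEmphasis": s["lgl"],
            "RunEntropy": s["entropy"],
            "RunLengthNonUniformity": s["sn"],
            "RunLengthNonUniformityNormalized": s["snn"],
            "RunPercentage": s["n"] / np_vox,
            "RunVariance": s["sv"],
            "ShortRunEmphasis": s["small"],
            "ShortRunHighGrayLevelEmphasis": s["shgl"],
            "ShortRunLowGrayLevelEmphasis": s["slgl"],
        })
    feats = {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_NAMES}
    return feats, set()


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    ng = int(levels[mask].max())
    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    rows, cols, vals = [], [], []
    zone_sizes: dict[tuple[int, int], int] = {}
    for lvl in range(1, ng + 1):
        lab, nz = ndimage.label(levels == lvl, structure=structure)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for size in sizes:
            key = (lvl, int(size))
            zone_sizes[key] = zone_sizes.get(key, 0) + 1
    smax = max(s for _, s in zone_sizes)
    P = np.zeros((ng, smax), dtype=float)
    for (lvl, size), cnt in zone_sizes.items():
        P[lvl - 1, size - 1] += cnt
    return P


def _glszm_features(levels, mask) -> tuple[dict[str, float], set[str]]:
    P = glszm_matrix(levels, mask)
    s = _rl_stats(P)
    feats = {
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "GrayLevelVariance": s["glv"],
        "HighGrayLevelZoneEmphasis": s["hgl"],
        "LargeAreaEmphasis": s["large"],
        "LargeAreaHighGrayLevelEmphasis": s["lhgl"],
        "LargeAreaLowGrayLevelEmphasis": s["llgl"],
        "LowGrayLevelZoneEmphasis": s["lgl"],
        "SizeZoneNonUniformity": s["sn"],
        "SizeZoneNonUniformityNormalized": s["snn"],
        "SmallAreaEmphasis": s["small"],
        "SmallAreaHighGrayLevelEmphasis": s["shgl"],
        "SmallAreaLowGrayLevelEmphasis": s["slgl"],
        "ZoneEntropy": s["entropy"],
        "ZonePercentage": s["n"] / float(mask.sum()),
        "ZoneVariance": s["sv"],
    }
    return feats, set()


def texture_features(levels: np.ndarray, mask: np.ndarray, kind: str
                     ) -> tuple[dict[str, float], set[str]]:
    """Dispatch to the GLDM (14), GLRLM (16) or GLSZM (16) feature set."""
    kind = kind.upper()
    if kind == "GLDM":
        return _gldm_features(levels, mask)
    if kind == "GLRLM":
        return _glrlm_features(levels, mask)
    if kind == "GLSZM":
        return _glszm_features(levels, mask)
    raise ValueError(f"unknown texture matrix kind {kind!r}")
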