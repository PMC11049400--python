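"""Naive reference implementations of the 86-feature battery.

Everything here is written as direct, loop-based transliteration of the
feature definitions — explicit pair/run/zone enumeration and explicit
summations — independently of the vectorized implementations in the
package.  Used as the oracle in equivalence tests.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

EPS = float(np.spacing(1.0))

DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]

NEIGHBOURS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


def _voxels(mask):
    return [tuple(v) for v in np.argwhere(mask)]


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def ref_first_order(values, bin_width, shift, voxel_volume):
    x = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(x)
    mean = sum(x) / n
    mn, mx = x[0], x[-1]

    def pct(q):
        return float(np.percentile(x, q))  # linear interpolation, as standard

    p10, p25, p75, p90 = pct(10), pct(25), pct(75), pct(90)
    energy = sum((v + shift) ** 2 for v in x)
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n

    mn_lv = mn
    hist = defaultdict(int)
    for v in x:
        hist[math.floor((v - mn_lv) / bin_width) + 1] += 1
    probs = [c / n for c in hist.values()]

    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)

    return {
        "10Percentile": p10,
        "90Percentile": p90,
        "Energy": energy,
        "Entropy": -sum(p * math.log2(p + EPS) for p in probs),
        "InterquartileRange": p75 - p25,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Maximum": mx,
        "Mean": mean,
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "Median": float(np.median(x)),
        "Minimum": mn,
        "Range": mx - mn,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": sum(p * p for p in probs),
        "Variance": m2,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def ref_glcm_matrices(levels, mask):
    ng = int(levels[mask].max())
    shape = levels.shape
    mats = []
    for d in DIRECTIONS_13:
        C = np.zeros((ng, ng))
        for v in _voxels(mask):
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, w) and mask[w]:
                C[levels[v] - 1, levels[w] - 1] += 1
                C[levels[w] - 1, levels[v] - 1] += 1
        if C.sum() > 0:
            mats.append(C / C.sum())
    return mats


def _ref_glcm_one(p):
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    sigx = math.sqrt(sum(px[i] * (i + 1 - ux) ** 2 for i in range(ng)))

    pd = defaultdict(float)
    ps = defaultdict(float)
    for i in range(ng):
        for j in range(ng):
            pd[abs(i - j)] += p[i, j]
            ps[i + j + 2] += p[i, j]
    da = sum(k * v for k, v in pd.items())

    hxy = -sum(p[i, j] * math.log2(p[i, j] + EPS)
               for i in range(ng) for j in range(ng) if p[i, j] > 0)
    hx = -sum(q * math.log2(q + EPS) for q in px if q > 0)
    hxy1 = -sum(p[i, j] * math.log2(px[i] * px[j] + EPS)
                for i in range(ng) for j in range(ng))
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j] + EPS)
                for i in range(ng) for j in range(ng))

    if sigx > 0:
        corr = sum(p[i, j] * (i + 1 - ux) * (j + 1 - ux)
                   for i in range(ng) for j in range(ng)) / (sigx * sigx)
    else:
        corr = 1.0

    return {
        "Autocorrelation": sum(p[i, j] * (i + 1) * (j + 1)
                               for i in range(ng) for j in range(ng)),
        "ClusterProminence": sum(p[i, j] * (i + j + 2 - 2 * ux) ** 4
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum(p[i, j] * (i + j + 2 - 2 * ux) ** 3
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum(p[i, j] * (i + j + 2 - 2 * ux) ** 2
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum(p[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v + EPS) for v in pd.values() if v > 0),
        "DifferenceVariance": sum(v * (k - da) ** 2 for k, v in pd.items()),
        "Id": sum(v / (1 + k) for k, v in pd.items()),
        "Idm": sum(v / (1 + k * k) for k, v in pd.items()),
        "Idmn": sum(v / (1 + (k / ng) ** 2) for k, v in pd.items()),
        "Idn": sum(v / (1 + k / ng) for k, v in pd.items()),
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(1 - math.exp(-2 * max(hxy2 - hxy, 0.0))),
        "InverseVariance": sum(v / k**2 for k, v in pd.items() if k > 0),
        "JointAverage": ux,
        "JointEnergy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "MaximumProbability": p.max(),
        "SumEntropy": -sum(v * math.log2(v + EPS) for v in ps.values() if v > 0),
        "SumSquares": sum(p[i, j] * (i + 1 - ux) ** 2
                          for i in range(ng) for j in range(ng)),
    }


def ref_glcm_features(levels, mask):
    mats = ref_glcm_matrices(levels, mask)
    if not mats:
        return None
    per = [_ref_glcm_one(p) for p in mats]
    return {k: sum(d[k] for d in per) / len(per) for k in per[0]}


# ---------------------------------------------------------------------------
# count-matrix statistics shared by GLDM / GLRLM / GLSZM
# ---------------------------------------------------------------------------

def _ref_stats(entries):
    """entries: list of (gray level, size, count)."""
    ns = sum(c for _, _, c in entries)
    mu_i = sum(i * c for i, _, c in entries) / ns
    mu_j = sum(j * c for _, j, c in entries) / ns
    by_i = defaultdict(float)
    by_j = defaultdict(float)
    for i, j, c in entries:
        by_i[i] += c
        by_j[j] += c
    return {
        "small": sum(c / j**2 for _, j, c in entries) / ns,
        "large": sum(c * j**2 for _, j, c in entries) / ns,
        "gln": sum(v * v for v in by_i.values()) / ns,
        "glnn": sum(v * v for v in by_i.values()) / ns**2,
        "sn": sum(v * v for v in by_j.values()) / ns,
        "snn": sum(v * v for v in by_j.values()) / ns**2,
        "glv": sum(c * (i - mu_i) ** 2 for i, _, c in entries) / ns,
        "sv": sum(c * (j - mu_j) ** 2 for _, j, c in entries) / ns,
        "entropy": -sum((c / ns) * math.log2(c / ns + EPS)
                        for _, _, c in _merge_cells(entries)),
        "lgl": sum(c / i**2 for i, _, c in entries) / ns,
        "hgl": sum(c * i**2 for i, _, c in entries) / ns,
        "slgl": sum(c / (i**2 * j**2) for i, j, c in entries) / ns,
        "shgl": sum(c * i**2 / j**2 for i, j, c in entries) / ns,
        "llgl": sum(c * j**2 / i**2 for i, j, c in entries) / ns,
        "lhgl": sum(c * i**2 * j**2 for i, j, c in entries) / ns,
        "n": ns,
    }


def _merge_cells(entries):
    cells = defaultdict(float)
    for i, j, c in entries:
        cells[(i, j)] += c
    return [(i, j, c) for (i, j), c in cells.items() if c > 0]


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def ref_gldm_entries(levels, mask, alpha=0):
    shape = levels.shape
    counts = defaultdict(int)
    for v in _voxels(mask):
        dep = 1
        for d in NEIGHBOURS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(shape, w) and mask[w] and abs(int(levels[v]) - int(levels[w])) <= alpha:
                dep += 1
        counts[(int(levels[v]), dep)] += 1
    return [(i, j, c) for (i, j), c in counts.items()]


def ref_gldm_features(levels, mask):
    s = _ref_stats(ref_gldm_entries(levels, mask))
    return {
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


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def ref_glrlm_entries(levels, mask):
    """One entry list (gray level, run length, count) per direction."""
    shape = levels.shape
    out = []
    for d in DIRECTIONS_13:
        counts = defaultdict(int)
        for v in _voxels(mask):
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if _inside(shape, prev) and mask[prev] and levels[prev] == levels[v]:
                continue  # not a run start
            length = 1
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            while _inside(shape, w) and mask[w] and levels[w] == levels[v]:
                length += 1
                w = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
            counts[(int(levels[v]), length)] += 1
        out.append([(i, j, c) for (i, j), c in counts.items()])
    return out


def ref_glrlm_features(levels, mask):
    np_vox = int(mask.sum())
    per = []
    for entries in ref_glrlm_entries(levels, mask):
        s = _ref_stats(entries)
        per.append({
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
    return {k: sum(d[k] for d in per) / len(per) for k in per[0]}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def ref_glszm_entries(levels, mask):
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    counts = defaultdict(int)
    for v in _voxels(mask):
        if seen[v]:
            continue
        lvl = int(levels[v])
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for d in NEIGHBOURS_26:
                w = (u[0] + d[0], u[1] + d[1], u[2] + d[2])
                if (_inside(shape, w) and mask[w] and not seen[w]
                        and int(levels[w]) == lvl):
                    seen[w] = True
                    stack.append(w)
        counts[(lvl, size)] += 1
    return [(i, j, c) for (i, j), c in counts.items()]


def ref_glszm_features(levels, mask):
    s = _ref_stats(ref_glszm_entries(levels, mask))
    return {
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
        "ZonePercentage": s["n"] / int(mask.sum()),
        "ZoneVariance": s["sv"],
    }


def ref_all_86(grid, mask, bin_width=1.0, shift=0.0, voxel_volume=1.0):
    """All 86 reference features on an integer grid, keyed class_name."""
    values = grid[mask].astype(float)
    mn = values.min()
    levels = np.zeros(grid.shape, dtype=int)
    for v in _voxels(mask):
        levels[v] = math.floor((grid[v] - mn) / bin_width) + 1
    out = {}
    for k, val in ref_first_order(values, bin_width, shift, voxel_volume).items():
        out[f"firstorder_{k}"] = val
    glcm = ref_glcm_features(levels, mask)
    for k, val in (glcm or {}).items():
        out[f"glcm_{k}"] = val
    for k, val in ref_gldm_features(levels, mask).items():
        out[f"gldm_{k}"] = val
    for k, val in ref_glrlm_features(levels, mask).items():
        out[f"glrlm_{k}"] = val
    for k, val in ref_glszm_features(levels, mask).items():
        out[f"glszm_{k}"] = val
    return out
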