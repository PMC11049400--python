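"""Per-feature temporal screening across the seven contrast phases.

Each feature is fit with a linear mixed model

    value ~ timepoint + (1 | patient)           [+ (1 | visit) optionally]

by REML, with the timepoint entering as a numeric covariate 1-7 by default
(a categorical joint test is available for non-monotone profiles).  The
Wald statistic for the timepoint effect is referred to a t distribution
with residual degrees of freedom ``N - n_groups - n_slope_terms``; for the
balanced within-patient design screened here this equals the Satterthwaite
degrees of freedom.  Raw p-values are corrected with the Benjamini-
Hochberg step-up FDR, and a feature is called significant only when both
p < alpha and q < alpha.  Non-converging or degenerate (zero-variance,
flagged) features are excluded from the FDR universe, mirroring how
non-converging energy features are handled in practice.

Mean temporal profiles are z-scored over the seven phases and clustered
with complete-linkage hierarchical clustering on Euclidean distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

LONG_COLUMNS = ("subject", "visit", "roi", "phase", "feature", "value", "flag")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    timepoint_coding: str = "numeric"     # or "categorical"
    formula: str = "patient"              # or "patient+visit"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.timepoint_coding not in ("numeric", "categorical"):
            raise ValueError("timepoint_coding must be 'numeric' or 'categorical'")
        if self.formula not in ("patient", "patient+visit"):
            raise ValueError("formula must be 'patient' or 'patient+visit'")


@dataclass
class LmmResult:
    feature: str
    estimate: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    converged: bool = False
    excluded: bool = False


def validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format feature table contract."""
    missing = [c for c in ("subject", "roi", "phase", "feature", "value") if c not in table]
    if missing:
        raise ValueError(f"long table missing columns: {missing}")
    if not table["phase"].isin(range(1, 8)).all():
        raise ValueError("phase must be in 1..7")
    keys = ["subject", "roi", "phase", "feature"]
    if "visit" in table:
        keys.insert(1, "visit")
    if table.duplicated(subset=keys).any():
        raise ValueError("duplicate (subject, visit, roi, phase, feature) rows")
    return table


def fit_lmm(table: pd.DataFrame, cfg: StatsConfig | None = None,
            feature: str | None = None) -> LmmResult:
    """Fit the mixed model for one feature (table restricted to one
    feature and one ROI) and test the timepoint effect."""
    cfg = cfg or StatsConfig()
    name = feature or (str(table["feature"].iloc[0]) if "feature" in table else "feature")
    df = table.copy()
    if "flag" in df:
        df = df[~df["flag"].astype(bool)]
    df = df.dropna(subset=["value"])
    result = LmmResult(feature=name)

    if df.empty or df["subject"].nunique() < 2 or df["phase"].nunique() < 2:
        result.excluded = True
        return result
    y = df["value"].to_numpy(dtype=float)
    scale = y.std()
    if scale == 0 or not np.isfinite(scale):
        result.excluded = True
        return result
    y_std = (y - y.mean()) / scale

    data = pd.DataFrame({
        "y": y_std,
        "phase": df["phase"].to_numpy(dtype=float),
        "subject": df["subject"].to_numpy(),
    })
    n_groups = df["subject"].nunique()
    vc_formula = None
    if cfg.formula == "patient+visit" and "visit" in df:
        data["visit"] = df["visit"].astype(str).to_numpy()
        vc_formula = {"visit": "0 + C(visit)"}
        n_groups += int(df.groupby("subject")["visit"].nunique().sum()) - n_groups

    formula = "y ~ phase" if cfg.timepoint_coding == "numeric" else "y ~ C(phase)"
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, groups="subject",
                                     vc_formula=vc_formula, data=data)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = model.fit(reml=True, method=method, maxiter=200)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
    if fit is None:
        result.excluded = True
        return result

    fe = fit.fe_params
    slope_names = [n for n in fe.index if n.startswith(("phase", "C(phase)"))]
    cov = fit.cov_params().loc[slope_names, slope_names].to_numpy(dtype=float)
    df_resid = len(y) - n_groups - len(slope_names)
    if df_resid < 1:
        result.excluded = True
        return result

    if len(slope_names) == 1:
        est = float(fe[slope_names[0]]) * scale  # back on the feature's own scale
        se = float(np.sqrt(cov[0, 0]))
        if not np.isfinite(se) or se == 0:
            result.excluded = True
            return result
        tval = fe[slope_names[0]] / se
        p = float(2 * sps.t.sf(abs(tval), df_resid))
    else:  # joint Wald F test over the phase contrasts
        b = fe[slope_names].to_numpy(dtype=float)
        try:
            fstat = float(b @ np.linalg.solve(cov, b)) / len(slope_names)
        except np.linalg.LinAlgError:
            result.excluded = True
            return result
        p = float(sps.f.sf(fstat, len(slope_names), df_resid))
        est = float("nan")

    result.estimate = est
    result.p = min(max(p, 0.0), 1.0)
    result.converged = bool(getattr(fit, "converged", True))
    if not result.converged:
        result.excluded = True
    return result


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significant_features(results: list[LmmResult], cfg: StatsConfig | None = None
                         ) -> set[str]:
    """Features with a converged fit and both p and q below alpha."""
    cfg = cfg or StatsConfig()
    return {
        r.feature
        for r in results
        if r.converged and not r.excluded
        and np.isfinite(r.p) and np.isfinite(r.q)
        and r.p < cfg.alpha and r.q < cfg.alpha
    }


def screen_features(table: pd.DataFrame, cfg: StatsConfig | None = None,
                    roi: str | None = None) -> pd.DataFrame:
    """Run the LMM screen for every feature of one ROI and attach BH q-values.

    Returns a DataFrame (feature, estimate, p, q, converged, excluded,
    significant) sorted by feature name.
    """
    cfg = cfg or StatsConfig()
    validate_long_table(table)
    if roi is not None:
        table = table[table["roi"] == roi]
    results: list[LmmResult] = []
    for feat, sub in table.groupby("feature", sort=True):
        results.append(fit_lmm(sub, cfg, feature=str(feat)))
    usable = [r for r in results if not r.excluded and np.isfinite(r.p)]
    qvals = bh_fdr([r.p for r in usable])
    for r, q in zip(usable, qvals):
        r.q = float(q)
    sig = significant_features(results, cfg)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "estimate": [r.estimate for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "converged": [r.converged for r in results],
            "excluded": [r.excluded for r in results],
            "significant": [r.feature in sig for r in results],
        }
    )


def zscore_profile(table: pd.DataFrame, feature: str, roi: str | None = None
                   ) -> tuple[np.ndarray, bool]:
    """Mean feature value per phase over all patients, z-scored across the
    phases (sample sd).  A constant profile returns zeros with a flag."""
    df = table[table["feature"] == feature]
    if roi is not None:
        df = df[df["roi"] == roi]
    if "flag" in df:
        df = df[~df["flag"].astype(bool)]
    means = df.groupby("phase")["value"].mean().sort_index().to_numpy(dtype=float)
    sd = means.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(means), True
    return (means - means.mean()) / sd, False


def cluster_profiles(profiles: dict[str, np.ndarray], k: int | None = None
                     ) -> tuple[dict[str, int], np.ndarray]:
    """Complete-linkage Euclidean clustering of z-scored temporal profiles.

    If ``k`` is None it is chosen at the largest relative gap between
    successive merge heights.  Returns (feature -> 1-based cluster id,
    scipy linkage matrix).
    """
    names = list(profiles)
    X = np.vstack([profiles[n] for n in names])
    if len(names) == 1:
        return {names[0]: 1}, np.empty((0, 4))
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    if k is None:
        heights = Z[:, 2]
        if len(heights) < 2 or heights[-1] == 0:
            k = 1
        else:
            ratios = (heights[1:] + 1e-12) / (heights[:-1] + 1e-12)
            k = len(names) - (int(np.argmax(ratios)) + 1)
            k = max(k, 2)
    labels = hierarchy.fcluster(Z, t=max(k, 1), criterion="maxclust")
    return dict(zip(names, (int(l) for l in labels))), Z


def linkage_to_nested(Z: np.ndarray, names: list[str]):
    """Export a linkage matrix as nested lists of feature names."""
    if len(Z) == 0:
        return names[0] if len(names) == 1 else list(names)
    tree = hierarchy.to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return names[node.id]
        return [walk(node.left), walk(node.right)]

    return walk(tree)


def profile_heatmap(profiles: dict[str, np.ndarray], path, clusters=None) -> None:
    """Optional heatmap of z-scored profiles (features x phases)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(profiles)
    if clusters:
        names.sort(key=lambda n: (clusters.get(n, 0), n))
    X = np.vstack([profiles[n] for n in names])
    fig, ax = plt.subplots(figsize=(6, max(2, 0.12 * len(names))))
    im = ax.imshow(X, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(X.shape[1]), [f"TP{i}" for i in range(1, X.shape[1] + 1)])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
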