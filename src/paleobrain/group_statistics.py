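"""Tabular group statistics: descriptive volumetrics, ICV adjustment,
ANOVA with Ryan's pairwise procedure, laterality, effect sizes and
confound-adjusted cognition regression.

Conventions that matter for degrees-of-freedom bookkeeping:

* ICV adjustment is two-step residualization (fit a pooled ICV slope,
  analyse residuals + grand mean), so a k-group ANOVA on N specimens keeps
  error df = N - k (e.g. 1190 for N = 1193, k = 3), not N - k - 1;
* laterality contrasts between groups are computed on the side-stacked
  table (two rows per specimen), error df = 2N - 2k (2380 at full cohort);
* cognition regression fits volume ~ intercept + score + ICV + age + sex,
  a 5-parameter model, df = n - 5 (1090 at n = 1095).

Volumes are carried in mm^3 internally and reported in cc (1 cc = 1000 mm^3)
by the summary helpers; ratios are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "volume_summary",
    "icv_adjust",
    "anova_ryan",
    "ryan_alpha",
    "cohens_d",
    "laterality_analysis",
    "build_symmetrized_atlas",
    "cognition_regression",
]


@dataclass
class GroupTestResult:
    effect: str
    statistic: float          # F or t
    df: tuple[float, float]   # (df1, df2) for F, (1, df) for t
    p: float
    significant: bool
    alpha_nominal: float
    procedure: str

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p outside [0, 1]")


# ---------------------------------------------------------------------------
# descriptive volumetrics

def volume_summary(table: pd.DataFrame, round_like_print: bool = False) -> pd.DataFrame:
    """Per-group mean ± SD of cerebral volume, cerebellar volume and the
    per-specimen cerebellum/cerebrum ratio.

    ``table`` needs columns ``specimen, group, cerebrum_cc, cerebellum_cc``
    (cc; mm^3 columns named ``*_mm3`` are converted).  The ratio is the mean
    of per-specimen ratios, not the ratio of means.  SD uses the n-1
    denominator.  ``round_like_print`` rounds volumes to whole cc and the
    ratio to 3 decimals, the printed precision of the study tables.
    """
    df = table.copy()
    for col in ("cerebrum", "cerebellum"):
        if f"{col}_cc" not in df.columns:
            if f"{col}_mm3" in df.columns:
                df[f"{col}_cc"] = df[f"{col}_mm3"] / 1000.0
            else:
                raise ValueError(f"missing column {col}_cc or {col}_mm3")
    rows = []
    for g, sub in df.groupby("group", sort=False):
        n = len(sub)
        if n < 2:
            raise ValueError(f"group {g!r} has a single specimen; SD undefined")
        ratio = sub["cerebellum_cc"] / sub["cerebrum_cc"]
        rows.append(
            dict(
                group=g, n=n,
                cerebral_mean_cc=sub["cerebrum_cc"].mean(),
                cerebral_sd_cc=sub["cerebrum_cc"].std(ddof=1),
                cerebellar_mean_cc=sub["cerebellum_cc"].mean(),
                cerebellar_sd_cc=sub["cerebellum_cc"].std(ddof=1),
                ratio_mean=ratio.mean(),
                ratio_sd=ratio.std(ddof=1),
            )
        )
    out = pd.DataFrame(rows)
    if round_like_print:
        for c in out.columns:
            if c.endswith("_cc"):
                out[c] = out[c].round(0)
        out["ratio_mean"] = out["ratio_mean"].round(3)
        out["ratio_sd"] = out["ratio_sd"].round(3)
    return out


# ---------------------------------------------------------------------------
# ICV adjustment

def icv_adjust(volumes: np.ndarray, icv: np.ndarray) -> np.ndarray:
    """Regress ICV out of a volume vector: residual + grand mean.

    One pooled slope across all specimens; the adjusted values are exactly
    uncorrelated with ICV and invariant to adding a constant to all ICVs.
    """
    v = np.asarray(volumes, dtype=float)
    x = np.asarray(icv, dtype=float)
    if x.std() == 0:
        raise ValueError("ICV is constant; cannot adjust")
    xc = x - x.mean()
    b = float(xc @ (v - v.mean()) / (xc @ xc))
    return v - b * xc


# ---------------------------------------------------------------------------
# ANOVA + Ryan's sequentially rejective pairwise procedure

def ryan_alpha(alpha: float, k: int, r: int) -> float:
    """Nominal level for a comparison of means ``r`` ranks apart among ``k``
    ordered group means: alpha' = 2 alpha / (k (r - 1))."""
    return 2.0 * alpha / (k * (r - 1))


def _one_way_anova(values: np.ndarray, groups: np.ndarray):
    """One-way fixed-effects ANOVA; returns (F, df1, df2, p, mse, means, ns)."""
    labels = pd.unique(groups)
    k = len(labels)
    n = len(values)
    means, ns = {}, {}
    ss_between = 0.0
    ss_within = 0.0
    grand = values.mean()
    for g in labels:
        sub = values[groups == g]
        means[g] = sub.mean()
        ns[g] = len(sub)
        ss_between += len(sub) * (sub.mean() - grand) ** 2
        ss_within += ((sub - sub.mean()) ** 2).sum()
    df1, df2 = k - 1, n - k
    mse = ss_within / df2 if df2 > 0 else np.nan
    if df1 == 0:
        return np.nan, df1, df2, np.nan, mse, means, ns
    F = (ss_between / df1) / mse if mse > 0 else (0.0 if ss_between == 0 else np.inf)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return F, df1, df2, p, mse, means, ns


def anova_ryan(values: np.ndarray, groups, alpha: float = 0.05,
               bonferroni_m: int = 1, effect: str = "") -> list[GroupTestResult]:
    """Omnibus one-way ANOVA (optionally Bonferroni across ``bonferroni_m``
    effects) followed by Ryan's sequentially rejective pairwise t tests.

    A pair of means ``r`` ranks apart is tested at nominal level
    ``2 alpha / (k (r-1))`` and declared significant only if every enclosing
    pair is (step-down consistency).  With k = 2 this reduces to a plain
    two-sample t test.  Pairwise t uses the pooled ANOVA MSE with df N - k.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size == 0 or len(groups) != len(values):
        raise ValueError("empty group input")
    F, df1, df2, p, mse, means, ns = _one_way_anova(values, groups)
    alpha_omni = alpha / max(1, bonferroni_m)
    results = [
        GroupTestResult(
            effect=f"{effect}:omnibus" if effect else "omnibus",
            statistic=float(F), df=(df1, df2), p=p,
            significant=p < alpha_omni, alpha_nominal=alpha_omni,
            procedure="one-way ANOVA" + (f" (Bonferroni m={bonferroni_m})"
                                         if bonferroni_m > 1 else ""),
        )
    ]
    labels = sorted(means, key=means.get)
    k = len(labels)
    if k < 2:
        return results
    # pairwise, widest spans first (step-down)
    pair_res: dict[frozenset, GroupTestResult] = {}
    sig: dict[frozenset, bool] = {}
    spans = sorted(
        [(abs(labels.index(a) - labels.index(b)) + 1, a, b)
         for a, b in combinations(labels, 2)],
        key=lambda t: -t[0],
    )
    for r, a, b in spans:
        se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        t = (means[a] - means[b]) / se if se > 0 else 0.0
        pr = 2.0 * float(stats.t.sf(abs(t), df2))
        a_nom = ryan_alpha(alpha, k, r) if k > 2 else alpha
        # consistency: every enclosing span must already be significant
        ia, ib = sorted((labels.index(a), labels.index(b)))
        enclosing_ok = all(
            sig.get(frozenset((labels[ja], labels[jb])), True)
            for ja in range(0, ia + 1)
            for jb in range(ib, k)
            if (jb - ja) > (ib - ia)
            and frozenset((labels[ja], labels[jb])) in sig
        )
        decided = (pr < a_nom) and enclosing_ok
        sig[frozenset((a, b))] = decided
        pair_res[frozenset((a, b))] = GroupTestResult(
            effect=f"{effect}:{a} vs {b}" if effect else f"{a} vs {b}",
            statistic=float(t), df=(1, df2), p=pr, significant=decided,
            alpha_nominal=a_nom, procedure="Ryan pairwise t",
        )
    results.extend(pair_res[frozenset(p_)] for p_ in combinations(labels, 2))
    return results


def cohens_d(a, b) -> float:
    """Standardized mean difference with the (n_a + n_b - 2)-pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (
        len(a) + len(b) - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# laterality

def laterality_analysis(table: pd.DataFrame, alpha: float = 0.05):
    """Group x laterality analysis of size-adjusted cerebellar volumes.

    ``table`` columns: ``specimen, group, icv, left, right`` where left and
    right are the per-specimen volumes of one cerebellar region family,
    already combined over the symmetrized and mirrored atlas variants
    (average of the two parcellations).

    Returns a dict with:

    * ``simple_main_effects``: per group, F test of L != R from the
      within-specimen differences against the pooled difference variance
      (error df N - k);
    * ``between_group``: Ryan pairwise contrasts of each side separately on
      the side-stacked table (error df 2N - 2k);
    * ``interaction``: group x side interaction F from the stacked two-way
      layout.
    """
    req = {"specimen", "group", "icv", "left", "right"}
    if not req <= set(table.columns):
        raise ValueError(f"missing columns: {sorted(req - set(table.columns))}")
    if table[["left", "right"]].isna().any().any():
        raise ValueError("specimen missing one side")
    df = table.copy()
    N = len(df)
    groups = pd.unique(df["group"])
    k = len(groups)
    # size adjustment on the stacked table (one pooled ICV slope)
    stacked = pd.concat(
        [
            df.assign(side="L", volume=df["left"]),
            df.assign(side="R", volume=df["right"]),
        ],
        ignore_index=True,
    )
    stacked["adj"] = icv_adjust(stacked["volume"].to_numpy(),
                                stacked["icv"].to_numpy())
    # simple main effects from within-specimen L-R differences
    adj_l = stacked.loc[stacked.side == "L", "adj"].to_numpy()
    adj_r = stacked.loc[stacked.side == "R", "adj"].to_numpy()
    diff = adj_l - adj_r
    glab = df["group"].to_numpy()
    ss_within = sum(
        ((diff[glab == g] - diff[glab == g].mean()) ** 2).sum() for g in groups
    )
    df_err = N - k
    var_d = ss_within / df_err
    simple = {}
    for g in groups:
        dg = diff[glab == g]
        F = len(dg) * dg.mean() ** 2 / var_d if var_d > 0 else 0.0
        p = float(stats.f.sf(F, 1, df_err))
        simple[g] = GroupTestResult(
            effect=f"laterality within {g}", statistic=float(F),
            df=(1, df_err), p=p, significant=p < alpha, alpha_nominal=alpha,
            procedure="simple main effect (paired differences)",
        )
    # between-group contrasts per side on the stacked table, df 2N - 2k
    between = {}
    for side in ("L", "R"):
        sub = stacked[stacked.side == side]
        res = anova_ryan(sub["adj"].to_numpy(), sub["group"].to_numpy(),
                         alpha=alpha, effect=f"side {side}")
        # Ryan t tests against the stacked-table error variance, df 2N-2k
        cell_resid = stacked.groupby(["group", "side"])["adj"].transform(
            lambda s: s - s.mean()
        )
        mse_full = float((cell_resid ** 2).sum() / (2 * N - 2 * k))
        adj_res = []
        for r in res:
            if r.procedure.startswith("Ryan"):
                a, b = r.effect.split(":")[1].split(" vs ")
                na = int((sub["group"] == a).sum())
                nb = int((sub["group"] == b).sum())
                se = np.sqrt(mse_full * (1.0 / na + 1.0 / nb))
                ma = sub.loc[sub["group"] == a, "adj"].mean()
                mb = sub.loc[sub["group"] == b, "adj"].mean()
                t = (ma - mb) / se if se > 0 else 0.0
                pr = 2.0 * float(stats.t.sf(abs(t), 2 * N - 2 * k))
                adj_res.append(
                    GroupTestResult(
                        effect=r.effect, statistic=float(t),
                        df=(1, 2 * N - 2 * k), p=pr,
                        significant=pr < r.alpha_nominal,
                        alpha_nominal=r.alpha_nominal,
                        procedure="Ryan pairwise t (stacked)",
                    )
                )
            else:
                adj_res.append(r)
        between[side] = adj_res
    # interaction from the stacked two-way layout
    grand = stacked["adj"].mean()
    cell = stacked.groupby(["group", "side"])["adj"].mean()
    gmean = stacked.groupby("group")["adj"].mean()
    smean = stacked.groupby("side")["adj"].mean()
    ss_int = 0.0
    for (g, s), m in cell.items():
        ncell = int(((stacked["group"] == g) & (stacked["side"] == s)).sum())
        ss_int += ncell * (m - gmean[g] - smean[s] + grand) ** 2
    cell_resid = stacked.groupby(["group", "side"])["adj"].transform(
        lambda s: s - s.mean()
    )
    mse_full = float((cell_resid ** 2).sum() / (2 * N - 2 * k))
    if k > 1 and mse_full > 0:
        F_int = (ss_int / (k - 1)) / mse_full
        p_int = float(stats.f.sf(F_int, k - 1, 2 * N - 2 * k))
    else:
        F_int, p_int = np.nan, np.nan
    interaction = GroupTestResult(
        effect="group x laterality", statistic=float(F_int),
        df=(k - 1, 2 * N - 2 * k), p=p_int, significant=p_int < alpha,
        alpha_nominal=alpha, procedure="two-way ANOVA interaction",
    )
    return {"simple_main_effects": simple, "between_group": between,
            "interaction": interaction}


def combine_atlas_variant_volumes(sym: pd.DataFrame, mir: pd.DataFrame,
                                  on=("specimen",)) -> pd.DataFrame:
    """Average per-region volumes from the symmetrized and mirrored atlas
    parcellations (numeric columns averaged, keys preserved)."""
    on = list(on)
    merged = sym.merge(mir, on=on, suffixes=("_sym", "_mir"))
    out = merged[on].copy()
    for c in sym.columns:
        if c in on:
            continue
        if np.issubdtype(sym[c].dtype, np.number):
            out[c] = (merged[f"{c}_sym"] + merged[f"{c}_mir"]) / 2.0
        else:
            out[c] = merged[f"{c}_sym"]
    return out


def build_symmetrized_atlas(endocasts, atlas_labels, atlas_table,
                            cfg=None, n_outer: int = 2, fwhm: float = 2.0):
    """Symmetrized atlas via a template from originals plus x-flipped copies.

    ``endocasts``: list of binary endocast ScalarVolumes in a common frame
    whose first axis is left-right; the mirror plane is the grid centre
    plane of axis 0 (for even dimensions this is the half-voxel plane
    between the two middle slices, so ``labels[::-1]`` realizes the flip).
    Returns ``(symmetrized LabelVolume, mirrored LabelVolume, template)``.
    The mirrored variant is the x-flip of the symmetrized labels with L/R
    region ids swapped according to the table.
    """
    from .diffeo_registration import RegistrationConfig, build_template, exp_velocity, register, smooth_mask, warp
    from .imaging_core import LabelVolume, ScalarVolume, VoxelGrid

    cfg = cfg or RegistrationConfig()
    grid = endocasts[0].grid
    images = []
    for e in endocasts:
        sm = smooth_mask(e, fwhm)
        images.append(sm)
        images.append(ScalarVolume(grid, sm.values[::-1, :, :].copy()))
    template, _vels, _mp, _res = build_template(images, cfg, n_outer=n_outer)
    # warp the atlas from its native (canonical) frame onto the symmetric
    # template: register template <- canonical endocast, pull labels back
    # with the inverse
    canon = images[0]
    v, _d = register(template, canon, cfg)
    # exp(v) maps template voxels to canonical coordinates, so it pulls the
    # canonical-frame atlas onto the symmetric template directly
    phi = exp_velocity(v, cfg.squaring_steps)
    sym_labels = warp(atlas_labels, phi, mode="nearest")
    # mirrored: x-flip + L/R id swap
    swap = {}
    info = atlas_table.set_index(atlas_table.region_id.astype(int))
    for rid in info.index:
        row = info.loc[rid]
        if row.hemisphere in ("L", "R"):
            other = info[(info.lobe_group == row.lobe_group)
                         & (info.hemisphere == ("R" if row.hemisphere == "L" else "L"))]
            swap[rid] = int(other.region_id.iloc[0])
        else:
            swap[rid] = rid
    flipped = sym_labels.labels[::-1, :, :].copy()
    mirrored = np.zeros_like(flipped)
    for rid, new in swap.items():
        mirrored[flipped == rid] = new
    return sym_labels, LabelVolume(grid, mirrored), template


# ---------------------------------------------------------------------------
# cognition regression

def cognition_regression(table: pd.DataFrame, tasks: list[str] | None = None,
                         volume_col: str = "regional_volume_cc",
                         alpha: float = 0.05,
                         response: str = "volume") -> pd.DataFrame:
    """Per-task confound-adjusted regression with Bonferroni over tasks.

    Default direction follows the published analysis: for each task fit
    ``volume ~ intercept + score + ICV + age + sex`` (5 parameters, slope t
    with df n - 5) and flag tasks passing the ``alpha / n_tasks`` threshold.
    ``response='score'`` fits ``score ~ volume + ICV + age + sex`` instead —
    the slope of that direction estimates the generative score-per-volume
    coefficient directly (the t statistic and p are identical either way,
    both being the partial-correlation test).
    """
    import statsmodels.api as sm

    tasks = tasks or table.attrs.get("tasks")
    if tasks is None:
        raise ValueError("task column names required")
    need = set(tasks) | {volume_col, "icv_cc", "age", "sex"}
    if not need <= set(table.columns):
        raise ValueError(f"missing columns: {sorted(need - set(table.columns))}")
    n = len(table)
    if n <= 5:
        raise ValueError("need n > 5")
    m = len(tasks)
    conf = table[["icv_cc", "age", "sex"]].to_numpy(dtype=float)
    vol = table[volume_col].to_numpy(dtype=float)
    rows = []
    for t in tasks:
        score = table[t].to_numpy(dtype=float)
        if response == "volume":
            X = sm.add_constant(np.column_stack([score, conf]))
            y = vol
        elif response == "score":
            X = sm.add_constant(np.column_stack([vol, conf]))
            y = score
        else:
            raise ValueError("response must be 'volume' or 'score'")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design for task {t!r}")
        fit = sm.OLS(y, X).fit()
        rows.append(
            dict(task=t, slope=float(fit.params[1]), se=float(fit.bse[1]),
                 t=float(fit.tvalues[1]), df=int(fit.df_resid),
                 p=float(fit.pvalues[1]),
                 significant=bool(fit.pvalues[1] < alpha / m),
                 alpha_nominal=alpha / m)
        )
    return pd.DataFrame(rows)
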