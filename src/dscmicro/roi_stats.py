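"""Lesion segmentation, ROI extraction/normalization, longitudinal rates,
age matching, outlier screening, and the cohort-level statistical battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage import measure

DAYS_PER_MONTH = 30.44


# ---------------------------------------------------------------------------
# segmentation and ROIs
# ---------------------------------------------------------------------------

def segment_lesion(
    t2w_map: np.ndarray,
    threshold: float,
    *,
    min_component: int = 1,
    voxel_volume: float = 8.0,
    seed_region: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Threshold-based lesion segmentation on a T2-weighted-like map.

    Voxels above ``threshold`` are labelled, connected components smaller
    than ``min_component`` voxels are dropped, and when ``seed_region`` is
    given only components intersecting it are kept (stand-in for the
    manual highlighting step of semi-automated protocols).  Returns the
    binary mask and the lesion volume in mL (voxel_volume in mm^3).  A
    threshold above the global maximum yields an empty mask and volume 0.
    """
    t2w_map = np.asarray(t2w_map, dtype=float)
    if not np.all(np.isfinite(t2w_map)):
        raise ValueError("map contains non-finite values")
    binary = t2w_map > threshold
    labels = measure.label(binary)
    mask = np.zeros_like(binary)
    for region in measure.regionprops(labels):
        if region.num_pixels < min_component:
            continue
        comp = labels == region.label
        if seed_region is not None and not np.any(comp & seed_region):
            continue
        mask |= comp
    volume_ml = float(mask.sum()) * voxel_volume / 1000.0
    return mask, volume_ml


@dataclass
class ROISpec:
    """Named region of interest: an explicit mask, or a cuboid given by a
    center voxel and a size in perfusion-map voxels.  Bilateral ROIs carry
    two masks that are pooled voxel-wise before averaging."""

    name: str
    mask: np.ndarray | None = None
    center: tuple[int, int, int] | None = None
    size: int | None = None
    mask_contralateral: np.ndarray | None = None

    def resolve(self, shape: tuple[int, ...]) -> np.ndarray:
        if self.mask is not None:
            m = self.mask.astype(bool)
            if self.mask_contralateral is not None:
                m = m | self.mask_contralateral.astype(bool)
            if m.shape != shape:
                raise ValueError(f"ROI {self.name!r}: mask shape mismatch")
            return m
        if self.center is None or self.size is None:
            raise ValueError(f"ROI {self.name!r}: need mask or center+size")
        # cuboid of `size` voxels around the center, greedy in x then y
        nx = int(np.ceil(self.size ** (1 / 3)))
        half = nx // 2
        m = np.zeros(shape, dtype=bool)
        cx, cy, cz = self.center
        count = 0
        for dz in range(-half, half + 2):
            for dy in range(-half, half + 2):
                for dx in range(-half, half + 2):
                    if count >= self.size:
                        return m
                    x, y, z = cx + dx, cy + dy, cz + dz
                    if not (0 <= x < shape[0] and 0 <= y < shape[1]
                            and 0 <= z < shape[2]):
                        raise ValueError(f"ROI {self.name!r} out of bounds")
                    m[x, y, z] = True
                    count += 1
        return m


@dataclass
class ROIResult:
    roi: str
    map_name: str
    mean: float
    sd: float
    n_voxels: int
    relative: float | None = None


def extract_roi_stats(
    maps: dict[str, np.ndarray],
    rois: list[ROISpec],
) -> list[ROIResult]:
    """Mean/SD/count per ROI per map, NaN voxels excluded."""
    results = []
    for roi in rois:
        for map_name, vol in maps.items():
            m = roi.resolve(vol.shape)
            vals = vol[m]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"ROI {roi.name!r} is empty on map {map_name!r}")
            results.append(ROIResult(
                roi=roi.name, map_name=map_name,
                mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                n_voxels=int(vals.size),
            ))
    return results


def normalize_to_reference(
    value: ROIResult, reference: list[ROIResult]
) -> float:
    """Relative ROI value: ROI mean divided by the reference summary.

    The summary is the mean of the (nine) reference-ROI means on the same
    map; normalizing the reference ROIs against themselves therefore
    averages exactly 1.
    """
    ref_means = [r.mean for r in reference if r.map_name == value.map_name]
    if not ref_means:
        raise ValueError("no reference ROI on the same map")
    summary = float(np.mean(ref_means))
    if summary <= 0:
        raise ValueError("reference summary must be positive")
    rel = value.mean / summary
    value.relative = rel
    return rel


# ---------------------------------------------------------------------------
# longitudinal rates
# ---------------------------------------------------------------------------

def monthly_relative_change(
    days: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Per-interval relative change rates in percent per month.

    For consecutive visits (t1, v1), (t2, v2):
    rate = 100 * (v2 - v1) / (v1 * (t2 - t1) / 30.44) %/month.  Unit-free
    in the underlying value.  Duplicate visit days or nonpositive baseline
    values are errors.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size != values.size or days.size < 2:
        raise ValueError("need at least two (day, value) pairs")
    if np.any(np.diff(days) <= 0):
        raise ValueError("visit days must be strictly increasing (no duplicates)")
    if np.any(values[:-1] <= 0):
        raise ValueError("nonpositive baseline value in series")
    dv = np.diff(values)
    months = np.diff(days) / DAYS_PER_MONTH
    return 100.0 * dv / (values[:-1] * months)


# ---------------------------------------------------------------------------
# matching and screening
# ---------------------------------------------------------------------------

def match_by_age(
    case_ages: np.ndarray, control_ages: np.ndarray
) -> tuple[list[tuple[int, int]], float, float]:
    """Optimal 1:1 age matching of cases to controls.

    Solves the assignment problem minimizing the total absolute age
    difference (the "optimal" nearest-neighbour matching method).
    Returns (case_index, control_index) pairs plus the mean and SD of the
    signed age differences (control - case).
    """
    case_ages = np.asarray(case_ages, dtype=float)
    control_ages = np.asarray(control_ages, dtype=float)
    if case_ages.size == 0:
        raise ValueError("empty case list")
    if control_ages.size < case_ages.size:
        raise ValueError("need at least as many controls as cases")
    cost = np.abs(case_ages[:, None] - control_ages[None, :])
    rows, cols = optimize.linear_sum_assignment(cost)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    diffs = control_ages[cols] - case_ages[rows]
    return pairs, float(diffs.mean()), float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size n at level alpha."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_outliers(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iterative two-sided Grubbs outlier screen.

    Repeatedly tests the most extreme value; while the Grubbs statistic
    G = max|x - mean| / sd exceeds the critical value at ``alpha``, the
    value is removed (at most until 3 values remain).  Returns the kept
    values and the indices (into the original array) of removed values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    keep = np.arange(values.size)
    removed: list[int] = []
    while keep.size >= 3:
        x = values[keep]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical(keep.size, alpha):
            removed.append(int(keep[i]))
            keep = np.delete(keep, i)
        else:
            break
    return values[keep], removed


def hedges_g(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Hedges' g: pooled-SD standardized mean difference with the
    small-sample bias correction J = 1 - 3/(4(na+nb) - 9).

    Returns NaN when the pooled SD is zero and the means differ (the
    effect size is undefined); 0 for identical groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 observations")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0:
        return 0.0 if diff == 0 else float("nan")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * diff / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# statistical battery
# ---------------------------------------------------------------------------

@dataclass
class StatsResult:
    name: str
    test: str
    estimate: float
    statistic: float
    dof: float
    p_value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    note: str = ""


def welch_anova(groups: list[np.ndarray]) -> StatsResult:
    """Welch's heteroscedastic one-way ANOVA (unequal variances)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    if np.any(n < 2):
        raise ValueError("every group needs at least 2 observations")
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    f_num = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    f_den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f = f_num / f_den
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return StatsResult(name="welch_anova", test="Welch ANOVA",
                       estimate=float(mw), statistic=float(f),
                       dof=float(df2), p_value=p)


def dunnett_vs_control(
    groups: list[np.ndarray], control: np.ndarray, names: list[str] | None = None
) -> list[StatsResult]:
    """Dunnett's many-to-one comparisons against the control group."""
    res = stats.dunnett(*[np.asarray(g, float) for g in groups],
                        control=np.asarray(control, float))
    ci = res.confidence_interval()
    out = []
    for i, g in enumerate(groups):
        nm = names[i] if names else f"group{i}"
        out.append(StatsResult(
            name=f"dunnett:{nm}", test="Dunnett vs control",
            estimate=float(np.mean(g) - np.mean(control)),
            statistic=float(res.statistic[i]), dof=float("nan"),
            p_value=float(res.pvalue[i]),
            ci_low=float(ci.low[i]), ci_high=float(ci.high[i]),
        ))
    return out


def t_test(
    a: np.ndarray, b: np.ndarray, *, paired: bool = False,
    equal_var: bool = False, name: str = "t_test",
) -> StatsResult:
    """Two-tailed t test (Welch by default for unpaired comparisons)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        r = stats.ttest_rel(a, b)
    else:
        r = stats.ttest_ind(a, b, equal_var=equal_var)
    return StatsResult(name=name, test="paired t" if paired else
                       ("Student t" if equal_var else "Welch t"),
                       estimate=float(a.mean() - b.mean()),
                       statistic=float(r.statistic), dof=float(r.df),
                       p_value=float(r.pvalue))


def linear_regression(x: np.ndarray, y: np.ndarray, name: str = "ols") -> StatsResult:
    """Simple linear regression y ~ x (slope inference)."""
    r = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    n = np.asarray(x).size
    tcrit = stats.t.ppf(0.975, n - 2)
    return StatsResult(name=name, test="simple linear regression",
                       estimate=float(r.slope),
                       statistic=float(r.slope / r.stderr) if r.stderr > 0 else float("inf"),
                       dof=float(n - 2), p_value=float(r.pvalue),
                       ci_low=float(r.slope - tcrit * r.stderr),
                       ci_high=float(r.slope + tcrit * r.stderr))


def logistic_regression(
    x: np.ndarray, y: np.ndarray, name: str = "logit"
) -> StatsResult:
    """Binary logistic regression of outcome y on predictor x.

    Reports the odds ratio per unit x with Wald CI, the likelihood-ratio
    chi-square p value and McFadden pseudo-R^2 in the note.  Perfect
    separation is flagged in the note rather than raising.
    """
    import statsmodels.api as sm

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    design = sm.add_constant(x)
    note = ""
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            note = "separation or non-convergence flagged"
    except Exception:
        return StatsResult(name=name, test="logistic regression",
                           estimate=float("nan"), statistic=float("nan"),
                           dof=1.0, p_value=float("nan"),
                           note="separation: model not estimable")
    beta = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(se) or se > 1e3:
        note = note or "separation suspected (unstable SE)"
    orr = float(np.exp(beta))
    pseudo_r2 = float(fit.prsquared)
    return StatsResult(
        name=name, test="logistic regression", estimate=orr,
        statistic=float(fit.llr), dof=float(fit.df_model),
        p_value=float(fit.llr_pvalue),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        note=note or f"pseudo_r2={pseudo_r2:.4f}",
    )


def run_group_comparisons(
    cohort: pd.DataFrame, plan: list[dict]
) -> pd.DataFrame:
    """Execute a named-contrast analysis plan on a cohort table.

    Each plan entry is a dict with a ``test`` key choosing from
    ``welch_anova`` / ``dunnett`` / ``t`` / ``paired_t`` / ``pearson`` /
    ``ols`` / ``logit`` / ``mixed``, plus ``metric`` (column name),
    grouping keys and a ``name``.  Returns one row per result.  Contrasts naming fewer than
    two groups are an error.
    """
    results: list[StatsResult] = []
    for item in plan:
        test = item["test"]
        metric = item["metric"]
        name = item.get("name", f"{test}:{metric}")
        if metric not in cohort.columns:
            raise KeyError(f"plan references unknown column {metric!r}")

        def group_values(gname, day=None):
            sel = cohort["group"] == gname
            if day is not None:
                sel &= cohort["visit_day"] == day
            return cohort.loc[sel, metric].dropna().to_numpy()

        if test in ("welch_anova", "dunnett"):
            gnames = item["groups"]
            if len(gnames) < 2:
                raise ValueError(f"contrast {name!r} needs >= 2 groups")
            day = item.get("visit_day")
            groups = [group_values(g, day) for g in gnames]
            if test == "welch_anova":
                r = welch_anova(groups)
                r.name = name
                results.append(r)
            else:
                control = groups[0]
                results.extend(dunnett_vs_control(groups[1:], control,
                                                  names=gnames[1:]))
        elif test in ("t", "paired_t"):
            ga, gb = item["groups"]
            day_a = item.get("visit_day_a")
            day_b = item.get("visit_day_b")
            a = group_values(ga, day_a)
            b = group_values(gb, day_b)
            results.append(t_test(a, b, paired=(test == "paired_t"), name=name))
        elif test == "pearson":
            sub = cohort.dropna(subset=[item["x"], metric])
            r = stats.pearsonr(sub[item["x"]], sub[metric])
            results.append(StatsResult(
                name=name, test="Pearson correlation",
                estimate=float(r.statistic), statistic=float(r.statistic),
                dof=float(len(sub) - 2), p_value=float(r.pvalue)))
        elif test == "ols":
            sub = cohort.dropna(subset=[item["x"], metric])
            r = linear_regression(sub[item["x"]], sub[metric], name=name)
            results.append(r)
        elif test == "logit":
            sub = cohort.dropna(subset=[item["x"], metric])
            results.append(logistic_regression(sub[item["x"]], sub[metric],
                                               name=name))
        elif test == "mixed":
            # repeated measures with missing data: treatment (or time) as
            # fixed effect, subject as random intercept
            import statsmodels.formula.api as smf

            fixed = item.get("fixed", "visit_day")
            sub = cohort.dropna(subset=[metric, fixed]).copy()
            fit = smf.mixedlm(f"{metric} ~ {fixed}", sub,
                              groups=sub["subject"]).fit(reml=True)
            results.append(StatsResult(
                name=name, test="linear mixed effects",
                estimate=float(fit.params[fixed]),
                statistic=float(fit.tvalues[fixed]), dof=float("nan"),
                p_value=float(fit.pvalues[fixed]),
                note="delegated to statsmodels MixedLM "
                     "(random intercept per subject)"))
        else:
            raise ValueError(f"unknown test {test!r} in plan")
    return pd.DataFrame([vars(r) for r in results])
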