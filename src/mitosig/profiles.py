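"""Depth-resolved beta profiles and cohort statistics.

A z-stack of en-face NADH images yields one clustering exponent per slice;
assembled against depth these trace the epidermal metabolic gradient
(high beta in basal/parabasal layers, a minimum in the spinous layer,
recovery toward the stratum corneum in healthy skin).  Each stack is
summarised by its median beta and beta variability (IQR of per-slice beta
by default; SD optionally), and cohorts of stacks are compared between
conditions with a linear mixed model carrying random intercepts for
patient and imaging site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from mitosig.clustering import BetaConfig, BetaEstimate, image_beta
from mitosig.synthetic.images import ImageStack

__all__ = [
    "DepthProfile",
    "GroupComparison",
    "stack_profile",
    "locate_profile_minimum",
    "compare_conditions",
    "compare_metric_frame",
    "longitudinal_compare",
    "profiles_frame",
]

ALPHA = 0.05
_MIN_OK_SLICES = 5


@dataclass
class DepthProfile:
    """Per-slice beta versus depth for one stack, with smoothed curve.

    Depth is measured from the first analysed slice (slice_index * z_step,
    in um).  ``median_beta`` and ``beta_variability`` are computed over
    ok-status slices only; when fewer than five slices fit cleanly the
    profile is flagged incomplete and summaries are withheld (NaN).
    """

    depth_um: np.ndarray
    beta_per_slice: list[BetaEstimate]
    smooth_depth: np.ndarray
    smooth_beta: np.ndarray
    median_beta: float
    beta_variability: float
    complete: bool
    stack_meta: dict = field(default_factory=dict)

    @property
    def ok_mask(self) -> np.ndarray:
        return np.array([b.ok for b in self.beta_per_slice])

    @property
    def betas(self) -> np.ndarray:
        return np.array([b.beta for b in self.beta_per_slice])


@dataclass
class GroupComparison:
    """Result of a two-group comparison of a stack-level metric."""

    metric: str
    estimate: float
    se: float
    p_value: float
    model: str  # "mixed" or "t_test"
    n_per_group: dict[str, int]
    alpha: float = ALPHA
    converged: bool = True
    note: str = ""


def _variability(vals: np.ndarray, kind: str) -> float:
    if kind == "iqr":
        q1, q3 = np.percentile(vals, [25, 75])
        return float(q3 - q1)
    if kind == "sd":
        return float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    raise ValueError(f"unknown variability metric {kind!r}")


def stack_profile(
    stack: ImageStack,
    config: Optional[BetaConfig] = None,
    *,
    variability: str = "iqr",
    smoothing_lam: Optional[float] = None,
    grid_points: int = 101,
) -> DepthProfile:
    """Fit beta per slice and assemble the depth profile for one stack.

    The smooth curve is a cubic smoothing spline with the penalty chosen by
    generalized cross-validation (override via ``smoothing_lam``).  Slices
    whose fit fails are recorded but excluded from the spline and the
    summary metrics.
    """
    cfg = config or BetaConfig()
    estimates = [
        image_beta(
            stack.data[i],
            stack.pixel_size,
            config=cfg,
            source_id=f"{stack.stack_id}_z{i}",
        )
        for i in range(stack.n_slices)
    ]
    depths = stack.depths_um
    ok = np.array([e.ok for e in estimates])
    betas = np.array([e.beta for e in estimates])
    complete = int(ok.sum()) >= _MIN_OK_SLICES
    if complete:
        x, y = depths[ok], betas[ok]
        grid = np.linspace(x[0], x[-1], grid_points)
        try:
            spline = make_smoothing_spline(x, y, lam=smoothing_lam)
            smooth = spline(grid)
        except Exception:  # near-singular GCV; fall back to interpolation
            smooth = np.interp(grid, x, y)
        median_beta = float(np.median(y))
        beta_var = _variability(y, variability)
    else:
        grid = np.array([])
        smooth = np.array([])
        median_beta = float("nan")
        beta_var = float("nan")
    return DepthProfile(
        depth_um=depths,
        beta_per_slice=estimates,
        smooth_depth=grid,
        smooth_beta=smooth,
        median_beta=median_beta,
        beta_variability=beta_var,
        complete=complete,
        stack_meta=stack.meta(),
    )


def locate_profile_minimum(profile: DepthProfile) -> float:
    """Depth (um) of the smoothed curve's minimum; ties go shallower."""
    if not profile.complete:
        raise ValueError("profile is incomplete; minimum undefined")
    return float(profile.smooth_depth[int(np.argmin(profile.smooth_beta))])


def profiles_frame(profiles: Iterable[DepthProfile]) -> pd.DataFrame:
    """Tidy stack-level metric table from a collection of profiles."""
    rows = []
    for p in profiles:
        row = dict(p.stack_meta)
        row["median_beta"] = p.median_beta
        row["beta_variability"] = p.beta_variability
        row["complete"] = p.complete
        rows.append(row)
    return pd.DataFrame(rows)


def _ttest(df: pd.DataFrame, metric: str, groups: tuple[str, str]) -> GroupComparison:
    a = df.loc[df["condition"] == groups[0], metric].to_numpy()
    b = df.loc[df["condition"] == groups[1], metric].to_numpy()
    t = stats.ttest_ind(b, a, equal_var=True)
    diff = float(b.mean() - a.mean())
    n1, n2 = len(a), len(b)
    pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    se = float(pooled * np.sqrt(1 / n1 + 1 / n2))
    return GroupComparison(
        metric=metric,
        estimate=diff,
        se=se,
        p_value=float(t.pvalue),
        model="t_test",
        n_per_group={groups[0]: n1, groups[1]: n2},
    )


def _at_zero_boundary(model, fit, tol: float = 1e-2) -> bool:
    """True when the zero-variance boundary attains the REML optimum.

    The profiled REML log-likelihood is evaluated at (numerically) zero
    variance components; if it comes within ``tol`` of the fitted optimum
    the likelihood is flat against the boundary and the mixed model has
    degenerated to OLS.
    """
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    try:
        eps = 1e-8
        k_re = fit.cov_re.shape[0] if fit.cov_re.size else 0
        zero = MixedLMParams.from_components(
            fe_params=np.asarray(fit.fe_params),
            cov_re=np.eye(max(k_re, 1)) * eps,
            vcomp=np.full(len(fit.vcomp), eps),
        )
        ll0 = model.loglike(zero, profile_fe=True)
    except np.linalg.LinAlgError:
        return False
    return bool(ll0 >= fit.llf - tol)


def _mixed(df: pd.DataFrame, metric: str, groups: tuple[str, str]) -> GroupComparison:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.copy()
    data["condition"] = pd.Categorical(
        data["condition"], categories=list(groups), ordered=True
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            f"{metric} ~ condition",
            data,
            groups="patient",
            re_formula="1",
            vc_formula={"site": "0 + C(site)"},
        )
        fit = model.fit(reml=True)
    coef_name = f"condition[T.{groups[1]}]"
    est = float(fit.fe_params[coef_name])
    se = float(fit.bse_fe[coef_name])
    n = len(data)
    dof = n - 2
    # When the REML likelihood at the zero-variance boundary matches the
    # fitted optimum, the model degenerates to ordinary least squares and
    # the Wald t equals the pooled two-sample t; inference then uses that
    # exact limit instead of a near-singular covariance fit.
    if _at_zero_boundary(model, fit):
        res = _ttest(df, metric, groups)
        res.model = "mixed"
        res.note = "variance components at zero boundary; OLS/t inference"
        return res
    tstat = est / se
    p = float(2 * stats.t.sf(abs(tstat), dof))
    counts = data["condition"].value_counts().to_dict()
    return GroupComparison(
        metric=metric,
        estimate=est,
        se=se,
        p_value=p,
        model="mixed",
        n_per_group={g: int(counts.get(g, 0)) for g in groups},
        converged=bool(fit.converged),
    )


def compare_metric_frame(
    df: pd.DataFrame,
    metric: str = "median_beta",
    model: str = "mixed",
    groups: tuple[str, str] = ("nonlesional", "lesional"),
) -> GroupComparison:
    """Compare a stack-level metric between two conditions.

    ``model="mixed"`` fits ``metric ~ condition`` with random intercepts
    for patient and site (REML) and tests the condition coefficient with a
    Wald t statistic on residual degrees of freedom; ``model="t_test"``
    runs a pooled two-sample two-tailed t test on the stack-level values.
    The mixed model falls back to the t test (with a note) when a group has
    a single patient or the fit fails.
    """
    required = {metric, "condition", "patient", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = df.dropna(subset=[metric])
    for g in groups:
        if (df["condition"] == g).sum() < 2:
            raise ValueError(f"need >= 2 stacks in group {g!r}")
    if model == "t_test":
        return _ttest(df, metric, groups)
    if model != "mixed":
        raise ValueError(f"unknown model {model!r}")
    for g in groups:
        if df.loc[df["condition"] == g, "patient"].nunique() < 2:
            res = _ttest(df, metric, groups)
            res.note = f"single patient in group {g!r}; fell back to t_test"
            warnings.warn(res.note)
            return res
    try:
        return _mixed(df, metric, groups)
    except Exception as exc:  # singular fits on degenerate designs
        res = _ttest(df, metric, groups)
        res.converged = False
        res.note = f"mixed model failed ({exc}); fell back to t_test"
        return res


def compare_conditions(
    profiles: Iterable[DepthProfile],
    metric: str = "median_beta",
    model: str = "mixed",
    groups: tuple[str, str] = ("nonlesional", "lesional"),
) -> GroupComparison:
    """Compare complete stack profiles between two conditions."""
    df = profiles_frame(profiles)
    df = df[df["complete"]]
    return compare_metric_frame(df, metric=metric, model=model, groups=groups)


def longitudinal_compare(
    followup: Sequence[DepthProfile],
    reference: Sequence[DepthProfile],
    baseline: Optional[Sequence[DepthProfile]] = None,
    model: str = "t_test",
    alpha: float = ALPHA,
) -> dict:
    """Label treated follow-up skin "normalized" or "persistent".

    Follow-up lesional profiles are compared against the nonlesional
    reference for both summary metrics; when neither median beta nor beta
    variability differs at ``alpha`` the follow-up is labelled
    ``"normalized"``, otherwise ``"persistent"``.  If ``baseline`` is
    given, follow-up patient ids must be a subset of baseline patient ids.
    """
    if baseline is not None:
        base_pat = {p.stack_meta.get("patient") for p in baseline}
        fu_pat = {p.stack_meta.get("patient") for p in followup}
        unmatched = sorted(fu_pat - base_pat)
        if unmatched:
            raise ValueError(f"follow-up patients missing at baseline: {unmatched}")
    df_f = profiles_frame(followup)
    df_r = profiles_frame(reference)
    df_f = df_f[df_f["complete"]].assign(condition="followup")
    df_r = df_r[df_r["complete"]].assign(condition="reference")
    df = pd.concat([df_f, df_r], ignore_index=True)
    comparisons = {}
    for metric in ("median_beta", "beta_variability"):
        comparisons[metric] = compare_metric_frame(
            df, metric=metric, model=model, groups=("reference", "followup")
        )
    normalized = all(c.p_value >= alpha for c in comparisons.values())
    return {
        "label": "normalized" if normalized else "persistent",
        "comparisons": comparisons,
        "alpha": alpha,
    }
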