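"""Mixed-effects comparison of conduction velocity and voltage.

The per-circle measurements are repeated, unbalanced observations from a
small number of animals, so chamber and wall comparisons use a linear
mixed-effects model: mapping location and heart rate as fixed effects
(no interaction) and a random intercept per animal to absorb
inter-individual variation.  Velocity is log-transformed (natural log)
to normalise its right-skewed distribution; post-hoc results are
back-transformed, so velocity contrasts are ratios while voltage
contrasts stay additive differences in mV.

Group means are reported as estimated marginal means (EMMs) at a
reference heart rate of 90 bpm.  All-pairs contrasts are adjusted by
Tukey's studentized-range criterion, targeted subsets by Sidak.

Degrees of freedom
------------------
REML fits come from :class:`statsmodels.regression.mixed_linear_model.MixedLM`,
which does not provide Satterthwaite denominator df.  The default here
is a containment/between-within partition: coefficients of covariates
that are constant within each animal (e.g. sex, and the intercept) are
tested against animal-level df, everything that varies within animals
against residual df.  A plain normal approximation is available via
``df_method="normal"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

REFERENCE_HEART_RATE = 90.0  # bpm
NO_CORRELATION_BAND = 0.2    # |r| below this is read as "no linear correlation"


class IdentifiabilityError(ValueError):
    """The design cannot support the requested model."""


@dataclass
class MixedModelResult:
    """A fitted mixed model plus everything needed for EMMs/contrasts."""

    response: str                 # "log_cv" or "va"
    location: str                 # grouping column, e.g. "chamber"
    levels: list[str]
    params: pd.Series
    cov_params: pd.DataFrame
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_groups: int
    rank: int
    df_within: float
    df_between: float
    between_coef: pd.Series       # bool per coefficient: between-animal?
    df_method: str
    converged: bool
    singular: bool
    heart_rate_range: tuple[float, float]
    design_info: object = field(repr=False, default=None)
    factor_levels: dict = field(default_factory=dict)

    @property
    def is_log_scale(self) -> bool:
        return self.response == "log_cv"

    def coef_df(self, name: str) -> float:
        """Approximate denominator df for one coefficient's test."""
        if self.df_method == "normal":
            return np.inf
        return self.df_between if self.between_coef[name] else self.df_within


def _prepare(data: pd.DataFrame, response: str) -> pd.DataFrame:
    d = data.copy()
    if "valid" in d.columns:
        d = d[d["valid"]]
    if response == "log_cv":
        d = d[np.isfinite(d["cv"])]
        if (d["cv"] <= 0).any():
            raise ValueError("log_cv requires all cv > 0")
        d["_y"] = np.log(d["cv"])
    elif response == "va":
        d = d[np.isfinite(d["va"])]
        d["_y"] = d["va"].astype(float)
    else:
        raise ValueError("response must be 'log_cv' or 'va'")
    return d.reset_index(drop=True)


def fit_mixed_model(
    data: pd.DataFrame,
    response: str,
    location: str = "chamber",
    group: str = "animal_id",
    covariates: tuple = ("heart_rate",),
    extra_factors: tuple = (),
    df_method: str = "between_within",
) -> MixedModelResult:
    """REML fit of ``response ~ location + heart_rate + (1 | animal)``.

    ``data`` is the measurement table (one row per circle); rows flagged
    invalid by the outlier/zero-dt rules never enter the model.
    ``extra_factors`` adds further categorical fixed effects (e.g.
    ``("sex",)``).  Raises :class:`IdentifiabilityError` for a
    rank-deficient design; a fit with (near-)zero random-intercept
    variance is flagged ``singular``, not fatal.
    """
    if df_method not in ("between_within", "normal"):
        raise ValueError(f"unknown df_method {df_method!r}")
    d = _prepare(data, response)
    d = d.dropna(subset=[location, group, *covariates, *extra_factors])
    if len(d) == 0:
        raise ValueError("no usable measurements")
    levels = sorted(d[location].astype(str).unique())
    d[location] = pd.Categorical(d[location].astype(str), categories=levels)
    factor_levels = {location: levels}
    terms = [f"C({location})"] + [f"C({f})" for f in extra_factors] + list(covariates)
    for f in extra_factors:
        lv = sorted(d[f].astype(str).unique())
        d[f] = pd.Categorical(d[f].astype(str), categories=lv)
        factor_levels[f] = lv
    formula = "_y ~ " + " + ".join(terms)

    model = MixedLM.from_formula(formula, groups=group, data=d)
    exog = np.asarray(model.exog)
    p = exog.shape[1]
    if np.linalg.matrix_rank(exog) < p:
        raise IdentifiabilityError("fixed-effects design matrix is rank deficient")

    fit = _fit_robust(model)
    converged = bool(getattr(fit, "converged", True))

    resid_var = float(fit.scale)
    re_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    groups = d[group].to_numpy()
    n_groups = len(np.unique(groups))
    singular = (n_groups < 2) or (re_var <= 1e-8 * max(resid_var, 1e-12))

    names = list(model.exog_names)
    between = pd.Series(
        [_is_between(exog[:, j], groups) for j in range(p)], index=names
    )
    q_between = int(between.sum())
    df_between = max(n_groups - q_between, 1.0)
    df_within = max(len(d) - p - (n_groups - 1), 1.0)

    params = fit.fe_params.copy()
    covm = np.asarray(fit.cov_params())[:p, :p]
    covm = (covm + covm.T) / 2.0
    # degenerate (noise-free or boundary) fits can leave tiny negative
    # or non-finite entries; a perfect fit has zero sampling variance
    covm = np.where(np.isfinite(covm), covm, 0.0)
    np.fill_diagonal(covm, np.maximum(np.diag(covm), 0.0))
    cov = pd.DataFrame(covm, index=names, columns=names)
    hr = d["heart_rate"].to_numpy(float) if "heart_rate" in d else np.array([np.nan])
    return MixedModelResult(
        response=response,
        location=location,
        levels=levels,
        params=params,
        cov_params=cov,
        random_intercept_var=re_var,
        residual_var=resid_var,
        n_obs=len(d),
        n_groups=n_groups,
        rank=p,
        df_within=df_within,
        df_between=df_between,
        between_coef=between,
        df_method=df_method,
        converged=converged,
        singular=singular,
        heart_rate_range=(float(np.nanmin(hr)), float(np.nanmax(hr))),
        design_info=model.data.design_info,
        factor_levels=factor_levels,
    )


def _fit_robust(model: MixedLM):
    """REML fit with optimizer fallbacks.

    Gradient-based optimizers can stall at a spurious point when the
    random-intercept variance sits on the zero boundary; when the first
    fit looks degenerate, derivative-free refits are tried and the
    candidate with the best restricted likelihood wins.  Boundary fits
    themselves are legitimate (flagged ``singular`` downstream), so
    warnings are silenced here rather than surfaced per fit.
    """
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            candidates.append(model.fit(reml=True))
        except Exception:
            pass

        def suspect(f):
            re0 = float(np.asarray(f.cov_re).ravel()[0]) if f.cov_re.size else 0.0
            return (
                not np.all(np.isfinite(np.asarray(f.fe_params)))
                or re0 <= 1e-8 * max(float(f.scale), 1e-12)
                or not getattr(f, "converged", True)
            )

        if not candidates or suspect(candidates[0]):
            for method in ("powell", "cg"):
                try:
                    candidates.append(model.fit(reml=True, method=method))
                except Exception:
                    continue
    candidates = [
        f for f in candidates if np.all(np.isfinite(np.asarray(f.fe_params)))
    ]
    if not candidates:
        raise IdentifiabilityError("mixed-model fit failed with every optimizer")
    return max(candidates, key=lambda f: f.llf if np.isfinite(f.llf) else -np.inf)


def _is_between(col: np.ndarray, groups: np.ndarray) -> bool:
    """True iff a design column is constant within every group."""
    s = pd.Series(col).groupby(pd.Series(groups)).nunique()
    return bool((s <= 1).all())


# ---------------------------------------------------------------------
# Estimated marginal means
# ---------------------------------------------------------------------

def _emm_rows(result: MixedModelResult, heart_rate: float) -> dict[str, np.ndarray]:
    """Design-matrix row (averaged over non-focal factors) per level."""
    rows = {}
    other = {k: v for k, v in result.factor_levels.items() if k != result.location}
    for level in result.levels:
        grid = [{}]
        for fac, lv in other.items():
            grid = [dict(g, **{fac: l}) for g in grid for l in lv]
        mats = []
        for g in grid:
            rec = {result.location: [level], "heart_rate": [heart_rate], **{k: [v] for k, v in g.items()}}
            (X,) = build_design_matrices([result.design_info], pd.DataFrame(rec))
            mats.append(np.asarray(X)[0])
        rows[level] = np.mean(mats, axis=0)
    return rows


def emm_at(result: MixedModelResult, heart_rate: float = REFERENCE_HEART_RATE) -> pd.DataFrame:
    """Estimated marginal means per location at a reference heart rate.

    For the log-velocity model the point estimate and delta-method SE
    are back-transformed to the m/s scale (``estimate`` column); the
    link-scale quantities are kept alongside.  Extrapolating outside the
    observed heart-rate range emits a warning.
    """
    lo, hi = result.heart_rate_range
    if np.isfinite(lo) and not (lo <= heart_rate <= hi):
        warnings.warn(
            f"heart rate {heart_rate} bpm is outside the observed range "
            f"[{lo:g}, {hi:g}]; EMMs are extrapolated",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = result.params.to_numpy()
    cov = result.cov_params.to_numpy()
    recs = []
    for level, L in _emm_rows(result, heart_rate).items():
        est = float(L @ beta)
        se = float(np.sqrt(max(L @ cov @ L, 0.0)))
        df = result.df_within if result.df_method == "between_within" else np.inf
        tcrit = sps.t.ppf(0.975, df) if np.isfinite(df) else sps.norm.ppf(0.975)
        if result.is_log_scale:
            point, point_se = float(np.exp(est)), float(np.exp(est)) * se
            lcl, ucl = float(np.exp(est - tcrit * se)), float(np.exp(est + tcrit * se))
        else:
            point, point_se = est, se
            lcl, ucl = est - tcrit * se, est + tcrit * se
        recs.append(
            {
                result.location: level,
                "estimate": point,
                "se": point_se,
                "lcl": lcl,
                "ucl": ucl,
                "link_estimate": est,
                "link_se": se,
                "heart_rate": heart_rate,
            }
        )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------
# Pairwise contrasts
# ---------------------------------------------------------------------

def pairwise_contrasts(
    result: MixedModelResult,
    which: str | list = "all_pairs",
    adjust: str = None,
    heart_rate: float = REFERENCE_HEART_RATE,
) -> pd.DataFrame:
    """Pairwise location contrasts with multiplicity adjustment.

    ``which="all_pairs"`` compares every pair of levels (k(k-1)/2 rows),
    adjusted by Tukey's studentized-range criterion by default; a list
    of (level_a, level_b) tuples defines a targeted subset, adjusted by
    Sidak by default.  Log-velocity contrasts are reported as ratios
    ``level_a / level_b`` (delta-method SE); voltage contrasts as
    differences in mV.
    """
    if which == "all_pairs":
        pairs = [
            (a, b)
            for i, a in enumerate(result.levels)
            for b in result.levels[i + 1:]
        ]
        adjust = adjust or "tukey"
    else:
        pairs = [(str(a), str(b)) for a, b in which]
        adjust = adjust or "sidak"
    if adjust not in ("tukey", "sidak", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if len(result.levels) < 2 or not pairs:
        return pd.DataFrame(
            columns=["level_a", "level_b", "estimate", "se", "t", "df", "p_raw", "p_adj", "adjust"]
        )
    rows = _emm_rows(result, heart_rate)
    beta = result.params.to_numpy()
    cov = result.cov_params.to_numpy()
    df = result.df_within if result.df_method == "between_within" else np.inf
    k = len(result.levels)
    m = len(pairs)
    recs = []
    for a, b in pairs:
        L = rows[a] - rows[b]
        diff = float(L @ beta)
        se = float(np.sqrt(max(L @ cov @ L, 0.0)))
        # se == 0 only for degenerate noise-free fits
        t = diff / se if se > 0 else (np.inf if diff else 0.0)
        dfe = df if np.isfinite(df) else 1e7
        p_raw = float(2 * sps.t.sf(abs(t), dfe))
        if adjust == "tukey":
            p_adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2), k, dfe))
        elif adjust == "sidak":
            p_adj = float(1.0 - (1.0 - p_raw) ** m)
        else:
            p_adj = p_raw
        p_adj = min(max(p_adj, p_raw), 1.0)
        if result.is_log_scale:
            est, est_se = float(np.exp(diff)), float(np.exp(diff)) * se
        else:
            est, est_se = diff, se
        recs.append(
            {
                "level_a": a,
                "level_b": b,
                "estimate": est,
                "se": est_se,
                "link_estimate": diff,
                "link_se": se,
                "t": t,
                "df": df,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "adjust": adjust,
            }
        )
    return pd.DataFrame(recs)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment for m tests: 1 - (1 - p)^m."""
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


# ---------------------------------------------------------------------
# Correlation and sex effect
# ---------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Pearson correlation between cv and va on a stated scope."""

    scope: str
    r: float
    df: int                      # n - 2
    p_value: float
    n: int
    cv_cap: float | None = None

    @property
    def interpretation(self) -> str:
        if abs(self.r) < NO_CORRELATION_BAND:
            return "no linear correlation"
        direction = "positive" if self.r > 0 else "negative"
        return f"low {direction} linear correlation" if abs(self.r) < 0.5 else \
            f"{direction} linear correlation"

    def __str__(self) -> str:
        return (
            f"{self.scope}: r({self.df}) = {self.r:.2f}, p = {self.p_value:.3g}"
            f" [{self.interpretation}]"
        )


def pearson_correlation(
    data: pd.DataFrame, scope: str = "overall", cv_cap: float | None = None
) -> CorrelationResult:
    """Pearson correlation of cv vs va, optionally per chamber / capped.

    ``scope`` is ``"overall"`` or a chamber name; ``cv_cap`` restricts
    to circles with cv strictly below the cap (m/s) before correlating.
    Degrees of freedom are n - 2.  Constant input or n < 3 raise.
    """
    d = data
    if "valid" in d.columns:
        d = d[d["valid"]]
    if scope != "overall":
        d = d[d["chamber"] == scope]
    if cv_cap is not None:
        d = d[d["cv"] < cv_cap]
    d = d.dropna(subset=["cv", "va"])
    n = len(d)
    if n < 3:
        raise ValueError(f"need at least 3 pairs to correlate (got {n})")
    cv, va = d["cv"].to_numpy(float), d["va"].to_numpy(float)
    if np.ptp(cv) == 0 or np.ptp(va) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(cv, va)
    return CorrelationResult(scope=scope, r=float(r), df=n - 2, p_value=float(p),
                             n=n, cv_cap=cv_cap)


def sex_effect_test(
    data: pd.DataFrame, response: str, location: str = "chamber",
    group: str = "animal_id", df_method: str = "between_within",
) -> tuple[float, MixedModelResult]:
    """Test whether sex shifts the response, animal-level df.

    Adds sex to the fixed effects of the standard mixed model and
    reports the Wald p-value of its coefficient.  Sex is constant
    within an animal, so under the between-within rule the test uses
    animal-level degrees of freedom.  Single-sex data raise.
    """
    sexes = pd.Series(data["sex"].astype(str)).dropna().unique()
    if len(sexes) < 2:
        raise IdentifiabilityError("sex effect requires both sexes in the data")
    res = fit_mixed_model(
        data, response, location=location, group=group,
        extra_factors=("sex",), df_method=df_method,
    )
    name = next(n for n in res.params.index if n.startswith("C(sex)"))
    se = float(np.sqrt(res.cov_params.loc[name, name]))
    if se == 0:
        return (0.0 if res.params[name] else 1.0), res
    t = res.params[name] / se
    df = res.coef_df(name)
    dfe = df if np.isfinite(df) else 1e7
    p = float(2 * sps.t.sf(abs(t), dfe))
    return p, res
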