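"""Dose-effect inference with linear mixed models.

Each physiological index F (peak ventilatory frequency, heart rate,
interval CVs, average swimming speed) is regressed on the logarithmic
caffeine concentration C = ln(x_c + 1) with fixed intercept beta_0 and
slope beta_1, plus Gaussian random intercepts.  Eight candidate random
structures are fitted by maximum likelihood and compared by AIC:

    1: none                         5: by (concentration, individual)
    2: by individual                6: by concentration + by (conc, indiv)
    3: by concentration             7: by individual + by (conc, indiv)
    4: by individual + by conc      8: all three

No random slope is included: an individual experiences exactly one
concentration, which also makes the "individual" and "(concentration,
individual)" intercepts statistically confounded — both index the same
grouping — so models that include both are boundary-prone and their
convergence flags matter.  ML (not REML) likelihoods are used throughout
so AICs are comparable across random structures; inference on the fixed
effects is Wald-z (normal) with 95% confidence intervals.

Estimation is delegated to statsmodels (``MixedLM``; ordinary least
squares for model 1) behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ConvergenceError, DomainError, SectionError

DOSES_MG_PER_L = (0.0, 1.0, 50.0, 100.0)

#: random-intercept terms for each candidate model id
RANDOM_TERMS: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("j",),
    3: ("C",),
    4: ("j", "C"),
    5: ("Cj",),
    6: ("C", "Cj"),
    7: ("j", "Cj"),
    8: ("C", "j", "Cj"),
}

PIECEWISE_SECTIONS = ((0.0, 1.0), (1.0, 100.0))


def log_concentration(x_c, base: str = "e"):
    """Logarithmic caffeine concentration C = log(x_c + 1).

    Natural log by default; ``base="10"`` switches to log10.  The doses
    {0, 1, 50, 100} mg/L map to {0, 0.693, 3.932, 4.615} under ln.
    """
    x = np.asarray(x_c, dtype=float)
    if np.any(x < 0):
        raise DomainError("concentration must be nonnegative")
    c = np.log(x + 1.0) if base == "e" else np.log10(x + 1.0)
    return float(c) if np.isscalar(x_c) else c


@dataclass(frozen=True)
class LMMSpec:
    """One of the eight candidate random-intercept structures."""

    model_id: int

    def __post_init__(self) -> None:
        if self.model_id not in RANDOM_TERMS:
            raise DomainError(f"model_id must be in 1..8, got {self.model_id}")

    @property
    def random_terms(self) -> tuple[str, ...]:
        return RANDOM_TERMS[self.model_id]


@dataclass
class LMMFit:
    """Fitted fixed effects and random-effect SDs for one candidate model."""

    spec: LMMSpec
    beta0: float
    beta1: float
    se0: float
    se1: float
    p0: float
    p1: float
    ci0: tuple[float, float]
    ci1: tuple[float, float]
    random_sds: dict[str, float] = field(default_factory=dict)
    residual_sd: float = np.nan
    loglik: float = np.nan
    aic: float = np.nan
    n_obs: int = 0
    n_params: int = 0
    converged: bool = False
    boundary: bool = False

    @property
    def total_random_sd(self) -> float:
        """SD of the summed random-intercept terms (sqrt of summed variances)."""
        if not self.random_sds:
            return 0.0
        return float(np.sqrt(sum(s**2 for s in self.random_sds.values())))


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "C" not in df.columns:
        df["C"] = log_concentration(df["concentration_mg_per_l"].to_numpy())
    df["_conc"] = df["concentration_mg_per_l"].astype(str)
    df["_ind"] = df["individual_id"].astype(str)
    # deterministic row order -> order-invariant estimates
    df = df.sort_values(["_conc", "_ind", "value"], kind="stable").reset_index(drop=True)
    return df


def _wald(beta: float, se: float) -> tuple[float, tuple[float, float]]:
    z = beta / se
    p = 2.0 * _stats.norm.sf(abs(z))
    half = _stats.norm.ppf(0.975) * se
    return float(p), (float(beta - half), float(beta + half))


def fit_candidate(table: pd.DataFrame, spec: LMMSpec) -> LMMFit:
    """Fit one candidate model by maximum likelihood.

    ``table`` needs columns ``individual_id``, ``concentration_mg_per_l``
    and ``value`` (one metric, one condition/section).  Boundary variance
    estimates (a random SD collapsing to ~0) are flagged, not hidden; the
    fit is still returned.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _prepare(table)
    n = len(df)
    if df["_conc"].nunique() < 2:
        raise SectionError("need >= 2 concentration groups to estimate a slope")
    terms = spec.random_terms

    if not terms:  # model 1: plain linear regression, ML loglik
        X = sm.add_constant(df["C"].to_numpy())
        res = sm.OLS(df["value"].to_numpy(), X).fit()
        b0, b1 = float(res.params[0]), float(res.params[1])
        s0, s1 = float(res.bse[0]), float(res.bse[1])
        p0, ci0 = _wald(b0, s0)
        p1, ci1 = _wald(b1, s1)
        k = 3  # beta0, beta1, sigma^2
        return LMMFit(
            spec=spec, beta0=b0, beta1=b1, se0=s0, se1=s1, p0=p0, p1=p1,
            ci0=ci0, ci1=ci1, random_sds={},
            residual_sd=float(np.sqrt(res.ssr / n)),
            loglik=float(res.llf), aic=float(-2 * res.llf + 2 * k),
            n_obs=n, n_params=k, converged=True, boundary=False,
        )

    j_like = [t for t in terms if t in ("j", "Cj")]
    if "C" in terms:
        groups, re_formula = "_conc", "1"
        vc = {t: "0 + _ind" for t in j_like}
    else:
        groups, re_formula = "_ind", "1"
        vc = {t: "0 + _ind" for t in j_like[1:]}  # first j-like term is the group intercept
    model = smf.mixedlm(
        "value ~ C", df, groups=df[groups], re_formula=re_formula,
        vc_formula=vc or None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, maxiter=2000)
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is None or not np.isfinite(res.llf):
            nan = float("nan")
            return LMMFit(
                spec=spec, beta0=nan, beta1=nan, se0=nan, se1=nan, p0=nan, p1=nan,
                ci0=(nan, nan), ci1=(nan, nan), n_obs=n, converged=False, boundary=True,
            )

    b0, b1 = float(res.fe_params["Intercept"]), float(res.fe_params["C"])
    s0, s1 = float(res.bse_fe["Intercept"]), float(res.bse_fe["C"])
    p0, ci0 = _wald(b0, s0)
    p1, ci1 = _wald(b1, s1)
    scale = float(res.scale)
    random_sds: dict[str, float] = {}
    # group-level random intercept variance (cov_re is 1x1 here)
    group_term = "C" if "C" in terms else j_like[0]
    random_sds[group_term] = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
    for name, v in zip(vc.keys(), np.atleast_1d(res.vcomp)):
        random_sds[name] = float(np.sqrt(max(v, 0.0)))
    n_var = 1 + len(vc)
    k = 2 + n_var + 1
    boundary = any(sd**2 <= 1e-6 * scale for sd in random_sds.values())
    return LMMFit(
        spec=spec, beta0=b0, beta1=b1, se0=s0, se1=s1, p0=p0, p1=p1,
        ci0=ci0, ci1=ci1, random_sds=random_sds,
        residual_sd=float(np.sqrt(scale)),
        loglik=float(res.llf), aic=float(-2 * res.llf + 2 * k),
        n_obs=n, n_params=k,
        converged=bool(res.converged), boundary=boundary,
    )


def select_model_aic(table: pd.DataFrame) -> tuple[LMMFit, pd.DataFrame]:
    """Fit all eight candidates and return the minimum-AIC converged fit.

    Non-converged fits are excluded from selection but still listed in the
    returned AIC table; AIC ties break toward fewer parameters.
    """
    fits = [fit_candidate(table, LMMSpec(m)) for m in sorted(RANDOM_TERMS)]
    aic_table = pd.DataFrame(
        {
            "model_id": [f.spec.model_id for f in fits],
            "aic": [f.aic for f in fits],
            "loglik": [f.loglik for f in fits],
            "n_params": [f.n_params for f in fits],
            "converged": [f.converged for f in fits],
            "boundary": [f.boundary for f in fits],
        }
    )
    usable = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not usable:
        raise ConvergenceError("no candidate mixed model converged")
    best = min(usable, key=lambda f: (round(f.aic, 9), f.n_params, f.spec.model_id))
    return best, aic_table


def piecewise_fit(
    table: pd.DataFrame,
    sections: tuple[tuple[float, float], ...] = PIECEWISE_SECTIONS,
) -> dict[tuple[float, float], tuple[LMMFit, pd.DataFrame]]:
    """Independent model selection on closed dose sections.

    Used where an index rises then falls across the dose range (heartbeat
    CV, swimming speed): default sections are [0, 1] and [1, 100] mg/L,
    with the 1 mg/L dose belonging to both.
    """
    out = {}
    for lo, hi in sections:
        sub = table[
            (table["concentration_mg_per_l"] >= lo)
            & (table["concentration_mg_per_l"] <= hi)
        ]
        if sub.empty or sub["concentration_mg_per_l"].nunique() < 2:
            raise SectionError(
                f"section [{lo}, {hi}] mg/L needs >= 2 dose groups with data"
            )
        out[(lo, hi)] = select_model_aic(sub)
    return out


def significance_stars(p: float) -> str:
    """Conventional significance bands: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def report(fits: dict[str, LMMFit]) -> pd.DataFrame:
    """Assemble fitted metrics into a results table.

    One row per metric (in insertion order): slope with p/stars/CI,
    intercept with p/stars/CI, combined random-effect SD, residual SD,
    and the selected model id.
    """
    rows = []
    for metric, fit in fits.items():
        rows.append(
            {
                "metric": metric,
                "model_id": fit.spec.model_id,
                "beta1": fit.beta1,
                "p_beta1": fit.p1,
                "stars_beta1": significance_stars(fit.p1),
                "ci_beta1_low": fit.ci1[0],
                "ci_beta1_high": fit.ci1[1],
                "beta0": fit.beta0,
                "p_beta0": fit.p0,
                "stars_beta0": significance_stars(fit.p0),
                "ci_beta0_low": fit.ci0[0],
                "ci_beta0_high": fit.ci0[1],
                "random_sd": fit.total_random_sd,
                "residual_sd": fit.residual_sd,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
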