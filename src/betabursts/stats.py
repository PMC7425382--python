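"""Group/session models for burst features and symptom regressions.

Burst-rate counts are modelled by mixed-effects Poisson regression
(Group and Session fixed, subject random intercept, log analysed minutes
as exposure offset). Per-event burst duration, inter-burst interval and
peak amplitude are modelled on the log scale — lognormal, or shifted
lognormal with a profiled shift — as linear mixed models with a subject
random intercept. Evidence for or against each factor is summarised by
Bayes factors approximated from BIC differences of nested model fits
(BF ~ exp((BIC_without - BIC_with)/2)), read on the conventional scale
where BF > 3 / BF < 1/3 counts as conclusive evidence for / against an
effect. Post-hoc contrasts are summarised by an exceedance probability:
the probability mass of the contrast's distribution on the side of zero
opposite to the point estimate (near 0 = clear difference, near 0.5 =
none).

Symptom models regress each of the six motor-factor scores (Poisson) on
the burst rate within patients; the rate effect is reported as the
percent change of the expected score per +10 bursts/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import SubjectBurstSummary
from .io import SYMPTOM_FACTORS
from .mixed import PoissonMixedGLM

__all__ = [
    "ModelResult",
    "SymptomEffect",
    "fit_rate_model",
    "fit_feature_model",
    "fit_symptom_models",
    "approx_bf",
    "exceedance_prob",
    "pct_change",
    "pct_change_inv",
    "summaries_to_frame",
    "events_long_table",
]


def pct_change(beta: float, per: float = 1.0) -> float:
    """Log-scale coefficient -> percent change over ``per`` units."""
    return 100.0 * (np.exp(per * beta) - 1.0)


def pct_change_inv(pct: float, per: float = 1.0) -> float:
    """Percent change over ``per`` units -> log-scale coefficient."""
    return np.log1p(pct / 100.0) / per


@dataclass
class ModelResult:
    """Fitted model summary: coefficient table, BFs and contrasts.

    ``coefficients`` has columns (name, estimate, se, ci_lo, ci_hi);
    ``contrasts`` maps contrast names to dicts with percent-scale
    estimate/CI and the exceedance probability ``p_prob``. Bayes factors
    are None when the corresponding factor is absent from the design.
    """

    coefficients: pd.DataFrame
    bf_group: float | None = None
    bf_session: float | None = None
    bf_interaction: float | None = None
    contrasts: dict = field(default_factory=dict)
    family: str = ""
    shift: float = 0.0
    models: dict = field(default_factory=dict)


@dataclass
class SymptomEffect:
    factor: str
    pct_change_per_10: float
    ci_lo: float
    ci_hi: float
    p_prob: float

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.pct_change_per_10 <= self.ci_hi):
            raise ValueError("CI must contain the point estimate")


def summaries_to_frame(summaries: list[SubjectBurstSummary] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return pd.DataFrame([s.to_row() for s in summaries])


def events_long_table(summaries: list[SubjectBurstSummary]) -> pd.DataFrame:
    """Per-event rows (subject, group, session, duration/IBI/amplitude)."""
    rows = []
    for s in summaries:
        for i in range(s.n_bursts):
            rows.append(
                {
                    "subject": s.subject,
                    "group": s.group,
                    "session": s.session,
                    "duration_ms": s.durations_ms[i],
                    "peak_amp": s.peak_amps[i],
                    "ibi_ms": s.ibis_ms[i] if i < len(s.ibis_ms) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame, interaction: bool) -> tuple[np.ndarray, list[str]]:
    """Intercept + group/session indicator design matrix.

    Group is coded patient=1 (controls the reference level), session 2=1.
    Columns that would be constant (single group or session) are dropped.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    groups = sorted(df["group"].unique())
    sessions = sorted(df["session"].unique())
    if len(groups) > 1:
        g = (df["group"] == "patient").to_numpy(float)
        if g.std() == 0:  # 'patient' absent: indicator on the later label
            g = (df["group"] == groups[-1]).to_numpy(float)
        cols.append(g)
        names.append("group")
    if len(sessions) > 1:
        s = (df["session"] == sessions[-1]).to_numpy(float)
        cols.append(s)
        names.append("session")
    if interaction and "group" in names and "session" in names:
        cols.append(cols[names.index("group")] * cols[names.index("session")])
        names.append("group:session")
    return np.column_stack(cols), names


def approx_bf(model_with, model_without) -> float:
    """BIC-approximated Bayes factor for a nested model pair.

    ``BF = exp((BIC_without - BIC_with) / 2)``: BF > 1 favours the model
    containing the factor. Both fits must describe the same data
    (identical observation count) and be nested (the smaller model's
    coefficient names a subset of the larger's).
    """
    n_with = getattr(model_with, "n_obs_", None)
    n_without = getattr(model_without, "n_obs_", None)
    if n_with != n_without:
        raise ValueError("models were fitted to different data")
    names_with = set(getattr(model_with, "exog_names_", []))
    names_without = set(getattr(model_without, "exog_names_", []))
    if not (names_without <= names_with or names_with <= names_without):
        raise ValueError("models are not nested")
    return float(np.exp((model_without.bic_ - model_with.bic_) / 2.0))


def exceedance_prob(contrast, se: float | None = None) -> float:
    """Probability mass on the side of zero opposite the point estimate.

    Accepts either an array of contrast samples (e.g. from a parametric
    bootstrap) or a (estimate, se) pair for the Gaussian/Wald version.
    Values near 0 indicate a clear difference; 0.5 indicates none.
    """
    if se is not None:
        est = float(contrast)
        if se <= 0:
            raise ValueError("degenerate (zero-variance) contrast")
        return float(norm.sf(abs(est) / se))
    samples = np.asarray(contrast, dtype=float)
    if samples.size < 2 or samples.std() == 0:
        raise ValueError("degenerate (zero-variance) contrast")
    center = samples.mean()
    if center >= 0:
        return float(np.mean(samples < 0) + 0.5 * np.mean(samples == 0))
    return float(np.mean(samples > 0) + 0.5 * np.mean(samples == 0))


def _bootstrap_contrast(model: PoissonMixedGLM, name: str, n_boot: int, seed) -> np.ndarray:
    """Parametric-bootstrap samples of one coefficient."""
    rng = np.random.default_rng(seed)
    i = model.exog_names_.index(name)
    out = np.empty(n_boot)
    for b in range(n_boot):
        y_new = model.simulate(rng)
        out[b] = model.refit(y_new).coef_[i]
    return out


def fit_rate_model(
    summaries,
    bootstrap_n: int = 0,
    seed: int = 0,
) -> ModelResult:
    """Mixed-effects Poisson model of the burst counts.

    Fixed effects Group and Session, subject random intercept, exposure
    offset = log analysed minutes; contrasts are reported as percent
    rate differences. ``bootstrap_n > 0`` switches the exceedance
    probability from the Wald tail to a parametric bootstrap.
    """
    df = summaries_to_frame(summaries)
    if df.groupby("group")["subject"].nunique().min() < 1:
        raise ValueError("need at least one subject per group")
    y = df["n_bursts"].to_numpy(float)
    offset = np.log(df["analyzed_s"].to_numpy(float) / 60.0)
    subjects = df["subject"].to_numpy()

    X_full, names_full = _design(df, interaction=False)
    fits: dict[str, PoissonMixedGLM] = {}
    fits["additive"] = PoissonMixedGLM().fit(
        X_full, y, subjects, offset=offset, exog_names=names_full
    )
    Xi, names_i = _design(df, interaction=True)
    if "group:session" in names_i:
        fits["interaction"] = PoissonMixedGLM().fit(
            Xi, y, subjects, offset=offset, exog_names=names_i
        )

    bf_group = bf_session = bf_interaction = None
    for factor in ("group", "session"):
        if factor in names_full:
            drop = [j for j, n in enumerate(names_full) if n != factor]
            reduced = PoissonMixedGLM().fit(
                X_full[:, drop],
                y,
                subjects,
                offset=offset,
                exog_names=[names_full[j] for j in drop],
            )
            fits[f"no_{factor}"] = reduced
            bf = approx_bf(fits["additive"], reduced)
            if factor == "group":
                bf_group = bf
            else:
                bf_session = bf
    if "interaction" in fits:
        bf_interaction = approx_bf(fits["interaction"], fits["additive"])

    full = fits["additive"]
    z = norm.ppf(0.975)
    coef_table = pd.DataFrame(
        {
            "name": full.exog_names_,
            "estimate": full.coef_,
            "se": full.coef_se_,
            "ci_lo": full.coef_ - z * full.coef_se_,
            "ci_hi": full.coef_ + z * full.coef_se_,
        }
    )
    contrasts = {}
    for factor in ("group", "session"):
        if factor in full.exog_names_:
            est, lo, hi = full.wald_ci(factor)
            i = full.exog_names_.index(factor)
            if bootstrap_n > 0:
                samples = _bootstrap_contrast(full, factor, bootstrap_n, seed)
                p_prob = exceedance_prob(samples)
            else:
                p_prob = exceedance_prob(est, full.coef_se_[i])
            contrasts[factor] = {
                "pct": pct_change(est),
                "pct_ci_lo": pct_change(lo),
                "pct_ci_hi": pct_change(hi),
                "p_prob": p_prob,
            }
    return ModelResult(
        coefficients=coef_table,
        bf_group=bf_group,
        bf_session=bf_session,
        bf_interaction=bf_interaction,
        contrasts=contrasts,
        family="poisson",
        models=fits,
    )


class _MixedLMWrap:
    """Uniform (bic_, n_obs_, exog_names_) facade over a linear-model fit.

    ``jacobian`` carries the -sum(log(y - shift)) change-of-variable term
    of a shifted-lognormal likelihood so BICs of models fitted to the
    same shifted data remain comparable on the original scale.
    """

    def __init__(self, result, exog_names, jacobian: float = 0.0, has_re: bool = True):
        self.result = result
        self.exog_names_ = list(exog_names)
        self.n_obs_ = int(result.nobs)
        self.has_re_ = has_re
        self.loglik_ = float(result.llf) + jacobian
        # fixed effects + residual variance (+ RE variance when present)
        k = len(exog_names) + 1 + int(has_re)
        self.bic_ = -2.0 * self.loglik_ + k * np.log(self.n_obs_)

    @property
    def fe_params(self):
        return np.asarray(self.result.params)[: len(self.exog_names_)]

    @property
    def bse_fe(self):
        if self.has_re_:
            return np.asarray(self.result.bse_fe)
        return np.asarray(self.result.bse)[: len(self.exog_names_)]


def _fit_lmm(log_y, X, names, subjects, jacobian: float = 0.0) -> _MixedLMWrap:
    """Linear mixed model of log values with a subject random intercept.

    When the random-intercept variance estimate collapses to the
    boundary (singular RE covariance, non-finite likelihood or standard
    errors) the model degenerates to ordinary least squares, which is
    then fitted directly — same fixed effects, no RE variance term.
    """
    import statsmodels.api as sm

    names = names if names is not None else [f"x{i}" for i in range(X.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(log_y, X, groups=subjects).fit(reml=False)
            ok = (
                np.isfinite(res.llf)
                and np.all(np.isfinite(np.asarray(res.bse_fe)))
                and float(np.asarray(res.cov_re).ravel()[0]) > 1e-8
            )
        except Exception:
            ok = False
        if ok:
            return _MixedLMWrap(res, names, jacobian, has_re=True)
        warnings.simplefilter("default")
        ols = sm.OLS(log_y, X).fit()
    warnings.warn(
        "random-intercept variance at the boundary; refitted without it",
        RuntimeWarning,
        stacklevel=2,
    )
    return _MixedLMWrap(ols, names, jacobian, has_re=False)


def fit_feature_model(
    values: np.ndarray,
    design: pd.DataFrame,
    family: str = "lognormal",
    shift_grid_n: int = 8,
) -> ModelResult:
    """Lognormal / shifted-lognormal mixed model of per-event values.

    ``values`` (ms or amplitude units) align row-wise with ``design``
    (columns subject, group, session). The shifted-lognormal shift is
    profiled on a coarse grid over [0, 0.99 * min(values)] using the full
    additive model, then held fixed for every nested fit so the BICs
    compare like with like. Effects are percent changes of the median of
    the shifted component (exp of the linear predictor).
    """
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    values = values[keep]
    design = design.loc[keep].reset_index(drop=True)
    if values.size == 0:
        raise ValueError("no finite values to model")

    X_full, names_full = _design(design, interaction=False)
    subjects = design["subject"].to_numpy()

    if family == "shifted_lognormal":
        grid = np.linspace(0.0, 0.99 * values.min(), shift_grid_n)
    elif family == "lognormal":
        grid = np.array([0.0])
    else:
        raise ValueError(f"unknown family {family!r}")
    if np.any(values - grid.max() <= 0):
        raise ValueError("non-positive values after shift")

    best = None
    for shift in grid:
        log_y = np.log(values - shift)
        jac = -float(np.sum(np.log(values - shift)))
        wrap = _fit_lmm(log_y, X_full, names_full, subjects, jacobian=jac)
        if best is None or wrap.loglik_ > best[1].loglik_:
            best = (shift, wrap)
    shift, full_wrap = best
    log_y = np.log(values - shift)
    jac = -float(np.sum(np.log(values - shift)))

    fits = {"additive": full_wrap}
    bf_group = bf_session = bf_interaction = None
    for factor in ("group", "session"):
        if factor in names_full:
            drop = [j for j, n in enumerate(names_full) if n != factor]
            fits[f"no_{factor}"] = _fit_lmm(
                log_y, X_full[:, drop], [names_full[j] for j in drop], subjects, jacobian=jac
            )
            bf = approx_bf(full_wrap, fits[f"no_{factor}"])
            if factor == "group":
                bf_group = bf
            else:
                bf_session = bf
    Xi, names_i = _design(design, interaction=True)
    if "group:session" in names_i:
        fits["interaction"] = _fit_lmm(log_y, Xi, names_i, subjects, jacobian=jac)
        bf_interaction = approx_bf(fits["interaction"], full_wrap)

    z = norm.ppf(0.975)
    fe = full_wrap.fe_params
    se = full_wrap.bse_fe
    coef_table = pd.DataFrame(
        {
            "name": names_full,
            "estimate": np.asarray(fe),
            "se": np.asarray(se),
            "ci_lo": np.asarray(fe) - z * np.asarray(se),
            "ci_hi": np.asarray(fe) + z * np.asarray(se),
        }
    )
    contrasts = {}
    for factor in ("group", "session"):
        if factor in names_full:
            i = names_full.index(factor)
            est, s = float(fe[i]), float(se[i])
            contrasts[factor] = {
                "pct": pct_change(est),
                "pct_ci_lo": pct_change(est - z * s),
                "pct_ci_hi": pct_change(est + z * s),
                "p_prob": exceedance_prob(est, s),
            }
    return ModelResult(
        coefficients=coef_table,
        bf_group=bf_group,
        bf_session=bf_session,
        bf_interaction=bf_interaction,
        contrasts=contrasts,
        family=family,
        shift=float(shift),
        models=fits,
    )


def fit_symptom_models(
    summaries,
    scores: pd.DataFrame,
    factors: list[str] | None = None,
    bootstrap_n: int = 0,
    seed: int = 0,
) -> list[SymptomEffect]:
    """Per-factor Poisson regressions of symptom score on burst rate.

    Patients only. Each factor score is modelled as Poisson with log
    mean linear in the burst rate, a subject random intercept and a
    session intercept. A session random effect with two levels is only
    weakly identified, so session enters as a fixed intercept shift
    (the deterministic equivalent); see the methods note. The rate
    effect is returned as percent change per +10 bursts/min.
    """
    df = summaries_to_frame(summaries)
    df = df[df["group"] == "patient"] if (df["group"] == "patient").any() else df
    merged = df.merge(scores, on=["subject", "session"], how="inner", suffixes=("", "_score"))
    if merged.empty:
        raise ValueError("no overlapping subject/session records between rates and scores")
    if factors is None:
        factors = [f for f in SYMPTOM_FACTORS if f in merged.columns]

    rate = merged["rate_per_min"].to_numpy(float)
    rate_c = rate - rate.mean()  # centred for a stable intercept
    subjects = merged["subject"].to_numpy()
    sessions = sorted(merged["session"].unique())

    cols = [np.ones(len(merged)), rate_c]
    names = ["intercept", "rate"]
    if len(sessions) > 1:
        cols.append((merged["session"] == sessions[-1]).to_numpy(float))
        names.append("session")
    X = np.column_stack(cols)

    effects: list[SymptomEffect] = []
    for factor in factors:
        y = merged[factor].to_numpy(float)
        if np.all(y == 0):
            warnings.warn(f"factor {factor!r} is all-zero; skipped", RuntimeWarning)
            continue
        fit = PoissonMixedGLM().fit(X, y, subjects, exog_names=names)
        est, lo, hi = fit.wald_ci("rate")
        i = fit.exog_names_.index("rate")
        if bootstrap_n > 0:
            samples = _bootstrap_contrast(fit, "rate", bootstrap_n, seed)
            p_prob = exceedance_prob(samples)
        else:
            p_prob = exceedance_prob(est, fit.coef_se_[i])
        effects.append(
            SymptomEffect(
                factor=factor,
                pct_change_per_10=pct_change(est, per=10.0),
                ci_lo=pct_change(lo, per=10.0),
                ci_hi=pct_change(hi, per=10.0),
                p_prob=p_prob,
            )
        )
    return effects
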