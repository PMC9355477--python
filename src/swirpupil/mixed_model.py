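"""Mixed-effects workflow for the pupil-baseline and recall models.

The analysis regresses a block-level outcome (pupil baseline in mm, or
recall percentage) on centered Block, Reading-Span score (RS) and SNR,
starting from the maximal model — all fixed effects up to the three-way
interaction, with by-participant random intercepts and random slopes for
Block, RS and SNR — and simplifying it by backward elimination:
singular/aliased random slopes first, then REML likelihood-ratio pruning
of random slopes (alpha = 0.1), then Wald pruning of fixed effects
(alpha = 0.05) respecting marginality.  Estimation is REML via
statsmodels' MixedLM with an unstructured random-effects covariance.

Derived statistics: Type II Wald chi-square tests, marginal/conditional
R2 (variance-partition form), variance inflation factors, a median split
of RS into low/high working-memory groups, simple slopes of SNR at each
group's mean centered RS, and group contrasts over a grid of centered
SNR values.

Fixed-effect p-values use the Wald z (infinite-df) reference, consistent
with chi-square reporting; no Satterthwaite/Kenward-Roger correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from swirpupil.config import PipelineConfig

logger = logging.getLogger("swirpupil")

__all__ = [
    "ModelSpec",
    "ModelFit",
    "PosthocResult",
    "FIXED_TERMS_FULL",
    "RANDOM_TERMS_FULL",
    "center_predictors",
    "prepare_model_frame",
    "fit_lmm",
    "fit_maximal",
    "backward_eliminate",
    "anova_type2",
    "r2_nakagawa",
    "r2_from_components",
    "vif",
    "median_split",
    "simple_slopes",
    "snr_grid_contrasts",
    "build_report",
]

BASE_PREDICTORS = ("Block", "RS", "SNR")
FIXED_TERMS_FULL = (
    "Block", "RS", "SNR", "Block:RS", "Block:SNR", "RS:SNR", "Block:RS:SNR",
)
RANDOM_TERMS_FULL = ("intercept", "Block", "RS", "SNR")

TABLE_LABELS = {
    "Intercept": "Intercept",
    "Block": "Block",
    "RS": "RS test score",
    "SNR": "SNR",
    "RS:SNR": "RS test score x SNR",
    "Block:RS": "Block x RS test score",
    "Block:SNR": "Block x SNR",
    "Block:RS:SNR": "Block x RS test score x SNR",
}


def _parts(term: str) -> frozenset[str]:
    return frozenset(term.split(":"))


def _contains(outer: str, inner: str) -> bool:
    """True when ``outer`` is a strictly higher-order relative of ``inner``."""
    return _parts(inner) < _parts(outer)


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """Which terms enter the model.

    ``fixed_terms`` are interaction strings over {Block, RS, SNR} (the
    intercept is implicit); ``random_terms`` are by-participant effects
    from {intercept, Block, RS, SNR}.  Marginality is enforced among
    fixed terms only: a random slope may outlive its fixed counterpart
    (the recall model keeps a Block random slope with no fixed Block).
    """

    outcome: str
    fixed_terms: tuple[str, ...] = FIXED_TERMS_FULL
    random_terms: tuple[str, ...] = RANDOM_TERMS_FULL

    def __post_init__(self) -> None:
        self.fixed_terms = tuple(self.fixed_terms)
        self.random_terms = tuple(self.random_terms)
        for t in self.fixed_terms:
            if not _parts(t) <= set(BASE_PREDICTORS):
                raise ValueError(f"unknown fixed term {t!r}")
        for t in self.random_terms:
            if t != "intercept" and t not in BASE_PREDICTORS:
                raise ValueError(f"unknown random term {t!r}")
        if "intercept" not in self.random_terms:
            raise ValueError("the by-participant random intercept is always kept")
        self.check_marginality()

    def check_marginality(self) -> None:
        for t in self.fixed_terms:
            for p in _parts(t):
                if len(_parts(t)) > 1 and p not in self.fixed_terms:
                    raise ValueError(
                        f"marginality violation: {t!r} present without {p!r}"
                    )

    def droppable_fixed(self) -> list[str]:
        """Fixed terms not contained in any retained interaction."""
        return [
            t for t in self.fixed_terms
            if not any(_contains(o, t) for o in self.fixed_terms)
        ]

    def without_fixed(self, term: str) -> "ModelSpec":
        return ModelSpec(self.outcome,
                         tuple(t for t in self.fixed_terms if t != term),
                         self.random_terms)

    def without_random(self, term: str) -> "ModelSpec":
        return ModelSpec(self.outcome, self.fixed_terms,
                         tuple(t for t in self.random_terms if t != term))


# ---------------------------------------------------------------------------
# centering and design construction


def center_predictors(
    df: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Add centered predictor columns Block, RS, SNR.

    Each predictor is reduced by its grand mean over the analysis rows;
    by default it is *not* divided by its SD (``standardize_predictors``
    restores full standardization).  Centering is idempotent: re-centering
    already-centered columns subtracts a zero mean.  Constant columns are
    zeroed with a warning.
    """
    cfg = cfg or PipelineConfig()
    out = df.copy()
    src = {"Block": "block", "RS": "rs_score", "SNR": "snr_db"}
    offsets: dict[str, float] = {}
    for name, col in src.items():
        base = out[name] if name in out.columns else out[col]
        x = base.to_numpy(dtype=float)
        mu = float(np.mean(x))
        offsets[name] = mu
        centered = x - mu
        sd = float(np.std(centered, ddof=1)) if len(x) > 1 else 0.0
        if sd == 0.0:
            logger.warning("predictor %s is constant; centered to all zeros", name)
        elif cfg.standardize_predictors:
            centered = centered / sd
            offsets[f"{name}_sd"] = sd
        out[name] = centered
    return out, offsets


def prepare_model_frame(
    blocks: pd.DataFrame,
    outcome: str,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Assemble the analysis table: drop rows with missing outcome or
    covariates, then center the predictors on the retained rows."""
    col = {"pupil_baseline": "pupil_baseline_mm",
           "recall_pct": "recall_pct"}.get(outcome, outcome)
    needed = ["participant", "block", "rs_score", "snr_db", col]
    frame = blocks[needed].dropna().reset_index(drop=True)
    frame = frame.rename(columns={col: "outcome"})
    frame, offsets = center_predictors(frame, cfg)
    return frame, offsets


def _design(spec: ModelSpec, frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    X = pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)
    for t in spec.fixed_terms:
        cols = [frame[p].to_numpy() for p in sorted(_parts(t), key=t.split(":").index)]
        X[t] = np.prod(cols, axis=0)
    Z = pd.DataFrame(index=frame.index)
    for t in spec.random_terms:
        Z[t] = 1.0 if t == "intercept" else frame[t].to_numpy()
    return X, Z


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ModelFit:
    """A fitted linear mixed model plus everything derived statistics need."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    cov_beta: pd.DataFrame
    cov_re: pd.DataFrame
    sigma2: float
    llf: float
    converged: bool
    singular: bool
    singular_reasons: list[str]
    n_obs: int
    n_groups: int
    frame: pd.DataFrame = field(repr=False)
    X: pd.DataFrame = field(repr=False)
    Z: pd.DataFrame = field(repr=False)
    cfg: PipelineConfig = field(repr=False, default_factory=PipelineConfig)

    @property
    def ci(self) -> pd.DataFrame:
        lo = self.params - 1.96 * self.se
        hi = self.params + 1.96 * self.se
        return pd.DataFrame({"low": lo, "high": hi})

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def coef(self, term: str, default: float = 0.0) -> float:
        return float(self.params.get(term, default))

    def cov(self, a: str, b: str) -> float:
        if a in self.cov_beta.index and b in self.cov_beta.columns:
            return float(self.cov_beta.loc[a, b])
        return 0.0


def _check_singular(cov_re: pd.DataFrame, y_sd: float,
                    cfg: PipelineConfig) -> list[str]:
    reasons = []
    sds = np.sqrt(np.maximum(np.diag(cov_re.to_numpy()), 0.0))
    for name, sd in zip(cov_re.index, sds):
        if sd < cfg.singular_sd_rel_tol * y_sd:
            reasons.append(f"random SD of {name} is ~0")
    if len(sds) > 1:
        denom = np.outer(sds, sds)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov_re.to_numpy() / denom
        off = corr[~np.eye(len(sds), dtype=bool)]
        if np.any(np.abs(off[np.isfinite(off)]) >= cfg.singular_corr_tol):
            reasons.append("random-effect correlation at +/-1 boundary")
    return reasons


def fit_lmm(
    spec: ModelSpec,
    frame: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    reml: bool = True,
    start: "ModelFit | None" = None,
) -> ModelFit:
    """Fit the specified model by REML.

    The random-effects covariance is unstructured.  ``start`` warm-starts
    the covariance search from a previous fit (used heavily during
    backward elimination, where consecutive refits share almost the same
    random structure).  Non-convergence or a numerical failure is
    recorded on the returned fit (``converged`` / ``singular``) rather
    than raised; backward elimination treats such fits as singular.
    """
    cfg = cfg or PipelineConfig()
    if frame["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    X, Z = _design(spec, frame)
    y = frame["outcome"].to_numpy(dtype=float)
    groups = frame["participant"].to_numpy()
    model = sm.MixedLM(y, X, groups=groups, exog_re=Z)
    start_params = None
    if (start is not None and start.converged and start.sigma2 > 0
            and np.isfinite(start.sigma2)
            and set(Z.columns) <= set(start.cov_re.index)):
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        sub = start.cov_re.loc[list(Z.columns), list(Z.columns)].to_numpy()
        try:
            start_params = MixedLMParams.from_components(
                cov_re=sub / start.sigma2)
        except (ValueError, np.linalg.LinAlgError):
            start_params = None
    res = None
    converged = False
    attempts = (["warm", None, "powell"] if start_params is not None
                else [None, "powell"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in attempts:
            try:
                if method == "warm":
                    res = model.fit(reml=reml, method="powell", maxiter=500,
                                    start_params=start_params)
                elif method is None:
                    res = model.fit(reml=reml, maxiter=500)
                else:
                    res = model.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                continue
            if res.converged:
                converged = True
                break
    if res is None:
        nan = pd.Series(np.nan, index=X.columns)
        return ModelFit(spec, nan, nan, pd.DataFrame(np.nan, index=X.columns,
                        columns=X.columns), pd.DataFrame(np.nan,
                        index=Z.columns, columns=Z.columns),
                        float("nan"), -np.inf, False, True,
                        ["optimizer failure"], len(y),
                        frame["participant"].nunique(), frame, X, Z, cfg)
    params = pd.Series(np.asarray(res.fe_params), index=X.columns)
    cov_beta = pd.DataFrame(np.asarray(res.cov_params())[:len(X.columns),
                                                         :len(X.columns)],
                            index=X.columns, columns=X.columns)
    se = pd.Series(np.sqrt(np.diag(cov_beta)), index=X.columns)
    cov_re = pd.DataFrame(np.asarray(res.cov_re), index=Z.columns,
                          columns=Z.columns)
    reasons = _check_singular(cov_re, float(np.std(y, ddof=1)), cfg)
    if not converged:
        reasons = reasons + ["did not converge"]
    return ModelFit(
        spec=spec, params=params, se=se, cov_beta=cov_beta, cov_re=cov_re,
        sigma2=float(res.scale), llf=float(res.llf), converged=converged,
        singular=bool(reasons), singular_reasons=reasons, n_obs=len(y),
        n_groups=frame["participant"].nunique(), frame=frame, X=X, Z=Z,
        cfg=cfg,
    )


def fit_maximal(
    frame: pd.DataFrame,
    outcome: str,
    cfg: PipelineConfig | None = None,
) -> ModelFit:
    """Fit the maximal identifiable model.

    Starts from the full specification (three-way fixed structure, random
    intercept plus slopes for Block, RS and SNR) and removes only the
    random slopes that are structurally aliased with the intercept
    (covariates constant within participant) before fitting.
    """
    spec = ModelSpec(outcome)
    for t in _aliased_random_terms(spec, frame):
        spec = spec.without_random(t)
    return fit_lmm(spec, frame, cfg)


# ---------------------------------------------------------------------------
# backward elimination


def _aliased_random_terms(spec: ModelSpec, frame: pd.DataFrame) -> list[str]:
    """Random slopes whose covariate is constant within every participant.

    Such a slope's within-group design column is proportional to the
    intercept column, so the model is structurally unidentifiable
    (singular by construction) and the slope is removed before fitting.
    """
    aliased = []
    for t in spec.random_terms:
        if t == "intercept":
            continue
        wvar = frame.groupby("participant")[t].var(ddof=0)
        if float(wvar.max()) < 1e-12:
            aliased.append(t)
    return aliased


def _random_lrt(spec: ModelSpec, term: str, frame: pd.DataFrame,
                cfg: PipelineConfig, full: ModelFit) -> tuple[float, ModelFit]:
    """REML likelihood-ratio p-value for dropping one random slope.

    Removing a slope from a q-dimensional unstructured covariance removes
    q parameters (its variance and q-1 covariances); the statistic is
    referred to a plain chi-square on that many df.
    """
    reduced = fit_lmm(spec.without_random(term), frame, cfg, start=full)
    df = len(spec.random_terms)  # q covariance parameters removed
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    return float(stats.chi2.sf(stat, df)), reduced


def backward_eliminate(
    spec: ModelSpec,
    frame: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[ModelFit, list[dict]]:
    """Simplify the maximal model: random structure first, then fixed.

    Phase 0 removes structurally aliased random slopes; while the fit is
    singular or non-convergent, the weakest remaining slope is removed.
    Phase 1 repeatedly drops the random slope with the largest REML-LRT
    p-value >= ``alpha_random``.  Phase 2 repeatedly drops the droppable
    fixed term (one not contained in a retained interaction) with the
    largest Wald p-value >= ``alpha_fixed``, refitting after each drop.
    Returns the final fit and the full elimination trail.
    """
    cfg = cfg or PipelineConfig()
    trail: list[dict] = []
    for t in _aliased_random_terms(spec, frame):
        spec = spec.without_random(t)
        trail.append({"phase": "random", "action": "drop", "term": t,
                      "reason": "aliased with random intercept"})
    fit = fit_lmm(spec, frame, cfg)
    # singular fits: strip the slopes that *are* the singularity — a failed
    # optimization, or a slope whose own variance has collapsed.  A boundary
    # correlation or a degenerate intercept variance is left alone: the REML
    # LRT below remains valid on the boundary and decides those cases.
    y_sd = float(frame["outcome"].std(ddof=1))
    while len(spec.random_terms) > 1:
        slopes = [t for t in spec.random_terms if t != "intercept"]
        sds = {t: float(np.sqrt(max(fit.cov_re.loc[t, t], 0.0)))
               if np.isfinite(fit.cov_re.loc[t, t]) else 0.0 for t in slopes}
        if not fit.converged:
            weakest = min(sds, key=sds.get)
            reason = "no converged fit"
        else:
            collapsed = [t for t in slopes
                         if sds[t] < cfg.singular_sd_rel_tol * y_sd]
            if not collapsed:
                break
            weakest = min(collapsed, key=sds.get)
            reason = "singular fit: " + "; ".join(fit.singular_reasons)
        spec = spec.without_random(weakest)
        trail.append({"phase": "random", "action": "drop", "term": weakest,
                      "reason": reason})
        fit = fit_lmm(spec, frame, cfg, start=fit)
    # LRT pruning of random slopes
    while True:
        slopes = [t for t in spec.random_terms if t != "intercept"]
        if not slopes:
            break
        pvals: dict[str, tuple[float, ModelFit]] = {}
        for t in slopes:
            pvals[t] = _random_lrt(spec, t, frame, cfg, fit)
        worst = max(pvals, key=lambda t: pvals[t][0])
        p, reduced = pvals[worst]
        if p >= cfg.alpha_random:
            spec = spec.without_random(worst)
            trail.append({"phase": "random", "action": "drop", "term": worst,
                          "p": p, "reason": f"LRT p={p:.3g} >= {cfg.alpha_random}"})
            fit = reduced
        else:
            for t, (pv, _) in pvals.items():
                trail.append({"phase": "random", "action": "keep", "term": t,
                              "p": pv})
            break
    # Wald pruning of fixed effects
    while True:
        droppable = spec.droppable_fixed()
        if not droppable:
            break
        pv = fit.pvalues
        cand = {t: float(pv[t]) for t in droppable}
        worst = max(cand, key=cand.get)
        if cand[worst] >= cfg.alpha_fixed:
            spec = spec.without_fixed(worst)
            trail.append({"phase": "fixed", "action": "drop", "term": worst,
                          "p": cand[worst]})
            fit = fit_lmm(spec, frame, cfg, start=fit)
        else:
            for t, p in cand.items():
                trail.append({"phase": "fixed", "action": "keep", "term": t,
                              "p": p})
            break
    return fit, trail


# ---------------------------------------------------------------------------
# derived statistics


def anova_type2(fit: ModelFit) -> pd.DataFrame:
    """Type II Wald chi-square table.

    Each term is tested after all others except its higher-order
    relatives: the Wald statistic for term T comes from a refit of the
    model without any interaction containing T (the full fit when none
    does).  All terms here are single-coefficient, so chi2 = (beta/SE)^2
    on 1 df.
    """
    rows = []
    for term in fit.spec.fixed_terms:
        higher = [t for t in fit.spec.fixed_terms if _contains(t, term)]
        if higher:
            spec_t = fit.spec
            for h in sorted(higher, key=lambda t: -len(_parts(t))):
                if h in spec_t.fixed_terms:
                    spec_t = spec_t.without_fixed(h)
            sub = fit_lmm(spec_t, fit.frame, fit.cfg, start=fit)
        else:
            sub = fit
        z = sub.coef(term) / float(sub.se[term])
        chi2 = z * z
        rows.append({"term": term, "chi2": chi2, "df": 1,
                     "p": float(stats.chi2.sf(chi2, 1))})
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["term", "chi2", "df", "p"])
    aliased = np.linalg.matrix_rank(fit.X.to_numpy()) < fit.X.shape[1]
    if aliased:
        raise ValueError("rank-deficient fixed design; aliased columns: "
                         f"{list(fit.X.columns)}")
    return out


def r2_from_components(var_fixed: float, var_random: float,
                       var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R2 from variance components."""
    total = var_fixed + var_random + var_resid
    return var_fixed / total, (var_fixed + var_random) / total


def r2_nakagawa(fit: ModelFit) -> tuple[float, float]:
    """Variance-partition R2 for a Gaussian mixed model.

    ``var_fixed`` is the variance of the fixed-effect linear predictor
    over the data; ``var_random`` is the mean over observations of
    ``z_i' G z_i`` (the random-effect variance contribution); the
    residual variance is the REML scale.
    """
    eta = fit.X.to_numpy() @ fit.params.to_numpy()
    var_f = float(np.var(eta, ddof=1))
    Z = fit.Z.to_numpy()
    G = fit.cov_re.to_numpy()
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", Z, G, Z)))
    return r2_from_components(var_f, var_r, fit.sigma2)


def vif(fit: ModelFit) -> pd.Series:
    """Variance inflation factor of each non-intercept fixed column."""
    cols = [c for c in fit.X.columns if c != "Intercept"]
    if len(cols) < 2:
        raise ValueError("VIF needs at least two fixed-effect columns")
    out = {}
    for c in cols:
        yj = fit.X[c].to_numpy()
        others = fit.X[["Intercept"] + [o for o in cols if o != c]].to_numpy()
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def median_split(rs_scores: np.ndarray | pd.Series) -> np.ndarray:
    """Label each score 'high' (strictly above the sample median) or 'low'.

    Ties at the median go to the low group, so with an odd number of
    distinct scores the low group is larger by one.
    """
    x = np.asarray(rs_scores, dtype=float)
    if len(x) < 2:
        raise ValueError("median split needs at least two scores")
    med = float(np.median(x))
    labels = np.where(x > med, "high", "low")
    if (labels == "low").all():
        logger.warning("all scores at or below the median; single group")
    return labels


@dataclass
class PosthocResult:
    """Simple slopes and SNR-grid contrasts for the WM-capacity groups."""

    m_low: float
    m_high: float
    slopes: pd.DataFrame          # group, slope, se, ci_low, ci_high
    slope_diff: float
    slope_diff_se: float
    slope_diff_p: float
    grid: pd.DataFrame | None = None  # snr_c, diff, se, z, p


def _group_means_centered_rs(fit: ModelFit) -> tuple[float, float]:
    per = fit.frame.groupby("participant")["RS"].first()
    labels = median_split(per.to_numpy())
    m_low = float(per.to_numpy()[labels == "low"].mean())
    m_high = float(per.to_numpy()[labels == "high"].mean())
    return m_low, m_high


def simple_slopes(fit: ModelFit,
                  group_means: tuple[float, float] | None = None) -> PosthocResult:
    """Conditional SNR slope at each WM group's mean centered RS.

    ``slope_g = b_SNR + b_RSxSNR * m_g`` exactly; standard errors follow
    from the fixed-effect covariance (delta method, here exact since the
    slope is linear in the estimates).  The group difference is
    ``b_RSxSNR * (m_high - m_low)`` with a Wald z test.
    """
    if group_means is None:
        m_low, m_high = _group_means_centered_rs(fit)
    else:
        m_low, m_high = group_means
    b_snr = fit.coef("SNR")
    b_int = fit.coef("RS:SNR")
    v_snr = fit.cov("SNR", "SNR")
    v_int = fit.cov("RS:SNR", "RS:SNR")
    c = fit.cov("SNR", "RS:SNR")
    rows = []
    for g, m in (("low", m_low), ("high", m_high)):
        slope = b_snr + b_int * m
        var = v_snr + m * m * v_int + 2 * m * c
        se = float(np.sqrt(max(var, 0.0)))
        rows.append({"group": g, "slope": slope, "se": se,
                     "ci_low": slope - 1.96 * se, "ci_high": slope + 1.96 * se})
    dm = m_high - m_low
    diff = b_int * dm
    diff_se = float(np.sqrt(max(v_int, 0.0))) * abs(dm)
    if diff_se > 0:
        p = float(2.0 * stats.norm.sf(abs(diff) / diff_se))
    else:
        p = 1.0
    return PosthocResult(
        m_low=m_low, m_high=m_high, slopes=pd.DataFrame(rows),
        slope_diff=diff, slope_diff_se=diff_se, slope_diff_p=p,
    )


def snr_grid_contrasts(
    fit: ModelFit,
    group_means: tuple[float, float] | None = None,
    grid: np.ndarray | None = None,
) -> PosthocResult:
    """Predicted high-minus-low group difference at each centered SNR.

    At grid value s the difference in predicted outcome is
    ``(b_RS + b_RSxSNR * s) * (m_high - m_low)``; each point gets a Wald
    z and an unadjusted p-value (only two groups are compared per point).
    """
    result = simple_slopes(fit, group_means)
    if grid is None:
        grid = np.arange(-5.0, 8.0, 1.0)
    dm = result.m_high - result.m_low
    b_rs = fit.coef("RS")
    b_int = fit.coef("RS:SNR")
    v_rs = fit.cov("RS", "RS")
    v_int = fit.cov("RS:SNR", "RS:SNR")
    c = fit.cov("RS", "RS:SNR")
    rows = []
    for s in np.asarray(grid, dtype=float):
        diff = (b_rs + b_int * s) * dm
        var = (v_rs + s * s * v_int + 2 * s * c) * dm * dm
        se = float(np.sqrt(max(var, 0.0)))
        z = diff / se if se > 0 else 0.0
        rows.append({"snr_c": s, "diff": diff, "se": se, "z": z,
                     "p": float(2.0 * stats.norm.sf(abs(z))) if se > 0 else 1.0})
    result.grid = pd.DataFrame(rows)
    return result


# ---------------------------------------------------------------------------
# reporting


def build_report(
    fit: ModelFit,
    trail: list[dict] | None = None,
    posthoc: PosthocResult | None = None,
) -> dict:
    """Assemble the JSON-ready report for a fitted model."""
    ci = fit.ci
    coeffs = [{
        "term": t,
        "label": TABLE_LABELS.get(t, t),
        "estimate": float(fit.params[t]),
        "se": float(fit.se[t]),
        "ci_low": float(ci.loc[t, "low"]),
        "ci_high": float(ci.loc[t, "high"]),
        "p": float(fit.pvalues[t]),
    } for t in fit.params.index]
    report: dict = {
        "outcome": fit.spec.outcome,
        "coefficients": coeffs,
        "random_terms": list(fit.spec.random_terms),
        "variance_components": {
            "cov_re": fit.cov_re.to_numpy().tolist(),
            "cov_re_names": list(fit.cov_re.index),
            "sigma2": fit.sigma2,
        },
        "loglik_reml": fit.llf,
        "converged": fit.converged,
        "singular": fit.singular,
        "n_obs": fit.n_obs,
        "n_participants": fit.n_groups,
    }
    try:
        table = anova_type2(fit)
        report["anova_type2"] = table.to_dict(orient="records")
    except ValueError:
        report["anova_type2"] = None
    marginal, conditional = r2_nakagawa(fit)
    report["r2_marginal"] = marginal
    report["r2_conditional"] = conditional
    try:
        report["vif"] = {k: (None if not np.isfinite(v) else float(v))
                         for k, v in vif(fit).items()}
    except ValueError:
        report["vif"] = None
    if trail is not None:
        report["elimination_trail"] = trail
    if posthoc is not None:
        report["posthoc"] = {
            "m_low": posthoc.m_low,
            "m_high": posthoc.m_high,
            "slopes": posthoc.slopes.to_dict(orient="records"),
            "slope_diff": posthoc.slope_diff,
            "slope_diff_p": posthoc.slope_diff_p,
            "grid": (posthoc.grid.to_dict(orient="records")
                     if posthoc.grid is not None else None),
        }
    return report
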