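"""Mixed-model workflow: centering, fitting, elimination, derived stats."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from swirpupil import mixed_model as mm, simulate
from swirpupil.config import GeneratorConfig, PipelineConfig


def _sim_frame(n_participants, seed, outcome="pupil_baseline", **gen_kwargs):
    cfg = GeneratorConfig(n_participants=n_participants, **gen_kwargs)
    df, truth = simulate.simulate_block_data(cfg, np.random.default_rng(seed))
    frame, offsets = mm.prepare_model_frame(df, outcome)
    return frame, truth


def _fake_fit(params: dict, cov: pd.DataFrame | None = None) -> mm.ModelFit:
    """A hand-assembled fit for exact-arithmetic checks of the post hocs."""
    idx = list(params)
    p = pd.Series(params)
    if cov is None:
        cov = pd.DataFrame(np.zeros((len(idx), len(idx))), index=idx, columns=idx)
    se = pd.Series(np.sqrt(np.diag(cov)), index=idx)
    dummy = pd.DataFrame({"participant": ["a", "b"], "RS": [0.0, 1.0]})
    X = pd.DataFrame({"Intercept": [1.0, 1.0]})
    Z = pd.DataFrame({"intercept": [1.0, 1.0]})
    spec = mm.ModelSpec("pupil_baseline", fixed_terms=("Block", "RS", "SNR",
                                                       "RS:SNR"),
                        random_terms=("intercept",))
    return mm.ModelFit(spec=spec, params=p, se=se, cov_beta=cov,
                       cov_re=pd.DataFrame([[0.0]], index=["intercept"],
                                           columns=["intercept"]),
                       sigma2=1.0, llf=0.0, converged=True, singular=False,
                       singular_reasons=[], n_obs=2, n_groups=2,
                       frame=dummy, X=X, Z=Z)


# ---------------------------------------------------------------------------
# centering


def test_center_block_range():
    df = pd.DataFrame({"participant": "p", "block": np.arange(1, 29),
                       "rs_score": 40.0, "snr_db": 6.0})
    out, offsets = mm.center_predictors(df)
    assert out["Block"].mean() == pytest.approx(0.0)
    assert out["Block"].min() == pytest.approx(-13.5)
    assert out["Block"].max() == pytest.approx(13.5)
    assert offsets["Block"] == pytest.approx(14.5)


def test_centering_is_idempotent(rng):
    df = pd.DataFrame({
        "participant": np.repeat([f"p{i}" for i in range(5)], 4),
        "block": np.tile(np.arange(1, 5), 5),
        "rs_score": np.repeat(rng.normal(42, 12, 5), 4),
        "snr_db": np.repeat(rng.normal(6.6, 3, 5), 4),
    })
    once, _ = mm.center_predictors(df)
    twice, _ = mm.center_predictors(once)
    for col in ("Block", "RS", "SNR"):
        np.testing.assert_allclose(twice[col], once[col], atol=1e-12)


def test_centered_snr_range_matches_observed_spread():
    # SNRs spanning 2.60..13.4 dB around a 6.65 mean center to ~[-4.05, 6.75]
    snr = np.array([2.60, 4.0, 6.65, 9.0, 13.4])
    df = pd.DataFrame({"participant": list("abcde"), "block": 1,
                       "rs_score": 40.0, "snr_db": snr})
    out, _ = mm.center_predictors(df)
    assert out["SNR"].min() == pytest.approx(2.60 - snr.mean())
    assert out["SNR"].max() == pytest.approx(13.4 - snr.mean())


def test_constant_predictor_zeroed_with_warning(caplog):
    df = pd.DataFrame({"participant": list("ab"), "block": [3, 3],
                       "rs_score": [40.0, 50.0], "snr_db": [6.0, 7.0]})
    with caplog.at_level("WARNING", logger="swirpupil"):
        out, _ = mm.center_predictors(df)
    assert (out["Block"] == 0).all()
    assert any("constant" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# fitting


def test_intercept_only_truth_recovered_to_machine_precision():
    frame, _ = _sim_frame(30, seed=2, b_block=0, b_rs=0, b_snr=0, b_rs_snr=0,
                          tau0=0.0, tau_block=0.0, sigma_eps=1e-6,
                          tau_g_block=0.0)
    spec = mm.ModelSpec("pupil_baseline", fixed_terms=(),
                        random_terms=("intercept",))
    fit = mm.fit_lmm(spec, frame)
    assert abs(fit.coef("Intercept") - 3.48) < 1e-6


def test_singularity_rule_on_constructed_covariances():
    """Zero variance or a boundary correlation marks a fit singular."""
    cfg = PipelineConfig()
    names = ["intercept", "Block"]

    def check(mat):
        return mm._check_singular(
            pd.DataFrame(mat, index=names, columns=names), y_sd=0.5, cfg=cfg)

    assert any("Block" in r for r in check([[0.09, 0.0], [0.0, 0.0]]))
    rho = 0.9995
    sd = np.array([0.3, 0.003])
    boundary = np.outer(sd, sd) * np.array([[1, rho], [rho, 1]])
    assert any("correlation" in r for r in check(boundary))
    healthy = np.outer(sd, sd) * np.array([[1, 0.1], [0.1, 1]])
    assert check(healthy) == []


def test_zero_slope_variance_generator_loses_its_random_slope():
    # with no true Block-slope heterogeneity the slope does not survive
    # the random-structure phase (dropped as singular or by LRT)
    frame, _ = _sim_frame(40, seed=3, tau_block=0.0)
    fit, trail = mm.backward_eliminate(mm.ModelSpec("pupil_baseline"), frame)
    assert fit.spec.random_terms == ("intercept",)
    dropped = [e for e in trail if e["action"] == "drop" and e["term"] == "Block"
               and e["phase"] == "random"]
    assert dropped


def test_maximal_model_drops_aliased_participant_level_slopes():
    frame, _ = _sim_frame(25, seed=4)
    fit = mm.fit_maximal(frame, "pupil_baseline")
    # RS and SNR are constant within participant: their random slopes are
    # exactly collinear with the random intercept and cannot be estimated
    assert set(fit.spec.random_terms) == {"intercept", "Block"}
    assert fit.spec.fixed_terms == mm.FIXED_TERMS_FULL


def test_fixed_effects_match_lme4_reference(tmp_path):
    """Independent oracle: lme4::lmer on the same small dataset."""
    assert shutil.which("Rscript"), "Rscript expected on PATH"
    frame, _ = _sim_frame(25, seed=5)
    spec = mm.ModelSpec("pupil_baseline",
                        fixed_terms=("Block", "RS", "SNR", "RS:SNR"),
                        random_terms=("intercept", "Block"))
    fit = mm.fit_lmm(spec, frame)
    csv = tmp_path / "d.csv"
    frame.to_csv(csv, index=False)
    script = tmp_path / "ref.R"
    script.write_text(f"""
suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
d$RSxSNR <- d$RS * d$SNR
m <- lmer(outcome ~ Block + RS + SNR + RSxSNR + (1 + Block | participant),
          data = d, REML = TRUE)
cat(toJSON(list(fe = as.list(fixef(m)), ll = as.numeric(logLik(m))),
           digits = 12, auto_unbox = TRUE))
""")
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    ref = json.loads(out.stdout)
    pairs = {"(Intercept)": "Intercept", "Block": "Block", "RS": "RS",
             "SNR": "SNR", "RSxSNR": "RS:SNR"}
    for rname, term in pairs.items():
        assert fit.coef(term) == pytest.approx(ref["fe"][rname], abs=2e-4)
    assert fit.llf == pytest.approx(ref["ll"], abs=0.05)


# ---------------------------------------------------------------------------
# backward elimination


def test_null_model_reduces_to_intercept_only():
    frame, _ = _sim_frame(40, seed=100, b_block=0, b_rs=0, b_snr=0, b_rs_snr=0,
                          tau_block=0.0)
    fit, trail = mm.backward_eliminate(mm.ModelSpec("pupil_baseline"), frame)
    assert fit.spec.fixed_terms == ()
    assert fit.spec.random_terms == ("intercept",)
    assert any(e["phase"] == "random" and e["action"] == "drop" for e in trail)


def test_elimination_recovers_generating_structure():
    frame, _ = _sim_frame(100, seed=7)
    fit, trail = mm.backward_eliminate(mm.ModelSpec("pupil_baseline"), frame)
    assert set(fit.spec.fixed_terms) == {"Block", "RS", "SNR", "RS:SNR"}
    assert set(fit.spec.random_terms) == {"intercept", "Block"}


def test_elimination_keeps_random_slope_without_fixed_counterpart():
    # recall: RS fixed effect only, but Block-slope heterogeneity remains
    frame, _ = _sim_frame(100, seed=8, outcome="recall_pct")
    fit, _ = mm.backward_eliminate(mm.ModelSpec("recall_pct"), frame)
    assert "RS" in fit.spec.fixed_terms
    assert "Block" not in fit.spec.fixed_terms
    assert "Block" in fit.spec.random_terms


def test_marginality_enforced_in_spec():
    with pytest.raises(ValueError):
        mm.ModelSpec("pupil_baseline", fixed_terms=("RS:SNR",))


# ---------------------------------------------------------------------------
# ANOVA


def test_single_coefficient_wald_identity():
    frame, _ = _sim_frame(30, seed=9)
    spec = mm.ModelSpec("pupil_baseline",
                        fixed_terms=("Block", "RS", "SNR", "RS:SNR"),
                        random_terms=("intercept", "Block"))
    fit = mm.fit_lmm(spec, frame)
    table = mm.anova_type2(fit).set_index("term")
    for term in ("Block",):  # not contained in any retained interaction
        z = fit.coef(term) / float(fit.se[term])
        assert table.loc[term, "chi2"] == pytest.approx(z * z)
        assert table.loc[term, "df"] == 1


def test_type2_equals_type3_on_orthogonal_balanced_design():
    # balanced 2x2 factorial of RS/SNR over participants makes every fixed
    # column exactly orthogonal, so testing a main effect before or after
    # its interactions coincides
    rng = np.random.default_rng(10)
    rows = []
    pid = 0
    for rs in (-1.0, 1.0):
        for snr in (-1.0, 1.0):
            for _ in range(6):
                pid += 1
                u0 = rng.normal(0, 0.3)
                for b in range(1, 9):
                    bc = b - 4.5
                    y = 3.4 - 0.01 * bc + 0.05 * rs - 0.05 * snr + u0 \
                        + rng.normal(0, 0.1)
                    rows.append({"participant": f"p{pid}", "block": b,
                                 "rs_score": rs, "snr_db": snr, "outcome": y})
    frame = pd.DataFrame(rows)
    frame, _ = mm.center_predictors(frame)
    spec = mm.ModelSpec("pupil_baseline", random_terms=("intercept",))
    fit = mm.fit_lmm(spec, frame)
    table = mm.anova_type2(fit).set_index("term")
    for term in ("Block", "RS", "SNR"):
        z = fit.coef(term) / float(fit.se[term])  # Type III from the full fit
        assert table.loc[term, "chi2"] == pytest.approx(z * z, rel=0.05)


def test_block_main_effect_significant_at_study_scale():
    frame, _ = _sim_frame(60, seed=11)
    fit, _ = mm.backward_eliminate(mm.ModelSpec("pupil_baseline"), frame)
    table = mm.anova_type2(fit).set_index("term")
    assert table.loc["Block", "p"] < 0.05


# ---------------------------------------------------------------------------
# R2, VIF, median split


def test_r2_closed_form_components():
    marginal, conditional = mm.r2_from_components(0.458, 0.488, 0.054)
    assert marginal == pytest.approx(0.458)
    assert conditional == pytest.approx(0.946)


def test_r2_no_random_variance_collapses_to_marginal():
    m, c = mm.r2_from_components(0.4, 0.0, 0.6)
    assert m == c == pytest.approx(0.4)


def test_r2_null_model_is_zero():
    m, _ = mm.r2_from_components(0.0, 0.5, 0.5)
    assert m == 0.0


def test_r2_of_fit_accounts_for_random_slopes():
    frame, _ = _sim_frame(80, seed=12)
    spec = mm.ModelSpec("pupil_baseline",
                        fixed_terms=("Block", "RS", "SNR", "RS:SNR"),
                        random_terms=("intercept", "Block"))
    fit = mm.fit_lmm(spec, frame)
    marginal, conditional = mm.r2_nakagawa(fit)
    assert 0 < marginal < conditional < 1
    # sigma_eps = 0.1 against tau0 = 0.3 + fixed spread: conditional is high
    assert conditional > 0.85


def test_vif_orthogonal_columns():
    n = 1000
    X = pd.DataFrame({"Intercept": 1.0,
                      "Block": np.tile([-1.0, 1.0], n // 2),
                      "RS": np.repeat([-1.0, 1.0], n // 2)})
    fit = _fake_fit({"Intercept": 0.0, "Block": 0.0, "RS": 0.0})
    fit.X = X
    assert np.allclose(mm.vif(fit).to_numpy(), 1.0)


def test_vif_duplicated_column_is_infinite(rng):
    x = rng.normal(size=500)
    X = pd.DataFrame({"Intercept": 1.0, "RS": x, "SNR": x})
    fit = _fake_fit({"Intercept": 0.0, "RS": 0.0, "SNR": 0.0})
    fit.X = X
    assert np.isinf(mm.vif(fit)["RS"])


def test_vif_of_centered_interaction_stays_low(rng):
    n = 10_000
    rs = rng.normal(0, 11.99, n)
    snr = rng.normal(0, 3.08, n)
    X = pd.DataFrame({"Intercept": 1.0, "RS": rs, "SNR": snr,
                      "RS:SNR": rs * snr})
    fit = _fake_fit({"Intercept": 0.0, "RS": 0.0, "SNR": 0.0, "RS:SNR": 0.0})
    fit.X = X
    assert (mm.vif(fit) < 1.3).all()


def test_median_split_21_scores_gives_11_low_10_high(rng):
    scores = rng.choice(np.arange(25, 76), size=21, replace=False)
    labels = mm.median_split(scores)
    assert (labels == "low").sum() == 11
    assert (labels == "high").sum() == 10


def test_median_split_even_and_ties():
    assert mm.median_split([1, 2, 3, 4]).tolist() == ["low", "low",
                                                      "high", "high"]
    labels = mm.median_split([1, 5, 5, 5, 9])
    assert labels.tolist() == ["low", "low", "low", "low", "high"]


# ---------------------------------------------------------------------------
# simple slopes and grid contrasts


def test_simple_slopes_reproduce_published_arithmetic():
    fit = _fake_fit({"Intercept": 3.48, "Block": -0.01, "RS": 0.01,
                     "SNR": -0.09, "RS:SNR": -0.01})
    res = mm.simple_slopes(fit, group_means=(-9.57, 9.57))
    slopes = {r["group"]: r["slope"] for r in res.slopes.to_dict("records")}
    assert round(slopes["high"], 2) == -0.19
    assert round(slopes["low"], 2) == 0.01


def test_no_interaction_means_equal_slopes_and_p_one():
    fit = _fake_fit({"Intercept": 3.48, "Block": -0.01, "RS": 0.01,
                     "SNR": -0.09, "RS:SNR": 0.0})
    res = mm.simple_slopes(fit, group_means=(-9.57, 9.57))
    slopes = {r["group"]: r["slope"] for r in res.slopes.to_dict("records")}
    assert slopes["low"] == slopes["high"] == pytest.approx(-0.09)
    assert res.slope_diff_p == pytest.approx(1.0)


def test_posthoc_is_exact_linear_function_of_estimates():
    frame, _ = _sim_frame(50, seed=13)
    spec = mm.ModelSpec("pupil_baseline",
                        fixed_terms=("Block", "RS", "SNR", "RS:SNR"),
                        random_terms=("intercept", "Block"))
    fit = mm.fit_lmm(spec, frame)
    res = mm.snr_grid_contrasts(fit)
    # slope_g = c' beta with c = (0,0,0,1,m_g); SE = sqrt(c' Sigma c)
    beta = fit.params
    Sigma = fit.cov_beta
    for row in res.slopes.to_dict("records"):
        m = res.m_low if row["group"] == "low" else res.m_high
        c = pd.Series(0.0, index=beta.index)
        c["SNR"], c["RS:SNR"] = 1.0, m
        assert row["slope"] == pytest.approx(float(c @ beta), abs=1e-12)
        assert row["se"] == pytest.approx(
            float(np.sqrt(c @ Sigma @ c)), abs=1e-12)
    dm = res.m_high - res.m_low
    for row in res.grid.to_dict("records"):
        c = pd.Series(0.0, index=beta.index)
        c["RS"], c["RS:SNR"] = dm, row["snr_c"] * dm
        assert row["diff"] == pytest.approx(float(c @ beta), abs=1e-12)
        assert row["se"] == pytest.approx(
            float(np.sqrt(c @ Sigma @ c)), abs=1e-12)


def test_grid_differences_are_collinear_in_snr():
    fit = _fake_fit({"Intercept": 3.48, "Block": -0.01, "RS": 0.01,
                     "SNR": -0.09, "RS:SNR": -0.01})
    res = mm.snr_grid_contrasts(fit, group_means=(-9.57, 9.57))
    diffs = res.grid["diff"].to_numpy()
    second = np.diff(diffs, n=2)
    np.testing.assert_allclose(second, 0.0, atol=1e-12)
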