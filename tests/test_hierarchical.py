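"""Structure, gradients, identifiability and summaries of the multilevel
log-normal decay model (fast checks; recovery runs live with the
acceptance suite)."""

import math

import numpy as np
import pandas as pd
import pytest

from ema_rt import hierarchical as hm
from ema_rt.simulate import SimConfig, generate_cohort
from tests.conftest import toy_records

FAST_MCMC = hm.McmcConfig(chains=2, warmup=200, draws=200,
                          target_accept=0.9, seed=0)


def small_model(small_cohort, **spec_kw):
    _, records, labels, _ = small_cohort
    spec = hm.HierarchicalSpec(mcmc=FAST_MCMC, **spec_kw)
    feeling = records[records["item"] == "feeling"]
    return hm.build(feeling, labels, spec), spec


def test_unmoderated_none_variant_has_no_subject_latents(small_cohort):
    model, _ = small_model(small_cohort, variant="none", moderated=False)
    # fixed effects (3) + option offsets (6) + residual scale (1)
    assert model.n_params == 10
    assert not any(n in model.slices for n in ("z_a", "z_b", "u_c", "eps_c"))


@pytest.mark.parametrize("variant,latents", [
    ("b_only", {"z_b"}),
    ("a_and_b", {"z_a", "z_b"}),
    ("b_and_c", {"z_b", "u_c", "eps_c"}),
    ("full", {"z_a", "z_b", "u_c", "eps_c"}),
])
def test_variant_latent_structure(small_cohort, variant, latents):
    model, _ = small_model(small_cohort, variant=variant)
    present = {n for n in ("z_a", "z_b", "u_c", "eps_c")
               if n in model.slices}
    assert present == latents


def test_multi_item_records_rejected(small_cohort):
    _, records, labels, _ = small_cohort
    with pytest.raises(ValueError, match="item"):
        hm.build(records, labels, hm.HierarchicalSpec())


def test_unlabeled_subject_rejected(small_cohort):
    _, records, labels, _ = small_cohort
    with pytest.raises(ValueError, match="label"):
        hm.build(records[records["item"] == "feeling"], labels.iloc[1:],
                 hm.HierarchicalSpec())


def test_small_subjects_excluded_with_audit(small_cohort):
    _, records, labels, _ = small_cohort
    feeling = records[records["item"] == "feeling"]
    sid = feeling["subject_id"].iloc[0]
    clipped = pd.concat([feeling[feeling["subject_id"] != sid],
                         feeling[feeling["subject_id"] == sid].head(3)])
    model = hm.build(clipped, labels, hm.HierarchicalSpec())
    assert model.audit["excluded_small_subjects"] == [sid]
    assert sid not in model.subject_ids


@pytest.mark.parametrize("likelihood,prior_family", [
    ("lognormal", "normal"), ("student_t", "normal"),
    ("lognormal", "student_t"),
])
def test_gradient_matches_finite_differences(small_cohort, likelihood,
                                             prior_family):
    model, _ = small_model(small_cohort, variant="full", moderated=True,
                           likelihood=likelihood,
                           prior_family=prior_family)
    rng = np.random.default_rng(1)
    x = model.initial_point(rng)
    _, grad = model.logp_and_grad(x)
    idx = rng.choice(model.n_params, size=30, replace=False)
    h = 1e-6
    for i in idx:
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fd = (model.logp_and_grad(xp)[0]
              - model.logp_and_grad(xm)[0]) / (2 * h)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


@pytest.fixture(scope="module")
def tiny_posterior(small_cohort):
    _, records, labels, _ = small_cohort
    spec = hm.HierarchicalSpec(variant="b_and_c", moderated=True,
                               mcmc=FAST_MCMC)
    return hm.fit(records[records["item"] == "feeling"], labels, spec)


def test_alpha_sum_to_zero_every_draw(tiny_posterior):
    derived = tiny_posterior.model.subject_params(tiny_posterior.flat)
    sums = derived["alpha"].sum(axis=1)
    assert np.max(np.abs(sums)) < 1e-12


def test_positivity_of_linked_parameters(tiny_posterior):
    derived = tiny_posterior.model.subject_params(tiny_posterior.flat)
    assert np.all(derived["theta_a"] > 0)
    assert np.all(derived["theta_b"] > 0)
    assert np.all(derived["sigma_log"] > 0)


def test_sampling_deterministic_given_seed(small_cohort):
    _, records, labels, _ = small_cohort
    spec = hm.HierarchicalSpec(variant="b_only", moderated=False,
                               mcmc=hm.McmcConfig(chains=1, warmup=100,
                                                  draws=100, seed=4,
                                                  target_accept=0.9))
    feeling = records[records["item"] == "feeling"]
    p1 = hm.fit(feeling, labels, spec)
    p2 = hm.fit(feeling, labels, spec)
    assert np.array_equal(p1.draws, p2.draws)


def test_group_effect_enumeration(tiny_posterior):
    """Hand-set beta1 draws {0, log 2, log 4}: median 2, P(inc) = 2/3."""
    post = tiny_posterior
    draws = post.draws.copy()
    slot = post.model.slices["beta1_b"].start
    flatview = draws.reshape(-1, draws.shape[-1])
    n = flatview.shape[0]
    third = n // 3
    flatview[:third, slot] = 0.0
    flatview[third:2 * third, slot] = math.log(2)
    flatview[2 * third:, slot] = math.log(4)
    hacked = hm.Posterior(model=post.model, spec=post.spec, draws=draws,
                          chain_stats=[], rhat_max=1.0, ess_min=1.0,
                          divergence_frac=0.0, reliable=True, warnings=[])
    eff = hm.group_effect_summary(hacked, "theta_b")
    assert eff.ratio_median == pytest.approx(2.0)
    assert eff.p_increase == pytest.approx((n - third) / n, abs=1e-12)
    assert eff.cri_low <= eff.ratio_median <= eff.cri_high


def test_group_effect_constant_draws(tiny_posterior):
    post = tiny_posterior
    draws = post.draws.copy()
    slot = post.model.slices["beta1_c"].start
    draws.reshape(-1, draws.shape[-1])[:, slot] = math.log(2)
    hacked = hm.Posterior(model=post.model, spec=post.spec, draws=draws,
                          chain_stats=[], rhat_max=1.0, ess_min=1.0,
                          divergence_frac=0.0, reliable=True, warnings=[])
    eff = hm.group_effect_summary(hacked, "exp_theta_c")
    assert eff.ratio_median == pytest.approx(2.0)
    assert (eff.cri_low, eff.cri_high) == (pytest.approx(2.0),
                                           pytest.approx(2.0))
    assert eff.p_increase == 1.0


def test_group_effect_requires_moderation(small_cohort):
    _, records, labels, _ = small_cohort
    spec = hm.HierarchicalSpec(variant="none", moderated=False,
                               mcmc=hm.McmcConfig(chains=1, warmup=80,
                                                  draws=80, seed=1,
                                                  target_accept=0.8))
    post = hm.fit(records[records["item"] == "feeling"], labels, spec)
    with pytest.raises(ValueError, match="moderated"):
        hm.group_effect_summary(post, "theta_b")
    with pytest.raises(ValueError, match="parameter"):
        hm.group_effect_summary(post, "sigma_log")


def test_duplicate_variant_loo_ties(tiny_posterior):
    table = hm.compare_loo([("one", tiny_posterior),
                            ("two", tiny_posterior)])
    diff = abs(table["elpd_loo"].iloc[0] - table["elpd_loo"].iloc[1])
    assert diff < 1e-9
    assert table["frac_pareto_k_le_0_7"].between(0, 1).all()


def test_loo_rejects_mismatched_observations(small_cohort, tiny_posterior):
    _, records, labels, _ = small_cohort
    spec = hm.HierarchicalSpec(variant="none", moderated=False,
                               mcmc=hm.McmcConfig(chains=1, warmup=80,
                                                  draws=80, seed=1,
                                                  target_accept=0.8))
    other = hm.fit(records[records["item"] == "appetite"], labels, spec)
    with pytest.raises(ValueError, match="observations"):
        hm.compare_loo([("a", tiny_posterior), ("b", other)])


def test_ppc_needs_two_bins(tiny_posterior):
    with pytest.raises(ValueError):
        hm.ppc_binned(tiny_posterior, n_bins=1)


def test_ppc_flat_data_predicts_flat():
    """A single subject with constant RT yields a near-constant
    predictive median across time bins."""
    rec = toy_records(np.full(12, 3.0))
    labels = pd.DataFrame({"subject_id": ["s01"], "is_responder": [0]})
    spec = hm.HierarchicalSpec(variant="none", moderated=False,
                               mcmc=hm.McmcConfig(chains=1, warmup=150,
                                                  draws=150, seed=2,
                                                  target_accept=0.9))
    post = hm.fit(rec, labels, spec)
    ppc = hm.ppc_binned(post, n_bins=4, seed=0)
    med = ppc["predictive_median"]
    assert med.max() - med.min() < 0.25 * med.mean()


def test_zero_noise_concentrates_sigma_log():
    """Noiseless log-RTs drive the residual scale toward zero and the
    predictor through the data."""
    t = np.arange(10, dtype=float)
    rt = np.exp(1.2 * np.exp(-0.4 * t) + 0.9)
    rec = toy_records(rt)
    labels = pd.DataFrame({"subject_id": ["s01"], "is_responder": [0]})
    spec = hm.HierarchicalSpec(variant="none", moderated=False,
                               mcmc=hm.McmcConfig(chains=1, warmup=300,
                                                  draws=300, seed=6,
                                                  target_accept=0.9))
    post = hm.fit(rec, labels, spec)
    sigma = post.model.subject_params(post.flat)["sigma_log"]
    assert np.median(sigma) < 0.05
    eta = post.model.eta_draws(post.flat)
    resid = np.log(rt)[None, :] - eta
    assert np.abs(resid.mean(axis=0)).max() < 3 * np.median(sigma) + 0.05


def test_prior_predictive_rts_right_skewed_positive(small_cohort):
    model, _ = small_model(small_cohort, variant="b_and_c", moderated=True)
    rts = hm.prior_predictive(model, n_draws=100, seed=1)
    assert np.all(rts > 0)
    # wide weakly-informative priors can overflow to inf on rare draws;
    # the substantive claim is positivity and right-skew of the bulk
    finite = rts[np.isfinite(rts)]
    assert finite.size / rts.size > 0.99
    assert np.mean(finite) > np.median(finite)


def test_full_variant_elpd_close_when_no_amplitude_heterogeneity():
    """On data without subject-varying amplitude, the full variant's
    ELPD-LOO does not beat the selected (b_and_c) variant by more than a
    few units."""
    cfg = SimConfig(n_subjects=12, n_days=10, sigma_a=1e-9, seed=21,
                    outlier_rate=0.0, missing_rate=0.0)
    records, _, truth = generate_cohort(cfg)
    labels = truth["subjects"][["subject_id", "is_responder"]]
    feeling = records[records["item"] == "feeling"]
    fits = []
    for variant in ("b_and_c", "full"):
        spec = hm.HierarchicalSpec(variant=variant, moderated=False,
                                   mcmc=hm.McmcConfig(chains=1, warmup=250,
                                                      draws=250, seed=13,
                                                      target_accept=0.9))
        fits.append((variant, hm.fit(feeling, labels, spec)))
    table = hm.compare_loo(fits).set_index("variant")
    gain = table.loc["full", "elpd_loo"] - table.loc["b_and_c", "elpd_loo"]
    assert gain < 5.0


def test_sensitivity_suite_covers_truth(small_cohort):
    """All four sensitivity specifications produce decay-rate ratio CrIs
    covering the cohort's true ratio, with reliability flags reported."""
    cfg, records, labels, truth = small_cohort
    feeling = records[records["item"] == "feeling"]
    base = hm.HierarchicalSpec(variant="b_and_c", moderated=True,
                               mcmc=hm.McmcConfig(chains=1, warmup=200,
                                                  draws=200, seed=3,
                                                  target_accept=0.9))
    table = hm.sensitivity_suite(feeling, labels, base)
    assert set(table["specification"]) == {
        "base", "full_random_effects", "student_t_likelihood",
        "student_t_priors"}
    assert set(table["parameter"]) == {"theta_b", "exp_theta_c"}
    true_ratio = np.exp(cfg.beta1_b)
    rows = table[table["parameter"] == "theta_b"]
    covered = ((rows["cri_low"] <= true_ratio)
               & (true_ratio <= rows["cri_high"])).sum()
    assert covered >= 3  # small-cohort CrIs are wide; one miss tolerated
    assert table["reliable"].isin([True, False]).all()


def test_averaged_outcome_single_item_day():
    rec = toy_records([2.0, 4.0], likert=[3, 5])
    avg = hm.averaged_outcome(rec)
    assert list(avg["rt_seconds"]) == [2.0, 4.0]
    assert list(avg["likert"]) == [3, 5]
    assert set(avg["item"]) == {"average"}


def test_average_score_binning_convention():
    assert hm.bin_average_score([4.0])[0] == 4
    assert hm.bin_average_score([1.0])[0] == 1
    assert hm.bin_average_score([7.0])[0] == 7


def test_binning_matches_brute_force_histogram():
    grid = np.arange(1.0, 7.0 + 1e-9, 0.25)
    bins = hm.bin_average_score(grid)
    counts = np.bincount(bins, minlength=8)[1:]
    expect, _ = np.histogram(grid, bins=np.linspace(1, 7, 8))
    np.testing.assert_array_equal(counts, expect)


def test_averaged_outcome_pools_items():
    cfg = SimConfig(n_subjects=4, n_days=6, missing_rate=0.0, seed=5)
    records, _, _ = generate_cohort(cfg)
    avg = hm.averaged_outcome(records)
    assert len(avg) == 4 * 6
    one = records[(records.subject_id == avg.subject_id.iloc[0])
                  & (records.day_index == avg.day_index.iloc[0])]
    assert avg["rt_seconds"].iloc[0] == pytest.approx(
        one["rt_seconds"].mean())
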