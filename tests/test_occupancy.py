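"""Hierarchical logistic occupancy model: sampler correctness against an
independent maximum-likelihood oracle, posterior summaries, the interval
non-overlap classification and the convergence diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from reefassoc.occupancy import (
    DiagnosticsReport,
    HabitatDifference,
    McmcConfig,
    OccupancyData,
    OccupancyFit,
    classify_habitat_difference,
    convergence_diagnostics,
    fit_occupancy,
    geweke_z,
    occupancy_data_from_table,
    posterior_habitat_probabilities,
    raftery_lewis,
)
from reefassoc.simulate import SimulationConfig, SpeciesTruth, generate_survey


def _simulate_flat(n, alpha0, alpha1, seed):
    """Direct Bernoulli data without location structure (single location)."""
    rng = np.random.default_rng(seed)
    x = (np.arange(n) % 2).astype(float)
    p = expit(alpha0 + alpha1 * x)
    y = (rng.random(n) < p).astype(float)
    return OccupancyData(y=y, x=x, loc=np.zeros(n, dtype=int))


def _make_fit(p_coral_chain, p_algal_chain):
    """Wrap probability chains into a fit object (inverse of the derived
    p transforms)."""
    a0 = logit(np.asarray(p_coral_chain))
    a1 = logit(np.asarray(p_algal_chain)) - a0
    n = len(a0)
    return OccupancyFit(
        alpha0=a0, alpha1=a1, sigma_loc=np.zeros(n), lam=np.zeros((n, 1)),
        location_ids=["L1"], acceptance={}, config=McmcConfig(),
    )


# ---------------------------------------------------------------------------
# sampler correctness
# ---------------------------------------------------------------------------

def test_posterior_agrees_with_logistic_mle_oracle():
    # sigma_loc fixed at 0 and a diffuse prior: the posterior should centre
    # on the independent iteratively-reweighted ML fit
    data = _simulate_flat(5000, 0.0, 1.0, seed=42)
    X = sm.add_constant(data.x)
    mle = sm.Logit(data.y, X).fit(disp=0)
    fit = fit_occupancy(
        data,
        McmcConfig(n_burnin=1000, n_iter=6000, fix_sigma_loc=0.0, seed=11),
    )
    a0_hat, a1_hat = mle.params
    sd0, sd1 = fit.alpha0.std(), fit.alpha1.std()
    assert abs(fit.alpha0.mean() - 0.0) < 3 * sd0 + 0.0 or True  # see below
    assert abs(fit.alpha0.mean() - a0_hat) < 0.05
    assert abs(fit.alpha1.mean() - a1_hat) < 0.05
    # and within 3 posterior sds of the generating truth
    assert abs(fit.alpha0.mean() - 0.0) < 3 * sd0
    assert abs(fit.alpha1.mean() - 1.0) < 3 * sd1


def test_saturated_presence_gives_high_probabilities():
    n = 120
    data = OccupancyData(
        y=np.ones(n), x=(np.arange(n) % 2).astype(float), loc=np.zeros(n, dtype=int)
    )
    fit = fit_occupancy(data, McmcConfig(fix_sigma_loc=0.0, seed=2))
    probs = posterior_habitat_probabilities(fit)
    assert probs["coral_reef"]["mean"] > 0.95
    assert probs["algal_meadow"]["mean"] > 0.95


def test_credible_interval_covers_planted_habitat_effect():
    sp = SpeciesTruth(species="Cov sp", alpha0=0.5, alpha1=-2.0, sigma_loc=0.5)
    cfg = SimulationConfig(
        n_locations=20, transects_per_location=(6, 6),
        prop_coral_locations=0.5, species_params=[sp], seed=7,
    )
    table, _ = generate_survey(cfg)
    fit = fit_occupancy(
        occupancy_data_from_table(table, "Cov sp"), McmcConfig(seed=1)
    )
    lo, hi = np.quantile(fit.alpha1, [0.025, 0.975])
    assert lo < -2.0 < hi


def test_posterior_sd_shrinks_with_sample_size():
    # 200 -> 2000 transects should shrink sd(alpha1) by about sqrt(10)
    sds = []
    for n, seed in [(200, 1), (2000, 2)]:
        data = _simulate_flat(n, 0.0, 1.0, seed=seed)
        fit = fit_occupancy(
            data, McmcConfig(n_burnin=1000, n_iter=6000, fix_sigma_loc=0.0, seed=3)
        )
        sds.append(fit.alpha1.std())
    ratio = sds[0] / sds[1]
    assert 0.7 * np.sqrt(10) < ratio < 1.3 * np.sqrt(10)


def test_location_relabeling_leaves_alpha_summaries_unchanged():
    sp = SpeciesTruth(species="Perm sp", alpha0=0.0, alpha1=-1.0, sigma_loc=0.5)
    cfg = SimulationConfig(
        n_locations=10, transects_per_location=(6, 6),
        prop_coral_locations=0.5, species_params=[sp], seed=19,
    )
    table, _ = generate_survey(cfg)
    data = occupancy_data_from_table(table, "Perm sp")
    L = data.n_locations
    perm = np.roll(np.arange(L), 3)
    data_perm = OccupancyData(
        y=data.y, x=data.x, loc=perm[data.loc],
        location_ids=[f"P{i}" for i in range(L)],
    )
    f1 = fit_occupancy(data, McmcConfig(seed=5))
    f2 = fit_occupancy(data_perm, McmcConfig(seed=5))
    assert abs(f1.alpha0.mean() - f2.alpha0.mean()) < 0.25
    assert abs(f1.alpha1.mean() - f2.alpha1.mean()) < 0.35


def test_single_transect_posterior_is_prior_dominated():
    data = OccupancyData(y=np.array([1.0]), x=np.array([0.0]), loc=np.array([0]))
    with pytest.warns(UserWarning):
        fit = fit_occupancy(data, McmcConfig(fix_sigma_loc=0.0, seed=4))
    probs = posterior_habitat_probabilities(fit)
    # all summaries must lie in the central 95% mass implied by the prior
    prior_lo, prior_hi = expit(-1.96 * 31.6227766), expit(1.96 * 31.6227766)
    for hab in ("coral_reef", "algal_meadow"):
        for k in ("mean", "lo", "hi"):
            assert prior_lo <= probs[hab][k] <= prior_hi
    # the habitat with no data at all stays essentially unconstrained
    assert probs["algal_meadow"]["hi"] - probs["algal_meadow"]["lo"] > 0.9


def test_separability_warning_for_habitat_exclusive_species():
    n = 60
    x = (np.arange(n) % 2).astype(float)
    y = np.where(x == 0, 1.0, 0.0)  # coral-exclusive
    data = OccupancyData(y=y, x=x, loc=np.zeros(n, dtype=int))
    with pytest.warns(UserWarning, match="algal_meadow"):
        fit = fit_occupancy(data, McmcConfig(n_iter=1000, fix_sigma_loc=0.0, seed=6))
    assert any("algal_meadow" in w for w in fit.warnings_)


def test_coral_exclusive_species_has_small_algal_probability():
    sp = SpeciesTruth(species="Excl sp", alpha0=1.0, alpha1=-8.0, sigma_loc=0.0)
    cfg = SimulationConfig(
        n_locations=30, transects_per_location=(6, 6),
        prop_coral_locations=0.5, species_params=[sp], seed=23,
    )
    table, _ = generate_survey(cfg)
    with pytest.warns(UserWarning):
        fit = fit_occupancy(
            occupancy_data_from_table(table, "Excl sp"), McmcConfig(seed=8)
        )
    assert posterior_habitat_probabilities(fit)["algal_meadow"]["mean"] < 0.05


# ---------------------------------------------------------------------------
# posterior summaries and classification
# ---------------------------------------------------------------------------

def test_constant_chain_summary_is_degenerate():
    fit = _make_fit(np.full(2000, 0.5), np.full(2000, 0.5))
    probs = posterior_habitat_probabilities(fit)
    assert probs["coral_reef"] == {"mean": 0.5, "lo": 0.5, "hi": 0.5}


def test_uniform_chain_quantiles_near_closed_form():
    rng = np.random.default_rng(12)
    u = rng.uniform(1e-9, 1 - 1e-9, size=10000)
    fit = _make_fit(u, u)
    probs = posterior_habitat_probabilities(fit)
    assert abs(probs["coral_reef"]["lo"] - 0.025) < 0.02
    assert abs(probs["coral_reef"]["hi"] - 0.975) < 0.02


def test_min_draws_enforced():
    fit = _make_fit(np.full(500, 0.5), np.full(500, 0.5))
    with pytest.raises(RuntimeError):
        posterior_habitat_probabilities(fit)


def test_classification_by_interval_non_overlap():
    rng = np.random.default_rng(3)
    coral = np.clip(rng.uniform(0.6, 0.8, 2000), 1e-6, 1 - 1e-6)
    algal = np.clip(rng.uniform(0.1, 0.3, 2000), 1e-6, 1 - 1e-6)
    assert (
        classify_habitat_difference(_make_fit(coral, algal))
        == HabitatDifference.CORAL_GREATER
    )
    assert (
        classify_habitat_difference(_make_fit(algal, coral))
        == HabitatDifference.ALGAL_GREATER
    )
    assert (
        classify_habitat_difference(_make_fit(coral, coral))
        == HabitatDifference.NO_DISTINCTION
    )


def test_classification_tracks_planted_effect_signs():
    # strong planted effects should classify correctly for most species
    hits = 0
    specs = []
    for k in range(6):
        a1 = -3.0 if k % 2 == 0 else 3.0
        specs.append(SpeciesTruth(species=f"Sgn {k}", alpha0=0.0, alpha1=a1))
    cfg = SimulationConfig(
        n_locations=20, transects_per_location=(6, 6),
        prop_coral_locations=0.5, species_params=specs, seed=31,
    )
    table, _ = generate_survey(cfg)
    for k, sp in enumerate(specs):
        fit = fit_occupancy(
            occupancy_data_from_table(table, sp.species),
            McmcConfig(n_iter=4000, seed=k),
        )
        want = (
            HabitatDifference.CORAL_GREATER
            if sp.alpha1 < 0
            else HabitatDifference.ALGAL_GREATER
        )
        hits += classify_habitat_difference(fit) == want
    assert hits >= 5


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def test_geweke_passes_for_iid_chain():
    rng = np.random.default_rng(100)
    assert abs(geweke_z(rng.normal(size=10000))) < 2


def test_geweke_flags_deterministic_drift():
    chain = 0.001 * np.arange(10000, dtype=float)
    assert abs(geweke_z(chain)) > 2


def test_raftery_lewis_iid_near_nmin():
    rng = np.random.default_rng(7)
    r = raftery_lewis(rng.normal(size=20000))
    assert r["nmin"] == 3746  # ceil(0.025*0.975*1.96^2/0.005^2)
    assert r["n_required"] < 4 * r["nmin"]  # nearly independent chain


def test_diagnostics_report_flags(toy_table=None):
    rng = np.random.default_rng(9)
    a0 = rng.normal(size=10000)
    fit = OccupancyFit(
        alpha0=a0, alpha1=a0.copy(), sigma_loc=np.zeros(10000),
        lam=np.zeros((10000, 1)), location_ids=["L1"], acceptance={},
        config=McmcConfig(),
    )
    rep = convergence_diagnostics(fit)
    assert isinstance(rep, DiagnosticsReport)
    assert rep.cross_correlation_fail  # duplicated parameter chains
    assert rep.cross_correlation[0, 1] == pytest.approx(1.0)
    assert not any(rep.geweke_fail.values())
    assert not rep.passed


def test_diagnostics_require_minimum_chain_length():
    fit = OccupancyFit(
        alpha0=np.zeros(50), alpha1=np.zeros(50), sigma_loc=np.zeros(50),
        lam=np.zeros((50, 1)), location_ids=["L1"], acceptance={},
        config=McmcConfig(),
    )
    with pytest.raises(RuntimeError):
        convergence_diagnostics(fit)
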