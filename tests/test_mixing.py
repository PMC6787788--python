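import math

import numpy as np
import pytest
from scipy.stats import norm

import allochthon as al
from allochthon.io import ConsumerSample
from allochthon.mixing import (DegenerateLikelihoodError, MixingConfig, ilr,
                               ilr_inv, sample_posterior)

FAST = dict(n_iter=8000, n_burn=4000, thin=2, n_chains=3)


def _src(name, mean, sd, tdf=0.0, tdf_sd=0.0):
    return al.SourceDistribution(name, {"d13C": mean}, {"d13C": sd},
                                 {"d13C": tdf}, {"d13C": tdf_sd})


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_collapsed_mixture_reduces_to_standard_normal():
    sources = [_src("a", -30.0, 0.0, tdf=0.4), _src("b", -10.0, 0.0), _src("c", -20.0, 0.0)]
    ll = al.log_likelihood({"d13C": -29.6}, [1.0, 0.0, 0.0], sources,
                           resid_sd={"d13C": 1.0}, tracers=("d13C",))
    assert ll == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)
    assert ll == pytest.approx(-0.9189, abs=1e-4)


def test_symmetric_two_source_likelihood_peaks_at_even_split():
    sources = [_src("a", -30.0, 2.0), _src("b", -10.0, 2.0)]
    mid = {"d13C": -20.0}
    ll_mid = al.log_likelihood(mid, [0.5, 0.5], sources, {"d13C": 1.0}, ("d13C",))
    for p1 in (0.2, 0.35, 0.65, 0.8):
        assert ll_mid > al.log_likelihood(mid, [p1, 1 - p1], sources, {"d13C": 1.0}, ("d13C",))


def test_likelihood_matches_independent_formula_on_random_instance():
    """Density equals a brute-force recomputation coded directly from the
    mixture mean/variance formula with scipy.stats.norm."""
    rng = np.random.default_rng(42)
    sources = [
        al.SourceDistribution("s1", {"d13C": -31.3, "d2H": -50.0},
                              {"d13C": 2.2, "d2H": 14.0}, {"d13C": 0.4}, {"d13C": 1.3}),
        al.SourceDistribution("s2", {"d13C": -13.1, "d2H": -50.0},
                              {"d13C": 1.0, "d2H": 14.0}, {"d13C": 0.4}, {"d13C": 1.3}),
        al.SourceDistribution("s3", {"d13C": -30.0, "d2H": -150.0},
                              {"d13C": 3.0, "d2H": 27.0}, {"d13C": 0.4}, {"d13C": 1.3}),
    ]
    for _ in range(20):
        p = rng.dirichlet([1.0, 1.0, 1.0])
        x = {"d13C": rng.uniform(-35, -10), "d2H": rng.uniform(-150, -30)}
        s = {"d13C": rng.uniform(0.1, 2.0), "d2H": rng.uniform(0.1, 5.0)}
        expected = 0.0
        for t in ("d13C", "d2H"):
            m = sum(pk * (src.mean(t) + src.tdf_mean(t)) for pk, src in zip(p, sources))
            v = sum(pk ** 2 * (src.sd(t) ** 2 + src.tdf_sd(t) ** 2)
                    for pk, src in zip(p, sources)) + s[t] ** 2
            expected += norm.logpdf(x[t], m, math.sqrt(v))
        got = al.log_likelihood(x, p, sources, s, ("d13C", "d2H"))
        assert got == pytest.approx(expected, rel=1e-12)


def test_zero_total_variance_is_degenerate():
    sources = [_src("a", -30.0, 0.0), _src("b", -10.0, 0.0)]
    with pytest.raises(DegenerateLikelihoodError):
        al.log_likelihood({"d13C": -20.0}, [0.5, 0.5], sources, None, ("d13C",))


# ---------------------------------------------------------------------------
# ILR transform
# ---------------------------------------------------------------------------

def test_ilr_round_trip_on_simplex():
    rng = np.random.default_rng(0)
    for k in (2, 3, 4):
        p = rng.dirichlet(np.ones(k), size=5)
        back = np.atleast_2d(ilr_inv(ilr(p)))
        assert np.allclose(back, p, atol=1e-12)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def test_point_source_mixture_recovers_linear_algebra():
    """Consumers at −25 between point sources at −30/−10 demand p₁ = 0.75."""
    sources = [_src("a", -30.0, 0.05), _src("b", -10.0, 0.05)]
    x = np.full((40, 1), -25.0)
    cfg = MixingConfig(tracers=("d13C",), seed=5, error_structure="process_plus_residual",
                       **FAST)
    draws = sample_posterior(x, sources, cfg)
    assert np.median(draws[:, :, 0]) == pytest.approx(0.75, abs=0.02)


def test_mcmc_matches_grid_integration_oracle(two_sources_1d):
    """Posterior mean of p₁ from MCMC agrees with deterministic quadrature
    over the 1-simplex within 0.02 on a 5-consumer instance."""
    from scipy.integrate import quad
    x = np.array([[-26.0], [-24.0], [-25.0], [-27.0], [-23.0]])
    cfg = MixingConfig(tracers=("d13C",), seed=7, error_structure="process_only", **FAST)
    draws = sample_posterior(x, two_sources_1d, cfg)

    def unnorm(p1):
        m = p1 * -30.0 + (1 - p1) * -10.0
        v = p1 ** 2 * 1.5 ** 2 + (1 - p1) ** 2 * 1.5 ** 2
        return math.exp(float(np.sum(norm.logpdf(x[:, 0], m, math.sqrt(v)))))

    num = quad(lambda p: p * unnorm(p), 0, 1, limit=200)[0]
    den = quad(unnorm, 0, 1, limit=200)[0]
    assert draws[:, :, 0].mean() == pytest.approx(num / den, abs=0.02)


def test_draws_live_on_the_simplex(foodweb):
    table, _ = foodweb
    x = np.array([[c.d13C] for c in table.consumers[:20]])
    cfg = MixingConfig(tracers=("d13C",), seed=3, **FAST)
    draws = sample_posterior(x, table.sources, cfg)
    assert np.allclose(draws.sum(axis=-1), 1.0, atol=1e-9)
    assert (draws >= 0).all()


def test_prior_recovered_with_no_consumers():
    """Zero observations → posterior is the Dirichlet(1) prior: mean 1/3."""
    sources = [_src("a", -30.0, 2.0), _src("b", -10.0, 2.0), _src("c", -20.0, 2.0)]
    cfg = MixingConfig(tracers=("d13C",), seed=11, error_structure="process_only", **FAST)
    draws = sample_posterior(np.empty((0, 1)), sources, cfg).reshape(-1, 3)
    assert np.allclose(draws.mean(axis=0), 1 / 3, atol=0.025)
    # Dirichlet(1) marginals are Beta(1, 2): sd = sqrt(2)/ (3*sqrt(4)) ≈ 0.2357
    assert np.allclose(draws.std(axis=0), math.sqrt(2) / 6, atol=0.02)


def test_config_invariants():
    cfg = MixingConfig(n_iter=30000, n_burn=15000, thin=5)
    assert cfg.n_keep == 3000
    with pytest.raises(ValueError):
        MixingConfig(n_iter=100, n_burn=100)
    with pytest.raises(ValueError):
        MixingConfig(error_structure="bogus")
    with pytest.raises(ValueError):
        MixingConfig(n_chains=1)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def _consumers(values, community="fish"):
    return [ConsumerSample(f"c{i}", v, 8.0, None, community=community)
            for i, v in enumerate(values)]


def test_fit_summary_shape_and_permutation_equivariance():
    sources = [_src("a", -30.0, 2.0), _src("b", -10.0, 2.0), _src("m", -20.0, 2.0)]
    cons = _consumers(np.linspace(-26, -22, 10))
    cfg = MixingConfig(tracers=("d13C",), group_by="community", seed=13, **FAST)
    r1 = al.fit(cons, sources, cfg)
    r2 = al.fit(cons, sources[::-1], cfg)
    assert list(r1.summary["source"]) == sorted(["a", "b", "m"])
    assert (r1.summary["median"] - r2.summary["median"]).abs().max() == 0.0
    med_sum = r1.summary.groupby("group")["median"].sum().iloc[0]
    assert 0.8 < med_sum < 1.2  # medians of a composition need not sum to exactly 1


def test_fit_skips_tiny_groups_and_counts_missing():
    sources = [_src("a", -30.0, 2.0), _src("b", -10.0, 2.0)]
    cons = _consumers(np.linspace(-26, -22, 8), community="fish") \
        + _consumers([-25.0, -24.0], community="aquatic_invertebrate")
    cons[3] = ConsumerSample("c3", None, 8.0, None, community="fish")
    cfg = MixingConfig(tracers=("d13C",), group_by="community", seed=17, **FAST)
    with pytest.warns(UserWarning, match="skipped"):
        res = al.fit(cons, sources, cfg)
    assert res.report["n_excluded_missing_tracer"] == 1
    assert res.report["skipped_groups"][0]["group"] == "aquatic_invertebrate"
    assert set(res.summary["group"]) == {"fish"}


def test_fit_requires_two_sources():
    with pytest.raises(ValueError, match="2 sources"):
        al.fit(_consumers([-25.0] * 4), [_src("a", -30.0, 2.0)],
               MixingConfig(tracers=("d13C",), **FAST))


# ---------------------------------------------------------------------------
# sensitivity sweep
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fish_subset(request):
    table, truth = al.simulate_foodweb(al.GeneratorConfig(seed=1, n_per_group=30))
    from allochthon.trophic import correct_table
    corr = correct_table(table.consumers, table.water)
    d2h = dict(zip(corr["sample_id"], corr["d2H_source"]))
    fish = [c for c in table.consumers if c.community == "fish"]
    return fish, table.sources, d2h


def test_single_value_sweep_equals_plain_fit(fish_subset):
    fish, sources, d2h = fish_subset
    cfg = MixingConfig(tracers=("d13C", "d2H"), group_by="community", seed=19, **FAST)
    plain = al.fit(fish, sources, cfg, d2H_override=d2h).summary
    swept = al.sensitivity_sweep(fish, sources, cfg, "algae.d2H.mean", [-150.0],
                                 d2H_override=d2h)
    assert np.allclose(swept["median"].to_numpy(), plain["median"].to_numpy())
    assert np.allclose(swept["abs_change_vs_central"].to_numpy(), 0.0)


def test_sweep_moves_algae_c3_split_monotonically(fish_subset):
    fish, sources, d2h = fish_subset
    cfg = MixingConfig(tracers=("d13C", "d2H"), group_by="community", seed=23, **FAST)
    table = al.sensitivity_sweep(fish, sources, cfg, "algae.d2H.mean",
                                 [-130.0, -150.0, -170.0], d2H_override=d2h)
    algae = table[table["source"] == "algae"].sort_values("swept_value")["median"].to_numpy()
    c3 = table[table["source"] == "terrestrial_C3"].sort_values("swept_value")["median"].to_numpy()
    assert (np.diff(algae) > 0).all() or (np.diff(algae) < 0).all()
    assert (np.diff(c3) > 0).all() or (np.diff(c3) < 0).all()


def test_sweep_never_mutates_inputs(fish_subset):
    fish, sources, d2h = fish_subset
    algae = next(s for s in sources if s.name == "algae")
    before = algae.mean("d2H")
    cfg = MixingConfig(tracers=("d13C", "d2H"), group_by="community", seed=29,
                       n_iter=2000, n_burn=1000, thin=2, n_chains=2)
    al.sensitivity_sweep(fish, sources, cfg, "algae.d2H.mean", [-130.0], d2H_override=d2h)
    assert algae.mean("d2H") == before


def test_empty_sweep_is_a_usage_error(fish_subset):
    fish, sources, d2h = fish_subset
    cfg = MixingConfig(tracers=("d13C",), **FAST)
    with pytest.raises(ValueError, match="empty"):
        al.sensitivity_sweep(fish, sources, cfg, "algae.d2H.mean", [])
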