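import math

import numpy as np
import pytest

import allochthon as al
from allochthon.simulate import GeneratorConfig, GroupSpec, default_sources


def test_same_seed_gives_identical_tables(tmp_path):
    cfg = GeneratorConfig(seed=7, n_per_group=15)
    t1, truth1 = al.simulate_foodweb(cfg)
    t2, truth2 = al.simulate_foodweb(cfg)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    al.write_consumers(t1.consumers, p1)
    al.write_consumers(t2.consumers, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert truth1 == truth2


def test_different_seeds_differ():
    t1, _ = al.simulate_foodweb(GeneratorConfig(seed=1, n_per_group=5))
    t2, _ = al.simulate_foodweb(GeneratorConfig(seed=2, n_per_group=5))
    assert t1.consumers[0].d13C != t2.consumers[0].d13C


def test_zero_noise_pure_c3_diet_is_analytic():
    """With all noise off, a pure-C3 TP=1 group lands exactly on the C3
    end-member: δ13C = −31.3 + 0.4 (TDF) and source-scale δ2H = −50."""
    cfg = GeneratorConfig(
        seed=0, n_per_group=4, zero_noise=True,
        group_specs={"g": GroupSpec(true_proportions=(1.0, 0.0, 0.0),
                                    community="fish", TP_mean=1.0, TP_sd=0.0)})
    table, truth = al.simulate_foodweb(cfg)
    for c, tr in zip(table.consumers, truth["consumers"]):
        assert c.d13C == pytest.approx(-31.3 + 0.4, abs=1e-12)
        assert c.d15N == pytest.approx(5.6, abs=1e-12)
        # TP=1 ⇒ no compounding: measured δ2H equals the source-scale value
        assert c.d2H == pytest.approx(-50.0, abs=1e-12)
        assert tr["d2H_source"] == pytest.approx(-50.0, abs=1e-12)


def test_zero_noise_compounding_applied_forward():
    cfg = GeneratorConfig(
        seed=0, n_per_group=1, zero_noise=True,
        group_specs={"g": GroupSpec(true_proportions=(1.0, 0.0, 0.0),
                                    community="fish", TP_mean=2.5, TP_sd=0.0)})
    table, _ = al.simulate_foodweb(cfg)
    om_c = al.omega_compound(0.28, 1.5)
    assert table.consumers[0].d2H == pytest.approx((1 - om_c) * -50.0, abs=1e-12)


def test_tp2_group_mean_d15N_near_nine():
    """δ15N = 5.6 + 3.4·(TP−1): a TP=2 group should average 9.0‰."""
    n = 200
    cfg = GeneratorConfig(
        seed=5, n_per_group=n,
        group_specs={"g": GroupSpec(true_proportions=(0.5, 0.25, 0.25),
                                    community="fish", TP_mean=2.0, TP_sd=0.2)})
    table, _ = al.simulate_foodweb(cfg)
    d15N = np.array([c.d15N for c in table.consumers])
    se = d15N.std(ddof=1) / math.sqrt(n)
    assert abs(d15N.mean() - 9.0) < 2 * se


def test_invalid_simplex_rejected():
    with pytest.raises(ValueError, match="simplex"):
        GroupSpec(true_proportions=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError, match="match"):
        GeneratorConfig(group_specs={"g": GroupSpec(true_proportions=(0.5, 0.5))})


def test_outlier_fraction_injects_c4_feeders():
    cfg = GeneratorConfig(seed=9, n_per_group=100, outlier_fraction=0.3)
    table, truth = al.simulate_foodweb(cfg)
    pure_c4 = [t for t in truth["consumers"] if t["proportions"][1] == 1.0]
    assert 10 < len(pure_c4) < 100
    heavy = [c.d13C for c in table.consumers if c.d13C > -17.0]
    assert len(heavy) >= len(pure_c4) // 2  # C4 diets carry the high-δ13C signature


def test_truth_record_supports_analytic_reconstruction():
    cfg = GeneratorConfig(seed=3, n_per_group=2, zero_noise=True)
    table, truth = al.simulate_foodweb(cfg)
    srcs = default_sources()
    mus = {t: np.array([s.mean(t) for s in srcs]) for t in ("d13C", "d2H")}
    for c, tr in zip(table.consumers, truth["consumers"]):
        p = np.array(tr["proportions"])
        assert c.d13C == pytest.approx(float(p @ mus["d13C"]) + 0.4, abs=1e-9)
        assert tr["d2H_source"] == pytest.approx(float(p @ mus["d2H"]), abs=1e-9)


def test_equilibration_forward_noise_free_round_trip():
    run = al.simulate_equilibration(0.0, -77.0)
    assert run.d2H_total_A == run.d2H_total_B == -77.0  # f_ex=0: water-independent
    f_ex, d2h_n = al.solve_two_water(al.simulate_equilibration(0.35, -120.0))
    assert (f_ex, d2h_n) == (pytest.approx(0.35), pytest.approx(-120.0))


def test_equilibration_estimates_unbiased_under_noise():
    """500 noisy replicates: mean f_ex estimate within 2 SE of the truth."""
    ests = []
    for i in range(500):
        run = al.simulate_equilibration(0.2, -100.0, noise_sd=2.0, seed=1000 + i)
        f_ex, _ = al.solve_two_water(run)
        ests.append(f_ex)
    ests = np.array(ests)
    se = ests.std(ddof=1) / math.sqrt(len(ests))
    assert abs(ests.mean() - 0.2) < 2 * se
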