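"""Materials, cross sections and interaction sampling."""

import math

import numpy as np
import pytest
from scipy import stats

from straydose import physics as ph


class TestCrossSections:
    def test_shipped_tables_match_generator(self):
        """The CSV resources are reproducible bit-for-bit from the models."""
        for el in ("H", "O", "W", "Pb"):
            shipped = ph.load_table(el)
            regen = ph.generate_element_table(el)
            # CSVs are written at 8 significant digits
            np.testing.assert_allclose(shipped.mu_over_rho_photoelectric,
                                       regen[:, 1], rtol=1e-7)
            np.testing.assert_allclose(shipped.mu_over_rho_incoherent,
                                       regen[:, 2], rtol=1e-7)
            np.testing.assert_allclose(shipped.mu_over_rho_pair,
                                       regen[:, 3], rtol=1e-7)

    def test_partials_sum_to_total(self):
        t = ph.load_table("Ca")
        np.testing.assert_allclose(
            t.total, t.mu_over_rho_photoelectric + t.mu_over_rho_incoherent
            + t.mu_over_rho_pair, rtol=1e-12)
        # and at interpolated energies, through the material interface
        m = ph.Material("ca", 1.55, (("Ca", 1.0),))
        for E in (0.0137, 0.33, 2.77):
            assert m.mu_total(E) == pytest.approx(
                sum(m.mu_partial(E, k) for k in ph.INTERACTIONS), rel=1e-12)

    def test_water_reference_value_at_1mev(self):
        """mu/rho of water at 1 MeV is 0.0707 cm^2/g in standard photo-atomic
        tables (coherent scattering excluded)."""
        mu = ph.MATERIALS["water"].mu_total(1.0)
        assert mu == pytest.approx(0.0707, rel=0.005)

    def test_vacuum_is_transparent(self):
        assert ph.VACUUM.mu_total(1.0) == 0.0

    def test_mixture_rule_is_exactly_linear(self):
        half = ph.Material("half", 2.0, (("Al", 0.5), ("Cu", 0.5)))
        al = ph.Material("al", 1.0, (("Al", 1.0),))
        cu = ph.Material("cu", 1.0, (("Cu", 1.0),))
        for E in (0.05, 0.511, 3.3):
            expected = 2.0 * 0.5 * (al.mu_total(E) + cu.mu_total(E))
            assert half.mu_total(E) == pytest.approx(expected, rel=1e-12)

    def test_energy_out_of_range_raises(self):
        with pytest.raises(ph.PhysicsError, match="outside"):
            ph.MATERIALS["water"].mu_total(0.001)
        with pytest.raises(ph.PhysicsError, match="outside"):
            ph.MATERIALS["water"].mu_total(11.0)

    def test_pair_zero_below_threshold(self):
        assert ph.MATERIALS["lead"].mu_partial(1.0, "pair") == 0.0
        assert ph.MATERIALS["lead"].mu_partial(2.0, "pair") > 0.0

    def test_material_validation(self):
        with pytest.raises(ph.PhysicsError, match="sum"):
            ph.Material("bad", 1.0, (("H", 0.5), ("O", 0.6)))
        with pytest.raises(ph.PhysicsError, match="density"):
            ph.Material("bad", -1.0, (("H", 1.0),))
        with pytest.raises(ph.PhysicsError, match="library"):
            ph.Material("bad", 1.0, (("Xx", 1.0),))


class TestFreePath:
    def test_exponential_mean(self):
        rng = np.random.default_rng(3)
        n = 200_000
        draws = np.array([ph.sample_free_path(1.0, rng) for _ in range(n)])
        assert abs(draws.mean() - 1.0) < 3.0 / math.sqrt(n)

    def test_large_mu_short_path(self):
        rng = np.random.default_rng(4)
        assert np.mean([ph.sample_free_path(1e6, rng)
                        for _ in range(100)]) < 1e-5

    def test_fixed_seed_bit_identical(self):
        a = [ph.sample_free_path(0.2, np.random.default_rng(9)) for _ in "xy"]
        b = [ph.sample_free_path(0.2, np.random.default_rng(9)) for _ in "xy"]
        assert a[0] == b[0]


class TestInteractionSampling:
    def test_no_pair_below_threshold(self):
        rng = np.random.default_rng(5)
        tags = {ph.sample_interaction(ph.MATERIALS["lead"], 0.8, rng)
                for _ in range(2000)}
        assert "pair" not in tags

    def test_photoelectric_fraction_high_z(self):
        """At 50 keV in lead the sampled photoelectric share matches the
        partial/total ratio of the table."""
        pb = ph.MATERIALS["lead"]
        E = 0.05
        p = pb.mu_partial(E, "photoelectric") / pb.mu_total(E)
        rng = np.random.default_rng(6)
        n = 100_000
        hits = sum(ph.sample_interaction(pb, E, rng) == "photoelectric"
                   for _ in range(n))
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma

    def test_frequencies_chi_square(self):
        """Sampled channel frequencies are consistent with the table ratios."""
        w = ph.MATERIALS["water"]
        E = 2.0
        parts = np.array(w.mu_partials(E))
        probs = parts / parts.sum()
        rng = np.random.default_rng(7)
        n = 100_000
        counts = {"photoelectric": 0, "compton": 0, "pair": 0}
        for _ in range(n):
            counts[ph.sample_interaction(w, E, rng)] += 1
        obs = np.array([counts[k] for k in ph.INTERACTIONS])
        _, pval = stats.chisquare(obs, probs * n)
        assert pval > 0.001


class TestCompton:
    def test_backscatter_bound_at_cs137_energy(self):
        """No scattered photon falls below E/(1 + 2E/0.511) = 0.1843 MeV."""
        E = 0.6616
        bound = E / (1 + 2 * E / 0.511)
        assert bound == pytest.approx(0.1843, abs=5e-5)
        rng = np.random.default_rng(8)
        e_s, _, _ = ph.sample_compton(E, rng, size=300_000)
        assert e_s.min() >= bound - 1e-12
        assert e_s.max() <= E + 1e-12

    def test_thomson_limit_symmetric(self):
        """As E -> 0 the angular distribution is fore-aft symmetric."""
        rng = np.random.default_rng(9)
        n = 1_000_000
        _, ct, _ = ph.sample_compton(1e-4, rng, size=n)
        assert abs(ct.mean()) < 3 * ct.std(ddof=1) / math.sqrt(n)

    def test_mean_fraction_matches_quadrature(self):
        rng = np.random.default_rng(10)
        E, n = 0.5, 1_000_000
        e_s, _, e_dep = ph.sample_compton(E, rng, size=n)
        frac = e_s / E
        expected = ph.kn_mean_scattered_fraction(E)
        assert abs(frac.mean() - expected) < 3 * frac.std(ddof=1) / math.sqrt(n)
        np.testing.assert_allclose(e_s + e_dep, E, rtol=1e-12)

    def test_kinematics_relation(self):
        """Sampled (E', cos) pairs satisfy the Compton relation exactly."""
        rng = np.random.default_rng(11)
        E = 1.3
        e_s, ct, _ = ph.sample_compton(E, rng, size=1000)
        np.testing.assert_allclose(
            e_s, E / (1 + (E / ph.MEC2) * (1 - ct)), rtol=1e-10)

    def test_closed_form_total_vs_quadrature(self):
        for E in (0.05, 0.6616, 6.0):
            assert ph.kn_total_cross_section(E) == pytest.approx(
                ph.kn_total_by_quadrature(E), rel=1e-8)


class TestPair:
    def test_threshold_case(self):
        rng = np.random.default_rng(12)
        dep, photons = ph.sample_pair(1.022, rng)
        assert dep == 0.0
        assert [e for e, _ in photons] == [0.511, 0.511]

    def test_annihilation_antiparallel(self):
        rng = np.random.default_rng(13)
        _, [(_, d1), (_, d2)] = ph.sample_pair(4.0, rng)
        dot = sum(a * b for a, b in zip(d1, d2))
        assert dot == pytest.approx(-1.0, abs=1e-12)

    def test_energy_balance_exact(self):
        rng = np.random.default_rng(14)
        E = 3.3
        dep, photons = ph.sample_pair(E, rng)
        assert dep + sum(e for e, _ in photons) == pytest.approx(E, abs=1e-15)

    def test_below_threshold_raises(self):
        with pytest.raises(ph.PhysicsError):
            ph.sample_pair(1.0, np.random.default_rng(0))


def test_rotate_direction_preserves_norm_and_angle(rng):
    for _ in range(100):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        ct = rng.uniform(-1, 1)
        w = ph.rotate_direction(tuple(u), ct, rng.uniform(0, 2 * math.pi))
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-9)
        assert float(np.dot(u, w)) == pytest.approx(ct, abs=1e-9)


def test_heating_coefficient_between_bounds():
    """mu_en-style heating lies between 0 and mu_total, and equals mu_total
    where photoelectric absorption dominates."""
    w = ph.MATERIALS["water"]
    for E in (0.02, 0.1, 1.0, 6.0):
        mu_h = w.mu_heating(E)
        assert 0.0 < mu_h < w.mu_total(E)
    pb = ph.MATERIALS["lead"]
    assert pb.mu_heating(0.02) / pb.mu_total(0.02) > 0.95
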