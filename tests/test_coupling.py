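import numpy as np
import pytest
from scipy import stats

from retcouple.coupling import (
    cohens_d,
    compare_gap_junction_sizes,
    coupling_census,
    drive_table,
    ff_fb_bias,
    gj_density_per_length,
    input_spectrum,
    network_ff_fb_totals,
    polarity_profile,
    power_two_sample_t,
    round_extrapolated,
)

from conftest import build_graph


class TestDriveTable:
    def test_hand_arithmetic_on_toy_cell(self, toy_graph):
        t = drive_table(toy_graph, "g1", arbor_fraction=1.0)
        rib = t.rows["ribbon_in"]
        assert rib.n == 3
        assert rib.mean_area_um2 == pytest.approx(0.2)
        assert rib.total_area_um2 == pytest.approx(0.6)
        assert t.rows["conventional_in"].n == 1
        assert t.rows["gap_junction"].n == 2

    def test_identity_fraction_extrapolation(self, toy_graph):
        t = drive_table(toy_graph, "g1", arbor_fraction=1.0)
        for row in t.rows.values():
            assert row.extrapolated_n == row.n
            assert row.extrapolated_total_area_um2 == pytest.approx(
                round(row.total_area_um2)
            )

    def test_totals_are_exact_sums(self, fixture_graph):
        t = drive_table(fixture_graph, "GC606", arbor_fraction=0.18)
        areas = [c.area_um2 for c in fixture_graph.incoming("GC606", "ribbon")]
        assert t.rows["ribbon_in"].total_area_um2 == pytest.approx(sum(areas), rel=1e-12)

    def test_rounding_policy(self):
        assert round_extrapolated(1438.9) == 1440
        assert round_extrapolated(1266.7) == 1270
        assert round_extrapolated(54.4) == 54
        assert round_extrapolated(999.6) == 1000

    def test_unknown_cell_and_bad_fraction(self, toy_graph):
        with pytest.raises(KeyError):
            drive_table(toy_graph, "ghost")
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                drive_table(toy_graph, "g1", arbor_fraction=bad)


class TestInputSpectrum:
    def test_toy_fractions(self, toy_graph):
        s = input_spectrum(toy_graph, "g1", "ribbon")
        assert s.total == 3
        assert s.fractions.to_dict() == pytest.approx({"CBb4w": 2 / 3, "CBb5": 1 / 3})

    def test_three_to_one_split(self):
        g = build_graph(
            [("x", "CBb4w", "ON"), ("y", "CBb5", "ON"), ("g", "GC ON")],
            [("r1", "ribbon", "x", "g", 0.1), ("r2", "ribbon", "x", "g", 0.1),
             ("r3", "ribbon", "x", "g", 0.1), ("r4", "ribbon", "y", "g", 0.1)],
        )
        s = input_spectrum(g, "g", "ribbon")
        assert s.fractions.to_dict() == pytest.approx({"CBb4w": 0.75, "CBb5": 0.25})

    def test_fractions_sum_to_one(self, fixture_graph):
        s = input_spectrum(fixture_graph, "GC606", "ribbon")
        assert s.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert s.counts.sum() == s.total == 259

    def test_dominant_class_and_exclusion(self, fixture_graph):
        s = input_spectrum(fixture_graph, "GC606", "ribbon")
        assert s.dominant_class == "CBb4w"
        assert s.fractions["CBb4w"] == pytest.approx(0.54, abs=0.005)
        assert s.exclusion_fraction("CBb5") > 0.99
        assert s.exclusion_fraction("CBb5") + s.fractions["CBb5"] == pytest.approx(1.0)

    def test_cell_with_no_inputs(self, toy_graph):
        s = input_spectrum(toy_graph, "b1", "ribbon")
        assert s.total == 0 and s.dominant_class is None


class TestPolarityProfile:
    def test_pure_on_cell(self, fixture_graph):
        assert polarity_profile(fixture_graph, "GC606")["classification"] == "ON"

    def test_pure_off_cell(self, fixture_graph):
        assert polarity_profile(fixture_graph, "GC9787")["classification"] == "OFF"

    def test_mixed_input_is_on_off(self):
        g = build_graph(
            [("on", "CBb4w", "ON"), ("off", "CBa2", "OFF"), ("g", "GC ON OFF")],
            [("r1", "ribbon", "on", "g", 0.1), ("r2", "ribbon", "off", "g", 0.1)],
        )
        assert polarity_profile(g, "g")["classification"] == "ON_OFF"

    def test_no_ribbon_input_is_unknown(self, toy_graph):
        assert polarity_profile(toy_graph, "a1")["classification"] == "unknown"


class TestBias:
    def test_iac_analog_target_ratio(self, fixture_graph):
        b = ff_fb_bias(fixture_graph, ["IAC9769"])
        assert b.target_counts == {"bipolar": 3, "ganglion": 13, "amacrine": 38}
        assert b.ff_fb_ratio_by_target == pytest.approx(17.0)
        assert b.ff_fb_ratio_by_synapse > 10

    def test_ai_cohort_is_pure_feedback(self, fixture_graph):
        b = ff_fb_bias(fixture_graph, [f"AI:{i}" for i in range(5)])
        assert b.feedback_synapses == 837
        assert b.feedforward_to_GC == 0 and b.feedforward_to_AC == 0
        assert b.ff_fb_ratio_by_synapse == 0
        assert not b.feedback_free

    def test_cell_without_outputs(self, toy_graph):
        b = ff_fb_bias(toy_graph, ["a2"])
        assert b.feedback_synapses == 0
        assert b.ff_fb_ratio_by_synapse is None and b.ff_fb_ratio_by_target is None

    def test_feedback_free_flag(self):
        g = build_graph(
            [("a", "AC", "unknown", "amacrine"), ("g", "GC ON", "ON", "ganglion")],
            [("s", "conventional", "a", "g", 0.05)],
        )
        b = ff_fb_bias(g, ["a"])
        assert b.feedback_free and b.ff_fb_ratio_by_synapse is None

    def test_empty_cohort_rejected(self, fixture_graph):
        with pytest.raises(ValueError):
            ff_fb_bias(fixture_graph, [])


class TestNetworkTotals:
    def test_fixture_reproduces_published_tallies(self, fixture_graph):
        t = network_ff_fb_totals(fixture_graph)
        assert t["feedback_to_BC"] == 2359
        assert t["feedforward_to_GC"] == 336
        assert t["feedforward_to_AC"] == 564
        assert round(t["fb_ff_ratio"]) == 3

    def test_toy_ratio(self):
        g = build_graph(
            [("a", "AC", "unknown", "amacrine"), ("b", "RB", "ON", "bipolar"),
             ("g", "GC ON", "ON", "ganglion"), ("a2", "AC", "unknown", "amacrine")],
            [("s1", "conventional", "a", "b", 0.05), ("s2", "conventional", "a", "b", 0.05),
             ("s3", "conventional", "a", "b", 0.05), ("s4", "conventional", "a", "b", 0.05),
             ("s5", "conventional", "a", "g", 0.05), ("s6", "conventional", "a", "a2", 0.05)],
        )
        assert network_ff_fb_totals(g)["fb_ff_ratio"] == pytest.approx(2.0)

    def test_graph_without_amacrine_synapses(self, toy_graph):
        g = build_graph([("b", "RB", "ON", "bipolar")], [])
        t = network_ff_fb_totals(g)
        assert t["feedback_to_BC"] == 0 and t["fb_ff_ratio"] is None


class TestCouplingCensus:
    def test_fixture_has_no_gc_gc_coupling(self, fixture_graph):
        m = coupling_census(fixture_graph)
        assert m.homocellular_in_class_count("ganglion", fixture_graph) == 0
        assert ("ganglion", "ganglion") not in m.superclass_pair_counts.index

    def test_gc_partners_are_gabaergic(self, fixture_graph):
        m = coupling_census(fixture_graph)
        assert all(t == "GABA" for _, t in m.partners["GC606"])

    def test_categories_partition_junction_set(self, fixture_graph):
        m = coupling_census(fixture_graph)
        n_junctions = sum(1 for c in fixture_graph.contacts.values() if c.kind == "gap_junction")
        assert len(m.categories) == n_junctions
        assert sum(m.count(c) for c in
                   ("homocellular_in_class", "homocellular_cross_class", "heterocellular")
                   ) == n_junctions

    def test_aii_cbb_junction_is_heterocellular(self):
        g = build_graph(
            [("aii", "AII", "ON_OFF", "amacrine"), ("cbb", "CBb4w", "ON", "bipolar")],
            [("j", "gap_junction", "aii", "cbb", 0.03)],
        )
        assert coupling_census(g).count("heterocellular") == 1

    def test_cross_class_homocellular(self):
        g = build_graph(
            [("x", "CBb3n", "ON", "bipolar"), ("y", "CBb4", "ON", "bipolar")],
            [("j", "gap_junction", "x", "y", 0.03)],
        )
        assert coupling_census(g).count("homocellular_cross_class") == 1

    def test_empty_graph(self):
        m = coupling_census(build_graph([], []))
        assert m.class_pair_counts.empty and m.categories == {}


class TestGjDensity:
    def test_hand_arithmetic(self):
        g = build_graph([("g", "GC OFF alpha"), ("a", "AC")], [])
        g.neurons["g"].dendrite_length_um = 10.0
        from retcouple.model import Contact
        for i in range(2):
            g.add_contact(Contact(id=f"j{i}", kind="gap_junction", pre_id="g", post_id="a", area_um2=0.01))
        assert gj_density_per_length(g, "g") == pytest.approx(2000.0)

    def test_no_junctions_gives_zero(self):
        g = build_graph([("g", "GC ON")], [])
        g.neurons["g"].dendrite_length_um = 5.0
        assert gj_density_per_length(g, "g") == 0.0

    def test_missing_length_errors(self, toy_graph):
        with pytest.raises(ValueError):
            gj_density_per_length(toy_graph, "g1")

    def test_fixture_density_and_ratio(self, fixture_graph):
        d_off = gj_density_per_length(fixture_graph, "GC9787")
        d_ton = gj_density_per_length(fixture_graph, "GC606")
        assert d_off == pytest.approx(9142.0, rel=1e-9)
        assert d_off / d_ton == pytest.approx(0.46, abs=0.005)


def _moment_matched(rng, n, mean, sd):
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return x * sd + mean


class TestComparison:
    def test_identical_samples(self):
        a = [0.1, 0.2, 0.3, 0.4]
        r = compare_gap_junction_sizes(a, list(a))
        assert r.t_homoscedastic == 0.0 and r.p_t_homoscedastic == 1.0
        assert r.ks_D == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_gap_junction_sizes([0.1], [0.1, 0.2])

    def test_published_size_comparison_is_nonsignificant(self):
        # 13 junctions at 0.37 +/- 0.19 vs 228 at 0.28 +/- 0.18 um^2
        rng = np.random.default_rng(42)
        a = _moment_matched(rng, 13, 0.37, 0.19)
        b = _moment_matched(rng, 228, 0.28, 0.18)
        r = compare_gap_junction_sizes(a, b, alpha=0.05)
        assert r.p_t_homoscedastic > 0.05
        assert r.p_t_welch > 0.05
        assert r.p_F > 0.05
        assert r.p_ks > 0.05
        assert 0 < r.power < 1

    def test_cohens_d_pooled(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_power_matches_monte_carlo_oracle(self):
        """Noncentral-t power vs a 10,000-rep simulated rejection rate."""
        d, n1, n2, alpha = 0.5, 13, 228, 0.05
        rng = np.random.default_rng(2024)
        reps = 10_000
        a = rng.normal(d, 1.0, size=(reps, n1))
        b = rng.normal(0.0, 1.0, size=(reps, n2))
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
        t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(1 / n1 + 1 / n2))
        tcrit = stats.t.ppf(1 - alpha / 2, n1 + n2 - 2)
        mc_power = np.mean(np.abs(t) > tcrit)
        assert power_two_sample_t(d, n1, n2, alpha) == pytest.approx(mc_power, abs=0.02)

    def test_power_increases_with_effect_size(self):
        powers = [power_two_sample_t(d, 13, 228) for d in (0.2, 0.5, 0.8, 1.2)]
        assert powers == sorted(powers)
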