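"""Tornado, two-way grid, PSA draws, CEAC and WTP interpolation."""

import numpy as np
import pytest

from oncocea import (
    CEACPoint,
    PsaParameterSpec,
    PsaSpecError,
    ceac,
    ceac_table,
    draw_parameters,
    one_way,
    psa_table,
    run_base_case,
    run_psa,
    two_way,
    wtp_at_probability,
)
from oncocea.sensitivity import PsaDraw


class TestDrawParameters:
    def test_fixed_always_returns_mean(self):
        spec = PsaParameterSpec("econ.utility_pfs", "fixed", 0.84, 0.84, 0.84)
        assert all(
            draw_parameters([spec], seed)["econ.utility_pfs"] == 0.84
            for seed in range(5)
        )

    def test_uniform_discount_rate_within_printed_range(self):
        spec = PsaParameterSpec("econ.discount_rate_annual", "uniform", 0.03, 0.0, 0.05)
        rng = np.random.default_rng(0)
        draws = [draw_parameters([spec], rng)[spec.name] for _ in range(2000)]
        assert min(draws) >= 0.0 and max(draws) <= 0.05

    def test_beta_utility_mean_recovered(self):
        """Moment-matched beta for the PFS utility: sample mean within 3 SE."""
        spec = PsaParameterSpec("econ.utility_pfs", "beta", 0.84, 0.672, 1.0)
        rng = np.random.default_rng(1)
        draws = np.array([draw_parameters([spec], rng)[spec.name] for _ in range(10_000)])
        se = (1.0 - 0.672) / (2 * 1.96)
        assert np.all((draws > 0) & (draws < 1))
        assert abs(draws.mean() - 0.84) < 3 * se / np.sqrt(len(draws))

    def test_gamma_cost_mean_and_positivity(self):
        spec = PsaParameterSpec("econ.bsc_cost_per_cycle", "gamma", 4143.0, 3314.0, 4972.0)
        rng = np.random.default_rng(2)
        draws = np.array([draw_parameters([spec], rng)[spec.name] for _ in range(10_000)])
        se = (4972 - 3314) / (2 * 1.96)
        assert np.all(draws > 0)
        assert abs(draws.mean() - 4143.0) < 3 * se / np.sqrt(len(draws))

    def test_normal_truncated_to_range(self):
        spec = PsaParameterSpec("patient.body_weight", "normal", 70.0, 56.0, 84.0)
        rng = np.random.default_rng(3)
        draws = [draw_parameters([spec], rng)[spec.name] for _ in range(2000)]
        assert min(draws) >= 56.0 and max(draws) <= 84.0

    def test_infeasible_beta_rejected(self):
        spec = PsaParameterSpec("econ.utility_pfs", "beta", 0.5, -3.0, 4.0)
        with pytest.raises(PsaSpecError, match="utility_pfs"):
            draw_parameters([spec], 0)


class TestOneWay:
    def test_pfs_utilities_dominate_tornado(self, overall_inputs):
        """Arm-specific PFS utilities carry the widest ICER spans."""
        entries = one_way(overall_inputs)
        assert entries[0].parameter == "intervention.utility_pfs"
        assert "utility_pfs" in entries[1].parameter
        assert all(e.span >= 0 for e in entries)
        assert [e.span for e in entries] == sorted(
            (e.span for e in entries), reverse=True
        )

    def test_ranking_invariant_to_listing_order(self, overall_inputs):
        params = ["econ.bsc_cost_per_cycle", "intervention.olaparib_cost_per_cycle",
                  "econ.utility_pd"]
        a = one_way(overall_inputs, params)
        b = one_way(overall_inputs, params[::-1])
        assert [e.parameter for e in a] == [e.parameter for e in b]

    def test_null_parameter_ranks_last(self, overall_inputs):
        entries = one_way(overall_inputs, ["econ.utility_pd", "patient.serum_creatinine"])
        assert entries[-1].parameter == "patient.serum_creatinine"
        assert entries[-1].span == 0.0

    def test_raising_olaparib_price_raises_icer(self, overall_inputs):
        base = run_base_case(overall_inputs)[2].icer_per_qaly
        entry = next(
            e for e in one_way(overall_inputs, ["intervention.olaparib_cost_per_cycle"])
        )
        assert entry.icer_at_high > base > entry.icer_at_low

    def test_utility_excursion_capped_at_one(self, overall_inputs):
        entry = one_way(overall_inputs, ["intervention.utility_pfs"])[0]
        assert entry.high_value == 1.0  # 0.84 * 1.2 > 1 gets capped

    def test_invalid_fraction_rejected(self, overall_inputs):
        with pytest.raises(ValueError):
            one_way(overall_inputs, fraction=1.5)

    def test_unresolvable_parameter_rejected(self, overall_inputs):
        with pytest.raises(KeyError):
            one_way(overall_inputs, ["econ.nonexistent"])


class TestTwoWay:
    def test_monotone_in_intervention_utility(self, overall_inputs):
        grid = two_way(
            overall_inputs,
            "intervention.utility_pfs", np.linspace(0.70, 1.0, 7),
            "comparator.utility_pfs", [0.76, 0.84, 0.92],
            wtp=150_000.0,
        )
        for _, col in grid.groupby("comparator.utility_pfs"):
            flags = col.sort_values("intervention.utility_pfs")["cost_effective"]
            assert list(flags) == sorted(flags)  # False before True only

    def test_zero_wtp_never_cost_effective_without_dominance(self, overall_inputs):
        grid = two_way(
            overall_inputs,
            "intervention.utility_pfs", [0.8, 1.0],
            "comparator.utility_pfs", [0.8],
            wtp=0.0,
        )
        assert not grid["cost_effective"].any()


class TestPsa:
    def test_all_fixed_specs_reproduce_base_case(self, overall_inputs):
        import dataclasses

        fixed = dataclasses.replace(
            overall_inputs,
            psa_specs=tuple(
                dataclasses.replace(s, family="fixed") for s in overall_inputs.psa_specs
            ),
        )
        base = run_base_case(overall_inputs)[2]
        (draw,) = run_psa(fixed, n_iterations=1, seed=0)
        assert draw.delta_cost == pytest.approx(base.delta_cost, abs=1e-9)
        assert draw.delta_qaly == pytest.approx(base.delta_qaly, abs=1e-12)

    def test_seeded_reproducibility_byte_for_byte(self, overall_inputs):
        a = psa_table(run_psa(overall_inputs, 25, seed=42)).to_csv()
        b = psa_table(run_psa(overall_inputs, 25, seed=42)).to_csv()
        assert a == b

    def test_different_seeds_differ(self, overall_inputs):
        a = run_psa(overall_inputs, 5, seed=1)
        b = run_psa(overall_inputs, 5, seed=2)
        assert any(x.delta_cost != y.delta_cost for x, y in zip(a, b))

    def test_nonpositive_iterations_rejected(self, overall_inputs):
        with pytest.raises(ValueError):
            run_psa(overall_inputs, 0)


class TestCeac:
    def test_all_dominant_draws_give_probability_one(self):
        draws = [PsaDraw(-100.0, 0.5, {}) for _ in range(10)]
        curve = ceac(draws, [0, 50_000, 100_000])
        assert all(p.probability_cost_effective == 1.0 for p in curve)

    def test_wtp_zero_counts_cost_saving_draws(self):
        draws = [PsaDraw(-1.0, 0.1, {}), PsaDraw(1.0, 0.1, {}), PsaDraw(2.0, -0.1, {})]
        (p0,) = ceac(draws, [0.0])
        assert p0.probability_cost_effective == pytest.approx(1 / 3)

    def test_monotone_when_gains_positive(self, overall_inputs):
        draws = run_psa(overall_inputs, 200, seed=9)
        positive = [d for d in draws if d.delta_qaly > 0]
        curve = ceac(positive, np.arange(0, 300_001, 10_000))
        probs = [p.probability_cost_effective for p in curve]
        assert probs == sorted(probs)

    def test_table_round_trip(self, overall_inputs):
        curve = ceac(run_psa(overall_inputs, 50, seed=4), [0.0, 150_000.0])
        table = ceac_table(curve)
        assert list(table.columns) == ["wtp_usd_per_qaly", "probability_cost_effective"]


class TestWtpInterpolation:
    def test_midpoint_interpolation(self):
        curve = [CEACPoint(100_000, 0.4), CEACPoint(200_000, 0.6)]
        assert wtp_at_probability(curve, 0.5) == pytest.approx(150_000.0)

    def test_out_of_range_rejected(self):
        curve = [CEACPoint(0, 0.1), CEACPoint(100_000, 0.9)]
        with pytest.raises(ValueError):
            wtp_at_probability(curve, 0.99)
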