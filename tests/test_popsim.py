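"""Ground-truth population generator: proportions, determinism, injury effects."""

import numpy as np
import pytest

from drgquant import popsim
from drgquant.popsim import (
    ConditionEffect,
    PopulationParams,
    population_to_frame,
    frame_to_population,
    sample_population,
    apply_condition_effects,
)


def _combo_fractions(pop, probes):
    n = len(pop)
    out = {}
    for nr in pop:
        key = nr.truth_combo()
        out[key] = out.get(key, 0) + 1 / n
    return out


class TestSamplePopulation:
    def test_joint_combination_fractions_within_3se(self):
        """2038 draws from the multiplex joint distribution recover every
        category probability within 3 binomial standard errors."""
        params = popsim.multiplex_coexpression_params()
        n = 2038
        pop = sample_population(params, n, seed=7)
        fracs = _combo_fractions(pop, params.probes)
        for combo, p in params.coexpr_probs.items():
            se = np.sqrt(p * (1 - p) / n)
            got = fracs.get(popsim.combo_label(combo), 0.0)
            assert abs(got - p) <= 3 * se, (combo, got, p)

    def test_all_mass_on_none_gives_no_expression(self):
        params = PopulationParams(
            mode="multinomial",
            probes=("ASIC1a", "ASIC2b", "ASIC3"),
            coexpr_probs={frozenset(): 1.0},
        )
        pop = sample_population(params, 50, seed=0)
        assert all(not any(nr.truth_expr.values()) for nr in pop)
        # negative neurons draw counts from the negative distribution (<= 2)
        assert all(c <= 2 for nr in pop for c in nr.true_puncta.values())

    def test_determinism_and_conservation(self):
        params = popsim.multiplex_coexpression_params()
        a = population_to_frame(sample_population(params, 100, seed=42))
        b = population_to_frame(sample_population(params, 100, seed=42))
        assert a.equals(b)
        assert len(a) == 100
        assert a["marker"].value_counts().sum() == 100

    def test_bernoulli_marginals(self):
        params = popsim.asic3_marker_params("NF200")
        pop = sample_population(params, 4000, seed=3)
        frac = np.mean([nr.truth_expr["ASIC3"] for nr in pop])
        assert abs(frac - 0.73) <= 3 * np.sqrt(0.73 * 0.27 / 4000)

    def test_positive_counts_exceed_negative_counts(self):
        params = popsim.asic3_marker_params("CGRP")
        pop = sample_population(params, 500, seed=5)
        for nr in pop:
            if nr.truth_expr["ASIC3"]:
                assert nr.true_puncta["ASIC3"] >= 5
            else:
                assert nr.true_puncta["ASIC3"] <= 2

    def test_soma_areas_positive(self):
        params = PopulationParams(
            soma_area_params={m: (100.0, 400.0) for m in popsim.MARKERS}
        )
        pop = sample_population(params, 500, seed=1)
        assert all(nr.soma_area > 0 for nr in pop)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            sample_population(PopulationParams(), 0, seed=0)


class TestValidation:
    def test_marker_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="marker_proportions"):
            PopulationParams(marker_proportions={"NF200": 0.5, "CGRP": 0.2})

    def test_probability_outside_unit_interval_named(self):
        with pytest.raises(ValueError, match="CGRP.*ASIC3"):
            PopulationParams(expr_prob={("CGRP", "ASIC3"): 1.4})

    def test_nonpositive_area_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            PopulationParams(soma_area_params={"NF200": (700.0, 0.0)})

    def test_effect_with_unknown_probe_rejected(self):
        with pytest.raises(ValueError, match="unknown probe"):
            PopulationParams(
                condition_effects=[
                    ConditionEffect("L4", "CGRP", "ASIC9", new_probability=0.1)
                ]
            )


class TestConditionEffects:
    @pytest.fixture
    def injured_params(self):
        return PopulationParams(
            mode="bernoulli",
            probes=("ASIC1a", "ASIC1b"),
            marker_proportions={"CGRP": 0.5, "IB4": 0.5},
            expr_prob={
                ("CGRP", "ASIC1a"): 0.30,
                ("CGRP", "ASIC1b"): 0.30,
                ("IB4", "ASIC1a"): 0.30,
                ("IB4", "ASIC1b"): 0.30,
            },
            soma_area_params={"CGRP": (450.0, 100.0), "IB4": (400.0, 100.0)},
            condition_effects=[
                ConditionEffect("L4", "CGRP", "ASIC1a", new_probability=0.10),
                ConditionEffect("L4", "CGRP", "ASIC1b", new_probability=0.55),
            ],
        )

    def test_opposite_shifts_confined_to_target_group(self, injured_params):
        """Cuff moves L4 CGRP ASIC1a down and ASIC1b up; IB4 neurons and the
        L5 segment are bitwise untouched."""
        naive = sample_population(injured_params, 4000, seed=11, segment="L4")
        sham = apply_condition_effects(naive, injured_params, "sham", "L4", seed=1)
        cuff = apply_condition_effects(naive, injured_params, "cuff", "L4", seed=1)
        cuff_l5 = apply_condition_effects(naive, injured_params, "cuff", "L5", seed=1)

        def frac(pop, marker, probe):
            sel = [nr.truth_expr[probe] for nr in pop if nr.marker == marker]
            return np.mean(sel)

        assert frac(cuff, "CGRP", "ASIC1a") < frac(sham, "CGRP", "ASIC1a") - 0.1
        assert frac(cuff, "CGRP", "ASIC1b") > frac(sham, "CGRP", "ASIC1b") + 0.1
        for s, c, c5 in zip(sham, cuff, cuff_l5):
            if s.marker == "IB4":
                assert s.truth_expr == c.truth_expr
            assert s.truth_expr == c5.truth_expr

    def test_sham_is_pure_relabel(self, injured_params):
        naive = sample_population(injured_params, 200, seed=2)
        sham = apply_condition_effects(naive, injured_params, "sham", "L4", seed=9)
        for a, b in zip(naive, sham):
            assert b.condition == "sham" and b.segment == "L4"
            assert a.truth_expr == b.truth_expr
            assert a.true_puncta == b.true_puncta
            assert a.soma_area == b.soma_area

    def test_intensity_multiplier_recorded(self):
        params = PopulationParams(
            probes=("ASIC2b",),
            marker_proportions={"CGRP": 1.0},
            expr_prob={("CGRP", "ASIC2b"): 1.0},
            soma_area_params={"CGRP": (450.0, 80.0)},
            condition_effects=[
                ConditionEffect("L4", "CGRP", "ASIC2b", intensity_multiplier=1.5)
            ],
        )
        naive = sample_population(params, 20, seed=0)
        cuff = apply_condition_effects(naive, params, "cuff", "L4", seed=0)
        assert all(nr.intensity_scale["ASIC2b"] == 1.5 for nr in cuff)
        assert all(nr.intensity_scale["ASIC2b"] == 1.0 for nr in naive)


class TestInvariants:
    def test_multinomial_recovery_across_replicates(self):
        """In >= 95% of 100 seeded replicates (n=1000) every category lies
        within 4 SE of its generating probability."""
        params = popsim.multiplex_coexpression_params()
        n = 1000
        hits = 0
        for seed in range(100):
            pop = sample_population(params, n, seed=seed)
            fracs = _combo_fractions(pop, params.probes)
            ok = all(
                abs(fracs.get(popsim.combo_label(c), 0.0) - p)
                <= 4 * np.sqrt(p * (1 - p) / n)
                for c, p in params.coexpr_probs.items()
            )
            hits += ok
        assert hits >= 95

    def test_soma_area_independent_of_expression(self):
        params = popsim.multiplex_coexpression_params()
        pop = sample_population(params, 3000, seed=21)
        areas = np.array([nr.soma_area for nr in pop])
        state = np.array([nr.truth_expr["ASIC3"] for nr in pop], dtype=float)
        r = np.corrcoef(areas, state)[0, 1]
        assert abs(r) < 0.06

    def test_frame_round_trip(self):
        params = popsim.multiplex_coexpression_params()
        pop = sample_population(params, 30, seed=4)
        back = frame_to_population(population_to_frame(pop, params.probes))
        assert [nr.truth_expr for nr in back] == [nr.truth_expr for nr in pop]
        assert np.allclose([nr.soma_area for nr in back], [nr.soma_area for nr in pop])
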