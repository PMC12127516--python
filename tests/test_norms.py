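"""Normative flagging: cutoffs, domains, atrophy composites, derived norms."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import memclinic as mc
from memclinic.norms import (ATROPHY_REGIONS, DEFAULT_TEST_BATTERY,
                             IMPAIRED_IF_ABOVE, IMPAIRED_IF_BELOW,
                             LANGUAGE_REGIONS, CognitiveNorm)


def simple_norms():
    """Hand-set normative table with round cutoffs for rule tests."""
    cognitive = {
        "avlt_trial5": CognitiveNorm(5, IMPAIRED_IF_BELOW, "memory"),
        "avlt_delayed": CognitiveNorm(2, IMPAIRED_IF_BELOW, "memory"),
        "avlt_recognition": CognitiveNorm(8, IMPAIRED_IF_BELOW, "memory"),
        "digit_span_fwd": CognitiveNorm(5, IMPAIRED_IF_BELOW, "attention_executive"),
        "digit_span_bwd": CognitiveNorm(3, IMPAIRED_IF_BELOW, "attention_executive"),
        "tmt_a_time": CognitiveNorm(90, IMPAIRED_IF_ABOVE, "attention_executive"),
        "tmt_b_time": CognitiveNorm(280, IMPAIRED_IF_ABOVE, "attention_executive"),
        "symbol_digit": CognitiveNorm(25, IMPAIRED_IF_BELOW, "attention_executive"),
        "clock_total": CognitiveNorm(4, IMPAIRED_IF_BELOW, "visuoconstructive"),
        "fluency_animals": CognitiveNorm(10, IMPAIRED_IF_BELOW, "language"),
        "fluency_vegetables": CognitiveNorm(7, IMPAIRED_IF_BELOW, "language"),
        "bnt_total": CognitiveNorm(20, IMPAIRED_IF_BELOW, "language"),
        "mmse": CognitiveNorm(24, IMPAIRED_IF_BELOW, "global"),
    }
    vol = {f"{r}_total": 5.0 for r in ATROPHY_REGIONS}
    vol.update({f"{r}_{h}": 2.5 for r in LANGUAGE_REGIONS for h in ("rx", "lx")})
    return mc.NormativeTable(cognitive, vol, faq_item_threshold=2)


def best_scores():
    scores = {t: 1000.0 for t in DEFAULT_TEST_BATTERY}
    scores["tmt_a_time"] = scores["tmt_b_time"] = 1.0  # lower time is better
    for item in mc.schema.FAQ_ITEMS:
        scores[item] = 0
    return scores


class TestCognitiveFlags:
    def test_population_best_scores_flag_nothing(self):
        p = mc.flag_cognitive_deficits(best_scores(), simple_norms())
        assert not any(p.impaired.values())
        assert p.n_cognitive_impairments == 0 and p.n_functional_impairments == 0
        assert not (p.significant_functional_impairment or
                    p.significant_cognitive_impairment or p.memory_impaired)

    def test_memory_deficit_forced_by_cutoff_direction(self):
        scores = best_scores()
        scores["mmse"] = 20
        scores["avlt_delayed"] = 0
        p = mc.flag_cognitive_deficits(scores, simple_norms())
        assert p.memory_impaired and p.domain_impaired["memory"]
        assert p.n_cognitive_impairments >= 1

    def test_missing_score_not_impaired_but_recorded(self):
        scores = best_scores()
        scores["clock_total"] = float("nan")
        p = mc.flag_cognitive_deficits(scores, simple_norms())
        assert not p.impaired["clock_total"]
        assert "clock_total" in p.unassessed

    def test_random_grid_matches_bruteforce_comparison(self):
        """Per-test flags equal an exhaustive direction-aware comparison loop."""
        rng = np.random.default_rng(0)
        norms = simple_norms()
        for _ in range(200):
            scores = {t: float(rng.integers(0, 40)) for t in norms.cognitive}
            for item in mc.schema.FAQ_ITEMS:
                scores[item] = int(rng.integers(0, 5))
            p = mc.flag_cognitive_deficits(scores, norms)
            for t, n in norms.cognitive.items():
                expect = (scores[t] < n.cutoff if n.direction == IMPAIRED_IF_BELOW
                          else scores[t] > n.cutoff)
                assert p.impaired[t] == expect
            for d in mc.norms.COGNITIVE_DOMAINS:
                expect_d = any(p.impaired[t] for t, n in norms.cognitive.items()
                               if n.domain == d)
                assert p.domain_impaired[d] == expect_d
            n_func = sum(scores[i] >= 2 for i in mc.schema.FAQ_ITEMS)
            assert p.n_functional_impairments == n_func
            assert p.significant_functional_impairment == (
                any(scores[i] >= 4 for i in mc.schema.FAQ_ITEMS) or n_func >= 3)

    def test_count_unit_tests_vs_domains(self):
        scores = best_scores()
        scores["avlt_trial5"] = 0
        scores["avlt_delayed"] = 0
        by_domain = mc.flag_cognitive_deficits(scores, simple_norms())
        by_test = mc.flag_cognitive_deficits(scores, simple_norms(), count_unit="test")
        assert by_domain.n_cognitive_impairments == 1
        assert by_test.n_cognitive_impairments == 2

    def test_assessed_test_without_norm_is_configuration_error(self):
        norms = simple_norms()
        cognitive = dict(norms.cognitive)
        del cognitive["mmse"]
        broken = mc.NormativeTable(cognitive, norms.volumetric_p10)
        with pytest.raises(mc.ConfigurationError):
            mc.flag_cognitive_deficits(best_scores(), broken)

    @given(st.sampled_from(sorted(DEFAULT_TEST_BATTERY)),
           st.floats(0.5, 20, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_worsening_a_score_never_clears_flags(self, test, delta):
        norms = simple_norms()
        scores = best_scores()
        scores.update({t: norms.cognitive[t].cutoff for t in norms.cognitive})
        before = mc.flag_cognitive_deficits(scores, norms)
        direction = norms.cognitive[test].direction
        scores[test] += delta if direction == IMPAIRED_IF_ABOVE else -delta
        after = mc.flag_cognitive_deficits(scores, norms)
        for t in norms.cognitive:
            assert after.impaired[t] >= before.impaired[t]
        assert after.n_cognitive_impairments >= before.n_cognitive_impairments


class TestAtrophyFlags:
    def test_all_volumes_above_norms_inconsistent_mri(self):
        vols = {k: 10.0 for k in simple_norms().volumetric_p10}
        a = mc.flag_regional_atrophy(vols, simple_norms())
        assert not any(a.atrophic.values())
        assert a.mri_inconsistent

    def test_isolated_hippocampal_atrophy_is_medial_temporal(self):
        vols = {k: 10.0 for k in simple_norms().volumetric_p10}
        vols["hippocampus_total"] = 4.0
        a = mc.flag_regional_atrophy(vols, simple_norms())
        assert a.medial_temporal_atrophy
        assert not (a.parieto_occipital_atrophy or a.frontotemporal_atrophy or
                    a.dominant_hemisphere_focal_atrophy or a.mri_inconsistent)

    def test_tie_at_percentile_not_atrophic(self):
        vols = {k: 10.0 for k in simple_norms().volumetric_p10}
        vols["hippocampus_total"] = 5.0  # exactly the 10th percentile
        a = mc.flag_regional_atrophy(vols, simple_norms())
        assert not a.atrophic["hippocampus_total"]

    def test_left_dominant_focal_requires_spared_right(self):
        norms = simple_norms()
        vols = {k: 10.0 for k in norms.volumetric_p10}
        vols["mt_cortex_lx"] = 1.0
        a = mc.flag_regional_atrophy(vols, norms)
        assert a.dominant_hemisphere_focal_atrophy
        vols["mt_cortex_rx"] = 1.0
        b = mc.flag_regional_atrophy(vols, norms)
        assert not b.dominant_hemisphere_focal_atrophy

    def test_random_grid_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        norms = simple_norms()
        keys = sorted(norms.volumetric_p10)
        for _ in range(300):
            vols = {k: float(rng.uniform(0, 10)) for k in keys}
            a = mc.flag_regional_atrophy(vols, norms)
            flags = {k: vols[k] < norms.volumetric_p10[k] for k in keys}
            assert a.atrophic == flags
            mt = any(flags[f"{r}_total"] for r in
                     ("hippocampus", "parahippocampus", "mt_cortex"))
            po = flags["po_cortex_total"] or flags["precuneus_total"]
            ft = flags["ft_cortex_total"]
            dom = any(flags[f"{r}_lx"] and not flags[f"{r}_rx"]
                      for r in ("mt_cortex", "ft_cortex"))
            assert (a.medial_temporal_atrophy, a.parieto_occipital_atrophy,
                    a.frontotemporal_atrophy, a.dominant_hemisphere_focal_atrophy,
                    a.mri_inconsistent) == (mt, po, ft, dom,
                                            not (mt or po or ft or dom))

    def test_missing_volume_excluded_from_composites(self):
        vols = {k: 10.0 for k in simple_norms().volumetric_p10}
        vols["hippocampus_total"] = float("nan")
        a = mc.flag_regional_atrophy(vols, simple_norms())
        assert "hippocampus_total" in a.unassessed
        assert not a.medial_temporal_atrophy


class TestDerivedNorms:
    def test_identical_reference_gives_that_value(self, spec):
        one = mc.generate_cohort(spec, {"LOW_RISK": 1}, seed=0)
        ref = pd.concat([one] * 60, ignore_index=True)
        norms = mc.derive_norms_from_reference_cohort(ref)
        assert norms.volumetric_p10["hippocampus_total"] == pytest.approx(
            float(one["hippocampus_total"].iloc[0]))

    def test_uniform_sample_linear_interpolation_quantile(self, spec):
        ref = mc.generate_cohort(spec, {"LOW_RISK": 100}, seed=0)
        ref["hippocampus_total"] = np.arange(1.0, 101.0)
        norms = mc.derive_norms_from_reference_cohort(ref)
        assert norms.volumetric_p10["hippocampus_total"] == pytest.approx(10.9)

    def test_too_few_subjects_rejected(self, spec):
        ref = mc.generate_cohort(spec, {"LOW_RISK": 20}, seed=0)
        with pytest.raises(mc.ValidationError):
            mc.derive_norms_from_reference_cohort(ref)

    def test_healthier_reference_never_lowers_below_cutoff(self, spec):
        """Adding healthier values keeps an impaired-if-below cutoff at or above."""
        ref = mc.generate_cohort(spec, {"LOW_RISK": 200}, seed=4)
        norms = mc.derive_norms_from_reference_cohort(ref)
        healthier = ref.copy()
        healthier["avlt_trial5"] = healthier["avlt_trial5"] + 3
        enlarged = pd.concat([ref, healthier], ignore_index=True)
        norms2 = mc.derive_norms_from_reference_cohort(enlarged)
        assert norms2.cognitive["avlt_trial5"].cutoff >= \
            norms.cognitive["avlt_trial5"].cutoff

    def test_yaml_round_trip(self, tmp_path, norms):
        path = tmp_path / "norms.yaml"
        norms.to_yaml(path)
        back = mc.NormativeTable.from_yaml(path)
        assert back == norms
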