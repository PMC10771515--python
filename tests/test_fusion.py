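"""Label remapping, fusion probability rules, and the 6-bit probability-map
selection problem."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinfuse import beosa, fusion
from twinfuse.fusion import (
    HISTO_LABEL_MAP, MAMMO_LABEL_MAP, FusionItem, LabelMap,
    build_fusion_space, fused_label, fusion_fitness, modality_fused_probability,
    multimodal_fused_probability, optimize_fusion, remap_label,
    remap_probabilities,
)


class TestRemapLabel:
    @pytest.mark.parametrize("fine,label_map,coarse", [
        ("BC", MAMMO_LABEL_MAP, "B"),
        ("DC", HISTO_LABEL_MAP, "M"),
        ("N", MAMMO_LABEL_MAP, "N"),
        ("N", HISTO_LABEL_MAP, "N"),
        ("CALC", MAMMO_LABEL_MAP, "M"),
        ("PT", HISTO_LABEL_MAP, "B"),
    ])
    def test_mapping(self, fine, label_map, coarse):
        assert remap_label(fine, label_map) == coarse

    def test_unknown_label_lists_valid(self):
        with pytest.raises(KeyError, match="valid"):
            remap_label("XX", MAMMO_LABEL_MAP)

    def test_partition_enforced(self):
        with pytest.raises(ValueError):
            LabelMap({"N": ["N"], "B": ["X"], "M": ["X"]})


class TestRemapProbabilities:
    def test_sum_rule_mammography(self):
        # fine order N, BC, BM, CALC, M
        out = remap_probabilities([0.2, 0.1, 0.1, 0.3, 0.3], MAMMO_LABEL_MAP)
        assert np.allclose(out, [0.2, 0.2, 0.6])

    def test_one_hot_preserved(self):
        fine = np.zeros(5)
        fine[3] = 1.0  # CALC -> M
        assert np.allclose(remap_probabilities(fine, MAMMO_LABEL_MAP), [0, 0, 1])

    def test_uniform_histology_counts_members(self):
        out = remap_probabilities(np.full(12, 1 / 12), HISTO_LABEL_MAP)
        assert np.allclose(out, [1 / 12, 5 / 12, 6 / 12])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5))
    def test_mass_conserved(self, raw):
        fine = np.asarray(raw) / np.sum(raw)
        out = remap_probabilities(fine, MAMMO_LABEL_MAP)
        assert abs(out.sum() - 1.0) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            remap_probabilities([0.5, 0.5], MAMMO_LABEL_MAP)


class TestFusedProbabilities:
    def test_modality_rule_reproduces_printed_rows(self):
        assert modality_fused_probability(1.0, 0.954039) == pytest.approx(0.977020, abs=5.1e-7)
        assert modality_fused_probability(1.0, 0.671327) == pytest.approx(0.835664, abs=5.1e-7)

    def test_modality_rule_idempotent_on_equal_inputs(self):
        for x in (0.0, 0.3, 1.0):
            assert modality_fused_probability(x, x) == x

    def test_multimodal_rule_reproduces_printed_rows(self):
        assert multimodal_fused_probability(0.954039, 0.826078) == pytest.approx(0.683539, abs=5.1e-7)
        assert multimodal_fused_probability(0.954039, 0.567527) == pytest.approx(0.618901, abs=5.1e-7)
        assert multimodal_fused_probability(0.0, 0.0) == 0.0

    @pytest.mark.parametrize("fn", [modality_fused_probability,
                                    multimodal_fused_probability])
    def test_out_of_range_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(1.2, 0.5)


class TestFusedLabel:
    def test_disagreement_uses_en_dash(self):
        assert fused_label("M", "N") == "M–N"

    def test_agreement_collapses(self):
        assert fused_label("B", "B") == "B"

    def test_order_histology_first(self):
        assert fused_label("N", "M") == "N–M"

    def test_invalid_label(self):
        with pytest.raises(ValueError):
            fused_label("Q", "N")


def _item(probs, pos=None):
    return FusionItem(index=0, probs=np.asarray(probs),
                      pos=np.ones(6, dtype=int) if pos is None else np.asarray(pos))


class TestFusionSpace:
    def test_cartesian_count_and_init(self, table4_records):
        hist, mammo = table4_records
        space = build_fusion_space(hist[:2], mammo[:3])
        assert [it.index for it in space] == list(range(6))
        for it in space:
            assert (it.pos == 1).all()
            assert it.probs[:3].sum() == pytest.approx(1.0)
            assert it.probs[3:].sum() == pytest.approx(1.0)

    def test_paired_mode(self, table4_records):
        hist, mammo = table4_records
        space = build_fusion_space(hist, mammo, mode="paired")
        assert len(space) == 20

    def test_empty_rejected(self, table4_records):
        hist, _ = table4_records
        with pytest.raises(ValueError):
            build_fusion_space(hist, [])


class TestFusionFitness:
    def test_empty_selection_scores_two(self):
        assert fusion_fitness(_item([0.6, 0.3, 0.1, 0.5, 0.4, 0.1],
                                    pos=[0] * 6)) == 2.0

    def test_full_selection_of_normalized_vectors_scores_zero(self):
        assert fusion_fitness(_item([0.6, 0.3, 0.1, 0.5, 0.4, 0.1])) == pytest.approx(0.0)

    def test_hand_evaluated_partial_selection(self):
        it = _item([0.6, 0.3, 0.1, 0.5, 0.4, 0.1], pos=[1, 0, 0, 1, 0, 0])
        assert fusion_fitness(it) == pytest.approx(2.0 - (0.6 + 0.5))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6),
           st.integers(0, 63), st.integers(0, 5))
    def test_adding_a_bit_never_increases_fit(self, probs, pos_int, extra):
        pos = np.array([(pos_int >> k) & 1 for k in range(6)])
        bigger = pos.copy()
        bigger[extra] = 1
        lo = fusion_fitness(_item(probs, pos=bigger))
        hi = fusion_fitness(_item(probs, pos=pos))
        assert lo <= hi + 1e-12


class TestOptimizeFusion:
    def test_full_selection_is_optimal_for_single_item(self, table4_records):
        hist, mammo = table4_records
        space = build_fusion_space(hist[:1], mammo[:1])
        items, report = optimize_fusion(space)
        assert (items[0].pos == 1).all()
        assert items[0].fit == pytest.approx(0.0)

    def test_matches_brute_force_over_64_positions(self):
        probs = np.array([0.5, 0.3, 0.2, 0.7, 0.2, 0.1])
        rec = fusion.ProbabilityRecord("s", "histology", 1.0, 0.9, "DC", "DC",
                                       coarse_probs=probs[:3])
        rec2 = fusion.ProbabilityRecord("s", "mammography", 1.0, 0.9, "N", "N",
                                        coarse_probs=probs[3:])
        space = build_fusion_space([rec], [rec2])
        brute = min(
            fusion_fitness(_item(probs, pos=[(k >> b) & 1 for b in range(6)]))
            for k in range(64))
        items, _ = optimize_fusion(space, beosa.BeosaConfig(pop_size=8, max_iter=15, seed=2))
        assert items[0].fit == pytest.approx(brute)

    def test_fixture_report_labels(self, table4_records):
        hist, mammo = table4_records
        space = build_fusion_space(hist, mammo, mode="paired")
        _, report = optimize_fusion(space)
        assert (report["fused_label"] == "M–N").all()
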