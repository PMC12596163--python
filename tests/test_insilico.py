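import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecnorm import (CountMatrix, SampleMetadata, ValidationError, compare_ecs,
                    evaluate_ratio, flip_direction, normalization_ratio,
                    significance_stars, wilcoxon_rank_sum)
from ecnorm.benchmarks import brute_force_wilcoxon_p, ratio_detection_power


def _cm(rows: dict[str, list[int]]):
    genes = tuple(rows)
    counts = np.array(list(rows.values()), dtype=np.int64)
    samples = tuple(f"s{j}" for j in range(counts.shape[1]))
    return CountMatrix(genes, samples, counts)


class TestNormalizationRatio:
    def test_simple_ratios(self):
        cm = _cm({"bm": [10, 20], "ec": [5, 4]})
        rc = normalization_ratio(cm, "bm", "ec")
        assert np.allclose(rc.ratios, [2.0, 5.0])
        assert rc.excluded_samples == ()

    def test_zero_ec_sample_excluded_and_logged(self):
        cm = _cm({"bm": [10, 20, 30], "ec": [5, 4, 0]})
        rc = normalization_ratio(cm, "bm", "ec", zero_policy="exclude")
        assert rc.sample_ids == ("s0", "s1")
        assert rc.excluded_samples == ("s2",)

    def test_pseudocount_policy_keeps_all_samples(self):
        cm = _cm({"bm": [10, 20, 30], "ec": [5, 4, 0]})
        rc = normalization_ratio(cm, "bm", "ec", zero_policy="pseudocount")
        assert len(rc.ratios) == 3
        assert rc.ratios[2] == pytest.approx(30.5 / 0.5)

    def test_self_ratio_rejected(self):
        cm = _cm({"bm": [10, 20], "ec": [5, 4]})
        with pytest.raises(ValidationError, match="differ"):
            normalization_ratio(cm, "bm", "bm")

    def test_all_zero_ec_rejected(self):
        cm = _cm({"bm": [10, 20], "ec": [0, 0]})
        with pytest.raises(ValidationError, match="every sample"):
            normalization_ratio(cm, "bm", "ec")

    def test_ratios_invariant_to_per_sample_scaling(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            b = rng.integers(1, 500, size=6)
            e = rng.integers(1, 500, size=6)
            c = int(rng.integers(2, 10))
            cm1 = _cm({"bm": b.tolist(), "ec": e.tolist()})
            scaled_b, scaled_e = b.copy(), e.copy()
            scaled_b[2] *= c
            scaled_e[2] *= c
            cm2 = _cm({"bm": scaled_b.tolist(), "ec": scaled_e.tolist()})
            r1 = normalization_ratio(cm1, "bm", "ec").ratios
            r2 = normalization_ratio(cm2, "bm", "ec").ratios
            assert np.allclose(r1, r2)


class TestWilcoxonRankSum:
    def test_fully_separated_triples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6],
                                 mode="exact") == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_matches_enumeration_oracle(self):
        import itertools
        for n in (5, 6, 7):
            values = list(range(1, n + 1))
            for na in range(1, n):
                for a in itertools.combinations(values, na):
                    b = [v for v in values if v not in a]
                    assert wilcoxon_rank_sum(
                        np.array(a, float), np.array(b, float), mode="exact"
                    ) == pytest.approx(brute_force_wilcoxon_p(a, b), abs=1e-12)

    def test_exact_mode_with_ties_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="ties"):
            p = wilcoxon_rank_sum([1, 1, 2], [2, 3, 4], mode="exact")
        assert 0 <= p <= 1

    @given(st.lists(st.integers(min_value=0, max_value=60), min_size=1,
                    max_size=8),
           st.lists(st.integers(min_value=0, max_value=60), min_size=1,
                    max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_under_group_swap(self, a, b):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        assert wilcoxon_rank_sum(a, b, mode="normal") == pytest.approx(
            wilcoxon_rank_sum(b, a, mode="normal"), abs=1e-12)

    def test_rank_invariance_under_ec_rescaling(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(1, 10, size=9)
        b = rng.uniform(2, 12, size=9)
        p1 = wilcoxon_rank_sum(a, b)
        p2 = wilcoxon_rank_sum(a / 3.0, b / 3.0)  # EC counts scaled by 3
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestSignificanceStars:
    @pytest.mark.parametrize("p,label", [
        (0.0005, "***"), (0.001, "***"), (0.002, "**"), (0.01, "**"),
        (0.03, "*"), (0.05, "*"), (0.0500001, "ns"), (0.5, "ns"), (1.0, "ns"),
    ])
    def test_star_mapping(self, p, label):
        assert significance_stars(p) == label

    @pytest.mark.parametrize("p", [-0.1, 1.1, np.nan])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValidationError):
            significance_stars(p)


class TestEvaluateAndFlip:
    def _evaluated(self):
        cm = _cm({"bm": [10, 12, 11, 40, 42, 41], "ec": [5, 5, 5, 5, 5, 5]})
        meta = SampleMetadata(cm.sample_ids,
                              ("A", "A", "A", "B", "B", "B"), reference="A")
        return evaluate_ratio(normalization_ratio(cm, "bm", "ec"), meta)

    def test_direction_and_stars_filled(self):
        rc = self._evaluated()
        assert rc.direction == 1
        assert rc.stars == significance_stars(rc.wilcoxon_p)

    def test_flip_negates_direction_only(self):
        rc = self._evaluated()
        flipped = flip_direction(rc)
        assert flipped.direction == -rc.direction
        assert flipped.wilcoxon_p == rc.wilcoxon_p
        assert np.array_equal(flipped.ratios, rc.ratios)
        assert flip_direction(flipped).direction == rc.direction


class TestCompareEcs:
    def test_stable_ec_recapitulates_and_confounded_ec_cancels(self, default_de):
        cm, meta, truth, _sf, _disp, res = default_de
        genes = truth.genes
        biomarker = genes.loc[genes["true_lfc"] == 2.0, "gene_id"].iloc[0]
        stable_ec = genes.loc[genes["is_stable"], "gene_id"].iloc[0]
        confounded_ec = genes.loc[genes["true_lfc"] == 2.0, "gene_id"].iloc[1]
        out = compare_ecs(cm, meta, [biomarker], [stable_ec, confounded_ec],
                          de=res)
        out = out.set_index("ec")
        assert bool(out.loc[stable_ec, "recapitulated"])
        assert not bool(out.loc[confounded_ec, "recapitulated"])

    def test_grid_shape_and_columns(self, default_de):
        cm, meta, truth, _sf, _disp, res = default_de
        genes = truth.genes
        bms = list(genes.loc[genes["is_de"], "gene_id"].head(2))
        ecs = list(genes.loc[genes["is_stable"], "gene_id"].head(3))
        out = compare_ecs(cm, meta, bms, ecs, de=res)
        assert len(out) == 6
        assert {"biomarker", "ec", "wilcoxon_p", "stars", "direction",
                "recapitulated"} <= set(out.columns)

    def test_confounded_ec_drives_power_to_type_i_level(self):
        assert ratio_detection_power(106, confounded=True, n_reps=100) <= 0.10
        assert ratio_detection_power(105, confounded=False, n_reps=100) >= 0.8
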