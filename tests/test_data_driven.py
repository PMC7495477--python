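import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from memstab.core import ProteinTarget, StabilityRecord, Variant
from memstab.data_driven import (
    FactorWeights,
    ScoringMatrix,
    classify_stability,
    classify_stability_records,
    conservation_bin,
    contact_bin,
    derive_factor_weights,
    derive_scoring_matrix,
    score_positions,
    weights_to_scores,
)
from memstab.simulate import PLANTED_STAB_AA


def _record(pos, wt, rel, state="apo", target="T"):
    mut = "L" if wt == "A" else "A"
    return StabilityRecord(target, Variant(pos, wt, mut), rel, state)


class TestClassification:
    @pytest.mark.parametrize("rel,label", [
        (150.0, "stabilising"),
        (100.0, "neutral"),
        (80.0, "neutral"),    # boundary exclusive: "below 80%"
        (140.0, "neutral"),   # boundary exclusive: "above 140%"
        (140.001, "stabilising"),
        (79.999, "destabilising"),
    ])
    def test_thresholds(self, rel, label):
        assert classify_stability(rel) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_stability(-1.0)


class TestFactorWeights:
    def _features(self, n):
        return pd.DataFrame({
            "position": range(1, n + 1),
            "topology_class": ["TM_helix"] * n,
            "conservation": [55.0] * n,
            "lipid_contact": [0.5] * n,
            "helix_contact": [0.5] * n,
            "disorder": [0.1] * n,
        })

    def test_direct_frequency(self):
        # level G: 10 records, 4 stabilising -> stab_weight 0.4
        records = ([_record(p, "G", 150) for p in range(1, 5)]
                   + [_record(p, "G", 100) for p in range(5, 11)]
                   + [_record(p, "V", 100) for p in range(11, 14)])
        labels = classify_stability_records(records)
        fw = derive_factor_weights(records, labels,
                                   {"T": self._features(13)}, "amino_acid")
        assert fw.table.loc["G", "stab_weight"] == pytest.approx(0.4)
        assert fw.table.loc["G", "n_observations"] == 10

    def test_all_neutral_gives_zero_weights(self):
        records = [_record(p, aa, 100)
                   for p, aa in enumerate("GVLK", start=1)]
        labels = classify_stability_records(records)
        fw = derive_factor_weights(records, labels,
                                   {"T": self._features(4)}, "amino_acid")
        assert (fw.table[["stab_weight", "destab_weight"]] == 0).all().all()

    def test_single_level_unrankable(self):
        records = [_record(1, "G", 100), _record(2, "G", 150)]
        labels = classify_stability_records(records)
        with pytest.raises(ValueError, match="at least 2"):
            derive_factor_weights(records, labels,
                                  {"T": self._features(2)}, "amino_acid")

    def test_neutrals_count_in_denominator_only(self):
        records = [_record(1, "G", 150), _record(2, "G", 100),
                   _record(3, "G", 50), _record(4, "V", 100)]
        labels = classify_stability_records(records)
        fw = derive_factor_weights(records, labels,
                                   {"T": self._features(4)}, "amino_acid")
        assert fw.table.loc["G", "stab_weight"] == pytest.approx(1 / 3)
        assert fw.table.loc["G", "destab_weight"] == pytest.approx(1 / 3)


def _weights_frame(levels, stab, destab, n_obs=None):
    return FactorWeights("amino_acid", pd.DataFrame({
        "stab_weight": stab,
        "destab_weight": destab,
        "n_observations": n_obs or [10] * len(levels),
    }, index=pd.Index(levels, name="level")))


class TestRankScores:
    def test_twenty_level_worked_example(self):
        """A level 4th by stabilising and last (20th) by destabilising
        association scores 17 + 20 = 37."""
        levels = [f"L{i:02d}" for i in range(20)]
        stab = list(np.linspace(1.0, 0.05, 20))   # L00 ranked 1st ... L19 last
        destab = list(np.linspace(1.0, 0.1, 20))  # descending ...
        destab[3] = 0.01                          # ... with L03 least destabilising
        fw = _weights_frame(levels, stab, destab)
        scores = weights_to_scores(fw).set_index("level")
        # L03: 4th-highest stab weight, 20th (last) destab weight
        assert scores.loc["L03", "stab_score"] == 17
        assert scores.loc["L03", "destab_score"] == 20
        assert scores.loc["L03", "combined"] == 37

    def test_two_level_bounds(self):
        fw = _weights_frame(["X", "Y"], [0.9, 0.1], [0.1, 0.9])
        scores = weights_to_scores(fw).set_index("level")
        assert scores.loc["X", "combined"] == 4   # best on both orderings
        assert scores.loc["Y", "combined"] == 2

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=12),
           st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=12))
    def test_scores_are_permutations(self, stab, destab):
        n = min(len(stab), len(destab))
        levels = [f"L{i}" for i in range(n)]
        fw = _weights_frame(levels, stab[:n], destab[:n])
        scores = weights_to_scores(fw)
        assert sorted(scores["stab_score"]) == list(range(1, n + 1))
        assert sorted(scores["destab_score"]) == list(range(1, n + 1))
        assert scores["combined"].between(2, 2 * n).all()

    def test_tie_break_by_observations_then_name(self):
        fw = _weights_frame(["B", "A", "C"], [0.5, 0.5, 0.5], [0.2, 0.2, 0.2],
                            n_obs=[5, 5, 9])
        scores = weights_to_scores(fw).set_index("level")
        # C has most observations -> stab rank 1; A before B by name
        assert scores.loc["C", "stab_score"] == 3
        assert scores.loc["A", "stab_score"] == 2
        assert scores.loc["B", "stab_score"] == 1


class TestMatrixDerivation:
    def test_invariant_to_order_and_duplication(self, stability_dataset):
        records, feats, _, _ = stability_dataset
        records = records[:400]
        m1 = derive_scoring_matrix(records, feats)
        m2 = derive_scoring_matrix(list(reversed(records)), feats)
        doubled = records + [
            StabilityRecord(r.target_id, r.variant, r.relative_stability,
                            r.state + "_copy") for r in records]
        m3 = derive_scoring_matrix(doubled, feats)
        key = ["factor", "level"]
        for other in (m2, m3):
            a = m1.table.sort_values(key).reset_index(drop=True)
            b = other.table.sort_values(key).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)

    def test_recovers_planted_amino_acids(self, stability_dataset):
        records, feats, _, _ = stability_dataset
        matrix = derive_scoring_matrix(records, feats)
        aa = matrix.table[matrix.table["factor"] == "amino_acid"]
        top6 = set(aa.nlargest(6, "stab_score")["level"])
        assert len(top6 & set(PLANTED_STAB_AA)) >= 4


class TestPositionScoring:
    def _matrix(self):
        rows = []
        for factor, levels, scores in [
            ("amino_acid", ["G", "V"], [37, 8]),
            ("topology", ["TM_helix", "cytosolic_loop"], [8, 3]),
            ("conservation_bin", ["50-60", "00-10"], [14, 4]),
            ("lipid_contact_bin", ["0.4-0.6", "0.0-0.2"], [12, 4]),
            ("helix_contact_bin", ["0.4-0.6", "0.0-0.2"], [10, 4]),
            ("disorder_bin", ["0.0-0.2", "0.4-0.6"], [6, 2]),
        ]:
            for level, c in zip(levels, scores):
                rows.append({"factor": factor, "level": level,
                             "stab_score": c // 2, "destab_score": c - c // 2,
                             "combined": c})
        return ScoringMatrix(pd.DataFrame(rows))

    def _features(self):
        return pd.DataFrame({
            "position": [1, 2],
            "topology_class": ["TM_helix", "TM_helix"],
            "conservation": [55.0, 55.0],
            "lipid_contact": [0.5, 0.5],
            "helix_contact": [0.5, 0.5],
            "disorder": [0.1, 0.1],
        })

    def test_product_arithmetic_and_self_max(self):
        target = ProteinTarget("t", "GG")
        scored = score_positions(target, self._features(), self._matrix(),
                                 include_disorder=False)
        assert scored["final_score"].iloc[0] == 37 * 8 * 14 * 12 * 10  # 497,280
        assert (scored["normalised_score"] == 100.0).all()  # identical rows

    def test_identical_features_identical_scores(self):
        target = ProteinTarget("t", "GG")
        scored = score_positions(target, self._features(), self._matrix())
        assert scored["final_score"].nunique() == 1

    def test_disorder_factor_multiplies_in(self):
        target = ProteinTarget("t", "GG")
        five = score_positions(target, self._features(), self._matrix(),
                               include_disorder=False)
        six = score_positions(target, self._features(), self._matrix(),
                              include_disorder=True)
        assert six["final_score"].iloc[0] == five["final_score"].iloc[0] * 6

    def test_unseen_level_uses_factor_median(self, caplog):
        target = ProteinTarget("t", "KG")  # K unseen by the two-level matrix
        with caplog.at_level("WARNING", logger="memstab"):
            scored = score_positions(target, self._features(), self._matrix(),
                                     include_disorder=False)
        assert "unseen" in caplog.text
        k_row = scored.set_index("position").loc[1]
        assert k_row["score_amino_acid"] == pytest.approx((37 + 8) / 2)

    def test_planted_topology_class_scores_higher(self, stability_dataset):
        records, feats, _, targets = stability_dataset
        matrix = derive_scoring_matrix(records, feats)
        target = targets[0]
        scored = score_positions(target, feats[target.id], matrix)
        by_topo = scored.merge(
            feats[target.id], left_on="position", right_on="position")
        tm = by_topo["topology_class"] == "TM_helix"
        assert (by_topo.loc[tm, "normalised_score"].mean()
                > by_topo.loc[~tm, "normalised_score"].mean())

    def test_product_monotone_in_any_factor(self):
        # raising one factor's combined score never lowers the final score
        target = ProteinTarget("t", "GG")
        base = score_positions(target, self._features(), self._matrix(),
                               include_disorder=False)
        m2 = self._matrix()
        m2.table.loc[(m2.table["factor"] == "topology")
                     & (m2.table["level"] == "TM_helix"), "combined"] = 9
        boosted = score_positions(target, self._features(), ScoringMatrix(m2.table),
                                  include_disorder=False)
        assert (boosted["final_score"] >= base["final_score"]).all()


def test_bins_cover_their_domains():
    assert conservation_bin(0) == "00-10"
    assert conservation_bin(55.0) == "50-60"
    assert conservation_bin(100.0) == "90-100"
    assert contact_bin(0.0) == "0.0-0.2"
    assert contact_bin(1.0) == "0.8-1.0"
    with pytest.raises(ValueError):
        conservation_bin(101)


def test_packaged_synthetic_matrix_loads():
    from memstab.data_driven import load_synthetic_default_matrix
    m = load_synthetic_default_matrix()
    assert set(m.factors) == set(
        ("amino_acid", "topology", "conservation_bin", "lipid_contact_bin",
         "helix_contact_bin", "disorder_bin"))
    aa = m.table[m.table["factor"] == "amino_acid"]
    assert sorted(aa["stab_score"]) == list(range(1, 21))
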