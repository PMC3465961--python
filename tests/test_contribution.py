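"""Chemotaxis-derived contribution metrics: C.I.diff, PI, LTA PI, WPI."""
import pytest

from odornet import (ChemotaxisRecord, bin_nodes, ci_diff,
                     lta_phenotype_index, phenotype_index,
                     weighted_phenotype_index)

WILDTYPE = {"AWA": 0.9, "AWB": -0.95, "AWC": 0.85}


def rec(gene, neuron, diff, n_odors=None):
    return ChemotaxisRecord(gene=gene, neuron=neuron, ci_diff=diff,
                            n_odors=n_odors)


class TestCiDiff:
    def test_published_worked_example(self):
        assert ci_diff(0.9, 0.5) == pytest.approx(0.4)

    def test_identity(self):
        assert ci_diff(0.3, 0.3) == 0.0

    def test_awb_sign_preserved(self):
        # consistent with the odr-3 AWB deficit of -0.7 from wildtype -0.95
        assert ci_diff(-0.95, -0.25) == pytest.approx(-0.7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ci_diff(1.5, 0.0)


class TestPhenotypeIndex:
    def test_no_deficit_gives_zero(self):
        records = [rec("g", n, 0.0) for n in WILDTYPE]
        assert phenotype_index(records, WILDTYPE).pi == 0.0

    def test_three_neuron_hand_evaluation(self):
        records = [rec("odr-3", "AWA", 0.6), rec("odr-3", "AWB", -0.7),
                   rec("odr-3", "AWC", 0.5)]
        expected = (0.6 / 0.9) ** 2 + (0.7 / 0.95) ** 2 + (0.5 / 0.85) ** 2
        assert phenotype_index(records, WILDTYPE).pi == pytest.approx(expected)

    def test_single_neuron_full_deficit(self):
        # rgs-3: AWC deficit equals the wildtype index -> PI = 1
        score = phenotype_index([rec("rgs-3", "AWC", 0.85)], WILDTYPE)
        assert score.pi == pytest.approx(1.0)
        assert not score.complete

    def test_sign_convention_invariance(self):
        a = phenotype_index([rec("g", "AWB", -0.7)], WILDTYPE)
        flipped = {**WILDTYPE, "AWB": 0.95}
        b = phenotype_index([rec("g", "AWB", 0.7)], flipped)
        assert a.pi == pytest.approx(b.pi)

    def test_root_form_is_square_root(self):
        records = [rec("g", "AWA", 0.45)]
        plain = phenotype_index(records, WILDTYPE).pi
        root = phenotype_index(records, WILDTYPE, root_form=True).pi
        assert root == pytest.approx(plain ** 0.5)

    def test_zero_wildtype_reference_rejected(self):
        with pytest.raises(ValueError):
            phenotype_index([rec("g", "AWA", 0.2)], {"AWA": 0.0})


class TestLtaPhenotypeIndex:
    def test_fully_defective_mutant(self):
        # wildtype adaptation 0.9 -> 0.3 (diff 0.6); mutant has none
        assert lta_phenotype_index(0.6, 0.0) == pytest.approx(1.0)

    def test_wildtype_level_adaptation(self):
        assert lta_phenotype_index(0.6, 0.6) == 0.0

    def test_half_defective(self):
        assert lta_phenotype_index(0.6, 0.3) == pytest.approx(0.5)

    def test_zero_wildtype_response_rejected(self):
        with pytest.raises(ValueError):
            lta_phenotype_index(0.0, 0.1)


class TestWeightedPhenotypeIndex:
    def score(self, pi, w):
        from odornet.contribution import ContributionScore
        return ContributionScore(gene="g", pi=pi, weight=w)

    def test_single_member_normalizes_away_weight(self):
        assert weighted_phenotype_index([self.score(1.7, 3)]).wpi == \
            pytest.approx(1.7)

    def test_equal_weights_plain_mean(self):
        assert weighted_phenotype_index(
            [self.score(1, 1), self.score(3, 1)]).wpi == pytest.approx(2.0)

    def test_weighted_mean_hand_case(self):
        assert weighted_phenotype_index(
            [self.score(1, 1), self.score(4, 3)]).wpi == pytest.approx(3.25)

    def test_wpi_within_group_pi_range(self):
        scores = [self.score(0.5, 2), self.score(2.5, 1), self.score(1.0, 4)]
        wpi = weighted_phenotype_index(scores).wpi
        assert 0.5 <= wpi <= 2.5

    def test_constant_pi_group(self):
        scores = [self.score(0.7, w) for w in (1, 2, 5)]
        assert weighted_phenotype_index(scores).wpi == pytest.approx(0.7)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_phenotype_index([self.score(1, 0), self.score(2, 0)])


class TestBinNodes:
    def test_pathway_position_groups(self):
        cats = {f"g{i}": ("a" if i < 2 else "b") for i in range(5)}
        labels = bin_nodes({g: 0.0 for g in cats}, "pathway_position",
                           categories=cats)
        assert labels == cats

    def test_degenerate_ties_deterministic(self):
        values = {g: 1.0 for g in "abcd"}
        labels = bin_nodes(values, "quantiles_of_metric", k=2)
        assert labels == {"a": "bin1", "b": "bin1", "c": "bin2", "d": "bin2"}

    def test_one_gene_per_bin_when_k_equals_n(self):
        values = {"a": 1.0, "b": 2.0, "c": 3.0}
        labels = bin_nodes(values, "quantiles_of_metric", k=3)
        assert len(set(labels.values())) == 3

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            bin_nodes({"a": 1.0}, "quantiles_of_metric", k=2)
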