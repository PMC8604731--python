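"""Neopeptide enumeration, percentile ranking, IMM calling, HED scores."""

import numpy as np
import pytest

from mesomics import (
    HashAffinityScorer,
    HlaAllele,
    HlaGenotype,
    ReferencePanel,
    call_imm,
    enumerate_neopeptides,
    grantham_distance,
    grantham_matrix,
    hed_locus,
    hed_scores,
    rank_percentile,
)
from mesomics.immuno import CLASS_I_LOCI, CLASS_II_LOCI


def _genotype(class_i_names=None, loh=None, seqs=None):
    """Genotype with configurable class I allele names / LOH flags."""
    class_i_names = class_i_names or {
        "A": ("A*01:01", "A*02:01"),
        "B": ("B*07:02", "B*08:01"),
        "C": ("C*01:02", "C*04:01"),
    }
    loh = loh or {}
    seqs = seqs or {}
    alleles = {}
    for locus in CLASS_I_LOCI:
        pair = tuple(
            HlaAllele(locus, n, seqs.get(n, "ACDEFGHIKLMNPQRSTVWY" * 5),
                      somatic_loh=loh.get(n, False))
            for n in class_i_names[locus]
        )
        alleles[locus] = pair
    for locus in CLASS_II_LOCI:
        name = f"{locus}*01:01"
        a = HlaAllele(locus, name, "ACDEFGHIKLMNPQRSTVWY" * 5)
        alleles[locus] = (a, a)
    return HlaGenotype(alleles)


class TestGrantham:
    def test_identity_is_zero(self):
        assert grantham_distance("L", "L") == 0.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [("L", "I", 5), ("S", "R", 109), ("W", "C", 214), ("Y", "F", 22),
         ("D", "E", 45), ("G", "W", 184), ("A", "V", 64)],
    )
    def test_formula_derived_matrix_values(self, a, b, expected):
        assert grantham_distance(a, b) == expected

    def test_matrix_symmetric_with_zero_diagonal(self):
        m = grantham_matrix()
        residues = sorted({a for a, _ in m})
        assert len(residues) == 20
        for a in residues:
            assert m[(a, a)] == 0.0
            for b in residues:
                assert m[(a, b)] == m[(b, a)]

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            grantham_distance("L", "X")


class TestNeopeptideEnumeration:
    def test_central_mutation_yields_38_class_i_peptides_per_allele(self):
        g = _genotype()
        context = "A" * 14 + "W" + "A" * 14  # mutant W at index 14
        peps = enumerate_neopeptides("m1", context, 14, g, hla_class="I")
        by_allele = {}
        for p in peps:
            by_allele.setdefault(p.allele, []).append(p)
        assert set(len(v) for v in by_allele.values()) == {8 + 9 + 10 + 11}
        assert all("W" in p.peptide for p in peps)

    def test_truncated_window_near_protein_end(self):
        g = _genotype()
        context = "MKLVWPQRST"  # 10 residues, mutant at index 4
        peps = enumerate_neopeptides("m1", context, 4, g, hla_class="I")
        assert peps, "windows should survive truncation"
        for p in peps:
            assert p.peptide[p.mutant_offset] == "W"
            assert len(p.peptide) <= len(context)

    def test_homozygous_locus_pairs_once_per_unique_allele(self):
        g = _genotype(class_i_names={
            "A": ("A*01:01", "A*01:01"),
            "B": ("B*07:02", "B*08:01"),
            "C": ("C*01:02", "C*04:01"),
        })
        context = "A" * 14 + "W" + "A" * 14
        peps = enumerate_neopeptides("m1", context, 14, g, hla_class="I")
        alleles = {p.allele for p in peps}
        assert alleles == {"A*01:01", "B*07:02", "B*08:01", "C*01:02", "C*04:01"}

    def test_mutant_pos_outside_context_rejected(self):
        with pytest.raises(ValueError):
            enumerate_neopeptides("m1", "SHORT", 10, _genotype())


class TestRankPercentile:
    def test_best_score_near_zero_percentile(self):
        panel = np.sort(np.linspace(0.1, 1.0, 10_000))
        assert rank_percentile(0.0, panel) == pytest.approx(
            100 * 0.5 / 10_001, rel=1e-9
        )

    def test_worst_score_near_hundred(self):
        panel = np.sort(np.linspace(0.0, 0.9, 10_000))
        assert rank_percentile(1.0, panel) == pytest.approx(100.0, abs=0.01)

    def test_ties_use_midrank_against_sort_oracle(self):
        rng = np.random.default_rng(0)
        panel = np.sort(np.round(rng.random(500), 2))
        score = float(panel[250])
        better = int((panel < score).sum())
        ties = int((panel == score).sum())
        expected = 100 * (better + 0.5 * ties + 0.5) / 501
        assert rank_percentile(score, panel) == pytest.approx(expected)

    def test_result_in_half_open_interval(self):
        rng = np.random.default_rng(1)
        panel = np.sort(rng.random(200))
        for s in rng.random(50):
            r = rank_percentile(float(s), panel)
            assert 0 < r <= 100


class TestImmCalling:
    def _setup(self, size=400):
        return HashAffinityScorer(), ReferencePanel(size=size, seed=7)

    def test_no_strong_binder_yields_zero_imms(self):
        scorer, panel = self._setup()
        g = _genotype()
        # threshold 0: nothing can rank at or under the 0th percentile
        s = call_imm({"m1": ("A" * 29, 14)}, g, scorer, panel,
                     percentile_threshold=0.0)
        assert s.n_imm_class_i == 0 and s.n_imm_class_ii == 0

    def test_permissive_threshold_flags_every_mutation(self):
        scorer, panel = self._setup()
        g = _genotype()
        contexts = {"m1": ("A" * 14 + "W" + "A" * 14, 14)}
        s = call_imm(contexts, g, scorer, panel, percentile_threshold=100.0)
        assert s.n_imm_class_i == 1 and s.n_imm_class_ii == 1

    def test_imm_count_monotone_in_threshold(self):
        scorer, panel = self._setup()
        g = _genotype()
        rng = np.random.default_rng(2)
        from mesomics.immuno import AMINO_ACIDS

        contexts = {
            f"m{i}": (
                "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, 29)), 14
            )
            for i in range(12)
        }
        counts = []
        for thr in (0.5, 1.0, 5.0, 25.0, 100.0):
            s = call_imm(contexts, g, scorer, panel, percentile_threshold=thr)
            counts.append((s.n_imm_class_i, s.n_imm_class_ii))
        for (a1, b1), (a2, b2) in zip(counts, counts[1:]):
            assert a1 <= a2 and b1 <= b2

    def test_deterministic_across_runs(self):
        g = _genotype()
        contexts = {"m1": ("C" * 14 + "W" + "D" * 14, 14)}
        results = [
            call_imm(contexts, g, HashAffinityScorer(),
                     ReferencePanel(size=300, seed=7), 1.0).imm_flags
            for _ in range(2)
        ]
        assert results[0] == results[1]


class TestUniqueAlleles:
    def test_fully_heterozygous_no_loh(self):
        g = _genotype()
        assert g.unique_tumor_allele_count("I") == 6

    def test_heterozygous_allele_with_loh_subtracted(self):
        g = _genotype(loh={"A*02:01": True})
        assert g.unique_tumor_allele_count("I") == 5

    def test_homozygous_locus_counts_once_and_ignores_loh(self):
        g = _genotype(class_i_names={
            "A": ("A*01:01", "A*01:01"),
            "B": ("B*07:02", "B*08:01"),
            "C": ("C*01:02", "C*04:01"),
        }, loh={"A*01:01": True})
        # homozygous locus: the allele is still present after losing one copy
        assert g.unique_tumor_allele_count("I") == 5


class TestHED:
    def test_identical_sequences_score_zero(self):
        assert hed_locus("ACDEF" * 20, "ACDEF" * 20) == 0.0

    def test_single_substitution_scales_by_length(self):
        a = "A" * 100
        b = "A" * 50 + "W" + "A" * 49
        d = grantham_distance("A", "W")
        assert hed_locus(a, b) == pytest.approx(d / 100)

    def test_matches_position_by_position_oracle(self):
        rng = np.random.default_rng(4)
        from mesomics.immuno import AMINO_ACIDS

        s1 = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 120))
        s2 = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 120))
        expected = np.mean(
            [grantham_distance(a, b) for a, b in zip(s1, s2)]
        )
        assert hed_locus(s1, s2) == pytest.approx(float(expected))

    def test_symmetry(self):
        s1, s2 = "ACDEFGHIKL", "LMNPQRSTVW"
        assert hed_locus(s1, s2) == hed_locus(s2, s1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hed_locus("ACD", "ACDE")

    def test_homozygous_locus_scores_zero_and_mean_is_arithmetic(self):
        seqs = {"B*07:02": "A" * 60, "B*08:01": "W" * 60}
        g = _genotype(class_i_names={
            "A": ("A*01:01", "A*01:01"),
            "B": ("B*07:02", "B*08:01"),
            "C": ("C*01:02", "C*01:02"),
        }, seqs=seqs)
        s = hed_scores(g)
        assert s.hed_a == 0.0 and s.hed_c == 0.0
        assert s.hed_b == pytest.approx(grantham_distance("A", "W"))
        assert s.hed_mean == pytest.approx(s.hed_b / 3)
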