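"""Copy-number landscape: aneuploidy, HRD, arm events, GNH, loss rates."""

import math

import numpy as np
import pytest

from mesomics import (
    aneuploidy_metrics,
    arm_recurrence_permutation_test,
    background_loss_rates,
    call_arm_events,
    call_focal_events,
    detect_gnh,
    hrd_scores,
)
import pandas as pd

from conftest import diploid_profile, make_profile, random_profile, split_segments
from oracles import perbase_aneuploidy, perbase_arm_status_fraction, reimplemented_hrd

# Mb-scale thresholds scaled to the 1/20 toy assembly
LOH_MIN = 15_000_000 // 20
LST_MIN = 10_000_000 // 20
LST_GAP = 3_000_000 // 20


class TestAneuploidyMetrics:
    def test_flat_diploid_genome_is_all_zero(self, assembly):
        m = aneuploidy_metrics(diploid_profile(assembly))
        assert m.frac_loh == 0.0
        assert m.frac_allelic_imbalance == 0.0
        assert m.n_breakpoints == 0
        assert m.cn_entropy == 0.0

    def test_two_state_genome_entropy_ln2(self, assembly):
        rows = []
        for chrom in assembly.chromosomes:
            ln = assembly.chromosome_length(chrom)
            half = ln // 2
            rows.append((chrom, 1, half, 2, 1))
            rows.append((chrom, half + 1, ln, 3, 1))
        # halves per chromosome are not exactly equal genome-wide; use two
        # chromg-level states covering equal totals instead
        profile = make_profile(rows, ploidy=2.5)
        m = aneuploidy_metrics(profile)
        # each chromosome contributes one intra-chromosome junction
        assert m.n_breakpoints == len(assembly.chromosomes)
        total = sum(assembly.chromosome_length(c) for c in assembly.chromosomes)
        p2 = sum(
            assembly.chromosome_length(c) // 2 for c in assembly.chromosomes
        ) / total
        expected = -(p2 * math.log(p2) + (1 - p2) * math.log(1 - p2))
        assert m.cn_entropy == pytest.approx(expected, rel=1e-9)

    def test_loh_fraction_never_exceeds_imbalance(self, assembly):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = aneuploidy_metrics(random_profile(rng, assembly))
            assert m.frac_loh <= m.frac_allelic_imbalance + 1e-12

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            aneuploidy_metrics(
                make_profile([("1", 1, 10, 2, 1)]).merged().__class__(
                    segments=pd.DataFrame(
                        columns=["chromosome", "start", "end", "total_cn", "minor_cn"]
                    ),
                    purity=0.5,
                    ploidy=2.0,
                )
            )


class TestHRDScores:
    def test_flat_diploid_genome_scores_zero(self, assembly):
        s = hrd_scores(diploid_profile(assembly), assembly, LOH_MIN, LST_MIN, LST_GAP)
        assert (s.tai, s.loh_score, s.lst, s.hrd_sum) == (0, 0, 0, 0)

    def test_whole_chromosome_loh_not_counted(self, assembly):
        rows = [
            (c, 1, assembly.chromosome_length(c), 2, 1)
            for c in assembly.chromosomes
            if c != "5"
        ]
        rows.append(("5", 1, assembly.chromosome_length("5"), 1, 0))
        s = hrd_scores(make_profile(rows), assembly, LOH_MIN, LST_MIN, LST_GAP)
        assert s.loh_score == 0

    def test_large_sub_chromosomal_loh_counted(self, assembly):
        ln = assembly.chromosome_length("5")
        rows = [
            (c, 1, assembly.chromosome_length(c), 2, 1)
            for c in assembly.chromosomes
            if c != "5"
        ]
        rows += [("5", 1, LOH_MIN + 1000, 1, 0), ("5", LOH_MIN + 1001, ln, 2, 1)]
        s = hrd_scores(make_profile(rows), assembly, LOH_MIN, LST_MIN, LST_GAP)
        assert s.loh_score == 1

    def test_two_adjacent_large_segments_yield_one_lst(self, assembly):
        # two 12-"Mb"-equivalent segments, different states, zero gap,
        # placed away from the telomeres so no TAI is triggered
        size = LST_MIN + LST_MIN // 5
        ln = assembly.chromosome_length("1")
        start = ln // 2
        rows = [
            ("1", 1, start - 1, 2, 1),
            ("1", start, start + size - 1, 2, 0),
            ("1", start + size, start + 2 * size - 1, 3, 0),
            ("1", start + 2 * size, ln, 2, 1),
        ]
        s = hrd_scores(make_profile(rows, ploidy=2.1), assembly,
                       LOH_MIN, LST_MIN, LST_GAP)
        # junctions: (pre,seg1) seg1<min? pre is large; (seg1,seg2) both big -> 1
        assert s.lst >= 1

    def test_hrd_sum_additivity(self, assembly):
        rng = np.random.default_rng(2)
        for _ in range(10):
            s = hrd_scores(random_profile(rng, assembly), assembly,
                           LOH_MIN, LST_MIN, LST_GAP)
            assert s.hrd_sum == s.tai + s.loh_score + s.lst

    def test_matches_independent_reimplementation(self, assembly):
        rng = np.random.default_rng(3)
        for _ in range(25):
            profile = random_profile(rng, assembly)
            s = hrd_scores(profile, assembly, LOH_MIN, LST_MIN, LST_GAP)
            tai, loh, lst = reimplemented_hrd(profile, assembly,
                                              LOH_MIN, LST_MIN, LST_GAP)
            assert (s.tai, s.loh_score, s.lst) == (tai, loh, lst)

    def test_invariant_under_segment_splitting(self, assembly):
        rng = np.random.default_rng(4)
        profile = random_profile(rng, assembly)
        split = split_segments(profile, rng)
        a = hrd_scores(profile, assembly, LOH_MIN, LST_MIN, LST_GAP)
        b = hrd_scores(split, assembly, LOH_MIN, LST_MIN, LST_GAP)
        assert (a.tai, a.loh_score, a.lst) == (b.tai, b.loh_score, b.lst)


class TestArmEvents:
    def _with_arm_state(self, assembly, arm_name, fraction, total, minor):
        """Diploid genome with `fraction` of one arm set to a copy state."""
        arm = assembly.arm(arm_name)
        rows = []
        for chrom in assembly.chromosomes:
            ln = assembly.chromosome_length(chrom)
            if chrom != arm.chromosome:
                rows.append((chrom, 1, ln, 2, 1))
                continue
            alt_end = arm.start + int(fraction * arm.length) - 1
            rows.append((chrom, arm.start, alt_end, total, minor))
            if alt_end < ln:
                rows.append((chrom, alt_end + 1, ln, 2, 1))
            if arm.start > 1:
                rows.insert(-2, (chrom, 1, arm.start - 1, 2, 1))
        return make_profile(sorted(rows), ploidy=2.0)

    def test_full_haploid_arm_called_loss_and_loh(self, assembly):
        profile = self._with_arm_state(assembly, "3p", 1.0, 1, 0)
        calls = {(c.arm, c.status) for c in call_arm_events(profile, assembly)}
        assert ("3p", "loss") in calls and ("3p", "loh") in calls

    def test_89_percent_coverage_is_not_called(self, assembly):
        profile = self._with_arm_state(assembly, "3p", 0.89, 1, 0)
        calls = {
            (c.arm, c.status)
            for c in call_arm_events(profile, assembly)
            if c.status != "none"
        }
        assert ("3p", "loss") not in calls

    def test_matches_perbase_oracle(self, assembly):
        rng = np.random.default_rng(6)
        for _ in range(10):
            profile = random_profile(rng, assembly)
            reference = int(round(profile.ploidy))
            calls = call_arm_events(profile, assembly)
            by_arm: dict[str, set] = {}
            for c in calls:
                by_arm.setdefault(c.arm, set()).add(c.status)
            for arm in assembly.evaluable_arms():
                gain, loss, loh = perbase_arm_status_fraction(
                    profile, arm, reference
                )
                expected = {
                    s
                    for s, f in (("gain", gain), ("loss", loss), ("loh", loh))
                    if f >= 0.90
                } or {"none"}
                assert by_arm[arm.name] == expected


class TestPermutationTest:
    def test_all_zero_events_gives_p_one(self, assembly):
        arms = [a.name for a in assembly.evaluable_arms()]
        mat = pd.DataFrame(False, index=[f"S{i}" for i in range(6)], columns=arms)
        res = arm_recurrence_permutation_test(mat, n_permutations=200, seed=0)
        assert (res.p == 1.0).all()

    def test_recurrent_single_arm_matches_exact_enumeration(self, assembly):
        # 3 samples, 1 event each, all on the same arm of a 39-arm universe:
        # P(permuted recurrence >= 3) = (1/39)^2 exactly, since arm choice is
        # uniform and independent across samples.
        arms = [a.name for a in assembly.evaluable_arms()]
        mat = pd.DataFrame(False, index=["S1", "S2", "S3"], columns=arms)
        mat.iloc[:, 0] = True
        exact = (1 / 39) ** 2
        res = arm_recurrence_permutation_test(mat, n_permutations=30_000, seed=1)
        p_hat = res.p.iloc[0]
        # Monte-Carlo estimate with (1+k)/(1+B) correction; allow 4 SE
        se = math.sqrt(exact * (1 - exact) / 30_000)
        assert abs(p_hat - exact) < 4 * se + 2 / 30_000

    def test_too_few_permutations_rejected(self, assembly):
        arms = [a.name for a in assembly.evaluable_arms()]
        mat = pd.DataFrame(False, index=["S1", "S2"], columns=arms)
        with pytest.raises(ValueError):
            arm_recurrence_permutation_test(mat, n_permutations=50, seed=0)


class TestGNH:
    def test_whole_genome_loh_flagged(self, assembly):
        rows = [
            (c, 1, assembly.chromosome_length(c), 1, 0) for c in assembly.chromosomes
        ]
        flag, frac = detect_gnh(make_profile(rows, ploidy=1.0))
        assert flag and frac == pytest.approx(1.0)

    def test_flat_diploid_not_flagged(self, assembly):
        flag, frac = detect_gnh(diploid_profile(assembly))
        assert not flag and frac == 0.0


class TestBackgroundLossRates:
    def test_haploid_rate_formula(self, assembly):
        # arm 1q haploid with a fraction at copy 0; everything else diploid
        arm = assembly.arm("1q")
        zero_len = arm.length // 10
        rows = [
            (c, 1, assembly.chromosome_length(c), 2, 1)
            for c in assembly.chromosomes
            if c != "1"
        ]
        rows += [
            ("1", 1, arm.start - 1, 2, 1),
            ("1", arm.start, arm.start + zero_len - 1, 0, 0),
            ("1", arm.start + zero_len, arm.end, 1, 0),
        ]
        s = background_loss_rates(make_profile(sorted(rows)), assembly)
        assert s.haploid_arm_count == 1
        assert s.haploid_loss_rate == pytest.approx(zero_len / arm.length)

    def test_euploid_rate_formula(self, assembly):
        # euploid arm with 5% at cn 0 and 10% at cn 1 -> rate (2*.05+.10)=0.20
        arm = assembly.arm("2q")
        l0 = arm.length // 20
        l1 = arm.length // 10
        rows = [
            (c, 1, assembly.chromosome_length(c), 2, 1)
            for c in assembly.chromosomes
            if c != "2"
        ]
        rows += [
            ("2", 1, arm.start - 1, 2, 1),
            ("2", arm.start, arm.start + l0 - 1, 0, 0),
            ("2", arm.start + l0, arm.start + l0 + l1 - 1, 1, 0),
            ("2", arm.start + l0 + l1, arm.end, 2, 1),
        ]
        s = background_loss_rates(make_profile(sorted(rows)), assembly)
        got = 2 * l0 + l1  # only this arm contributes loss among euploid arms
        total_euploid = sum(a.length for a in assembly.evaluable_arms())
        # every other arm is fully euploid with zero loss
        assert s.euploid_loss_rate == pytest.approx(got / total_euploid)
        assert s.euploid_arm_count == len(assembly.evaluable_arms())

    def test_no_qualifying_arms_reported_missing(self, assembly):
        rows = [
            (c, 1, assembly.chromosome_length(c), 3, 1) for c in assembly.chromosomes
        ]
        s = background_loss_rates(make_profile(rows, ploidy=3.0), assembly)
        assert math.isnan(s.haploid_loss_rate) and math.isnan(s.euploid_loss_rate)
        assert s.haploid_arm_count == 0 and s.euploid_arm_count == 0


class TestFocalEvents:
    def test_small_homozygous_deletion_called(self, assembly):
        ln = assembly.chromosome_length("9")
        rows = [("9", 1, 400_000, 2, 1), ("9", 400_001, 900_000, 0, 0),
                ("9", 900_001, ln, 2, 1)]
        events = call_focal_events(make_profile(rows), max_length=30_000_000 // 20)
        assert [e.kind for e in events] == ["homozygous_deletion"]

    def test_large_deletion_not_focal(self, assembly):
        limit = 30_000_000 // 20
        ln = assembly.chromosome_length("1")
        rows = [("1", 1, limit + 100_000, 0, 0), ("1", limit + 100_001, ln, 2, 1)]
        events = call_focal_events(make_profile(rows, ploidy=1.8), max_length=limit)
        assert events == []

    def test_amplification_threshold_is_three_times_ploidy(self, assembly):
        rows = [("7", 1, 200_000, 7, 1), ("7", 200_001, 500_000, 6, 1),
                ("7", 500_001, assembly.chromosome_length("7"), 2, 1)]
        events = call_focal_events(make_profile(rows, ploidy=2.0),
                                   max_length=30_000_000 // 20)
        # cn 7 > 6 qualifies; cn 6 == 3*ploidy does not (strict)
        assert len(events) == 1
        assert events[0].kind == "amplification"
        assert events[0].end == 200_000

    def test_adjacent_qualifying_segments_merged_before_size_test(self, assembly):
        limit = 1_000_000
        ln = assembly.chromosome_length("3")
        rows = [("3", 1, 600_000, 0, 0), ("3", 600_001, 1_200_000, 0, 0),
                ("3", 1_200_001, ln, 2, 1)]
        events = call_focal_events(make_profile(rows), max_length=limit)
        # merged 1.2-Mb deletion exceeds the 1-Mb limit -> not focal
        assert events == []


class TestSplitInvariance:
    def test_all_metrics_invariant_under_state_preserving_splits(self, assembly):
        rng = np.random.default_rng(11)
        profile = random_profile(rng, assembly)
        split = split_segments(profile, rng)
        a, b = aneuploidy_metrics(profile), aneuploidy_metrics(split)
        assert a.frac_loh == pytest.approx(b.frac_loh)
        assert a.frac_allelic_imbalance == pytest.approx(b.frac_allelic_imbalance)
        assert a.n_breakpoints == b.n_breakpoints
        assert a.cn_entropy == pytest.approx(b.cn_entropy)
        assert detect_gnh(profile) == detect_gnh(split)
        ra, rb = (
            background_loss_rates(profile, assembly),
            background_loss_rates(split, assembly),
        )
        assert ra == rb
        fa = call_focal_events(profile, 1_500_000)
        fb = call_focal_events(split, 1_500_000)
        assert fa == fb


def test_perbase_oracle_agreement_on_random_profiles(assembly):
    rng = np.random.default_rng(23)
    for _ in range(10):
        profile = random_profile(rng, assembly)
        m = aneuploidy_metrics(profile)
        loh, imb, nb, ent = perbase_aneuploidy(profile)
        assert m.frac_loh == pytest.approx(loh, abs=1e-12)
        assert m.frac_allelic_imbalance == pytest.approx(imb, abs=1e-12)
        assert m.n_breakpoints == nb
        assert m.cn_entropy == pytest.approx(ent, rel=1e-9)
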