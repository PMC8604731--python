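"""Allele-specific copy-number landscape analytics.

Operates on per-sample allele-specific copy-number segment profiles
(total and minor-allele integer copy number per segment, plus tumor purity
and ploidy) and produces the structural genome metrics used as response
correlates:

* aneuploidy metrics — fraction of the genome with LOH and with allelic
  imbalance, copy-number breakpoint count, entropy of the copy-state
  distribution;
* homologous recombination deficiency (HRD) scores — telomeric allelic
  imbalance (TAI), large (>=15 Mb) non-whole-chromosome LOH segments, and
  large-scale state transitions (LST), plus their sum;
* chromosome-arm gain/loss/LOH calls (an arm is labeled when >=90% of its
  length carries the state) and a cohort-level permutation test of arm-event
  recurrence that preserves each sample's event-arm count over the 39
  evaluable arms;
* near-haploidization (GNH) detection, focal amplification/homozygous
  deletion calls, and haploid/euploid background loss rates.

All coordinates are 1-based inclusive (SEG convention); lengths are
``end - start + 1``. Adjacent segments with identical copy state are merged
before every metric so that segmentation granularity cannot change
biology-level results. Sex chromosomes are excluded by working on an
autosome-only assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import GenomeAssembly
from .stats import bh_adjust

SEGMENT_COLUMNS = ["chromosome", "start", "end", "total_cn", "minor_cn"]
ARM_EVENT_TYPES = ("gain", "loss", "loh")


@dataclass(frozen=True)
class CopySegment:
    chromosome: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.total_cn > 0 and self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError("minor_cn must be the smaller allele")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentProfile:
    """Allele-specific copy-number profile of one tumor sample."""

    segments: pd.DataFrame
    purity: float
    ploidy: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        missing = set(SEGMENT_COLUMNS) - set(self.segments.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        seg = self.segments.copy()
        seg["chromosome"] = seg["chromosome"].astype(str)
        for c in ("start", "end", "total_cn", "minor_cn"):
            seg[c] = seg[c].astype(np.int64)
        seg = seg.sort_values(["chromosome", "start"], kind="mergesort").reset_index(
            drop=True
        )
        if (seg.start > seg.end).any():
            raise ValueError("segment start must be <= end")
        if ((seg.minor_cn > seg.total_cn - seg.minor_cn) & (seg.total_cn > 0)).any():
            raise ValueError("minor_cn must be the smaller allele")
        prev = seg.groupby("chromosome", sort=False)["end"].shift()
        if ((seg.start <= prev).fillna(False)).any():
            raise ValueError("segments overlap within a chromosome")
        self.segments = seg

    def merged(self) -> "SegmentProfile":
        """Merge adjacent same-chromosome segments with identical copy state.

        Only abutting segments (no gap) are merged, so gaps in coverage are
        preserved.
        """
        seg = self.segments
        if seg.empty:
            return self
        same_chrom = seg.chromosome.eq(seg.chromosome.shift())
        abutting = seg.start.eq(seg.end.shift() + 1)
        same_state = seg.total_cn.eq(seg.total_cn.shift()) & seg.minor_cn.eq(
            seg.minor_cn.shift()
        )
        new_block = ~(same_chrom & abutting & same_state)
        block = new_block.cumsum()
        merged = seg.groupby(block, sort=False).agg(
            chromosome=("chromosome", "first"),
            start=("start", "first"),
            end=("end", "last"),
            total_cn=("total_cn", "first"),
            minor_cn=("minor_cn", "first"),
        )
        extra = [c for c in seg.columns if c not in SEGMENT_COLUMNS]
        for c in extra:
            merged[c] = seg.groupby(block, sort=False)[c].first()
        out = SegmentProfile.__new__(SegmentProfile)
        out.segments = merged.reset_index(drop=True)
        out.purity = self.purity
        out.ploidy = self.ploidy
        out.sample_id = self.sample_id
        return out


@dataclass(frozen=True)
class AneuploidyMetrics:
    frac_loh: float
    frac_allelic_imbalance: float
    n_breakpoints: int
    cn_entropy: float


@dataclass(frozen=True)
class HRDScores:
    tai: int
    loh_score: int
    lst: int

    @property
    def hrd_sum(self) -> int:
        return self.tai + self.loh_score + self.lst


@dataclass(frozen=True)
class ArmEventCall:
    arm: str
    status: str  # gain / loss / loh / none
    covered_fraction: float


@dataclass(frozen=True)
class FocalEvent:
    chromosome: str
    start: int
    end: int
    total_cn: int
    kind: str  # homozygous_deletion / amplification

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LossRateSummary:
    haploid_loss_rate: float  # nan when no qualifying arm
    euploid_loss_rate: float
    haploid_arm_count: int
    euploid_arm_count: int


def _lengths(seg: pd.DataFrame) -> np.ndarray:
    return (seg.end - seg.start + 1).to_numpy(dtype=np.int64)


def aneuploidy_metrics(profile: SegmentProfile) -> AneuploidyMetrics:
    """Genome-wide aneuploidy metrics from an allele-specific profile.

    LOH fraction: length-weighted fraction of covered genome with minor
    copy number 0 and at least one copy retained. Allelic-imbalance
    fraction: major != minor. Breakpoints: intra-chromosome junctions where
    the joint (total, minor) state changes; chromosome ends and coverage
    gaps are not breakpoints. Entropy: Shannon entropy (nats) of the
    length-weighted total-copy-number state distribution.
    """
    seg = profile.merged().segments
    if seg.empty:
        raise ValueError("empty segment profile")
    lens = _lengths(seg)
    covered = float(lens.sum())
    major = seg.total_cn - seg.minor_cn
    loh = (seg.minor_cn == 0) & (seg.total_cn >= 1)
    imb = major != seg.minor_cn
    frac_loh = float(lens[loh.to_numpy()].sum() / covered)
    frac_imb = float(lens[imb.to_numpy()].sum() / covered)

    same_chrom = seg.chromosome.eq(seg.chromosome.shift())
    state_change = ~(
        seg.total_cn.eq(seg.total_cn.shift()) & seg.minor_cn.eq(seg.minor_cn.shift())
    )
    n_break = int((same_chrom & state_change).sum())

    probs = (
        pd.Series(lens, index=seg.index).groupby(seg.total_cn).sum().to_numpy()
        / covered
    )
    entropy = float(-(probs * np.log(probs)).sum()) if probs.size > 1 else 0.0
    return AneuploidyMetrics(frac_loh, frac_imb, n_break, max(0.0, entropy))


def hrd_scores(
    profile: SegmentProfile,
    assembly: GenomeAssembly,
    loh_min_length: int = 15_000_000,
    lst_min_length: int = 10_000_000,
    lst_max_gap: int = 3_000_000,
) -> HRDScores:
    """HRD component scores (TAI, LOH, LST) and their sum.

    TAI counts allelic-imbalance segments that reach a chromosome end
    without crossing the centromere (no minimum size). The LOH score counts
    LOH segments of at least ``loh_min_length`` that do not span their whole
    chromosome. LST counts junctions between segments each of at least
    ``lst_min_length`` separated by at most ``lst_max_gap`` where the copy
    state differs. Length thresholds are in bases of the supplied assembly;
    for a down-scaled assembly scale them accordingly.
    """
    seg = profile.merged().segments
    tai = 0
    loh_score = 0
    lst = 0
    for chrom, cseg in seg.groupby("chromosome", sort=False):
        chrom_len = assembly.chromosome_length(chrom)
        cen_start, cen_end = assembly.centromere(chrom)
        cseg = cseg.reset_index(drop=True)
        lens = _lengths(cseg)
        major = (cseg.total_cn - cseg.minor_cn).to_numpy()
        minor = cseg.minor_cn.to_numpy()
        total = cseg.total_cn.to_numpy()
        starts = cseg.start.to_numpy()
        ends = cseg.end.to_numpy()

        imb = major != minor
        touches_tel = (starts == 1) | (ends == chrom_len)
        crosses_cen = (starts <= cen_start) & (ends >= cen_end)
        tai += int(np.sum(imb & touches_tel & ~crosses_cen))

        loh = (minor == 0) & (total >= 1)
        whole = (starts == 1) & (ends == chrom_len)
        loh_score += int(np.sum(loh & (lens >= loh_min_length) & ~whole))

        if len(cseg) > 1:
            big = lens >= lst_min_length
            gap_ok = (starts[1:] - ends[:-1] - 1) <= lst_max_gap
            diff = (total[1:] != total[:-1]) | (minor[1:] != minor[:-1])
            lst += int(np.sum(big[:-1] & big[1:] & gap_ok & diff))
    return HRDScores(tai=tai, loh_score=loh_score, lst=lst)


def call_arm_events(
    profile: SegmentProfile,
    assembly: GenomeAssembly,
    coverage_threshold: float = 0.90,
) -> list[ArmEventCall]:
    """Arm-level gain/loss/LOH calls.

    The copy-neutral reference is the sample ploidy rounded to the nearest
    integer; a segment is a gain above it and a loss below it, and LOH where
    the minor allele is absent with at least one copy retained (LOH is
    independent of gain/loss, so an arm can carry e.g. both loss and loh).
    An arm is labeled with a status iff at least ``coverage_threshold`` of
    its length carries that status. One call per (arm, status); arms with no
    qualifying status yield a single ``none`` call.
    """
    seg = profile.merged().segments
    reference = int(round(profile.ploidy))
    calls: list[ArmEventCall] = []
    for arm in assembly.evaluable_arms():
        cseg = seg[seg.chromosome == arm.chromosome]
        if cseg.empty:
            calls.append(ArmEventCall(arm.name, "none", 0.0))
            continue
        ov_start = np.maximum(cseg.start.to_numpy(), arm.start)
        ov_end = np.minimum(cseg.end.to_numpy(), arm.end)
        ov = np.maximum(0, ov_end - ov_start + 1).astype(np.int64)
        total = cseg.total_cn.to_numpy()
        minor = cseg.minor_cn.to_numpy()
        covered = {
            "gain": float(ov[total > reference].sum()),
            "loss": float(ov[total < reference].sum()),
            "loh": float(ov[(minor == 0) & (total >= 1)].sum()),
        }
        any_call = False
        for status in ARM_EVENT_TYPES:
            frac = covered[status] / arm.length
            if frac >= coverage_threshold:
                calls.append(ArmEventCall(arm.name, status, frac))
                any_call = True
        if not any_call:
            best = max(covered.values()) / arm.length
            calls.append(ArmEventCall(arm.name, "none", best))
    return calls


def arm_event_matrix(cohort_calls: dict[str, list[ArmEventCall]], assembly):
    """Sample x arm boolean matrices per event type from per-sample calls."""
    arms = [a.name for a in assembly.evaluable_arms()]
    out = {}
    for etype in ARM_EVENT_TYPES:
        mat = pd.DataFrame(False, index=list(cohort_calls), columns=arms)
        for sample, calls in cohort_calls.items():
            for c in calls:
                if c.status == etype and c.arm in arms:
                    mat.loc[sample, c.arm] = True
        out[etype] = mat
    return out


def arm_recurrence_permutation_test(
    event_matrix: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    randomized: bool = False,
) -> pd.DataFrame:
    """Permutation test of per-arm event recurrence across a cohort.

    ``event_matrix`` is a boolean samples x arms table for one event type
    (gain, loss or LOH). Each permutation replicate redraws, for every
    sample independently, the sample's observed number of event arms
    uniformly at random (without replacement) over the arm universe, thereby
    matching each sample's aneuploidy level. The per-arm empirical p-value is
    (1 + #{replicates with permuted recurrence >= observed}) / (1 + B),
    Benjamini-Hochberg adjusted across arms.

    With ``randomized=True`` the returned ``p`` column additionally resolves
    ties between the observed statistic and permuted replicates uniformly at
    random ("fuzzy" p-values), which are exactly uniform under the null and
    are intended for calibration studies; the conservative estimator is
    reported in ``p_conservative`` either way.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    mat = event_matrix.to_numpy(dtype=bool)
    n_samples, n_arms = mat.shape
    counts = mat.sum(axis=1)
    if (counts > n_arms).any():
        raise ValueError("per-sample event count exceeds the arm universe")
    observed = mat.sum(axis=0)

    rng = np.random.default_rng(seed)
    # recurrence per arm for each replicate, built sample by sample
    rec = np.zeros((n_permutations, n_arms), dtype=np.int32)
    for k in counts:
        if k == 0:
            continue
        # vectorized draw of k arms without replacement per replicate
        keys = rng.random((n_permutations, n_arms))
        picked = np.argpartition(keys, k - 1, axis=1)[:, :k]
        rows = np.repeat(np.arange(n_permutations), k)
        np.add.at(rec, (rows, picked.ravel()), 1)

    ge = (rec >= observed[None, :]).sum(axis=0)
    p_cons = (1.0 + ge) / (1.0 + n_permutations)
    if randomized:
        gt = (rec > observed[None, :]).sum(axis=0)
        ties = ge - gt
        u = rng.random(n_arms)
        p = (gt + u * (1.0 + ties)) / (1.0 + n_permutations)
    else:
        p = p_cons
    return pd.DataFrame(
        {
            "arm": event_matrix.columns,
            "observed_recurrence": observed,
            "p": p,
            "p_conservative": p_cons,
            "fdr": bh_adjust(p),
        }
    )


def detect_gnh(
    profile: SegmentProfile, threshold: float = 0.80
) -> tuple[bool, float]:
    """Flag genome near-haploidization: LOH over >= ``threshold`` of the genome."""
    frac_loh = aneuploidy_metrics(profile).frac_loh
    return frac_loh >= threshold, frac_loh


def background_loss_rates(
    profile: SegmentProfile,
    assembly: GenomeAssembly,
    state_threshold: float = 0.75,
) -> LossRateSummary:
    """Background loss rates in haploid versus euploid chromosome arms.

    An arm qualifies as haploid (euploid) when at least ``state_threshold``
    of its length has total copy number 1 (total 2 with minor 1 — two copies,
    no LOH). The haploid loss rate is the number of bases at copy number 0
    within haploid arms divided by the total haploid arm length; the euploid
    loss rate is (2 x bases at copy number 0 + bases at copy number 1)
    divided by the total euploid arm length. Arms qualifying for neither
    state are excluded; a state with no qualifying arms yields a nan rate.
    """
    seg = profile.merged().segments
    hap_len = eup_len = 0
    hap_zero = eup_zero = eup_one = 0
    hap_arms = eup_arms = 0
    for arm in assembly.evaluable_arms():
        cseg = seg[seg.chromosome == arm.chromosome]
        if cseg.empty:
            continue
        ov_start = np.maximum(cseg.start.to_numpy(), arm.start)
        ov_end = np.minimum(cseg.end.to_numpy(), arm.end)
        ov = np.maximum(0, ov_end - ov_start + 1).astype(np.int64)
        total = cseg.total_cn.to_numpy()
        minor = cseg.minor_cn.to_numpy()
        frac_hap = ov[total == 1].sum() / arm.length
        frac_eup = ov[(total == 2) & (minor == 1)].sum() / arm.length
        if frac_hap >= state_threshold:
            hap_arms += 1
            hap_len += arm.length
            hap_zero += int(ov[total == 0].sum())
        elif frac_eup >= state_threshold:
            eup_arms += 1
            eup_len += arm.length
            eup_zero += int(ov[total == 0].sum())
            eup_one += int(ov[total == 1].sum())
    return LossRateSummary(
        haploid_loss_rate=hap_zero / hap_len if hap_arms else math.nan,
        euploid_loss_rate=(2 * eup_zero + eup_one) / eup_len if eup_arms else math.nan,
        haploid_arm_count=hap_arms,
        euploid_arm_count=eup_arms,
    )


def call_focal_events(
    profile: SegmentProfile, max_length: int = 30_000_000
) -> list[FocalEvent]:
    """Focal homozygous deletions and amplifications.

    A region qualifies when the total copy number is 0 (homozygous deletion)
    or exceeds three times the sample ploidy (amplification); abutting
    qualifying segments of the same kind are merged before the size test,
    and only regions strictly shorter than ``max_length`` are returned.
    """
    seg = profile.merged().segments
    amp_cut = 3.0 * profile.ploidy
    kind = np.where(
        seg.total_cn == 0,
        "homozygous_deletion",
        np.where(seg.total_cn > amp_cut, "amplification", ""),
    )
    events: list[FocalEvent] = []
    cur = None  # [chrom, start, end, max_cn, kind]
    for row, k in zip(seg.itertuples(index=False), kind):
        if not k:
            if cur:
                events.append(FocalEvent(*cur))
                cur = None
            continue
        if (
            cur
            and cur[4] == k
            and cur[0] == row.chromosome
            and row.start == cur[2] + 1
        ):
            cur[2] = row.end
            cur[3] = max(cur[3], int(row.total_cn))
        else:
            if cur:
                events.append(FocalEvent(*cur))
            cur = [row.chromosome, int(row.start), int(row.end), int(row.total_cn), k]
    if cur:
        events.append(FocalEvent(*cur))
    return [e for e in events if e.length < max_length]
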