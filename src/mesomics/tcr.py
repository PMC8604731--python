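"""TCR repertoire statistics and antigen-specific clonotype calling.

Covers CDR3 quality filtering (begin with C, end with F/W, length >= 7),
productive clonality (1 minus Shannon entropy normalized by log richness),
dominant-clone representation (summed frequency of the top 5% of unique
clones after a 0.01% abundance filter), baseline-versus-resistance
differential clonotype abundance (two-sided Fisher exact on read counts,
Benjamini-Hochberg FDR < 0.01), and the five-criterion antigen-specificity
caller for peptide-stimulation culture experiments (MANAFEST-style):

1. significant expansion versus the no-peptide control (Fisher/BH, FDR < 0.05);
2. significant expansion versus every other peptide-stimulated culture;
3. odds ratio > 5 versus every other condition;
4. at least 30 reads in the positive well;
5. frequency at least 2x the background expansion in the HIV-negative control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust


@dataclass(frozen=True)
class TcrClone:
    cdr3_aa: str
    reads: int
    productive_frequency: float = math.nan


@dataclass
class Repertoire:
    sample_id: str
    clones: list[TcrClone]
    timepoint: str = "baseline"  # baseline / resistance / culture

    def __post_init__(self) -> None:
        keys = [c.cdr3_aa for c in self.clones]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate CDR3 keys in repertoire")

    @property
    def depth(self) -> int:
        return sum(c.reads for c in self.clones)

    def with_frequencies(self) -> "Repertoire":
        """Recompute productive frequencies from read counts."""
        depth = self.depth
        if depth == 0:
            raise ValueError("zero-depth repertoire")
        clones = [
            TcrClone(c.cdr3_aa, c.reads, c.reads / depth) for c in self.clones
        ]
        return Repertoire(self.sample_id, clones, self.timepoint)

    def frequency_of(self, cdr3: str) -> float:
        for c in self.clones:
            if c.cdr3_aa == cdr3:
                return c.productive_frequency
        return 0.0

    def reads_of(self, cdr3: str) -> int:
        for c in self.clones:
            if c.cdr3_aa == cdr3:
                return c.reads
        return 0


def cdr3_passes_qc(cdr3: str) -> bool:
    """CDR3 QC: starts with C, ends with F or W, at least 7 residues."""
    return len(cdr3) >= 7 and cdr3.startswith("C") and cdr3[-1] in "FW"


def qc_filter(rep: Repertoire) -> Repertoire:
    """Drop QC-failing clones and renormalize frequencies."""
    kept = [c for c in rep.clones if cdr3_passes_qc(c.cdr3_aa)]
    out = Repertoire(rep.sample_id, kept, rep.timepoint)
    return out.with_frequencies() if kept else out


@dataclass(frozen=True)
class RepertoireMetrics:
    clonality: float
    dominant_fraction: float
    richness: int


def repertoire_metrics(
    rep: Repertoire,
    dominant_top_fraction: float = 0.05,
    min_frequency: float = 1e-4,
) -> RepertoireMetrics:
    """Clonality, dominant-clone fraction and richness of a repertoire.

    Clonality is ``1 - H / ln(richness)`` with ``H`` the Shannon entropy
    (nats) of productive frequencies; a single-clone repertoire has
    clonality 1. The dominant fraction sums the frequencies of the top
    ``ceil(dominant_top_fraction * richness)`` clones (minimum 1) after
    dropping clones under ``min_frequency``; read-count ties are broken by
    lexicographic CDR3 order for reproducibility.
    """
    rep = rep.with_frequencies()
    if not rep.clones:
        raise ValueError("empty repertoire")
    freqs = np.array([c.productive_frequency for c in rep.clones])
    richness = len(freqs)
    if richness == 1:
        clonality = 1.0
    else:
        h = float(-(freqs * np.log(freqs)).sum())
        clonality = 1.0 - h / math.log(richness)
        clonality = min(1.0, max(0.0, clonality))

    big = [c for c in rep.clones if c.productive_frequency >= min_frequency]
    if big:
        k = max(1, math.ceil(dominant_top_fraction * len(big)))
        top = sorted(big, key=lambda c: (-c.productive_frequency, c.cdr3_aa))[:k]
        dominant = float(sum(c.productive_frequency for c in top))
    else:
        dominant = 0.0
    return RepertoireMetrics(clonality, dominant, richness)


@dataclass(frozen=True)
class DiffAbundanceRecord:
    cdr3_aa: str
    freq_a: float
    freq_b: float
    fold_change: float  # b over a, pseudo-count 0.5 reads when a side is 0
    p: float
    fdr: float
    call: str  # significant_positive / significant_negative / not_significant


def differential_abundance(
    a: Repertoire,
    b: Repertoire,
    min_frequency: float = 1e-4,
    fdr_threshold: float = 0.01,
) -> list[DiffAbundanceRecord]:
    """Differential clonotype abundance between two repertoires.

    Tests every clone reaching ``min_frequency`` in at least one sample with
    a two-sided Fisher exact test on raw read counts, BH-adjusts across
    tested clones, and calls expansion (positive, higher in ``b``) or
    regression (negative) at ``fdr < fdr_threshold``. Fold changes use a
    0.5-read pseudo-count on zero counts for direction/magnitude only.
    """
    a = a.with_frequencies()
    b = b.with_frequencies()
    depth_a, depth_b = a.depth, b.depth
    reads_a = {c.cdr3_aa: c.reads for c in a.clones}
    reads_b = {c.cdr3_aa: c.reads for c in b.clones}
    tested = sorted(
        cdr3
        for cdr3 in set(reads_a) | set(reads_b)
        if reads_a.get(cdr3, 0) / depth_a >= min_frequency
        or reads_b.get(cdr3, 0) / depth_b >= min_frequency
    )
    pvals = []
    rows = []
    for cdr3 in tested:
        ra, rb = reads_a.get(cdr3, 0), reads_b.get(cdr3, 0)
        _, p = sps.fisher_exact([[ra, depth_a - ra], [rb, depth_b - rb]])
        fa = (ra if ra else 0.5) / depth_a
        fb = (rb if rb else 0.5) / depth_b
        pvals.append(p)
        rows.append((cdr3, ra / depth_a, rb / depth_b, fb / fa))
    fdrs = bh_adjust(pvals)
    out = []
    for (cdr3, fa, fb, fc), p, q in zip(rows, pvals, fdrs):
        if q < fdr_threshold and fb > fa:
            call = "significant_positive"
        elif q < fdr_threshold and fb < fa:
            call = "significant_negative"
        else:
            call = "not_significant"
        out.append(DiffAbundanceRecord(cdr3, fa, fb, fc, float(p), float(q), call))
    return out


@dataclass(frozen=True)
class ManafestCall:
    cdr3_aa: str
    condition: str
    criteria_passed: tuple[bool, bool, bool, bool, bool]
    positive: bool


NO_PEPTIDE = "no_peptide"
HIV_NEGATIVE = "hiv_negative"


def _expansion_p(reads_pos, depth_pos, reads_ref, depth_ref) -> float:
    """One-directional expansion evidence: two-sided Fisher p, but only when
    the positive-well frequency exceeds the reference frequency (else 1)."""
    if reads_pos * depth_ref <= reads_ref * depth_pos:
        return 1.0
    _, p = sps.fisher_exact(
        [[reads_pos, depth_pos - reads_pos], [reads_ref, depth_ref - reads_ref]]
    )
    return float(p)


def _odds_ratio(reads_pos, depth_pos, reads_ref, depth_ref) -> float:
    a, b = reads_pos, depth_pos - reads_pos
    c, d = reads_ref, depth_ref - reads_ref
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane-Anscombe
    return (a * d) / (b * c)


def manafest_call(
    cultures: dict[str, Repertoire],
    fdr_threshold: float = 0.05,
    odds_ratio_threshold: float = 5.0,
    min_reads: int = 30,
    background_factor: float = 2.0,
    exclude_from_pairwise: tuple[str, ...] = (),
) -> list[ManafestCall]:
    """Five-criterion antigen-specific clonotype calls.

    ``cultures`` maps condition label -> QC'd repertoire and must contain the
    ``no_peptide`` and ``hiv_negative`` control conditions; every other
    condition is treated as a peptide-stimulated well. BH correction is
    applied across the clonotypes tested within each (condition, reference)
    comparison. ``exclude_from_pairwise`` names peptide conditions (e.g. a
    viral-epitope positive-control pool) omitted from the criterion-2/3
    comparison set.
    """
    for required in (NO_PEPTIDE, HIV_NEGATIVE):
        if required not in cultures:
            raise ValueError(f"missing control condition {required!r}")
    cultures = {k: v.with_frequencies() for k, v in cultures.items()}
    depths = {k: v.depth for k, v in cultures.items()}
    reads = {
        k: {c.cdr3_aa: c.reads for c in v.clones} for k, v in cultures.items()
    }
    peptide_conditions = [
        k for k in cultures if k not in (NO_PEPTIDE, HIV_NEGATIVE)
    ]
    calls: list[ManafestCall] = []
    for cond in peptide_conditions:
        clonotypes = sorted(reads[cond])
        others = [
            c
            for c in peptide_conditions
            if c != cond and c not in exclude_from_pairwise
        ]
        # criterion 1: expansion vs the no-peptide control, BH across clonotypes
        p1 = [
            _expansion_p(
                reads[cond][t], depths[cond],
                reads[NO_PEPTIDE].get(t, 0), depths[NO_PEPTIDE],
            )
            for t in clonotypes
        ]
        q1 = bh_adjust(p1)
        # criterion 2: expansion vs every other peptide-stimulated culture
        q2 = np.ones((len(clonotypes), len(others)))
        for j, other in enumerate(others):
            pj = [
                _expansion_p(
                    reads[cond][t], depths[cond],
                    reads[other].get(t, 0), depths[other],
                )
                for t in clonotypes
            ]
            q2[:, j] = bh_adjust(pj)
        all_other_conditions = [c for c in cultures if c != cond]
        for i, t in enumerate(clonotypes):
            c1 = bool(q1[i] < fdr_threshold)
            c2 = bool((q2[i] < fdr_threshold).all()) if others else True
            c3 = all(
                _odds_ratio(
                    reads[cond][t], depths[cond],
                    reads[o].get(t, 0), depths[o],
                )
                > odds_ratio_threshold
                for o in all_other_conditions
                if o not in exclude_from_pairwise or o in (NO_PEPTIDE, HIV_NEGATIVE)
            )
            c4 = reads[cond][t] >= min_reads
            freq = reads[cond][t] / depths[cond]
            bg = reads[HIV_NEGATIVE].get(t, 0) / depths[HIV_NEGATIVE]
            c5 = freq >= background_factor * bg
            crit = (c1, c2, c3, c4, c5)
            calls.append(ManafestCall(t, cond, crit, all(crit)))
    return calls


def repertoire_from_frame(
    df: pd.DataFrame, sample_id: str = "", timepoint: str = "baseline"
) -> Repertoire:
    """Build a repertoire from an AIRR-like or simplified 3-column frame.

    Accepts AIRR columns (``junction_aa``, ``duplicate_count``,
    ``productive``) or the simplified dialect (``cdr3_aa``, ``reads``,
    optional ``frequency``). Non-productive AIRR rows are dropped.
    """
    if "junction_aa" in df.columns:
        if "productive" in df.columns:
            prod = df["productive"].astype(str).str.upper().isin(["T", "TRUE", "1"])
            df = df[prod]
        grouped = df.groupby("junction_aa")["duplicate_count"].sum()
        clones = [TcrClone(str(k), int(v)) for k, v in grouped.items()]
    elif "cdr3_aa" in df.columns:
        clones = [
            TcrClone(str(r.cdr3_aa), int(r.reads)) for r in df.itertuples(index=False)
        ]
    else:
        raise ValueError("unrecognized repertoire table columns")
    rep = Repertoire(sample_id, clones, timepoint)
    return rep.with_frequencies() if clones else rep
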