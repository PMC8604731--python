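"""Neoantigen and HLA immunogenomics.

Immunogenic mutation (IMM) calling: mutant peptides (8-11-mers for MHC
class I, 15-mers for class II) spanning a missense change are scored by a
pluggable binding-affinity scorer and ranked against a reference panel of
proteome peptides (10,000 per peptide length per allele by default); a
mutation is an IMM for a class when any of its neopeptides ranks within the
top 1st percentile for any allele of that class.

HLA evolutionary divergence (HED): the mean Grantham distance between the
two allele protein sequences at each class I locus (A, B, C), zero for
homozygotes, plus their arithmetic mean as a cumulative score.

Tumor unique-allele counts subtract heterozygous alleles with somatic LOH
from the unique germline allele count, separately for class I and II.

The bundled :class:`HashAffinityScorer` is a synthetic, deterministic
pseudo-affinity (a vectorized FNV-1a hash mapped to [0, 1)); it exercises
the full IMM pipeline offline and is *not* a binding predictor. Production
use plugs any object satisfying the :class:`AffinityScorer` protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .grantham import grantham_distance

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DPA1", "DPB1", "DQA1", "DQB1", "DRB1")
CLASS_I_LENGTHS = (8, 9, 10, 11)
CLASS_II_LENGTHS = (15,)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HlaAllele:
    locus: str
    name: str  # e.g. "A*02:01"
    protein_seq: str = ""
    somatic_loh: bool = False


@dataclass
class HlaGenotype:
    """Two alleles per locus; identical names denote homozygosity."""

    alleles: dict[str, tuple[HlaAllele, HlaAllele]]

    def __post_init__(self) -> None:
        for locus, pair in self.alleles.items():
            if len(pair) != 2:
                raise ValueError(f"locus {locus}: exactly two alleles required")

    def loci(self, hla_class: str) -> tuple[str, ...]:
        return CLASS_I_LOCI if hla_class == "I" else CLASS_II_LOCI

    def unique_alleles(self, hla_class: str) -> list[HlaAllele]:
        """Unique germline alleles of a class, one entry per allele name."""
        seen: dict[str, HlaAllele] = {}
        for locus in self.loci(hla_class):
            for a in self.alleles.get(locus, ()):
                seen.setdefault(a.name, a)
        return list(seen.values())

    def is_homozygous(self, locus: str) -> bool:
        a, b = self.alleles[locus]
        return a.name == b.name

    def unique_tumor_allele_count(self, hla_class: str) -> int:
        """Unique germline alleles minus heterozygous alleles with somatic LOH."""
        n = len(self.unique_alleles(hla_class))
        lost = 0
        for locus in self.loci(hla_class):
            pair = self.alleles.get(locus)
            if pair is None or self.is_homozygous(locus):
                continue
            lost += sum(1 for a in pair if a.somatic_loh)
        return n - lost


@dataclass(frozen=True)
class Neopeptide:
    mutation_id: str
    allele: str
    peptide: str
    mutant_offset: int  # 0-based position of the mutant residue in the peptide
    affinity_score: float = float("nan")
    rank_percentile: float = float("nan")


class AffinityScorer(Protocol):
    """Deterministic peptide-MHC affinity scorer; lower = stronger binding."""

    def score(self, peptides: Sequence[str], allele: str) -> np.ndarray: ...


class HashAffinityScorer:
    """Synthetic deterministic pseudo-affinity from a vectorized FNV-1a hash.

    Scores are uniform-ish in [0, 1), fully determined by (allele, peptide),
    and impose a total ordering per allele. For testing and synthetic
    cohorts only.
    """

    _FNV_OFFSET = np.uint64(14695981039346656037)
    _FNV_PRIME = np.uint64(1099511628211)

    def score(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        peptides = list(peptides)
        if not peptides:
            return np.empty(0, dtype=float)
        lengths = {len(p) for p in peptides}
        if len(lengths) != 1:
            raise ValueError("score peptides of one length per call")
        mat = np.frombuffer(
            "".join(peptides).encode("ascii"), dtype=np.uint8
        ).reshape(len(peptides), lengths.pop())
        with np.errstate(over="ignore"):
            h = np.full(len(peptides), self._FNV_OFFSET, dtype=np.uint64)
            for byte in allele.encode("ascii"):
                h = (h ^ np.uint64(byte)) * self._FNV_PRIME
            for col in range(mat.shape[1]):
                h = (h ^ mat[:, col].astype(np.uint64)) * self._FNV_PRIME
        return (h >> np.uint64(11)).astype(np.float64) / float(2**53)


class ReferencePanel:
    """Reference peptide panels, one per peptide length.

    Peptides are drawn uniformly over the 20 standard residues with a fixed
    seed — a synthetic stand-in for proteome-sampled panels, adequate for
    percentile ranking with the synthetic scorer. Per-(allele, length) panel
    scores are cached.
    """

    def __init__(
        self,
        lengths: Sequence[int] = CLASS_I_LENGTHS + CLASS_II_LENGTHS,
        size: int = 10_000,
        seed: int = 20211108,
    ) -> None:
        if size < 1:
            raise ValueError("panel size must be >= 1")
        rng = np.random.default_rng(seed)
        self.size = size
        self.peptides: dict[int, list[str]] = {}
        for ln in lengths:
            idx = rng.integers(0, 20, size=(size, ln))
            self.peptides[ln] = ["".join(AMINO_ACIDS[j] for j in row) for row in idx]
        self._score_cache: dict[tuple[str, int], np.ndarray] = {}

    def scores(self, scorer: AffinityScorer, allele: str, length: int) -> np.ndarray:
        if length not in self.peptides:
            raise KeyError(f"no reference panel for peptide length {length}")
        key = (allele, length)
        if key not in self._score_cache:
            self._score_cache[key] = np.sort(
                np.asarray(scorer.score(self.peptides[length], allele), dtype=float)
            )
        return self._score_cache[key]


def rank_percentile(
    score: float, panel_scores: np.ndarray
) -> float:
    """Mid-rank percentile of a score within a reference score panel.

    The query is ranked among the ``N`` panel scores plus itself:
    ``100 * (n_better + 0.5 * n_ties + 0.5) / (N + 1)``, where better means
    strictly lower (stronger binding). The result lies in (0, 100].
    """
    panel = np.asarray(panel_scores)
    n = panel.size
    if n == 0:
        raise ValueError("empty reference panel")
    better = int(np.searchsorted(panel, score, side="left"))
    ties = int(np.searchsorted(panel, score, side="right")) - better
    return 100.0 * (better + 0.5 * ties + 0.5) / (n + 1)


def enumerate_neopeptides(
    mutation_id: str,
    context: str,
    mutant_pos: int,
    genotype: HlaGenotype,
    hla_class: str = "both",
) -> list[Neopeptide]:
    """All mutant peptides covering a missense change, paired with alleles.

    ``context`` is the mutant protein window (ideally >= 29 residues centered
    on the change, shorter near protein ends) and ``mutant_pos`` the 0-based
    index of the mutant residue within it. Peptides are paired once per
    unique allele of the matching class.
    """
    if not 0 <= mutant_pos < len(context):
        raise ValueError("mutant_pos outside context window")
    out: list[Neopeptide] = []
    classes = ("I", "II") if hla_class == "both" else (hla_class,)
    for cls in classes:
        lengths = CLASS_I_LENGTHS if cls == "I" else CLASS_II_LENGTHS
        alleles = [a.name for a in genotype.unique_alleles(cls)]
        windows = []
        for ln in lengths:
            lo = max(0, mutant_pos - ln + 1)
            hi = min(len(context) - ln, mutant_pos)
            for start in range(lo, hi + 1):
                windows.append((context[start : start + ln], mutant_pos - start))
        for allele in alleles:
            for pep, off in windows:
                out.append(Neopeptide(mutation_id, allele, pep, off))
    return out


@dataclass
class ImmSummary:
    n_imm_class_i: int = 0
    n_imm_class_ii: int = 0
    unique_class_i_alleles: int = 0
    unique_class_ii_alleles: int = 0
    imm_flags: dict[str, dict[str, bool]] = field(default_factory=dict)


def call_imm(
    mutation_contexts: dict[str, tuple[str, int]],
    genotype: HlaGenotype,
    scorer: AffinityScorer,
    panel: ReferencePanel,
    percentile_threshold: float = 1.0,
) -> ImmSummary:
    """Call immunogenic mutations (IMMs) for a tumor.

    ``mutation_contexts`` maps mutation id -> (mutant protein context,
    0-based mutant position); only missense mutations should be supplied.
    A mutation is an IMM for a class iff any neopeptide for any allele of
    that class ranks at or under ``percentile_threshold``.
    """
    summary = ImmSummary(
        unique_class_i_alleles=genotype.unique_tumor_allele_count("I"),
        unique_class_ii_alleles=genotype.unique_tumor_allele_count("II"),
    )
    for mut_id, (context, pos) in mutation_contexts.items():
        flags = {"I": False, "II": False}
        peptides = enumerate_neopeptides(mut_id, context, pos, genotype)
        by_key: dict[tuple[str, int, str], list[str]] = {}
        for p in peptides:
            cls = "I" if len(p.peptide) in CLASS_I_LENGTHS else "II"
            by_key.setdefault((p.allele, len(p.peptide), cls), []).append(p.peptide)
        for (allele, length, cls), peps in by_key.items():
            if flags[cls]:
                continue
            panel_scores = panel.scores(scorer, allele, length)
            scores = scorer.score(peps, allele)
            for s in scores:
                if rank_percentile(float(s), panel_scores) <= percentile_threshold:
                    flags[cls] = True
                    break
        summary.imm_flags[mut_id] = flags
        summary.n_imm_class_i += flags["I"]
        summary.n_imm_class_ii += flags["II"]
    return summary


@dataclass(frozen=True)
class HedScores:
    hed_a: float
    hed_b: float
    hed_c: float

    @property
    def hed_mean(self) -> float:
        return (self.hed_a + self.hed_b + self.hed_c) / 3.0


def hed_locus(
    seq_a: str,
    seq_b: str,
    region: tuple[int, int] | None = None,
) -> float:
    """Mean Grantham distance between two aligned allele protein sequences.

    ``region`` optionally restricts to a 0-based half-open residue interval
    (e.g. the peptide-binding domain). Sequences must be pre-aligned to
    equal length; positions where either sequence has a gap ('-') or 'X'
    are skipped.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("allele sequences must be aligned to equal length")
    if seq_a == seq_b:
        return 0.0
    if region is not None:
        seq_a = seq_a[region[0] : region[1]]
        seq_b = seq_b[region[0] : region[1]]
    dists = [
        grantham_distance(a, b)
        for a, b in zip(seq_a, seq_b)
        if a not in "-X" and b not in "-X"
    ]
    if not dists:
        raise ValueError("no comparable aligned positions")
    return float(np.mean(dists))


def hed_scores(genotype: HlaGenotype, region=None) -> HedScores:
    """Per-locus class I HED scores; homozygous loci score 0."""
    vals = {}
    for locus in CLASS_I_LOCI:
        a, b = genotype.alleles[locus]
        if a.name == b.name:
            vals[locus] = 0.0
        else:
            vals[locus] = hed_locus(a.protein_seq, b.protein_seq, region)
    return HedScores(hed_a=vals["A"], hed_b=vals["B"], hed_c=vals["C"])
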