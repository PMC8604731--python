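"""Per-tumor somatic mutation metrics.

Cancer cell fraction (CCF) estimation from read support, tumor purity and
local copy number; mutation burden summaries by consequence class and
clonality; gene-set annotation (DNA damage repair, chromatin regulators,
driver genes); and counting of mutations falling in single-copy regions of
the genome.

The CCF model assumes a tumor cell population of purity ``alpha`` in a
diploid normal background. A mutation present at multiplicity ``m`` (copies
per mutated cell) in a fraction ``ccf`` of tumor cells at a locus of tumor
total copy number ``C`` has expected variant allele fraction

    vaf = alpha * m * ccf / (alpha * C + 2 * (1 - alpha))

Multiplicity is estimated by rounding the value that makes ccf = 1, clamped
to [1, C]; the CCF interval propagates the exact (Clopper-Pearson) binomial
interval of the VAF through the same formula. CCF estimates are capped at
1.5 to absorb read-sampling noise rather than erroring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cna import SegmentProfile
from .stats import exact_binomial_ci

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice_site",
    "synonymous",
    "other",
)
NONSYNONYMOUS = frozenset({"missense", "nonsense", "frameshift", "splice_site"})

CCF_CAP = 1.5


@dataclass(frozen=True)
class MutationRecord:
    chromosome: str
    position: int
    ref: str
    alt: str
    gene: str
    consequence: str
    alt_reads: int
    total_reads: int
    hotspot: bool = False
    biallelic: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if not 0 <= self.alt_reads <= self.total_reads:
            raise ValueError("alt_reads must be in [0, total_reads]")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def vaf(self) -> float:
        if self.total_reads == 0:
            raise ValueError("VAF undefined for total_reads=0")
        return self.alt_reads / self.total_reads


@dataclass(frozen=True)
class CCFEstimate:
    ccf: float
    multiplicity: int
    ci_low: float
    ci_high: float
    clonal: bool


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


# Small bundled defaults for tests and synthetic runs; production gene sets
# are supplied via configuration files.
DEFAULT_GENE_SETS = (
    GeneSet(
        "ddr",
        frozenset(
            "BAP1 BRCA1 BRCA2 ATM ATR CHEK2 MLH1 MLH3 MSH2 MSH6 PALB2 RAD51 BLM FANCA".split()
        ),
    ),
    GeneSet(
        "chromatin",
        frozenset("SETD2 PBRM1 ARID1A ARID2 SMARCA4 KMT2D KMT2C EP300 CREBBP".split()),
    ),
    GeneSet("mpm_drivers", frozenset("BAP1 NF2 CDKN2A TP53 SETD2 LATS1 LATS2".split())),
)


@dataclass
class MutationBurdenSummary:
    n_total: int = 0
    n_nonsynonymous: int = 0
    n_missense: int = 0
    n_clonal_missense: int = 0
    n_subclonal_missense: int = 0
    n_subclonal: int = 0
    n_in_single_copy_regions: int = 0
    gene_set_mutated: dict[str, bool] = field(default_factory=dict)


def estimate_ccf(
    mutation: MutationRecord,
    purity: float,
    total_cn: int,
    clonal_ccf_cutoff: float = 0.9,
    ci_level: float = 0.95,
) -> CCFEstimate:
    """Estimate cancer cell fraction of one mutation.

    ``clonal`` is true when the point estimate reaches ``clonal_ccf_cutoff``
    or the upper confidence bound reaches 1.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if total_cn < 1:
        raise ValueError("total_cn must be >= 1")
    if mutation.total_reads == 0:
        raise ValueError("VAF undefined for total_reads=0")
    vaf = mutation.vaf
    denom = purity * total_cn + 2.0 * (1.0 - purity)
    raw_mult = vaf / purity * denom
    mult = int(min(max(round(raw_mult), 1), total_cn))

    def _ccf(v: float) -> float:
        return min(CCF_CAP, v * denom / (purity * mult))

    ci = exact_binomial_ci(mutation.alt_reads, mutation.total_reads, ci_level)
    ccf = _ccf(vaf)
    lo, hi = _ccf(ci.low), _ccf(ci.high)
    return CCFEstimate(
        ccf=ccf,
        multiplicity=mult,
        ci_low=lo,
        ci_high=hi,
        clonal=(ccf >= clonal_ccf_cutoff) or (hi >= 1.0),
    )


def count_single_copy_mutations(
    mutations, profile: SegmentProfile
) -> tuple[int, int]:
    """Count mutations lying in segments of total copy number exactly 1.

    Returns ``(n_single_copy, n_uncovered)``; mutations at loci with no
    segment coverage cannot be assigned a copy state and are reported
    separately, never counted.
    """
    seg = profile.merged().segments
    n_single = n_uncovered = 0
    by_chrom = {c: s for c, s in seg.groupby("chromosome", sort=False)}
    for m in mutations:
        cseg = by_chrom.get(str(m.chromosome))
        if cseg is None:
            n_uncovered += 1
            continue
        hit = cseg[(cseg.start <= m.position) & (m.position <= cseg.end)]
        if hit.empty:
            n_uncovered += 1
        elif int(hit.iloc[0].total_cn) == 1:
            n_single += 1
    return n_single, n_uncovered


def summarize_burden(
    mutations,
    ccfs=None,
    gene_sets=DEFAULT_GENE_SETS,
    profile: SegmentProfile | None = None,
) -> MutationBurdenSummary:
    """Per-tumor mutation burden summary.

    ``ccfs`` (aligned with ``mutations``) supplies clonality flags; when
    omitted, clonal counts are zero and all missense mutations count as
    subclonal-unknown. ``profile`` enables the single-copy-region count.
    """
    muts = list(mutations)
    if ccfs is not None:
        ccfs = list(ccfs)
        if len(ccfs) != len(muts):
            raise ValueError("ccfs must align with mutations")
    s = MutationBurdenSummary()
    s.n_total = len(muts)
    for i, m in enumerate(muts):
        if m.consequence in NONSYNONYMOUS:
            s.n_nonsynonymous += 1
        if m.consequence == "missense":
            s.n_missense += 1
            if ccfs is not None:
                if ccfs[i].clonal:
                    s.n_clonal_missense += 1
                else:
                    s.n_subclonal_missense += 1
        if ccfs is not None and not ccfs[i].clonal:
            s.n_subclonal += 1
    for gs in gene_sets:
        s.gene_set_mutated[gs.name] = any(
            m.gene in gs and m.consequence in NONSYNONYMOUS for m in muts
        )
    if profile is not None:
        s.n_in_single_copy_regions, _ = count_single_copy_mutations(muts, profile)
    return s


def mutations_from_frame(df: pd.DataFrame) -> list[MutationRecord]:
    """Build MutationRecord objects from a MAF-like DataFrame."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MutationRecord(
                chromosome=str(row.chromosome),
                position=int(row.position),
                ref=str(row.ref),
                alt=str(row.alt),
                gene=str(row.gene),
                consequence=str(row.consequence),
                alt_reads=int(row.alt_reads),
                total_reads=int(row.total_reads),
                hotspot=bool(getattr(row, "hotspot", False)),
                biallelic=bool(getattr(row, "biallelic", False)),
            )
        )
    return records
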