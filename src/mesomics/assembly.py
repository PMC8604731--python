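"""Genome assembly tables: chromosome lengths, centromeres and arm definitions.

Copy-number analytics in this package (arm-level events, telomeric allelic
imbalance, background loss rates, the 39-arm permutation null) are defined
relative to an assembly table of autosome lengths and centromere bounds.
The default is a desk-scale "toy" assembly: the 22 human autosomes with all
coordinates scaled down 20-fold, which preserves arm/centromere geometry
while keeping per-base oracle tests fast. A full-size human table (scale=1)
or any custom build can be loaded from the same TSV format.

Coordinates are 1-based inclusive throughout. The p arm runs from base 1 to
the base before the centromere; the q arm from the base after the centromere
to the chromosome end. The five acrocentric p arms (13p, 14p, 15p, 21p, 22p)
are excluded from the evaluable-arm universe, leaving 39 arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# GRCh37 autosome lengths and pericentromeric (acen) bounds.
_HUMAN_AUTOSOMES = [
    # (chromosome, length, centromere_start, centromere_end)
    ("1", 249250621, 121535434, 124535434),
    ("2", 243199373, 92326171, 95326171),
    ("3", 198022430, 90504854, 93504854),
    ("4", 191154276, 49660117, 52660117),
    ("5", 180915260, 46405641, 49405641),
    ("6", 171115067, 58830166, 61830166),
    ("7", 159138663, 58054331, 61054331),
    ("8", 146364022, 43838887, 46838887),
    ("9", 141213431, 47367679, 50367679),
    ("10", 135534747, 39254935, 42254935),
    ("11", 135006516, 51644205, 54644205),
    ("12", 133851895, 34856694, 37856694),
    ("13", 115169878, 16000000, 19000000),
    ("14", 107349540, 16000000, 19000000),
    ("15", 102531392, 17000000, 20000000),
    ("16", 90354753, 35335801, 38335801),
    ("17", 81195210, 22263006, 25263006),
    ("18", 78077248, 15460898, 18460898),
    ("19", 59128983, 24681782, 27681782),
    ("20", 63025520, 26369569, 29369569),
    ("21", 48129895, 11288129, 14288129),
    ("22", 51304566, 13000000, 16000000),
]

#: p arms of the acrocentric chromosomes carry no unique evaluable sequence.
ACROCENTRIC_P_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})


@dataclass(frozen=True)
class Arm:
    """One chromosome arm with 1-based inclusive bounds."""

    name: str  # e.g. "17p"
    chromosome: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAssembly:
    """Per-chromosome lengths and centromere bounds, plus the arm universe.

    Parameters
    ----------
    table
        DataFrame with columns ``chromosome``, ``length``,
        ``centromere_start``, ``centromere_end`` (1-based inclusive).
    """

    table: pd.DataFrame
    _arms: dict[str, Arm] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"chromosome", "length", "centromere_start", "centromere_end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"assembly table missing columns: {sorted(missing)}")
        t = self.table
        bad = t[(t.centromere_start < 1) | (t.centromere_end > t.length)]
        if len(bad):
            raise ValueError(
                "centromere outside chromosome bounds for: "
                + ", ".join(bad.chromosome.astype(str))
            )
        lengths: dict[str, int] = {}
        cens: dict[str, tuple[int, int]] = {}
        arms: dict[str, Arm] = {}
        for row in t.itertuples(index=False):
            chrom = str(row.chromosome)
            lengths[chrom] = int(row.length)
            cens[chrom] = (int(row.centromere_start), int(row.centromere_end))
            if row.centromere_start > 1:
                arms[chrom + "p"] = Arm(chrom + "p", chrom, 1, int(row.centromere_start) - 1)
            if row.centromere_end < row.length:
                arms[chrom + "q"] = Arm(
                    chrom + "q", chrom, int(row.centromere_end) + 1, int(row.length)
                )
        object.__setattr__(self, "_arms", arms)
        object.__setattr__(self, "_lengths", lengths)
        object.__setattr__(self, "_centromeres", cens)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def chromosome_length(self, chromosome: str) -> int:
        try:
            return self._lengths[str(chromosome)]
        except KeyError:
            raise KeyError(f"unknown chromosome {chromosome!r}") from None

    def centromere(self, chromosome: str) -> tuple[int, int]:
        try:
            return self._centromeres[str(chromosome)]
        except KeyError:
            raise KeyError(f"unknown chromosome {chromosome!r}") from None

    def arms(self, chromosome: str | None = None) -> list[Arm]:
        if chromosome is None:
            return list(self._arms.values())
        chromosome = str(chromosome)
        return [a for a in self._arms.values() if a.chromosome == chromosome]

    def arm(self, name: str) -> Arm:
        return self._arms[name]

    def evaluable_arms(self) -> list[Arm]:
        """Arms entering arm-level statistics (acrocentric p arms excluded)."""
        return [a for n, a in self._arms.items() if n not in ACROCENTRIC_P_ARMS]

    @property
    def genome_length(self) -> int:
        return int(self.table["length"].sum())


def human_autosomes(scale: int = 1) -> GenomeAssembly:
    """The 22 human autosomes, optionally linearly down-scaled.

    ``scale=20`` yields the default desk-scale assembly (~154 Mb genome)
    used by the synthetic cohort generator and the test suite.
    """
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    rows = [
        (c, max(2, ln // scale), max(1, cs // scale), max(2, ce // scale))
        for c, ln, cs, ce in _HUMAN_AUTOSOMES
    ]
    table = pd.DataFrame(
        rows, columns=["chromosome", "length", "centromere_start", "centromere_end"]
    )
    return GenomeAssembly(table)


def toy_assembly() -> GenomeAssembly:
    """Default 1/20-scale autosome assembly (39 evaluable arms)."""
    return human_autosomes(scale=20)


def load_assembly(path) -> GenomeAssembly:
    """Load an assembly table from TSV (chromosome, length, centromere bounds)."""
    table = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return GenomeAssembly(table)


def write_assembly(assembly: GenomeAssembly, path) -> None:
    assembly.table.to_csv(path, sep="\t", index=False)
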