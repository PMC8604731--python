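"""Synthetic cohort generation with planted, recoverable effects.

Generates complete per-patient bundles — somatic mutation tables,
allele-specific copy-number segment profiles, HLA genotypes, baseline (and
optional resistance) TCR repertoires and clinical outcomes — from a single
seeded configuration, together with a truth record of every planted effect
so downstream estimators can be validated by parameter recovery.

Distributional choices (all stand-ins, labeled as such in the truth record):

* missense burden: negative binomial, with a multiplicative mean shift in
  responders;
* response: Bernoulli per histology, histology mix multinomial;
* segment profiles: random tilings of the toy autosome assembly with
  configurable LOH content; near-haploid (GNH) tumors are guaranteed at
  least the configured minor-copy-0 genome fraction;
* clone frequencies: symmetric Dirichlet (optionally power-law), multinomial
  read sampling; the Dirichlet concentration is shifted between the OS >= 12
  months and OS < 12 months strata;
* survival: exponential with a planted hazard ratio on the germline-carrier
  flag and administrative censoring at a fixed horizon.

Identical config and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import GenomeAssembly, toy_assembly
from .cna import SegmentProfile
from .immuno import AMINO_ACIDS, CLASS_I_LOCI, CLASS_II_LOCI, HlaAllele, HlaGenotype
from .stats import PatientOutcome
from .tcr import NO_PEPTIDE, HIV_NEGATIVE, Repertoire, TcrClone

HISTOLOGIES = ("epithelioid", "sarcomatoid", "biphasic", "desmoplastic")


class ConfigurationError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort generator (defaults mirror the trial)."""

    n_patients: int = 55
    histology_mix: dict = field(
        default_factory=lambda: {
            "epithelioid": 41 / 55,
            "sarcomatoid": 7 / 55,
            "biphasic": 6 / 55,
            "desmoplastic": 1 / 55,
        }
    )
    response_rate_by_histology: dict = field(
        default_factory=lambda: {
            "epithelioid": 0.659,
            "sarcomatoid": 0.286,
            "biphasic": 0.286,
            "desmoplastic": 0.286,
        }
    )
    mutation_burden_mean: float = 18.0  # non-responder missense mean per exome
    mutation_burden_dispersion: float = 10.0  # negative-binomial size parameter
    burden_effect: float = 23.0 / 18.0  # responder multiplicative shift
    purity_range: tuple[float, float] = (0.25, 0.9)
    loh_fraction_range: tuple[float, float] = (0.05, 0.5)
    gnh_probability: float = 3.0 / 40.0
    gnh_loh_fraction: float = 0.88  # guaranteed minor-cn-0 fraction in GNH tumors
    clone_count_range: tuple[int, int] = (50, 300)
    repertoire_depth: int = 100_000
    clone_concentration: float = 1.0  # Dirichlet concentration, OS >= 12 m stratum
    clonality_effect: float = 0.25  # concentration multiplier, OS < 12 m stratum
    power_law_clones: bool = False
    os_median_months: float = 16.0
    hr_planted: float = 0.5  # carrier vs non-carrier hazard ratio
    # balanced planted covariate: the carrier flag exists to validate hazard
    # recovery at the configured precision, not to model germline prevalence
    carrier_probability: float = 0.5
    censor_horizon_months: float = 36.0
    pfs_median_months: float = 7.0
    n_resistance_pairs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if set(self.histology_mix) != set(HISTOLOGIES):
            raise ConfigurationError("histology_mix must cover the four histologies")
        probs = np.array([self.histology_mix[h] for h in HISTOLOGIES], dtype=float)
        if (probs < 0).any() or (probs > 1).any() or abs(probs.sum() - 1) > 1e-9:
            raise ConfigurationError("histology_mix proportions must sum to 1")
        for h, r in self.response_rate_by_histology.items():
            if not 0 <= r <= 1:
                raise ConfigurationError(
                    f"response_rate_by_histology[{h}] must be in [0, 1]"
                )
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("purity_range must lie within (0, 1]")
        lo, hi = self.loh_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("loh_fraction_range must lie within [0, 1]")
        if not 0 <= self.gnh_probability <= 1:
            raise ConfigurationError("gnh_probability must be in [0, 1]")
        if self.clone_count_range[0] < 1:
            raise ConfigurationError("clone_count_range lower bound must be >= 1")
        if self.repertoire_depth < self.clone_count_range[1]:
            raise ConfigurationError("repertoire_depth must cover clone_count_range")
        if self.mutation_burden_mean <= 0 or self.mutation_burden_dispersion <= 0:
            raise ConfigurationError("mutation_burden_mean/dispersion must be positive")
        if self.burden_effect <= 0:
            raise ConfigurationError("burden_effect must be positive")
        if self.os_median_months <= 0 or self.pfs_median_months <= 0:
            raise ConfigurationError("survival medians must be positive")
        if self.hr_planted <= 0:
            raise ConfigurationError("hr_planted must be positive")


@dataclass
class PatientBundle:
    patient_id: str
    mutations: pd.DataFrame
    profile: SegmentProfile
    hla: HlaGenotype
    baseline_repertoire: Repertoire
    resistance_repertoire: Repertoire | None
    outcome: PatientOutcome


@dataclass
class SyntheticCohort:
    config: CohortConfig
    patients: list[PatientBundle]
    truth: dict

    def outcomes(self) -> list[PatientOutcome]:
        return [p.outcome for p in self.patients]


# --- helpers -----------------------------------------------------------------


def _negative_binomial(rng, mean: float, dispersion: float, size=None):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


_HLA_POOL = {
    locus: [f"{locus}*{i:02d}:01" for i in range(1, 9)]
    for locus in CLASS_I_LOCI + CLASS_II_LOCI
}
_ALLELE_SEQ_CACHE: dict[str, str] = {}


def _allele_protein_seq(name: str, length: int = 180) -> str:
    """Deterministic synthetic protein sequence keyed by allele name."""
    if name not in _ALLELE_SEQ_CACHE:
        rng = np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)
        idx = rng.integers(0, 20, size=length)
        _ALLELE_SEQ_CACHE[name] = "".join(AMINO_ACIDS[i] for i in idx)
    return _ALLELE_SEQ_CACHE[name]


def random_cdr3(rng) -> str:
    """A QC-passing CDR3: 'C' + 5-18 random residues + 'F' or 'W'."""
    n = int(rng.integers(5, 19))
    mid = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))
    return "C" + mid + ("F" if rng.random() < 0.8 else "W")


def _unique_cdr3s(rng, n: int) -> list[str]:
    seen: dict[str, None] = {}
    while len(seen) < n:
        batch = max(16, n - len(seen))
        lengths = rng.integers(5, 19, size=batch)
        chars = rng.integers(0, 20, size=int(lengths.sum()))
        tails = rng.random(batch)
        off = 0
        for ln, tail in zip(lengths, tails):
            mid = "".join(AMINO_ACIDS[i] for i in chars[off : off + ln])
            off += ln
            seen.setdefault("C" + mid + ("F" if tail < 0.8 else "W"), None)
            if len(seen) == n:
                break
    return list(seen)


def generate_repertoire(
    n_clones: int,
    concentration: float,
    depth: int,
    seed,
    sample_id: str = "synthetic",
    timepoint: str = "baseline",
    power_law: bool = False,
) -> Repertoire:
    """One synthetic repertoire: Dirichlet (or power-law) clone frequencies,
    multinomially sampled to ``depth`` reads; all CDR3s pass QC. Clones that
    receive zero reads are dropped."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if depth < n_clones:
        raise ValueError("depth must be >= n_clones")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    cdr3s = _unique_cdr3s(rng, n_clones)
    if n_clones == 1:
        freqs = np.array([1.0])
    elif power_law:
        w = (np.arange(1, n_clones + 1)) ** (-1.0 / max(concentration, 1e-6))
        rng.shuffle(w)
        freqs = w / w.sum()
    else:
        freqs = rng.dirichlet(np.full(n_clones, concentration))
    reads = rng.multinomial(depth, freqs)
    clones = [
        TcrClone(c, int(r)) for c, r in zip(cdr3s, reads) if r > 0
    ]
    return Repertoire(sample_id, clones, timepoint).with_frequencies()


def _segment_profile(
    rng,
    assembly: GenomeAssembly,
    purity: float,
    target_loh_fraction: float,
    gnh: bool,
    sample_id: str,
) -> SegmentProfile:
    """Random gap-free tiling of the assembly with configurable LOH content."""
    rows = []
    for chrom in assembly.chromosomes:
        length = assembly.chromosome_length(chrom)
        n_seg = int(rng.integers(1, 5))
        cuts = np.sort(rng.integers(2, length, size=n_seg - 1)) if n_seg > 1 else []
        bounds = [1, *[int(c) for c in cuts], length + 1]
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1] - 1
            if end < start:  # duplicate cut point; empty piece
                continue
            u = rng.random()
            if u < target_loh_fraction:
                total, minor = (1, 0) if (gnh or rng.random() < 0.8) else (2, 0)
            elif u < target_loh_fraction + 0.08:
                total, minor = (3, 1) if rng.random() < 0.7 else (4, 1)
            elif u < target_loh_fraction + 0.085 and end - start < length // 3:
                total, minor = 0, 0  # focal homozygous deletion
            else:
                total, minor = 2, 1
            rows.append((chrom, start, end, total, minor))
    seg = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "total_cn", "minor_cn"]
    )
    if gnh:
        # guarantee the configured minor-cn-0 genome fraction
        lens = seg.end - seg.start + 1
        genome = lens.sum()
        loh = (seg.minor_cn == 0) & (seg.total_cn >= 1)
        deficit = target_loh_fraction * genome - lens[loh].sum()
        if deficit > 0:
            candidates = seg.index[~loh].tolist()
            candidates.sort(key=lambda i: -lens[i])
            for i in candidates:
                seg.loc[i, ["total_cn", "minor_cn"]] = (1, 0)
                deficit -= lens[i]
                if deficit <= 0:
                    break
    ploidy = float((seg.total_cn * (seg.end - seg.start + 1)).sum()) / float(
        (seg.end - seg.start + 1).sum()
    )
    return SegmentProfile(
        segments=seg, purity=purity, ploidy=max(ploidy, 0.5), sample_id=sample_id
    )


_GENE_POOLS = {
    "ddr": ["BAP1", "BRCA2", "MSH6", "BLM", "ATM"],
    "chromatin": ["SETD2", "PBRM1", "ARID1A", "KMT2D"],
    "driver": ["NF2", "CDKN2A", "TP53", "LATS1", "LATS2"],
}

_CONSEQUENCE_RATES = {
    "nonsense": 1.5,
    "frameshift": 1.0,
    "splice_site": 0.5,
    "synonymous": 6.0,
}


def _mutation_table(
    rng, assembly: GenomeAssembly, profile: SegmentProfile, n_missense: int
) -> pd.DataFrame:
    chrom_lengths = np.array(
        [assembly.chromosome_length(c) for c in assembly.chromosomes], dtype=float
    )
    chrom_p = chrom_lengths / chrom_lengths.sum()
    # (starts, totals) arrays per chromosome for O(log n) copy-state lookup
    seg_by_chrom = {
        c: (s["start"].to_numpy(), s["total_cn"].to_numpy())
        for c, s in profile.segments.groupby("chromosome", sort=False)
    }
    counts = [("missense", n_missense)] + [
        (cons, int(rng.poisson(rate))) for cons, rate in _CONSEQUENCE_RATES.items()
    ]
    bases = "ACGT"
    rows = []
    k = 0
    for consequence, n in counts:
        for _ in range(n):
            ci = rng.choice(len(chrom_lengths), p=chrom_p)
            chrom = assembly.chromosomes[ci]
            pos = int(rng.integers(1, int(chrom_lengths[ci]) + 1))
            total_cn = 2
            hit = seg_by_chrom.get(chrom)
            if hit is not None:
                starts, totals = hit
                j = int(np.searchsorted(starts, pos, side="right")) - 1
                if j >= 0:
                    total_cn = int(totals[j])
            total_cn = max(total_cn, 1)
            u = rng.random()
            if u < 0.06:
                gene = _GENE_POOLS["ddr"][int(rng.integers(len(_GENE_POOLS["ddr"])))]
            elif u < 0.12:
                gene = _GENE_POOLS["chromatin"][
                    int(rng.integers(len(_GENE_POOLS["chromatin"])))
                ]
            elif u < 0.2:
                gene = _GENE_POOLS["driver"][
                    int(rng.integers(len(_GENE_POOLS["driver"])))
                ]
            else:
                gene = f"GENE{int(rng.integers(1, 2000)):04d}"
            clonal = rng.random() < 0.75
            ccf = 1.0 if clonal else float(rng.uniform(0.1, 0.6))
            mult = 1
            purity = profile.purity
            vaf = purity * mult * ccf / (purity * total_cn + 2 * (1 - purity))
            total_reads = int(rng.poisson(100) + 20)
            alt = max(1, int(rng.binomial(total_reads, min(vaf, 0.99))))
            ref = bases[int(rng.integers(4))]
            alt_base = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
            rows.append(
                (
                    chrom, pos, ref, alt_base, gene, consequence,
                    alt, total_reads,
                    bool(rng.random() < 0.03),
                    bool(consequence in ("nonsense", "frameshift") and rng.random() < 0.3),
                    ccf,
                )
            )
            k += 1
    df = pd.DataFrame(
        rows,
        columns=[
            "chromosome", "position", "ref", "alt", "gene", "consequence",
            "alt_reads", "total_reads", "hotspot", "biallelic", "true_ccf",
        ],
    )
    return df.sort_values(["chromosome", "position"], kind="mergesort").reset_index(
        drop=True
    )


def _hla_genotype(rng) -> HlaGenotype:
    alleles: dict[str, tuple[HlaAllele, HlaAllele]] = {}
    for locus in CLASS_I_LOCI + CLASS_II_LOCI:
        pool = _HLA_POOL[locus]
        first = pool[int(rng.integers(len(pool)))]
        if rng.random() < 0.15:
            second = first
        else:
            second = pool[int(rng.integers(len(pool)))]
        is_class_i = locus in CLASS_I_LOCI
        pair = []
        for name in (first, second):
            loh = bool(
                is_class_i and first != second and rng.random() < 0.08
            )
            pair.append(
                HlaAllele(locus, name, _allele_protein_seq(name), somatic_loh=loh)
            )
        # at most one allele of a locus can be lost
        if pair[0].somatic_loh and pair[1].somatic_loh:
            pair[1] = HlaAllele(locus, pair[1].name, pair[1].protein_seq, False)
        alleles[locus] = (pair[0], pair[1])
    return HlaGenotype(alleles)


def generate_cohort(
    config: CohortConfig, assembly: GenomeAssembly | None = None
) -> SyntheticCohort:
    """Generate a full synthetic cohort from a validated configuration."""
    assembly = assembly or toy_assembly()
    root = np.random.SeedSequence(config.seed)
    (ss_clinical, ss_genome, ss_tcr) = root.spawn(3)
    rng_clin = np.random.default_rng(ss_clinical)

    n = config.n_patients
    hist_probs = [config.histology_mix[h] for h in HISTOLOGIES]
    histologies = [
        HISTOLOGIES[i] for i in rng_clin.choice(len(HISTOLOGIES), size=n, p=hist_probs)
    ]
    responders = np.array(
        [
            rng_clin.random() < config.response_rate_by_histology[h]
            for h in histologies
        ]
    )
    carriers = rng_clin.random(n) < config.carrier_probability

    base_rate = math.log(2.0) / config.os_median_months
    os_rates = base_rate * np.where(carriers, config.hr_planted, 1.0)
    os_raw = rng_clin.exponential(1.0 / os_rates)
    os_event = os_raw <= config.censor_horizon_months
    os_months = np.minimum(os_raw, config.censor_horizon_months)

    pfs_rate = math.log(2.0) / config.pfs_median_months
    pfs_raw = rng_clin.exponential(1.0 / pfs_rate, size=n)
    pfs_raw = np.minimum(pfs_raw, os_raw)
    pfs_event = pfs_raw <= config.censor_horizon_months
    pfs_months = np.minimum(pfs_raw, config.censor_horizon_months)

    burden_means = config.mutation_burden_mean * np.where(
        responders, config.burden_effect, 1.0
    )
    missense_counts = np.array(
        [
            max(1, _negative_binomial(rng_clin, m, config.mutation_burden_dispersion))
            for m in burden_means
        ]
    )
    gnh_flags = rng_clin.random(n) < config.gnh_probability

    genome_rngs = [np.random.default_rng(s) for s in ss_genome.spawn(n)]
    tcr_seeds = ss_tcr.spawn(n + config.n_resistance_pairs)

    patients: list[PatientBundle] = []
    truth_patients = {}
    resistance_assigned = 0
    for i in range(n):
        pid = f"P{i + 1:03d}"
        grng = genome_rngs[i]
        purity = float(grng.uniform(*config.purity_range))
        if gnh_flags[i]:
            target_loh = config.gnh_loh_fraction
        else:
            target_loh = float(grng.uniform(*config.loh_fraction_range))
        profile = _segment_profile(
            grng, assembly, purity, target_loh, bool(gnh_flags[i]), pid
        )
        muts = _mutation_table(grng, assembly, profile, int(missense_counts[i]))
        hla = _hla_genotype(grng)

        if responders[i]:
            bor = "PR" if grng.random() < 0.97 else "CR"
        else:
            bor = ("SD", "PD", "NE")[
                int(grng.choice(3, p=[0.75, 0.2, 0.05]))
            ]
        outcome = PatientOutcome(
            patient_id=pid,
            best_overall_response=bor,
            pfs_months=float(pfs_months[i]),
            pfs_event=bool(pfs_event[i]),
            os_months=float(os_months[i]),
            os_event=bool(os_event[i]),
            histology=histologies[i],
            germline_carrier=bool(carriers[i]),
        )

        n_clones = int(grng.integers(config.clone_count_range[0],
                                     config.clone_count_range[1] + 1))
        long_os = os_months[i] >= 12.0
        concentration = config.clone_concentration * (
            1.0 if long_os else config.clonality_effect
        )
        baseline = generate_repertoire(
            n_clones, concentration, config.repertoire_depth, tcr_seeds[i],
            sample_id=pid, timepoint="baseline",
            power_law=config.power_law_clones,
        )
        resistance = None
        if resistance_assigned < config.n_resistance_pairs and responders[i]:
            # resistance repertoire: same clones, sharpened distribution
            freqs = np.array([c.productive_frequency for c in baseline.clones])
            sharp = freqs**2.0
            sharp /= sharp.sum()
            rrng = np.random.default_rng(tcr_seeds[n + resistance_assigned])
            reads = rrng.multinomial(config.repertoire_depth, sharp)
            clones = [
                TcrClone(c.cdr3_aa, int(r))
                for c, r in zip(baseline.clones, reads)
                if r > 0
            ]
            resistance = Repertoire(pid, clones, "resistance").with_frequencies()
            resistance_assigned += 1

        patients.append(
            PatientBundle(pid, muts, profile, hla, baseline, resistance, outcome)
        )
        truth_patients[pid] = {
            "histology": histologies[i],
            "responder": bool(responders[i]),
            "germline_carrier": bool(carriers[i]),
            "missense_burden_mean": float(burden_means[i]),
            "n_missense": int(missense_counts[i]),
            "gnh": bool(gnh_flags[i]),
            "target_loh_fraction": float(target_loh),
            "purity": purity,
            "clone_concentration": float(concentration),
            "os_rate": float(os_rates[i]),
        }

    truth = {
        "note": (
            "All generator distributions are synthetic stand-ins "
            "(negative binomial burdens, Dirichlet clone frequencies, "
            "exponential survival); no distributional forms are claimed "
            "for real cohorts."
        ),
        "planted": {
            "burden_effect": config.burden_effect,
            "hr_planted": config.hr_planted,
            "clonality_effect": config.clonality_effect,
            "gnh_probability": config.gnh_probability,
            "os_median_months": config.os_median_months,
        },
        "patients": truth_patients,
    }
    return SyntheticCohort(config=config, patients=patients, truth=truth)


# --- MANAFEST experiment fixtures -------------------------------------------


def generate_manafest_experiment(
    positives: dict[str, str],
    n_conditions: int = 4,
    seed: int = 0,
    n_background: int = 30,
    depth: int = 50_000,
):
    """A synthetic peptide-stimulation culture experiment.

    ``positives`` maps planted antigen-specific CDR3 -> its positive
    condition (one of ``peptide_1 .. peptide_<n_conditions>``). Planted
    positives satisfy all five specificity criteria by construction.
    A set of planted negatives each violates exactly one named criterion;
    the returned truth record maps every planted clonotype to
    ``("positive", condition)`` or ``(violated_criterion, condition)``.

    Returns ``(cultures, truth)`` where ``cultures`` includes the
    ``no_peptide`` and ``hiv_negative`` controls.
    """
    rng = np.random.default_rng(seed)
    conditions = [f"peptide_{i + 1}" for i in range(n_conditions)]
    for cdr3, cond in positives.items():
        if cond not in conditions:
            raise ValueError(f"unknown condition {cond!r} for {cdr3!r}")
    all_conditions = conditions + [NO_PEPTIDE, HIV_NEGATIVE]
    background = _unique_cdr3s(rng, n_background + 4 * len(all_conditions))
    reads: dict[str, dict[str, int]] = {c: {} for c in all_conditions}
    for cdr3 in background[:n_background]:
        base = int(rng.integers(20, 400))
        for c in all_conditions:
            r = int(rng.poisson(base))
            if r > 0:
                reads[c][cdr3] = r
    # planted positives: strong, condition-exclusive expansions
    for cdr3, cond in positives.items():
        reads[cond][cdr3] = int(rng.integers(800, 2000))

    extra = iter(background[n_background:])
    truth: dict[str, tuple[str, str]] = {
        cdr3: ("positive", cond) for cdr3, cond in positives.items()
    }
    for cond in conditions:
        # criterion 4 violation: condition-exclusive but only 29 reads
        c4 = next(extra)
        reads[cond][c4] = 29
        truth[c4] = ("min_reads", cond)
        # criterion 3/2 violation: expanded but present in every well
        c3 = next(extra)
        for c in all_conditions:
            reads[c][c3] = int(rng.integers(300, 400))
        reads[cond][c3] = 500
        truth[c3] = ("odds_ratio", cond)
        # criterion 5 violation: matched expansion in the HIV-negative control
        c5 = next(extra)
        reads[cond][c5] = 900
        reads[HIV_NEGATIVE][c5] = 900
        truth[c5] = ("background", cond)
        # criterion 1 violation: too few reads everywhere for significance
        c1 = next(extra)
        reads[cond][c1] = 2
        truth[c1] = ("expansion", cond)

    cultures = {}
    # one shared filler clone pads every well to comparable depth so the
    # padding itself can never look condition-specific
    filler = "CPADPADPADF"
    for c in all_conditions:
        total = sum(reads[c].values())
        pad = max(0, depth - total)
        clones = [TcrClone(k, v) for k, v in sorted(reads[c].items())]
        if pad:
            clones.append(TcrClone(filler, pad))
        cultures[c] = Repertoire(c, clones, "culture").with_frequencies()
    return cultures, truth
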