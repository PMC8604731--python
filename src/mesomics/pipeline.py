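"""End-to-end pipeline orchestration.

Runs simulate -> per-patient metrics -> cohort associations -> report with a
single structured configuration, deterministic under a fixed seed. Every
per-patient metric defined by the analysis modules appears as a column of
the patient metric table; the association stage tests each configured
feature against radiographic response (Mann-Whitney) and against the
OS >= 12 months stratum, overall and within epithelioid tumors, and runs
log-rank/Cox survival comparisons for binary features, with
Benjamini-Hochberg q-values alongside raw p-values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .assembly import GenomeAssembly, toy_assembly
from .cna import (
    aneuploidy_metrics,
    arm_event_matrix,
    arm_recurrence_permutation_test,
    background_loss_rates,
    call_arm_events,
    call_focal_events,
    detect_gnh,
    hrd_scores,
)
from .immuno import HashAffinityScorer, ReferencePanel, call_imm, hed_scores, AMINO_ACIDS
from .somatic import (
    DEFAULT_GENE_SETS,
    estimate_ccf,
    mutations_from_frame,
    summarize_burden,
)
from .stats import (
    bh_adjust,
    compare_groups,
    response_rate,
    survival_analysis,
)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort
from .tcr import differential_abundance, qc_filter, repertoire_metrics

log = logging.getLogger("mesomics")


@dataclass
class RunConfig:
    """Pipeline run configuration with the analysis thresholds as defaults."""

    seed: int = 0
    cohort: CohortConfig | None = None  # simulate when set
    input_dir: str | None = None  # read a written cohort when set
    out_dir: str = "mesomics_run"
    # stage toggles
    run_somatic: bool = True
    run_cna: bool = True
    run_immuno: bool = True
    run_tcr: bool = True
    run_associations: bool = True
    # thresholds (named analysis defaults)
    imm_percentile: float = 1.0
    clonal_ccf_cutoff: float = 0.9
    gnh_threshold: float = 0.80
    arm_rule: float = 0.90
    state_rule: float = 0.75
    focal_max_mb: float = 30.0
    hrd_loh_min_mb: float = 15.0
    lst_min_mb: float = 10.0
    lst_gap_mb: float = 3.0
    tcr_min_freq: float = 1e-4
    diffab_fdr: float = 0.01
    permutations: int = 1000
    panel_size: int = 10_000
    genome_scale: int = 20  # assembly down-scaling; Mb thresholds scale with it

    def __post_init__(self) -> None:
        if self.cohort is None and self.input_dir is None:
            self.cohort = CohortConfig(seed=self.seed)
        if not 0 < self.imm_percentile <= 100:
            raise ValueError("imm_percentile must be in (0, 100]")
        if not 0 < self.arm_rule <= 1 or not 0 < self.state_rule <= 1:
            raise ValueError("arm_rule/state_rule must be in (0, 1]")

    def scaled_bases(self, mb: float) -> int:
        return max(1, int(mb * 1e6 / self.genome_scale))


@dataclass
class ReportBundle:
    patient_metrics: pd.DataFrame
    associations: pd.DataFrame
    arm_recurrence: pd.DataFrame
    manifest: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, patient: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for patient {patient!r}: {cause}")
        self.stage = stage
        self.patient = patient


def _mutation_context(rng, mutation) -> tuple[str, int]:
    """Synthetic mutant protein context window for a missense record.

    Deterministic per (gene, position): real runs supply true protein
    contexts; the synthetic path fabricates a 29-residue window whose
    central residue is the mutant one.
    """
    key = f"{mutation.gene}:{mutation.position}:{mutation.alt}"
    h = int(hashlib.blake2b(key.encode(), digest_size=8).hexdigest(), 16)
    crng = np.random.default_rng(h % (2**31))
    idx = crng.integers(0, 20, size=29)
    return "".join(AMINO_ACIDS[i] for i in idx), 14


def run_pipeline(config: RunConfig, assembly: GenomeAssembly | None = None) -> ReportBundle:
    """Execute the enabled stages in dependency order and build the report."""
    if assembly is None:
        assembly = toy_assembly() if config.genome_scale == 20 else None
    if assembly is None:
        raise ValueError("supply an assembly for non-default genome_scale")

    if config.input_dir is not None:
        cohort = _load_cohort(config.input_dir)
    else:
        cohort = generate_cohort(config.cohort, assembly)

    scorer = HashAffinityScorer()
    panel = ReferencePanel(size=config.panel_size)
    rng = np.random.default_rng(config.seed)

    rows = []
    cohort_arm_calls = {}
    for p in cohort.patients:
        pid = p.patient_id
        row: dict = {"patient": pid}
        o = p.outcome
        row.update(
            best_overall_response=o.best_overall_response,
            responder=o.responder,
            histology=o.histology,
            germline_carrier=o.germline_carrier,
            os_months=o.os_months,
            os_event=o.os_event,
            pfs_months=o.pfs_months,
            pfs_event=o.pfs_event,
        )
        muts = mutations_from_frame(p.mutations)
        profile = p.profile

        if config.run_somatic:
            try:
                ccfs = [
                    estimate_ccf(
                        m,
                        profile.purity,
                        _local_total_cn(profile, m),
                        clonal_ccf_cutoff=config.clonal_ccf_cutoff,
                    )
                    for m in muts
                ]
                burden = summarize_burden(
                    muts, ccfs, DEFAULT_GENE_SETS, profile=profile
                )
                row.update(
                    n_nonsynonymous=burden.n_nonsynonymous,
                    n_missense=burden.n_missense,
                    n_clonal_missense=burden.n_clonal_missense,
                    n_subclonal=burden.n_subclonal,
                    n_single_copy_mutations=burden.n_in_single_copy_regions,
                )
                for name, flag in burden.gene_set_mutated.items():
                    row[f"geneset_{name}"] = flag
            except Exception as e:  # pragma: no cover - structured failure path
                raise StageError("somatic", pid, e) from e

        if config.run_cna:
            try:
                am = aneuploidy_metrics(profile)
                hrd = hrd_scores(
                    profile,
                    assembly,
                    loh_min_length=config.scaled_bases(config.hrd_loh_min_mb),
                    lst_min_length=config.scaled_bases(config.lst_min_mb),
                    lst_max_gap=config.scaled_bases(config.lst_gap_mb),
                )
                gnh, frac_loh = detect_gnh(profile, config.gnh_threshold)
                arm_calls = call_arm_events(profile, assembly, config.arm_rule)
                cohort_arm_calls[pid] = arm_calls
                loss_rates = background_loss_rates(
                    profile, assembly, config.state_rule
                )
                focal = call_focal_events(
                    profile, max_length=config.scaled_bases(config.focal_max_mb)
                )
                row.update(
                    frac_loh=am.frac_loh,
                    frac_allelic_imbalance=am.frac_allelic_imbalance,
                    n_breakpoints=am.n_breakpoints,
                    cn_entropy=am.cn_entropy,
                    hrd_tai=hrd.tai,
                    hrd_loh=hrd.loh_score,
                    hrd_lst=hrd.lst,
                    hrd_sum=hrd.hrd_sum,
                    gnh=gnh,
                    n_focal_events=len(focal),
                    n_arm_events=sum(c.status != "none" for c in arm_calls),
                    haploid_loss_rate=loss_rates.haploid_loss_rate,
                    euploid_loss_rate=loss_rates.euploid_loss_rate,
                )
            except Exception as e:  # pragma: no cover
                raise StageError("cna", pid, e) from e

        if config.run_immuno:
            try:
                contexts = {
                    f"{pid}:{i}": _mutation_context(rng, m)
                    for i, m in enumerate(muts)
                    if m.consequence == "missense"
                }
                imm = call_imm(
                    contexts, p.hla, scorer, panel, config.imm_percentile
                )
                hed = hed_scores(p.hla)
                row.update(
                    n_imm_class_i=imm.n_imm_class_i,
                    n_imm_class_ii=imm.n_imm_class_ii,
                    unique_class_i_alleles=imm.unique_class_i_alleles,
                    unique_class_ii_alleles=imm.unique_class_ii_alleles,
                    hed_a=hed.hed_a,
                    hed_b=hed.hed_b,
                    hed_c=hed.hed_c,
                    hed_mean=hed.hed_mean,
                )
            except Exception as e:  # pragma: no cover
                raise StageError("immuno", pid, e) from e

        if config.run_tcr:
            try:
                rep = qc_filter(p.baseline_repertoire)
                rm = repertoire_metrics(rep, min_frequency=config.tcr_min_freq)
                row.update(
                    tcr_clonality=rm.clonality,
                    tcr_dominant_fraction=rm.dominant_fraction,
                    tcr_richness=rm.richness,
                )
                if p.resistance_repertoire is not None:
                    res = qc_filter(p.resistance_repertoire)
                    diff = differential_abundance(
                        rep, res, config.tcr_min_freq, config.diffab_fdr
                    )
                    row["n_expanded_clones"] = sum(
                        1 for d in diff if d.call == "significant_positive"
                    )
                    row["n_regressed_clones"] = sum(
                        1 for d in diff if d.call == "significant_negative"
                    )
            except Exception as e:  # pragma: no cover
                raise StageError("tcr", pid, e) from e

        rows.append(row)

    metrics = pd.DataFrame(rows).set_index("patient")

    arm_recurrence = pd.DataFrame()
    if config.run_cna and cohort_arm_calls:
        mats = arm_event_matrix(cohort_arm_calls, assembly)
        frames = []
        for etype, mat in mats.items():
            res = arm_recurrence_permutation_test(
                mat, n_permutations=config.permutations, seed=config.seed
            )
            res.insert(0, "event_type", etype)
            frames.append(res)
        arm_recurrence = pd.concat(frames, ignore_index=True)

    associations = pd.DataFrame()
    if config.run_associations:
        associations = _associations(metrics)

    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_patients": len(cohort.patients),
        "stages": {
            "somatic": config.run_somatic,
            "cna": config.run_cna,
            "immuno": config.run_immuno,
            "tcr": config.run_tcr,
            "associations": config.run_associations,
        },
    }
    return ReportBundle(metrics, associations, arm_recurrence, manifest)


def _local_total_cn(profile, mutation) -> int:
    seg = profile.segments
    hit = seg[
        (seg.chromosome == str(mutation.chromosome))
        & (seg.start <= mutation.position)
        & (mutation.position <= seg.end)
    ]
    if hit.empty:
        return 2
    return max(1, int(hit.iloc[0].total_cn))


_FEATURE_COLUMNS = [
    "n_missense",
    "n_clonal_missense",
    "n_single_copy_mutations",
    "frac_loh",
    "frac_allelic_imbalance",
    "n_breakpoints",
    "cn_entropy",
    "hrd_sum",
    "n_imm_class_i",
    "n_imm_class_ii",
    "hed_b",
    "hed_mean",
    "tcr_clonality",
    "tcr_dominant_fraction",
]


def _associations(metrics: pd.DataFrame) -> pd.DataFrame:
    """Feature-vs-outcome association table with BH q-values."""
    strata = {"all": metrics}
    epi = metrics[metrics.histology == "epithelioid"]
    if len(epi) >= 4:
        strata["epithelioid"] = epi
    rows = []
    for stratum, df in strata.items():
        for feature in _FEATURE_COLUMNS:
            if feature not in df.columns:
                continue
            for outcome, mask_col in (
                ("response", df.responder.astype(bool)),
                ("os_ge_12m", df.os_months >= 12.0),
            ):
                a = df.loc[mask_col, feature].dropna()
                b = df.loc[~mask_col, feature].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                try:
                    cmp = compare_groups(a, b, "mann_whitney")
                except ValueError:
                    continue
                rows.append(
                    (stratum, feature, outcome, "mann_whitney",
                     cmp.effect, cmp.p, len(a), len(b))
                )
    out = pd.DataFrame(
        rows,
        columns=["stratum", "feature", "outcome", "test", "effect", "p", "n_a", "n_b"],
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out


def _config_dict(config: RunConfig) -> dict:
    d = {}
    for k, v in vars(config).items():
        if k == "cohort" and v is not None:
            d[k] = {kk: vv for kk, vv in vars(v).items()}
            d[k]["purity_range"] = list(v.purity_range)
            d[k]["loh_fraction_range"] = list(v.loh_fraction_range)
            d[k]["clone_count_range"] = list(v.clone_count_range)
        else:
            d[k] = v
    return d


def write_report(bundle: ReportBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.patient_metrics.to_csv(
        out / "patient_metrics.tsv", sep="\t", float_format="%.6g"
    )
    bundle.associations.to_csv(
        out / "associations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    bundle.arm_recurrence.to_csv(
        out / "arm_recurrence.tsv", sep="\t", index=False, float_format="%.6g"
    )
    mio.write_json(bundle.manifest, out / "manifest.json")


def _load_cohort(input_dir) -> SyntheticCohort:
    """Load a written cohort directory back into memory."""
    from .synthetic import PatientBundle

    d = Path(input_dir)
    muts = mio.read_mutations(d / "mutations.tsv")
    profiles = mio.read_segments(d / "segments.tsv", d / "purity_ploidy.tsv")
    hla = mio.read_hla(d / "hla.tsv")
    outcomes = {o.patient_id: o for o in mio.read_clinical(d / "clinical.tsv")}
    patients = []
    for pid, outcome in outcomes.items():
        pmuts = muts[muts["sample"] == pid].drop(columns=["sample"]).reset_index(
            drop=True
        )
        baseline = mio.read_repertoire(
            d / "repertoires" / f"{pid}_baseline.tsv", pid, "baseline"
        )
        res_path = d / "repertoires" / f"{pid}_resistance.tsv"
        resistance = (
            mio.read_repertoire(res_path, pid, "resistance")
            if res_path.exists()
            else None
        )
        patients.append(
            PatientBundle(
                pid, pmuts, profiles[pid], hla[pid], baseline, resistance, outcome
            )
        )
    return SyntheticCohort(config=None, patients=patients, truth={})


def validate_inputs(input_dir) -> list[str]:
    """Schema and cross-file consistency checks; returns failure messages."""
    d = Path(input_dir)
    failures: list[str] = []
    try:
        muts = mio.read_mutations(d / "mutations.tsv")
    except Exception as e:
        failures.append(f"mutations.tsv: {e}")
        muts = None
    try:
        profiles = mio.read_segments(d / "segments.tsv", d / "purity_ploidy.tsv")
    except Exception as e:
        failures.append(f"segments.tsv: {e}")
        profiles = {}
    try:
        outcomes = {o.patient_id for o in mio.read_clinical(d / "clinical.tsv")}
    except Exception as e:
        failures.append(f"clinical.tsv: {e}")
        outcomes = set()
    if muts is not None:
        if (muts.position < 1).any():
            failures.append("mutations.tsv: positions must be >= 1")
        if (muts.alt_reads > muts.total_reads).any():
            failures.append("mutations.tsv: alt_reads exceed total_reads")
        if outcomes:
            orphans = set(muts["sample"].astype(str)) - outcomes
            if orphans:
                failures.append(
                    f"patients in mutations but not clinical table: {sorted(orphans)}"
                )
    for sample in profiles:
        if outcomes and sample not in outcomes:
            failures.append(f"sample {sample} in segments but not clinical table")
    return failures
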