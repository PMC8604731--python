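"""Readers and writers for the pipeline's tabular dialects.

All formats are plain TSV with documented columns and 1-based inclusive
coordinates:

* mutations (MAF-like): ``sample, chromosome, position, ref, alt, gene,
  consequence, alt_reads, total_reads`` plus optional ``hotspot``,
  ``biallelic``; unknown columns are preserved on round-trip;
* segments (SEG-like): ``sample, chromosome, start, end, total_cn,
  minor_cn`` with a companion ``sample, purity, ploidy`` table;
* HLA genotypes: ``patient, locus, allele, protein_seq, somatic_loh``;
* repertoires (AIRR-compatible): ``junction_aa, duplicate_count,
  productive`` or the simplified ``cdr3_aa, reads, frequency`` dialect;
* clinical outcomes: ``patient, best_overall_response, pfs_months,
  pfs_event, os_months, os_event, histology, germline_carrier``.

Writers emit fixed-precision numeric formatting so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cna import SegmentProfile
from .immuno import HlaAllele, HlaGenotype, CLASS_I_LOCI, CLASS_II_LOCI
from .stats import PatientOutcome
from .tcr import Repertoire, repertoire_from_frame

FLOAT_FORMAT = "%.6g"

MUTATION_COLUMNS = [
    "sample", "chromosome", "position", "ref", "alt", "gene", "consequence",
    "alt_reads", "total_reads", "hotspot", "biallelic",
]


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "sample": str})
    required = {"chromosome", "position", "ref", "alt", "gene", "consequence",
                "alt_reads", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    lead = [c for c in MUTATION_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_segments(path, purity_ploidy_path) -> dict[str, SegmentProfile]:
    """Read a multi-sample SEG-like table into per-sample profiles."""
    seg = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "sample": str})
    pp = pd.read_csv(purity_ploidy_path, sep="\t", dtype={"sample": str})
    profiles = {}
    pp = pp.set_index("sample")
    for sample, s in seg.groupby("sample", sort=False):
        if sample not in pp.index:
            raise ValueError(f"sample {sample!r} missing from purity/ploidy table")
        profiles[sample] = SegmentProfile(
            segments=s.drop(columns=["sample"]).reset_index(drop=True),
            purity=float(pp.loc[sample, "purity"]),
            ploidy=float(pp.loc[sample, "ploidy"]),
            sample_id=str(sample),
        )
    return profiles


def write_segments(profiles: dict[str, SegmentProfile], path, purity_ploidy_path):
    frames = []
    pp_rows = []
    for sample, p in profiles.items():
        s = p.segments.copy()
        s.insert(0, "sample", sample)
        frames.append(s)
        pp_rows.append((sample, p.purity, p.ploidy))
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    pd.DataFrame(pp_rows, columns=["sample", "purity", "ploidy"]).to_csv(
        purity_ploidy_path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_hla(path) -> dict[str, HlaGenotype]:
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    genotypes = {}
    for patient, rows in df.groupby("patient", sort=False):
        alleles = {}
        for locus, lrows in rows.groupby("locus", sort=False):
            if len(lrows) != 2:
                raise ValueError(
                    f"patient {patient}: locus {locus} needs exactly two alleles"
                )
            pair = tuple(
                HlaAllele(
                    locus=str(r.locus),
                    name=str(r.allele),
                    protein_seq=str(r.protein_seq),
                    somatic_loh=bool(r.somatic_loh),
                )
                for r in lrows.itertuples(index=False)
            )
            alleles[str(locus)] = pair
        genotypes[str(patient)] = HlaGenotype(alleles)
    return genotypes


def write_hla(genotypes: dict[str, HlaGenotype], path) -> None:
    rows = []
    for patient, g in genotypes.items():
        for locus in CLASS_I_LOCI + CLASS_II_LOCI:
            for a in g.alleles.get(locus, ()):
                rows.append((patient, locus, a.name, a.protein_seq, a.somatic_loh))
    pd.DataFrame(
        rows, columns=["patient", "locus", "allele", "protein_seq", "somatic_loh"]
    ).to_csv(path, sep="\t", index=False)


def read_repertoire(path, sample_id="", timepoint="baseline") -> Repertoire:
    df = pd.read_csv(path, sep="\t")
    return repertoire_from_frame(df, sample_id=sample_id, timepoint=timepoint)


def write_repertoire(rep: Repertoire, path) -> None:
    pd.DataFrame(
        [(c.cdr3_aa, c.reads, c.productive_frequency) for c in rep.clones],
        columns=["cdr3_aa", "reads", "frequency"],
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_clinical(path) -> list[PatientOutcome]:
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    out = []
    for r in df.itertuples(index=False):
        out.append(
            PatientOutcome(
                patient_id=str(r.patient),
                best_overall_response=str(r.best_overall_response),
                pfs_months=float(r.pfs_months),
                pfs_event=bool(r.pfs_event),
                os_months=float(r.os_months),
                os_event=bool(r.os_event),
                histology=str(r.histology),
                germline_carrier=bool(r.germline_carrier),
            )
        )
    return out


def write_clinical(outcomes, path) -> None:
    pd.DataFrame(
        [
            (
                o.patient_id, o.best_overall_response,
                o.pfs_months, o.pfs_event, o.os_months, o.os_event,
                o.histology, o.germline_carrier,
            )
            for o in outcomes
        ],
        columns=[
            "patient", "best_overall_response", "pfs_months", "pfs_event",
            "os_months", "os_event", "histology", "germline_carrier",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_cohort(cohort, out_dir) -> None:
    """Write a synthetic cohort to a directory in the pipeline's dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mut_frames = []
    for p in cohort.patients:
        m = p.mutations.copy()
        m.insert(0, "sample", p.patient_id)
        mut_frames.append(m)
    write_mutations(pd.concat(mut_frames, ignore_index=True), out / "mutations.tsv")
    write_segments(
        {p.patient_id: p.profile for p in cohort.patients},
        out / "segments.tsv",
        out / "purity_ploidy.tsv",
    )
    write_hla({p.patient_id: p.hla for p in cohort.patients}, out / "hla.tsv")
    rep_dir = out / "repertoires"
    rep_dir.mkdir(exist_ok=True)
    for p in cohort.patients:
        write_repertoire(p.baseline_repertoire, rep_dir / f"{p.patient_id}_baseline.tsv")
        if p.resistance_repertoire is not None:
            write_repertoire(
                p.resistance_repertoire, rep_dir / f"{p.patient_id}_resistance.tsv"
            )
    write_clinical(cohort.outcomes(), out / "clinical.tsv")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(cohort.truth, fh, sort_keys=True)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
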