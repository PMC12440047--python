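"""Plain-text readers/writers: cohort TSV, protein matrix TSV / minimal
ADAT-like dialect, clock JSON and ground-truth JSON."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clocks import ClockModel, ProteinMatrix
from .synthetic import GroundTruth

_BOOL_COLS = [
    "ses_high", "education_high", "adolescent_overweight", "activity_sustained", "university_degree",
    "adversity_childhood", "adversity_early_adult", "adversity_mid_adult", "adversity_later_adult",
    "overcrowding", "childhood_illness", "unemployment", "divorce", "conflict_children", "work_crisis",
    "social_isolation", "financial_troubles", "adult_overweight_early", "adult_overweight_mid",
    "adult_overweight_late", "social_support", "adult_ses_high", "died", "censored",
]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in _BOOL_COLS:
        if c in df.columns and df[c].dtype == object:
            df[c] = df[c].map({"True": True, "False": False}).astype("boolean")
        elif c in df.columns and df[c].notna().all():
            df[c] = df[c].astype(bool)
    return df


def write_matrix_tsv(matrix: ProteinMatrix, prefix) -> None:
    """Write abundance, annotations and QC flags as three TSVs."""
    prefix = Path(prefix)
    matrix.abundance.to_csv(prefix.with_suffix(".abundance.tsv"), sep="\t")
    matrix.annotations.to_csv(prefix.with_suffix(".annotations.tsv"), sep="\t")
    matrix.qc_flag.rename("qc_flag").to_csv(prefix.with_suffix(".qc.tsv"), sep="\t")


def read_matrix_tsv(prefix) -> ProteinMatrix:
    prefix = Path(prefix)
    ab = pd.read_csv(prefix.with_suffix(".abundance.tsv"), sep="\t", index_col=0)
    ann = pd.read_csv(prefix.with_suffix(".annotations.tsv"), sep="\t", index_col=0)
    qc = pd.read_csv(prefix.with_suffix(".qc.tsv"), sep="\t", index_col=0)["qc_flag"].astype(bool)
    return ProteinMatrix(abundance=ab, annotations=ann, qc_flag=qc)


def write_adat_like(matrix: ProteinMatrix, path) -> None:
    """Minimal tab-delimited ADAT-like dialect.

    ``^HEADER`` key/value lines, a ``^PROTEIN_META`` block with one row per
    protein (id, organ, scaling factor), then a ``^MATRIX`` block with one
    row per sample (id, QC flag, abundances in protein-meta order).
    """
    cols = list(matrix.abundance.columns)
    with open(path, "w") as fh:
        fh.write("^HEADER\n")
        fh.write("!Format\tlifeclocks-adat-1\n")
        fh.write(f"!Samples\t{len(matrix.abundance)}\n")
        fh.write(f"!Proteins\t{len(cols)}\n")
        fh.write("^PROTEIN_META\n")
        fh.write("protein_id\torgan\tscaling_factor\n")
        for pid in cols:
            row = matrix.annotations.loc[pid]
            fh.write(f"{pid}\t{row['organ']}\t{float(row['scaling_factor'])!r}\n")
        fh.write("^MATRIX\n")
        fh.write("sample_id\tqc_flag\t" + "\t".join(cols) + "\n")
        for sid, vals in matrix.abundance.iterrows():
            flag = bool(matrix.qc_flag.get(sid, False))
            fh.write(f"{sid}\t{int(flag)}\t" + "\t".join(repr(float(v)) for v in vals.to_numpy()) + "\n")


def read_adat_like(path) -> ProteinMatrix:
    section = None
    meta_rows, sample_ids, qc, data, cols = [], [], [], [], None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("^"):
                section = line[1:]
                header_seen = False
                continue
            if section == "HEADER" or not line:
                continue
            if section == "PROTEIN_META":
                if not header_seen:
                    header_seen = True
                    continue
                pid, organ, sf = line.split("\t")
                meta_rows.append((pid, organ, float(sf)))
            elif section == "MATRIX":
                if not header_seen:
                    header_seen = True
                    cols = line.split("\t")[2:]
                    continue
                parts = line.split("\t")
                sample_ids.append(parts[0])
                qc.append(bool(int(parts[1])))
                data.append([float(v) for v in parts[2:]])
    ann = pd.DataFrame(meta_rows, columns=["protein_id", "organ", "scaling_factor"]).set_index("protein_id")
    ab = pd.DataFrame(np.asarray(data), index=pd.Index(sample_ids, name="sample_id"), columns=cols)
    return ProteinMatrix(abundance=ab, annotations=ann, qc_flag=pd.Series(qc, index=ab.index, name="qc_flag"))


def write_clock(clock: ClockModel, path) -> None:
    payload = {
        "name": clock.name,
        "intercept": clock.intercept,
        "transform": clock.transform,
        "proteins": {
            p: {"weight": float(clock.weights[p]), "ref_mean": float(clock.ref_mean[p]), "ref_sd": float(clock.ref_sd[p])}
            for p in clock.proteins
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_clock(path) -> ClockModel:
    d = json.loads(Path(path).read_text())
    prots = list(d["proteins"])
    return ClockModel(
        name=d["name"],
        proteins=prots,
        weights=pd.Series({p: d["proteins"][p]["weight"] for p in prots}),
        ref_mean=pd.Series({p: d["proteins"][p]["ref_mean"] for p in prots}),
        ref_sd=pd.Series({p: d["proteins"][p]["ref_sd"] for p in prots}),
        intercept=float(d["intercept"]),
        transform=d.get("transform", "log10"),
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "exposure_effects": {f"{e}|{c}": b for (e, c), b in truth.exposure_effects.items()},
        "frailty_sd": truth.frailty_sd,
        "organ_noise_sd": truth.organ_noise_sd,
        "triad_sd": truth.triad_sd,
        "triad_organs": list(truth.triad_organs),
        "seeds": truth.seeds,
        "hazard": None if truth.hazard is None else {**truth.hazard.__dict__, "gap_coefs": dict(truth.hazard.gap_coefs)},
        "hazard_intercept": truth.hazard_intercept,
        "mediation_structure": truth.mediation_structure,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    from .config import HazardConfig

    d = json.loads(Path(path).read_text())
    effects = {}
    for key, b in d["exposure_effects"].items():
        e, c = key.split("|")
        effects[(e, c)] = b
    hz = None
    if d.get("hazard"):
        hz = HazardConfig(**d["hazard"])
    return GroundTruth(
        exposure_effects=effects,
        frailty_sd=d["frailty_sd"],
        organ_noise_sd=d["organ_noise_sd"],
        triad_sd=d.get("triad_sd", 0.0),
        triad_organs=tuple(d.get("triad_organs", ())),
        seeds=d.get("seeds", {}),
        hazard=hz,
        hazard_intercept=d.get("hazard_intercept"),
        mediation_structure=d.get("mediation_structure", {}),
    )
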