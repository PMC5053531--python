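"""Plain-text formats consumed and produced by the pipeline.

Everything is TSV or the whitespace-delimited rawcnv call dialect, so every
artifact diffs cleanly and round-trips losslessly for the fields the
pipeline consumes.  BED export converts the internal 1-based inclusive
coordinates to 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cnvsmoke.cnvcall import CNVCall, CNVComponent, parse_rawcnv, write_rawcnv
from cnvsmoke.mtc import PermutationNull
from cnvsmoke.simdata import ProbePanel

__all__ = [
    "write_phenotypes", "read_phenotypes",
    "write_truth", "read_truth",
    "write_panel", "read_panel",
    "read_rawcnv_file", "write_rawcnv_file",
    "write_components", "read_component_matrix", "components_to_bed",
    "write_null", "read_null",
]

PHENOTYPE_COLUMNS = ["subject_id", "sex", "age_years", "current_smoker",
                     "pack_years", "cigs_per_day", "admixture", "group"]


def write_phenotypes(subjects: pd.DataFrame, path) -> Path:
    path = Path(path)
    subjects.loc[:, PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    df["current_smoker"] = df["current_smoker"].astype(bool)
    return df


def write_truth(copy_number: np.ndarray, subject_ids, path) -> Path:
    """True per-subject copy numbers, one column per simulated component."""
    path = Path(path)
    cols = [f"component_{j}" for j in range(copy_number.shape[1])]
    df = pd.DataFrame(copy_number, columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    ids = df["subject_id"].astype(str).tolist()
    return df.drop(columns="subject_id").to_numpy(dtype=np.int16), ids


def write_panel(panel: ProbePanel, path) -> Path:
    """Long-format probe intensities: subject_id, chrom, position, lrr, baf."""
    path = Path(path)
    n, p = panel.lrr.shape
    df = pd.DataFrame({
        "subject_id": np.repeat(panel.subject_ids, p),
        "chrom": panel.chrom,
        "position": np.tile(panel.positions, n),
        "lrr": panel.lrr.ravel(),
        "baf": panel.baf.ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_panel(path) -> ProbePanel:
    df = pd.read_csv(path, sep="\t")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("panel file must describe a single chromosome")
    ids = list(dict.fromkeys(df["subject_id"].astype(str)))
    positions = np.sort(df["position"].unique())
    pos_idx = {p: i for i, p in enumerate(positions)}
    sub_idx = {s: i for i, s in enumerate(ids)}
    lrr = np.full((len(ids), positions.size), np.nan)
    baf = np.full((len(ids), positions.size), np.nan)
    rows = df["subject_id"].astype(str).map(sub_idx).to_numpy()
    cols = df["position"].map(pos_idx).to_numpy()
    lrr[rows, cols] = df["lrr"].to_numpy()
    baf[rows, cols] = df["baf"].to_numpy()
    return ProbePanel(chrom=str(chroms[0]), positions=positions,
                      lrr=lrr, baf=baf, subject_ids=ids)


def read_rawcnv_file(path) -> list[CNVCall]:
    with open(path) as fh:
        return parse_rawcnv(fh)


def write_rawcnv_file(calls: list[CNVCall], path) -> Path:
    path = Path(path)
    path.write_text(write_rawcnv(calls))
    return path


def write_components(components: list[CNVComponent], out_prefix) -> dict[str, Path]:
    """Component summary TSV plus the subject x component copy-number matrix."""
    out_prefix = Path(out_prefix)
    summary = pd.DataFrame([{
        "component_id": c.component_id, "chrom": c.chrom,
        "start": c.start_bp, "end": c.end_bp,
        "carrier_count": c.carrier_count, "frequency": c.frequency,
    } for c in components])
    summary_path = out_prefix.with_suffix(".tsv")
    summary.to_csv(summary_path, sep="\t", index=False)

    matrix_path = out_prefix.parent / (out_prefix.name + "_matrix.tsv")
    if components:
        mat = pd.DataFrame(
            {c.component_id: c.copy_number_by_subject for c in components})
        mat.insert(0, "subject_id", components[0].subject_ids)
    else:
        mat = pd.DataFrame(columns=["subject_id"])
    mat.to_csv(matrix_path, sep="\t", index=False)
    return {"summary": summary_path, "matrix": matrix_path}


def read_component_matrix(path) -> tuple[pd.DataFrame, list[str]]:
    """Copy-number matrix as a DataFrame (columns = component ids) + ids."""
    df = pd.read_csv(path, sep="\t")
    ids = df["subject_id"].astype(str).tolist()
    return df.drop(columns="subject_id"), ids


def components_to_bed(components: list[CNVComponent]) -> str:
    """BED (0-based half-open) export of component intervals."""
    lines = [f"{c.chrom}\t{c.start_bp - 1}\t{c.end_bp}\t{c.component_id}"
             f"\t{c.carrier_count}" for c in components]
    return "\n".join(lines) + ("\n" if lines else "")


def write_null(null: PermutationNull, out_prefix) -> dict[str, Path]:
    """Replicate maxima as one-column TSV + JSON sidecar with the threshold."""
    out_prefix = Path(out_prefix)
    tsv = out_prefix.with_suffix(".tsv")
    pd.DataFrame({"max_neglog10_p": null.max_neglog10_p}).to_csv(
        tsv, sep="\t", index=False)
    sidecar = out_prefix.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "alpha": null.alpha, "seed": null.seed, "threshold": null.threshold,
        "n_replicates": null.n_replicates, "m_components": null.m_components,
    }, indent=2) + "\n")
    return {"maxima": tsv, "sidecar": sidecar}


def read_null(out_prefix) -> PermutationNull:
    out_prefix = Path(out_prefix)
    maxima = pd.read_csv(out_prefix.with_suffix(".tsv"),
                         sep="\t")["max_neglog10_p"].to_numpy()
    meta = json.loads(out_prefix.with_suffix(".json").read_text())
    return PermutationNull(
        max_neglog10_p=maxima, n_replicates=len(maxima),
        threshold=meta["threshold"], alpha=meta["alpha"], seed=meta["seed"],
        m_components=meta.get("m_components"))
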