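"""Readers and writers for the on-disk formats.

Formats are deliberately plain: FASTA for sequences, tab-separated tables
for per-residue annotations and predictor propensities, JSON for reports.
Positions are 1-based in every file and converted at this boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import (
    Dataset,
    Label,
    PredictionTrack,
    ProteinRecord,
    Source,
    normalize_sequence,
)

_LABEL_TOKENS = {"DNA": Label.DNA, "OTHER": Label.OTHER, "NONE": Label.NONE}
_SOURCE_TOKENS = {"structure": Source.STRUCTURE, "disorder": Source.DISORDER}


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> normalized-sequence mapping.

    Sequences are upper-cased; characters outside the 20-letter amino-acid
    alphabet become X. Duplicate record ids are an error.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = normalize_sequence(str(rec.seq))
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n{seq}\n")


def read_annotations(path, sequences: dict[str, str]) -> list[ProteinRecord]:
    """Read a per-residue annotation TSV against known sequences.

    Expected columns: protein_id, position (1-based), label (DNA/OTHER/NONE),
    source (structure/disorder). Unlisted positions default to NONE. A row
    with label NONE carries only the protein's annotation source (written
    for proteins that have no binding residues at all). Proteins without any
    row default to STRUCTURE source.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")

    labels = {pid: np.zeros(len(seq), dtype=np.int8) for pid, seq in sequences.items()}
    sources: dict[str, Source] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid not in labels:
            raise KeyError(f"annotation for unknown protein {pid!r}")
        if row.label not in _LABEL_TOKENS:
            raise ValueError(f"unknown label token {row.label!r} for {pid!r}")
        src = _SOURCE_TOKENS.get(str(row.source).lower())
        if src is None:
            raise ValueError(f"unknown source token {row.source!r} for {pid!r}")
        prev = sources.setdefault(pid, src)
        if prev != src:
            raise ValueError(f"conflicting sources for protein {pid!r}")
        pos = int(row.position)
        if not 1 <= pos <= len(sequences[pid]):
            raise ValueError(
                f"position {pos} out of bounds for protein {pid!r} "
                f"(length {len(sequences[pid])})"
            )
        lab = _LABEL_TOKENS[row.label]
        if lab != Label.NONE:
            labels[pid][pos - 1] = lab

    return [
        ProteinRecord(pid, seq, labels[pid], sources.get(pid, Source.STRUCTURE))
        for pid, seq in sequences.items()
    ]


def write_annotations(proteins, path) -> None:
    """Write annotations; all-NONE proteins get one source-carrying NONE row."""
    rows = []
    for prot in proteins:
        any_row = False
        for i, lab in enumerate(prot.labels):
            if lab != Label.NONE:
                rows.append(
                    (prot.id, i + 1, Label(lab).name, prot.source.value)
                )
                any_row = True
        if not any_row:
            rows.append((prot.id, 1, "NONE", prot.source.value))
    pd.DataFrame(
        rows, columns=["protein_id", "position", "label", "source"]
    ).to_csv(path, sep="\t", index=False)


def load_dataset(fasta_path, annotation_path) -> Dataset:
    """Convenience loader: FASTA + annotation TSV -> Dataset."""
    sequences = read_fasta(fasta_path)
    ds = Dataset()
    for prot in read_annotations(annotation_path, sequences):
        ds.add_protein(prot)
    return ds


# ---- prediction tracks -----------------------------------------------------


def read_prediction_tsv(path, dataset: Dataset, predictor_id: str | None = None):
    """Read per-residue propensities for one predictor into the dataset.

    Expected columns: protein_id, position (1-based), residue, propensity,
    and optionally call (0/1). The residue column is checked against the
    protein sequence. Returns the list of tracks added.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str},
                     float_precision="round_trip")
    if predictor_id is None:
        if "predictor_id" not in df.columns:
            raise ValueError("predictor_id neither given nor present as a column")
        groups = df.groupby("predictor_id", sort=True)
    else:
        groups = [(predictor_id, df)]

    tracks = []
    for pred_id, sub in groups:
        for pid, rows in sub.groupby("protein_id", sort=True):
            protein = dataset.proteins.get(pid)
            if protein is None:
                raise KeyError(f"predictions for unknown protein {pid!r}")
            props = np.full(len(protein), np.nan)
            calls = None
            if "call" in rows.columns and rows["call"].notna().all():
                calls = np.zeros(len(protein), dtype=bool)
            for row in rows.itertuples(index=False):
                pos = int(row.position)
                if not 1 <= pos <= len(protein):
                    raise ValueError(
                        f"position {pos} out of bounds for {pid!r}"
                    )
                if row.residue != protein.sequence[pos - 1]:
                    raise ValueError(
                        f"residue mismatch for protein {pid!r} position {pos}: "
                        f"file has {row.residue!r}, sequence has "
                        f"{protein.sequence[pos - 1]!r}"
                    )
                props[pos - 1] = float(row.propensity)
                if calls is not None:
                    calls[pos - 1] = bool(int(row.call))
            if np.isnan(props).any():
                raise ValueError(
                    f"track {pred_id!r}/{pid!r}: not every position has a propensity"
                )
            track = PredictionTrack(pred_id, pid, props, calls)
            dataset.add_track(track)
            tracks.append(track)
    return tracks


def write_prediction_tsv(tracks, dataset: Dataset, path) -> None:
    """Write tracks with full-precision propensities (round-trip stable)."""
    rows = []
    for track in tracks:
        protein = dataset.proteins[track.protein_id]
        for i, prop in enumerate(track.propensities):
            row = {
                "predictor_id": track.predictor_id,
                "protein_id": track.protein_id,
                "position": i + 1,
                "residue": protein.sequence[i],
                "propensity": repr(float(prop)),
            }
            if track.calls is not None:
                row["call"] = int(track.calls[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_aux_tracks(path, dataset: Dataset, name: str) -> None:
    """Read an auxiliary per-residue track (e.g. predicted disorder)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str},
                     float_precision="round_trip")
    for pid, rows in df.groupby("protein_id", sort=True):
        protein = dataset.proteins.get(pid)
        if protein is None:
            raise KeyError(f"aux track for unknown protein {pid!r}")
        values = np.full(len(protein), np.nan)
        for row in rows.itertuples(index=False):
            values[int(row.position) - 1] = float(row.value)
        if np.isnan(values).any():
            raise ValueError(f"aux track {name!r}/{pid!r}: incomplete")
        dataset.add_aux_track(name, pid, values)


def write_aux_tracks(dataset: Dataset, name: str, path) -> None:
    rows = []
    for (tname, pid), values in sorted(dataset.aux_tracks.items()):
        if tname != name:
            continue
        for i, v in enumerate(values):
            rows.append((pid, i + 1, repr(float(v))))
    pd.DataFrame(rows, columns=["protein_id", "position", "value"]).to_csv(
        path, sep="\t", index=False
    )


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
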