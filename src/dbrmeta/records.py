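"""Core data model: proteins, per-residue binding labels, and predictor tracks.

Residue labels are ternary: a residue binds DNA, binds some other ligand
(protein, RNA, small molecule, ...), or is not annotated to bind anything.
Each protein additionally carries the provenance of its annotations --
whether they come from structures of complexes or from annotations of
intrinsically disordered regions -- because predictor behaviour differs
sharply between the two.

Positions are 0-based half-open everywhere inside this package; the I/O
layer converts from the 1-based convention used in files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

#: canonical amino-acid alphabet; anything else is normalized to X
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class Label(IntEnum):
    """Per-residue binding annotation."""

    NONE = 0   # not annotated to bind any ligand
    OTHER = 1  # binds a non-DNA ligand
    DNA = 2    # DNA-binding residue (DBR)


class Source(str, Enum):
    """Provenance of a protein's binding annotations."""

    STRUCTURE = "structure"  # from solved protein-DNA / protein-ligand complexes
    DISORDER = "disorder"    # from disordered-region annotations


class ProteinClass(str, Enum):
    DNA_BINDING = "dna_binding"
    OTHER_BINDING = "other_binding"


def normalize_sequence(seq: str) -> str:
    """Upper-case and map characters outside the 20-letter alphabet to X."""
    up = seq.upper()
    return "".join(c if c in AMINO_ACIDS else "X" for c in up)


@dataclass
class ProteinRecord:
    """One protein: sequence, per-residue labels, and annotation source."""

    id: str
    sequence: str
    labels: np.ndarray  # int8 array of Label values, len == len(sequence)
    source: Source

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.sequence):
            raise ValueError(
                f"protein {self.id!r}: {len(self.labels)} labels for "
                f"{len(self.sequence)} residues"
            )
        if not np.isin(self.labels, [Label.NONE, Label.OTHER, Label.DNA]).all():
            raise ValueError(f"protein {self.id!r}: unknown label value")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def protein_class(self) -> ProteinClass:
        """DNA-binding iff at least one residue is labeled DNA."""
        if (self.labels == Label.DNA).any():
            return ProteinClass.DNA_BINDING
        return ProteinClass.OTHER_BINDING

    @property
    def n_dna(self) -> int:
        return int((self.labels == Label.DNA).sum())

    @property
    def n_other(self) -> int:
        return int((self.labels == Label.OTHER).sum())


@dataclass
class PredictionTrack:
    """One predictor's per-residue DNA-binding propensities for one protein."""

    predictor_id: str
    protein_id: str
    propensities: np.ndarray
    calls: np.ndarray | None = None  # optional boolean calls

    def __post_init__(self) -> None:
        self.propensities = np.asarray(self.propensities, dtype=float)
        if not np.isfinite(self.propensities).all():
            raise ValueError(
                f"track {self.predictor_id!r}/{self.protein_id!r}: "
                "non-finite propensity"
            )
        if self.calls is not None:
            self.calls = np.asarray(self.calls, dtype=bool)
            if self.calls.shape != self.propensities.shape:
                raise ValueError("calls and propensities differ in length")

    def __len__(self) -> int:
        return len(self.propensities)

    def with_threshold(self, threshold: float) -> "PredictionTrack":
        """Return a copy whose calls are propensity > threshold."""
        return PredictionTrack(
            self.predictor_id,
            self.protein_id,
            self.propensities.copy(),
            self.propensities > threshold,
        )


@dataclass
class Dataset:
    """Proteins plus predictor tracks and auxiliary per-residue tracks.

    ``tracks`` maps (predictor_id, protein_id) -> PredictionTrack;
    ``aux_tracks`` maps (track_name, protein_id) -> per-residue floats
    (e.g. predicted disorder probability, predicted solvent accessibility).
    """

    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    tracks: dict[tuple[str, str], PredictionTrack] = field(default_factory=dict)
    aux_tracks: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def add_protein(self, protein: ProteinRecord) -> None:
        if protein.id in self.proteins:
            raise ValueError(f"duplicate protein id {protein.id!r}")
        self.proteins[protein.id] = protein

    def add_track(self, track: PredictionTrack) -> None:
        protein = self.proteins.get(track.protein_id)
        if protein is None:
            raise KeyError(f"track refers to unknown protein {track.protein_id!r}")
        if len(track) != len(protein):
            raise ValueError(
                f"track {track.predictor_id!r}/{track.protein_id!r}: length "
                f"{len(track)} != sequence length {len(protein)}"
            )
        self.tracks[(track.predictor_id, track.protein_id)] = track

    def add_aux_track(self, name: str, protein_id: str, values) -> None:
        protein = self.proteins.get(protein_id)
        if protein is None:
            raise KeyError(f"aux track refers to unknown protein {protein_id!r}")
        values = np.asarray(values, dtype=float)
        if len(values) != len(protein):
            raise ValueError(
                f"aux track {name!r}/{protein_id!r}: length mismatch"
            )
        self.aux_tracks[(name, protein_id)] = values

    # ---- views -------------------------------------------------------------

    @property
    def predictor_ids(self) -> list[str]:
        return sorted({pid for pid, _ in self.tracks})

    def protein_ids(
        self,
        protein_class: ProteinClass | None = None,
        source: Source | None = None,
    ) -> list[str]:
        """Ids of proteins matching the given class/source filters, sorted."""
        out = []
        for pid, prot in self.proteins.items():
            if protein_class is not None and prot.protein_class != protein_class:
                continue
            if source is not None and prot.source != source:
                continue
            out.append(pid)
        return sorted(out)

    def pooled_labels(self, protein_ids=None) -> np.ndarray:
        """Residue labels concatenated over the given proteins (sorted ids)."""
        ids = sorted(self.proteins) if protein_ids is None else list(protein_ids)
        return np.concatenate([self.proteins[p].labels for p in ids])

    def pooled_scores(self, predictor_id: str, protein_ids=None) -> np.ndarray:
        """One predictor's propensities concatenated in the same order."""
        ids = sorted(self.proteins) if protein_ids is None else list(protein_ids)
        parts = []
        for p in ids:
            key = (predictor_id, p)
            if key not in self.tracks:
                raise KeyError(
                    f"missing track {predictor_id!r} for protein {p!r}"
                )
            parts.append(self.tracks[key].propensities)
        return np.concatenate(parts)

    def n_residues(self) -> int:
        return sum(len(p) for p in self.proteins.values())
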