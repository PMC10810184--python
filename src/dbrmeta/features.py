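"""Per-residue feature profiles for the meta-predictor.

Each residue is described by 170 values built from three groups:

* group 1 -- the per-residue propensities of three base predictors
  (a disorder-trained track and two structure-trained tracks);
* group 2 -- seven sequence-derived hallmarks of DNA binding: five
  physicochemical amino-acid scales (polarizability, side-chain charge,
  hydrophilicity, disorder propensity, hydrophobicity) plus two auxiliary
  predicted tracks (relative solvent accessibility and disorder
  probability);
* group 3 -- twenty aggregate disorder statistics: for ten centered segment
  lengths (5, 9, ..., 41), the mean of the disorder track and the fraction
  of its values above 0.5.

Groups 1+2 (10 values per residue) are presented through a sliding window
of size 15 with zero padding at the termini (150 values); group 3 is
appended unwindowed, giving 15*10 + 20 = 170 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import AMINO_ACIDS, Dataset

# ---------------------------------------------------------------------------
# Amino-acid scales (order: ACDEFGHIKLMNPQRSTVWY)
# ---------------------------------------------------------------------------

# Charton & Charton polarizability
_POLARIZABILITY = [0.046, 0.128, 0.105, 0.151, 0.290, 0.000, 0.230, 0.186,
                   0.219, 0.186, 0.221, 0.134, 0.131, 0.180, 0.291, 0.062,
                   0.108, 0.140, 0.409, 0.298]
# net side-chain charge at neutral pH (His partially protonated)
_CHARGE = [0.0, 0.0, -1.0, -1.0, 0.0, 0.0, 0.1, 0.0, 1.0, 0.0, 0.0, 0.0,
           0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]
# Hopp & Woods hydrophilicity
_HYDROPHILICITY = [-0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
                   -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3]
# TOP-IDP intrinsic disorder propensity
_DISORDER_PROP = [0.060, 0.020, 0.192, 0.736, -0.697, 0.166, 0.303, -0.486,
                  0.586, -0.326, -0.397, 0.007, 0.987, 0.318, 0.180, 0.341,
                  0.059, -0.121, -0.884, -0.510]
# Kyte & Doolittle hydropathy
_HYDROPHOBICITY = [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
                   1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3]

AA_SCALES: dict[str, dict[str, float]] = {
    name: dict(zip(AMINO_ACIDS, values))
    for name, values in [
        ("polarizability", _POLARIZABILITY),
        ("charge", _CHARGE),
        ("hydrophilicity", _HYDROPHILICITY),
        ("disorder_propensity", _DISORDER_PROP),
        ("hydrophobicity", _HYDROPHOBICITY),
    ]
}

DEFAULT_SCALE_NAMES = tuple(AA_SCALES)
DEFAULT_AUX_NAMES = ("asa", "disorder")


def _normalized_table(name: str) -> dict[str, float]:
    """Min-max normalize a scale over the alphabet; X maps to the mean."""
    if name not in AA_SCALES:
        raise KeyError(f"unknown amino-acid scale {name!r}")
    vals = np.array([AA_SCALES[name][a] for a in AMINO_ACIDS])
    lo, hi = vals.min(), vals.max()
    normed = (vals - lo) / (hi - lo)
    table = dict(zip(AMINO_ACIDS, normed))
    table["X"] = float(normed.mean())
    return table


def scale_features(sequence: str, scale_names=DEFAULT_SCALE_NAMES) -> np.ndarray:
    """Apply min-max-normalized amino-acid scales position-wise.

    Returns an (L, n_scales) array in [0, 1]; X gets the alphabet mean.
    """
    tables = [_normalized_table(n) for n in scale_names]
    return np.array(
        [[t[c] for t in tables] for c in sequence], dtype=float
    ).reshape(len(sequence), len(tables))


@dataclass
class FeatureConfig:
    window: int = 15
    group1_predictors: tuple[str, ...] = ("diso_a", "struct_a", "struct_b")
    group2_scales: tuple[str, ...] = DEFAULT_SCALE_NAMES
    group2_aux: tuple[str, ...] = DEFAULT_AUX_NAMES
    group3_segments: tuple[int, ...] = tuple(range(5, 42, 4))  # 5,9,...,41
    include_group3: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be a positive odd integer")
        if any(s % 2 == 0 for s in self.group3_segments):
            raise ValueError("group-3 segment lengths must be odd")

    @property
    def n_per_residue(self) -> int:
        return (
            len(self.group1_predictors)
            + len(self.group2_scales)
            + len(self.group2_aux)
        )

    @property
    def n_group3(self) -> int:
        return 2 * len(self.group3_segments) if self.include_group3 else 0

    @property
    def n_columns(self) -> int:
        return self.window * self.n_per_residue + self.n_group3

    def column_names(self) -> list[str]:
        per_res = list(self.group1_predictors) + list(self.group2_scales) + [
            f"aux_{a}" for a in self.group2_aux
        ]
        half = self.window // 2
        names = [
            f"{feat}@{off:+d}"
            for off in range(-half, half + 1)
            for feat in per_res
        ]
        if self.include_group3:
            for s in self.group3_segments:
                names += [f"disorder_mean_w{s}", f"disorder_frac_w{s}"]
        return names


def aggregate_disorder_features(
    disorder_track, segments=tuple(range(5, 42, 4))
) -> np.ndarray:
    """Segment statistics of the disorder track, centered on each residue.

    For each segment length s the segment is truncated at the termini; the
    two statistics are the track mean and the fraction of values > 0.5.
    Returns (L, 2*len(segments)).
    """
    track = np.asarray(disorder_track, dtype=float)
    length = len(track)
    cols = []
    csum = np.concatenate([[0.0], np.cumsum(track)])
    chigh = np.concatenate([[0.0], np.cumsum(track > 0.5)])
    idx = np.arange(length)
    for s in segments:
        half = s // 2
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, length)
        n = hi - lo
        cols.append((csum[hi] - csum[lo]) / n)
        cols.append((chigh[hi] - chigh[lo]) / n)
    return np.column_stack(cols)


def windowed_profile(per_residue: np.ndarray, window: int) -> np.ndarray:
    """Concatenate each residue's neighborhood of per-residue vectors.

    Offsets run -(w-1)/2 .. +(w-1)/2; positions beyond the termini
    contribute zero vectors. (L, k) -> (L, window*k).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    per_residue = np.asarray(per_residue, dtype=float)
    length, k = per_residue.shape
    half = window // 2
    padded = np.zeros((length + 2 * half, k))
    padded[half:half + length] = per_residue
    out = np.empty((length, window * k))
    for j, off in enumerate(range(window)):
        out[:, j * k:(j + 1) * k] = padded[off:off + length]
    return out


@dataclass
class FeatureProfile:
    """Per-residue feature matrix for one protein."""

    protein_id: str
    matrix: np.ndarray  # (L, n_columns)
    column_names: list[str]


def _smooth(values: np.ndarray, window: int = 21) -> np.ndarray:
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(len(values))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, len(values))
    return (csum[hi] - csum[lo]) / (hi - lo)


def _fallback_aux(dataset: Dataset, pid: str, name: str) -> np.ndarray:
    """Scale-derived stand-in when a predicted aux track is absent.

    ``disorder`` falls back to the smoothed disorder-propensity scale and
    ``asa`` to the smoothed inverted hydrophobicity scale -- crude but
    sequence-only, so profiles can always be built.
    """
    seq = dataset.proteins[pid].sequence
    if name == "disorder":
        base = scale_features(seq, ("disorder_propensity",))[:, 0]
    elif name == "asa":
        base = 1.0 - scale_features(seq, ("hydrophobicity",))[:, 0]
    else:
        raise KeyError(f"no fallback for aux track {name!r}")
    return _smooth(base)


def build_profiles(
    dataset: Dataset,
    config: FeatureConfig | None = None,
    allow_aux_fallback: bool = True,
) -> dict[str, FeatureProfile]:
    """Build the full per-residue profile for every protein in the dataset.

    Columns are ordered [windowed groups 1+2 | group 3] and deterministic
    given the config. Missing group-1 tracks are an error; missing aux
    tracks use the documented scale-based fallback unless disallowed.
    """
    config = config or FeatureConfig()
    names = config.column_names()
    profiles: dict[str, FeatureProfile] = {}
    for pid in sorted(dataset.proteins):
        prot = dataset.proteins[pid]
        cols = []
        for pred in config.group1_predictors:
            key = (pred, pid)
            if key not in dataset.tracks:
                raise KeyError(f"protein {pid!r} lacks group-1 track {pred!r}")
            cols.append(dataset.tracks[key].propensities)
        scales = scale_features(prot.sequence, config.group2_scales)
        cols.extend(scales.T)
        aux_values = {}
        for aux in config.group2_aux:
            key = (aux, pid)
            if key in dataset.aux_tracks:
                values = dataset.aux_tracks[key]
            elif allow_aux_fallback:
                values = _fallback_aux(dataset, pid, aux)
            else:
                raise KeyError(f"protein {pid!r} lacks aux track {aux!r}")
            aux_values[aux] = values
            cols.append(values)
        per_residue = np.column_stack(cols)
        matrix = windowed_profile(per_residue, config.window)
        if config.include_group3:
            disorder = aux_values.get("disorder")
            if disorder is None:
                key = ("disorder", pid)
                disorder = (
                    dataset.aux_tracks[key]
                    if key in dataset.aux_tracks
                    else _fallback_aux(dataset, pid, "disorder")
                )
            group3 = aggregate_disorder_features(disorder, config.group3_segments)
            matrix = np.hstack([matrix, group3])
        if not np.isfinite(matrix).all():
            raise ValueError(f"non-finite feature values for protein {pid!r}")
        profiles[pid] = FeatureProfile(pid, matrix, names)
    return profiles
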