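"""False-positive proximity analysis around native DNA-binding residues.

Native DBR annotations depend on somewhat arbitrary atom-distance cutoffs,
so a "false positive" immediately adjacent to a native DBR may not be a
real mistake. This analysis computes a *tolerant* TPR: a predicted DBR
within x sequence positions of the nearest native DBR counts as correct,
for x = 0..x_max. The curve is compared against a baseline where residues
are called positive at random at the same rate; an excess in the x=0 -> 1
increment over the baseline's is the diagnostic signal that false
positives concentrate next to native sites.

The tolerant TPR keeps P (the native DBR count) as its denominator and is
deliberately not capped at 1: with a large tolerance a predictor can
accumulate more tolerated positives than there are native DBRs.
Proteins without any native DBR are excluded (distance undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import Dataset, Label


def dbr_distances(labels) -> np.ndarray:
    """Per-residue sequence distance to the nearest DNA-labeled residue.

    Distances are computed within one protein; requires >= 1 DNA residue.
    """
    labels = np.asarray(labels)
    anchors = np.flatnonzero(labels == Label.DNA)
    if anchors.size == 0:
        raise ValueError("protein has no DNA-labeled residues")
    idx = np.arange(len(labels))
    return np.abs(idx[:, None] - anchors[None, :]).min(axis=1)


@dataclass
class ProximityCurve:
    tolerances: np.ndarray      # 0..x_max
    tpr_at: np.ndarray          # tolerant TPR per tolerance
    baseline_at: np.ndarray | None  # rate-matched random baseline
    positive_rate: float
    n_pos: int

    def relative_increments(self) -> np.ndarray:
        """(TPR(x+1) - TPR(x)) / TPR(x) for consecutive tolerances."""
        return relative_increase(self.tpr_at[:-1], self.tpr_at[1:])


def relative_increase(tpr_lo, tpr_hi) -> np.ndarray:
    """Relative growth between two tolerant-TPR values, e.g.
    (0.59 - 0.49) / 0.49 ~= 0.20."""
    tpr_lo = np.asarray(tpr_lo, dtype=float)
    tpr_hi = np.asarray(tpr_hi, dtype=float)
    return (tpr_hi - tpr_lo) / tpr_lo


def _curve_from_calls(
    distances: list[np.ndarray], calls: list[np.ndarray], n_pos: int, x_max: int
) -> np.ndarray:
    dist = np.concatenate(distances)
    called = np.concatenate(calls)
    xs = np.arange(x_max + 1)
    return np.array([
        (called & (dist <= x)).sum() / n_pos for x in xs
    ])


def _collect(dataset: Dataset, calls_by_protein: dict[str, np.ndarray]):
    """Distances and calls for proteins that have >= 1 native DBR."""
    distances, calls, n_pos, n_res = [], [], 0, 0
    for pid in sorted(calls_by_protein):
        prot = dataset.proteins[pid]
        if (prot.labels == Label.DNA).sum() == 0:
            continue  # distance to nearest DBR undefined; skipped
        c = np.asarray(calls_by_protein[pid], dtype=bool)
        if len(c) != len(prot):
            raise ValueError(f"calls length mismatch for protein {pid!r}")
        distances.append(dbr_distances(prot.labels))
        calls.append(c)
        n_pos += prot.n_dna
        n_res += len(prot)
    if n_pos == 0:
        raise ValueError("no DNA-labeled residues in any protein")
    return distances, calls, n_pos, n_res


def tolerant_tpr_curve(
    dataset: Dataset,
    calls_by_protein: dict[str, np.ndarray],
    x_max: int = 5,
) -> ProximityCurve:
    """Tolerant TPR per tolerance x, pooled over proteins with native DBRs.

    TP(x) counts predicted positives at distance <= x from the nearest
    native DBR; TPR(x) = TP(x) / P. TPR(0) is the standard TPR.
    """
    distances, calls, n_pos, n_res = _collect(dataset, calls_by_protein)
    tpr = _curve_from_calls(distances, calls, n_pos, x_max)
    rate = float(np.concatenate(calls).mean())
    return ProximityCurve(np.arange(x_max + 1), tpr, None, rate, n_pos)


def random_baseline_curve(
    dataset: Dataset,
    calls_by_protein: dict[str, np.ndarray] | None = None,
    positive_rate: float | None = None,
    x_max: int = 5,
    n_reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Mean tolerant TPR of rate-matched i.i.d. random calls.

    Either explicit calls (whose rate is matched) or a positive rate must
    be given. Each replicate calls residues positive independently at that
    rate; the tolerant TPR is computed identically and averaged.
    """
    if calls_by_protein is None:
        if positive_rate is None:
            raise ValueError("provide calls_by_protein or positive_rate")
        calls_by_protein = {
            pid: np.zeros(len(p), dtype=bool)
            for pid, p in dataset.proteins.items()
        }
    distances, calls, n_pos, _ = _collect(dataset, calls_by_protein)
    if positive_rate is None:
        positive_rate = float(np.concatenate(calls).mean())
    if not 0 < positive_rate <= 1:
        raise ValueError("positive_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    total = np.zeros(x_max + 1)
    for _ in range(n_reps):
        rand_calls = [rng.random(len(d)) < positive_rate for d in distances]
        total += _curve_from_calls(distances, rand_calls, n_pos, x_max)
    return total / n_reps


def proximity_analysis(
    dataset: Dataset,
    calls_by_protein: dict[str, np.ndarray],
    x_max: int = 5,
    n_reps: int = 100,
    seed: int = 0,
) -> ProximityCurve:
    """Tolerant-TPR curve with its rate-matched random baseline attached."""
    curve = tolerant_tpr_curve(dataset, calls_by_protein, x_max)
    curve.baseline_at = random_baseline_curve(
        dataset, calls_by_protein, x_max=x_max, n_reps=n_reps, seed=seed
    )
    return curve
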