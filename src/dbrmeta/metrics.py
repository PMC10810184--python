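"""Ligand-aware evaluation statistics for per-residue DNA-binding predictions.

DNA-binding residues (DBRs) are rare (~1.5% of residues in realistic data),
so global ROC area alone is a blunt instrument. This module adds:

* **AULC** -- area under the low-false-positive-rate part of the ROC curve,
  either up to a fixed FPR bound or up to the threshold where the number of
  predicted DBRs equals the number of native DBRs; **AULCratio** divides it
  by the area a random (diagonal-ROC) predictor attains over the same
  region, so 1 is random and 2 is twice better than random.
* **CPR / OPR** -- the cross-prediction rate (fraction of residues binding
  *other* ligands that are called DNA-binding) and the over-prediction rate
  (fraction of non-binding residues called DNA-binding), with ratios
  against the analytic random baseline (a calibrated random predictor's
  CPR and OPR both equal its FPR).
* **AUCPC / AUOPC** -- areas under the CPR-vs-TPR and OPR-vs-TPR curves;
  0.5 is random, lower is better.
* Calibrated operating points (sensitivity at fixed FPR, specificity at
  fixed TPR) via linear interpolation on the ROC, so thresholds are
  standardized across predictors.

Positives are DNA-labeled residues; negatives are everything else
(OTHER plus NONE). Residues are pooled across proteins within a set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .records import Label


class DegenerateCurveError(ValueError):
    """Raised when a ROC curve cannot support the requested operation."""


# ---------------------------------------------------------------------------
# ROC curve
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """Monotone ROC curve with tied scores collapsed to single points.

    Points run from the strictest threshold (0, 0) to the loosest (1, 1).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # thresholds[0] is +inf (nothing called positive)
    n_pos: int
    n_neg: int


def compute_roc(labels, scores) -> RocCurve:
    """Build the ROC curve of pooled propensities against ternary labels.

    Positives are DNA residues; OTHER and NONE residues are both negatives.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    y = labels == Label.DNA
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateCurveError(
            f"ROC undefined: {n_pos} positives, {n_neg} negatives"
        )
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    return RocCurve(fpr, tpr, thr, n_pos, n_neg)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the full ROC curve.

    With tied scores collapsed, this equals the tie-corrected Mann-Whitney
    statistic (concordant pairs count 1, tied pairs 1/2).
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _tpr_at_fpr(curve: RocCurve, bound: float) -> float:
    return float(np.interp(bound, curve.fpr, curve.tpr))


def aulc(
    curve: RocCurve,
    mode: str = "fixed_fpr",
    fpr_bound: float = 0.1,
) -> tuple[float, float]:
    """Area under the low-FPR part of the ROC curve; returns (area, bound).

    ``fixed_fpr`` integrates over FPR in [0, fpr_bound]. ``count_matched``
    derives the bound as the FPR at the threshold where the number of
    predicted positives equals the number of native positives, i.e. where
    TP + FP = P. Linear interpolation is used at the bound.
    """
    if mode == "fixed_fpr":
        if not 0 < fpr_bound <= 1:
            raise ValueError("fpr_bound must be in (0, 1]")
        bound = float(fpr_bound)
    elif mode == "count_matched":
        # predicted positives along the curve: tpr*P + fpr*N, non-decreasing
        npred = curve.tpr * curve.n_pos + curve.fpr * curve.n_neg
        target = float(curve.n_pos)
        if npred[-1] < target:
            raise DegenerateCurveError("count-matched bound unattainable")
        bound = float(np.interp(target, npred, curve.fpr))
        if bound <= 0:
            # all P predicted positives sit at FPR 0; area degenerates
            raise DegenerateCurveError(
                "count-matched bound is 0 (no false positives before TP+FP=P)"
            )
    else:
        raise ValueError(f"unknown AULC mode {mode!r}")

    mask = curve.fpr < bound
    xs = np.concatenate([curve.fpr[mask], [bound]])
    ys = np.concatenate([curve.tpr[mask], [_tpr_at_fpr(curve, bound)]])
    return float(np.trapezoid(ys, xs)), bound


def aulc_ratio(aulc_value: float, fpr_bound: float) -> float:
    """AULC divided by a random predictor's AULC over the same region.

    The random baseline is the diagonal ROC, whose area up to FPR b is
    b^2/2 (analytic; no simulation noise). 1 = random, 2 = twice better.
    """
    if fpr_bound <= 0:
        raise ValueError("fpr_bound must be positive")
    return float(aulc_value / (fpr_bound**2 / 2.0))


def threshold_at(
    curve: RocCurve,
    fpr: float | None = None,
    tpr: float | None = None,
) -> tuple[float, float, float]:
    """Threshold achieving a target FPR or TPR by linear interpolation.

    Returns (threshold, achieved_fpr, achieved_tpr), the achieved rates
    being the interpolated values at exactly the target. This standardizes
    operating points across predictors regardless of score scale.
    """
    if (fpr is None) == (tpr is None):
        raise ValueError("specify exactly one of fpr= or tpr=")
    if len(curve.fpr) < 3:
        raise DegenerateCurveError(
            "calibration impossible: curve has no interior points "
            "(all scores identical)"
        )
    # interpolate along the appropriate monotone axis
    finite_thr = np.where(np.isfinite(curve.thresholds), curve.thresholds,
                          curve.thresholds[1])
    if fpr is not None:
        # at a vertical segment (duplicated FPR) the best -- highest -- TPR
        # attainable at this FPR is wanted; np.interp picks that side
        target = float(fpr)
        ach_fpr = target
        ach_tpr = float(np.interp(target, curve.fpr, curve.tpr))
        thr = float(np.interp(target, curve.fpr, finite_thr))
    else:
        # first attainment of the target TPR: the smallest FPR reaching it
        target = float(tpr)
        ach_tpr = target
        i = int(np.searchsorted(curve.tpr, target, side="left"))
        if curve.tpr[i] == target:
            ach_fpr = float(curve.fpr[i])
            thr = float(finite_thr[i])
        else:
            t0, t1 = curve.tpr[i - 1], curve.tpr[i]
            w = (target - t0) / (t1 - t0)
            ach_fpr = float(curve.fpr[i - 1] + w * (curve.fpr[i] - curve.fpr[i - 1]))
            thr = float(finite_thr[i - 1] + w * (finite_thr[i] - finite_thr[i - 1]))
    return thr, ach_fpr, ach_tpr


# ---------------------------------------------------------------------------
# Binary confusion counts, partitioned by negative class
# ---------------------------------------------------------------------------


@dataclass
class BinaryCounts:
    """Confusion counts with false positives split by what the residue binds.

    ``fp_other`` counts false positives among other-ligand-binding residues
    (cross-predictions); ``fp_none`` among non-binding residues
    (over-predictions). fp == fp_other + fp_none always.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    fp_other: int
    fp_none: int
    n_other: int
    n_none: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.tn + self.fp)


def binary_counts(labels, calls) -> BinaryCounts:
    labels = np.asarray(labels)
    calls = np.asarray(calls, dtype=bool)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls differ in length")
    is_dna = labels == Label.DNA
    is_other = labels == Label.OTHER
    is_none = labels == Label.NONE
    tp = int((is_dna & calls).sum())
    fn = int((is_dna & ~calls).sum())
    fp_other = int((is_other & calls).sum())
    fp_none = int((is_none & calls).sum())
    fp = fp_other + fp_none
    tn = int((~is_dna & ~calls).sum())
    return BinaryCounts(
        tp=tp, tn=tn, fp=fp, fn=fn,
        fp_other=fp_other, fp_none=fp_none,
        n_other=int(is_other.sum()), n_none=int(is_none.sum()),
    )


def f1_sens_spec(tpr: float, fpr: float) -> float:
    """Harmonic mean of sensitivity and specificity.

    F1 = 2 * TPR * (1 - FPR) / (TPR + (1 - FPR)); 0 when both terms vanish.
    Note this is *not* the conventional precision/recall F1 (see
    :func:`f1_precision_recall`); with heavily imbalanced classes the two
    differ substantially.
    """
    spec = 1.0 - fpr
    denom = tpr + spec
    if denom == 0:
        return 0.0
    return 2.0 * tpr * spec / denom


def f1_precision_recall(counts: BinaryCounts) -> float:
    """Conventional F1 = 2*precision*recall / (precision + recall)."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 0.0
    return 2.0 * counts.tp / denom


def max_f1(curve: RocCurve) -> float:
    """Maximum of the sensitivity/specificity F1 over all curve points."""
    vals = [f1_sens_spec(t, f) for f, t in zip(curve.fpr, curve.tpr)]
    return float(max(vals))


# ---------------------------------------------------------------------------
# Cross-prediction / over-prediction rates and curves
# ---------------------------------------------------------------------------


def cpr_opr(counts: BinaryCounts) -> tuple[float, float]:
    """Cross- and over-prediction rates from partitioned counts.

    CPR = FP_other / N_other, OPR = FP_none / N_none. An empty denominator
    makes the corresponding rate undefined and it is returned as NaN
    (flagged, never silently 0).
    """
    cpr = counts.fp_other / counts.n_other if counts.n_other > 0 else float("nan")
    opr = counts.fp_none / counts.n_none if counts.n_none > 0 else float("nan")
    return cpr, opr


def cpr_opr_ratios(
    cpr: float, opr: float, calibration_fpr: float
) -> tuple[float, float]:
    """Random-baseline ratios: random CPR and OPR both equal the FPR.

    A random predictor calibrated to a given FPR calls residues positive
    independently of labels, so its CPR and OPR equal that FPR; the ratio
    divides the baseline by the method's rate (higher = better). A rate of
    exactly 0 yields +inf.
    """
    if not 0 < calibration_fpr < 1:
        raise ValueError("calibration_fpr must be in (0, 1)")

    def ratio(rate: float) -> float:
        if np.isnan(rate):
            return float("nan")
        if rate == 0:
            return float("inf")
        return calibration_fpr / rate

    return ratio(cpr), ratio(opr)


@dataclass
class CrossOverCurves:
    """CPR-vs-TPR and OPR-vs-TPR curves swept over all thresholds."""

    tpr: np.ndarray
    cpr: np.ndarray
    opr: np.ndarray
    aucpc: float
    auopc: float


def cross_over_curves(labels, scores) -> CrossOverCurves:
    """Sweep thresholds and integrate CPR and OPR over TPR in [0, 1].

    Requires at least one residue in each of the DNA, OTHER and NONE
    classes. Random scores give areas near 0.5; a predictor that ranks all
    DNA residues above everything else attains 0; lower is better.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_dna = int((labels == Label.DNA).sum())
    n_other = int((labels == Label.OTHER).sum())
    n_none = int((labels == Label.NONE).sum())
    for name, n in [("DNA", n_dna), ("OTHER", n_other), ("NONE", n_none)]:
        if n == 0:
            raise DegenerateCurveError(
                f"cross/over-prediction curves undefined: no {name} residues"
            )

    order = np.argsort(-scores, kind="stable")
    slab = labels[order]
    sscores = scores[order]
    # collapse tied scores: keep cumulative counts at the last row of each tie
    cum_dna = np.cumsum(slab == Label.DNA)
    cum_other = np.cumsum(slab == Label.OTHER)
    cum_none = np.cumsum(slab == Label.NONE)
    last_of_tie = np.r_[sscores[1:] != sscores[:-1], True]
    tpr = np.r_[0.0, cum_dna[last_of_tie] / n_dna]
    cpr = np.r_[0.0, cum_other[last_of_tie] / n_other]
    opr = np.r_[0.0, cum_none[last_of_tie] / n_none]
    aucpc = float(np.trapezoid(cpr, tpr))
    auopc = float(np.trapezoid(opr, tpr))
    return CrossOverCurves(tpr=tpr, cpr=cpr, opr=opr, aucpc=aucpc, auopc=auopc)


# ---------------------------------------------------------------------------
# Full per-method report
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Named scalar metrics for one method on one pooled protein set."""

    auc: float
    aulc: float
    aulc_ratio: float
    aulc_bound: float
    sensitivity_at_fpr: dict[float, float]
    specificity_at_tpr: dict[float, float]
    max_f1: float
    cpr: float
    opr: float
    cpr_ratio: float
    opr_ratio: float
    aucpc: float
    auopc: float
    calibration_fpr: float

    def as_dict(self) -> dict[str, float]:
        out = {
            "auc": self.auc,
            "aulc": self.aulc,
            "aulc_ratio": self.aulc_ratio,
            "aulc_bound": self.aulc_bound,
            "max_f1": self.max_f1,
            "cpr": self.cpr,
            "opr": self.opr,
            "cpr_ratio": self.cpr_ratio,
            "opr_ratio": self.opr_ratio,
            "aucpc": self.aucpc,
            "auopc": self.auopc,
            "calibration_fpr": self.calibration_fpr,
        }
        for f, v in self.sensitivity_at_fpr.items():
            out[f"sensitivity_at_fpr_{f:g}"] = v
        for t, v in self.specificity_at_tpr.items():
            out[f"specificity_at_tpr_{t:g}"] = v
        return out


def compute_report(
    labels,
    scores,
    fpr_points: tuple[float, ...] = (0.1, 0.2),
    tpr_points: tuple[float, ...] = (0.5, 0.7),
    aulc_mode: str = "fixed_fpr",
    aulc_bound: float = 0.1,
    calibration_fpr: float = 0.1,
) -> MetricReport:
    """Compute the full metric panel for one method's pooled propensities."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    curve = compute_roc(labels, scores)
    area, bound = aulc(curve, mode=aulc_mode, fpr_bound=aulc_bound)

    sens = {f: threshold_at(curve, fpr=f)[2] for f in fpr_points}
    spec = {t: 1.0 - threshold_at(curve, tpr=t)[1] for t in tpr_points}

    thr, _, _ = threshold_at(curve, fpr=calibration_fpr)
    counts = binary_counts(labels, scores > thr)
    cpr, opr = cpr_opr(counts)
    cpr_r, opr_r = cpr_opr_ratios(cpr, opr, calibration_fpr)
    crossover = cross_over_curves(labels, scores)

    return MetricReport(
        auc=auc(curve),
        aulc=area,
        aulc_ratio=aulc_ratio(area, bound),
        aulc_bound=bound,
        sensitivity_at_fpr=sens,
        specificity_at_tpr=spec,
        max_f1=max_f1(curve),
        cpr=cpr,
        opr=opr,
        cpr_ratio=cpr_r,
        opr_ratio=opr_r,
        aucpc=crossover.aucpc,
        auopc=crossover.auopc,
        calibration_fpr=calibration_fpr,
    )


def metric_value(labels, scores, name: str, **report_kwargs) -> float:
    """Single named metric (any flat key of :meth:`MetricReport.as_dict`)."""
    if name == "auc":  # fast path: most subsampling runs only need AUC
        return auc(compute_roc(labels, scores))
    report = compute_report(labels, scores, **report_kwargs)
    flat = report.as_dict()
    if name not in flat:
        raise KeyError(
            f"unknown metric {name!r}; available: {sorted(flat)}"
        )
    return flat[name]
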