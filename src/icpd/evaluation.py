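"""Detection-to-truth matching and ROC / precision-recall evaluation.

The evaluation universe is list-based: the candidates in the OutList are the
only positives and negatives considered.  A detection is a *hit* when its
mass lies within dmz ppm of a truth mass and its elution window shares at
least one scan with the truth window.  Each truth peptide can be claimed by
at most one detection (the best-ranked match wins, ties broken by smallest
mass error); the remaining matches of an already-claimed truth are charge or
isotope duplicates of the same feature and are excluded from the counting
universe entirely, so one peptide can neither inflate TP nor FP.  Truth
peptides never claimed at any threshold remain false negatives throughout,
so the ROC curve need not reach TPR = 1.

Rates follow the standard definitions: TPR = recall = TP/(TP+FN),
FPR = FP/(TN+FP), precision = TP/(TP+FP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .icpd_core import ScoredPeak, outlist_to_frame
from .isotope_model import ValidationError
from .simulator import GroundTruth

__all__ = [
    "MatchResult",
    "CurveResult",
    "match_detections",
    "sweep_curves",
    "baseline_criteria_curves",
    "tier_curves",
    "precision_at_recall",
]

CRITERIA = ("score", "volume", "max_intensity")


@dataclass
class MatchResult:
    """Per-detection labels and per-truth hit flags.

    ``label``: +1 claimed a truth peptide, 0 decoy, -1 duplicate (excluded).
    ``truth_idx``: claimed truth row index, or -1.
    ``truth_hit``: per-truth flag, True when some detection claimed it.
    """

    label: np.ndarray
    truth_idx: np.ndarray
    truth_hit: np.ndarray


@dataclass
class CurveResult:
    """Threshold sweep output: ROC and PR points plus the trapezoidal ROC AUC."""

    roc: pd.DataFrame  # threshold, tpr, fpr, tp, fp, tn, fn
    pr: pd.DataFrame  # threshold, precision, recall
    auc: float
    n_truth: int
    n_universe: int


def _as_frame(outlist) -> pd.DataFrame:
    if isinstance(outlist, pd.DataFrame):
        return outlist.reset_index(drop=True)
    return outlist_to_frame(list(outlist))


def _truth_frame(truth) -> pd.DataFrame:
    df = truth.peptides if isinstance(truth, GroundTruth) else truth
    return df.reset_index(drop=True)


def match_detections(
    outlist, truth, dmz: float = 10.0, rank_col: str = "score"
) -> MatchResult:
    """Assign each detection a hit/decoy/duplicate label against the truth."""
    det = _as_frame(outlist)
    tru = _truth_frame(truth)
    label = np.zeros(len(det), dtype=int)
    truth_idx = np.full(len(det), -1, dtype=int)
    truth_hit = np.zeros(len(tru), dtype=bool)
    if len(det) == 0 or len(tru) == 0:
        return MatchResult(label=label, truth_idx=truth_idx, truth_hit=truth_hit)

    d_mass = det["mass"].to_numpy()
    d_lo = det["rt_start"].to_numpy()
    d_hi = det["rt_end"].to_numpy()
    rank = det[rank_col].to_numpy(dtype=float)
    pairs = []  # (det_i, truth_j, rank, ppm_error)
    for j, row in tru.iterrows():
        tol = dmz * 1e-6 * row["mass"]
        close = np.abs(d_mass - row["mass"]) <= tol
        overlap = (d_lo <= row["rt_end"]) & (d_hi >= row["rt_start"])
        for i in np.flatnonzero(close & overlap):
            ppm = abs(d_mass[i] - row["mass"]) / row["mass"] * 1e6
            pairs.append((int(i), int(j), rank[i], ppm))

    matched_dets = set()
    # greedy one-to-one assignment: best rank first, ties by mass error
    for i, j, _, _ in sorted(pairs, key=lambda p: (-p[2], p[3])):
        if i in matched_dets:
            continue
        if truth_hit[j]:
            continue
        truth_hit[j] = True
        matched_dets.add(i)
        label[i] = 1
        truth_idx[i] = j
    # remaining matchers are duplicates of already-claimed features
    for i, j, _, _ in pairs:
        if label[i] == 0 and i not in matched_dets:
            label[i] = -1
    return MatchResult(label=label, truth_idx=truth_idx, truth_hit=truth_hit)


def _sweep(values: np.ndarray, labels: np.ndarray, n_truth: int) -> CurveResult:
    """Threshold sweep over a ranking value; labels in {1 hit, 0 decoy}."""
    order = np.argsort(-values, kind="stable")
    v = values[order]
    lab = labels[order]
    tp_cum = np.cumsum(lab == 1)
    fp_cum = np.cumsum(lab == 0)
    # collapse ties: take the last index of each distinct value
    last = np.flatnonzero(np.append(np.diff(v) != 0, True))
    thresholds = v[last]
    tp = tp_cum[last]
    fp = fp_cum[last]
    n_neg = int((labels == 0).sum())
    fn = n_truth - tp
    tn = n_neg - fp
    tpr = tp / n_truth if n_truth else np.zeros_like(tp, dtype=float)
    fpr = fp / n_neg if n_neg else np.zeros_like(fp, dtype=float)
    with np.errstate(invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
    roc = pd.DataFrame(
        {"threshold": thresholds, "tpr": tpr, "fpr": fpr, "tp": tp, "fp": fp, "tn": tn, "fn": fn}
    )
    pr = pd.DataFrame({"threshold": thresholds, "precision": precision, "recall": tpr})
    auc = float(np.trapezoid(np.append([0.0], tpr), np.append([0.0], fpr))) if n_neg else float("nan")
    return CurveResult(
        roc=roc, pr=pr, auc=auc, n_truth=n_truth, n_universe=int(len(values))
    )


def sweep_curves(outlist, truth, dmz: float = 10.0, rank_col: str = "score") -> CurveResult:
    """ROC and PR curves by sweeping a threshold over all distinct scores."""
    det = _as_frame(outlist)
    tru = _truth_frame(truth)
    if len(det) == 0:
        empty = pd.DataFrame()
        return CurveResult(roc=empty, pr=empty, auc=float("nan"), n_truth=len(tru), n_universe=0)
    match = match_detections(det, tru, dmz=dmz, rank_col=rank_col)
    keep = match.label >= 0
    return _sweep(det[rank_col].to_numpy(dtype=float)[keep], match.label[keep], len(tru))


def baseline_criteria_curves(
    outlist, truth, criterion: str = "score", dmz: float = 10.0
) -> CurveResult:
    """Sweep an alternative peak-picking criterion (volume, max intensity)."""
    if criterion not in CRITERIA:
        raise ValidationError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    return sweep_curves(outlist, truth, dmz=dmz, rank_col=criterion)


def tier_curves(
    outlist, truth, dmz: float = 10.0, rank_col: str = "score", tier_col: str = "tier"
) -> dict[str, CurveResult]:
    """Per-abundance-tier curves: each tier's truths vs the shared decoys.

    Detections claiming truths of other tiers are excluded from a tier's
    universe, mirroring a per-tier reading of one global candidate list.
    """
    det = _as_frame(outlist)
    tru = _truth_frame(truth)
    if tier_col not in tru.columns:
        raise ValidationError(f"truth table has no {tier_col!r} column")
    match = match_detections(det, tru, dmz=dmz, rank_col=rank_col)
    values = det[rank_col].to_numpy(dtype=float)
    out: dict[str, CurveResult] = {}
    for tier, rows in tru.groupby(tier_col, sort=True):
        in_tier = np.zeros(len(det), dtype=bool)
        for i in np.flatnonzero(match.label == 1):
            if match.truth_idx[i] in rows.index:
                in_tier[i] = True
        universe = (match.label == 0) | in_tier
        labels = in_tier[universe].astype(int)
        out[str(tier)] = _sweep(values[universe], labels, n_truth=len(rows))
    return out


def precision_at_recall(result: CurveResult, recall: float) -> float:
    """Best precision attainable at or above a recall level (0 when unreachable)."""
    if len(result.pr) == 0:
        return 0.0
    ok = result.pr["recall"].to_numpy() >= recall
    if not ok.any():
        return 0.0
    return float(result.pr["precision"].to_numpy()[ok].max())
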