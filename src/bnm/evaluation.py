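"""Power/FDR/ROC evaluation of genome scans against known causative loci.

Scores are on [0, 1] with small values significant (R-values for the
block-network scan, P-values for an interval-mapping comparator); a
marker is *called* at a threshold when its score is <= the threshold.
Effect-size data points (one per causative locus per phenotype) are
ranked by effect size and grouped into overlapping sliding windows so
that power and FDR can be traced as a function of effect size.  A d-Mb
block-tolerance mode collapses calls within fixed d-megabase bins so a
near-miss inside the causative locus's bin counts as the same
discovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


def sliding_windows(n_points: int, window: int, offset: int) -> list[tuple[int, int]]:
    """Overlapping index intervals [k*offset, k*offset + window).

    Windows that would overrun ``n_points`` are dropped (no partial
    windows); (19000, 4000, 200) and (9500, 2000, 100) both give 76.
    """
    if window < 1 or offset < 1 or offset > window:
        raise ValueError("need window >= 1 and 1 <= offset <= window")
    if window > n_points:
        raise ValueError("window exceeds number of points")
    out = []
    k = 0
    while k * offset + window <= n_points:
        out.append((k * offset, k * offset + window))
        k += 1
    return out


def power_fdr(
    effect_sizes, scores, is_true, threshold: float, window: int, offset: int
) -> pd.DataFrame:
    """Per-window mean effect size, power and FDR at a fixed threshold.

    Points are sorted by ascending effect size (stable).  Within a
    window, power = called true points / true points and FDR = called
    false points / all called points; a window with no calls reports
    FDR as NaN (undefined).
    """
    effect_sizes = np.asarray(effect_sizes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    is_true = np.asarray(is_true, dtype=bool)
    order = np.argsort(effect_sizes, kind="stable")
    e, s, t = effect_sizes[order], scores[order], is_true[order]
    called = s <= threshold
    rows = []
    for start, end in sliding_windows(len(e), window, offset):
        cw, tw = called[start:end], t[start:end]
        n_calls = int(cw.sum())
        n_true = int(tw.sum())
        power = float((cw & tw).sum() / n_true) if n_true else np.nan
        fdr = float((cw & ~tw).sum() / n_calls) if n_calls else np.nan
        rows.append(
            {
                "mean_effect_size": float(e[start:end].mean()),
                "power": power,
                "fdr": fdr,
                "n_calls": n_calls,
            }
        )
    return pd.DataFrame(rows)


def roc_curve(scores, is_true):
    """ROC over the score sweep (small = significant) and its AUROC.

    Returns ``(fpr, tpr, auroc)``; tied scores are grouped, the area
    uses the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    is_true = np.asarray(is_true, dtype=bool)
    if is_true.all() or not is_true.any():
        raise ValueError("ROC needs both true and false points")
    fpr, tpr, _ = _sk_roc_curve(is_true, -scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def mb_bins(map_df: pd.DataFrame, d: float) -> pd.Series:
    """Fixed half-open d-Mb bin label per marker, anchored at 0.

    ``map_df`` needs chromosome and mb columns; labels are
    (chromosome, floor(mb / d)) tuples.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    return pd.Series(
        list(zip(map_df["chromosome"], np.floor(map_df["mb"].to_numpy() / d).astype(int))),
        index=map_df.index,
    )


def mb_block_truth(map_df: pd.DataFrame, true_loci, d: float):
    """Bin each marker and flag the bins containing a causative locus.

    ``true_loci`` is an iterable of (chromosome, marker_id).  Returns
    ``(bin_labels, truth_by_bin)`` where truth_by_bin maps bin label ->
    bool.
    """
    bins = mb_bins(map_df, d)
    truth_markers = {(str(c), str(m)) for c, m in true_loci}
    is_true_marker = [
        (str(c), str(m)) in truth_markers
        for c, m in zip(map_df["chromosome"], map_df["marker_id"])
    ]
    truth_by_bin = {}
    for b, t in zip(bins, is_true_marker):
        truth_by_bin[b] = truth_by_bin.get(b, False) or t
    return bins, truth_by_bin


def collapse_calls(bin_labels, called, truth_by_bin):
    """Collapse marker-level calls to one call per d-Mb bin.

    Returns ``(tp, fp)``: a called bin is one true positive when it
    contains the true locus, else one false positive.
    """
    called_bins = {b for b, c in zip(bin_labels, called) if c}
    tp = sum(1 for b in called_bins if truth_by_bin.get(b, False))
    return tp, len(called_bins) - tp


def mean_fdr(effect_sizes, scores, is_true, threshold, window, offset) -> float:
    """FDR at a threshold averaged over windows with at least one call."""
    table = power_fdr(effect_sizes, scores, is_true, threshold, window, offset)
    vals = table["fdr"].dropna()
    if vals.empty:
        raise ValueError("no window makes any call at this threshold")
    return float(vals.mean())


def match_threshold(
    scores_ref,
    truth_ref,
    threshold_ref: float,
    scores_alt,
    truth_alt,
    effect_ref,
    effect_alt,
    window: int,
    offset: int,
) -> float:
    """Find the alt-score threshold with the closest mean windowed FDR.

    The reference mean FDR is computed at ``threshold_ref``; candidates
    are the distinct alt scores, and ties prefer the smaller threshold.
    Raises when the reference makes no calls.
    """
    target = mean_fdr(effect_ref, scores_ref, truth_ref, threshold_ref, window, offset)
    best_thr, best_gap = None, np.inf
    for thr in np.unique(np.asarray(scores_alt, dtype=float)):
        try:
            fdr = mean_fdr(effect_alt, scores_alt, truth_alt, thr, window, offset)
        except ValueError:
            continue
        gap = abs(fdr - target)
        if gap < best_gap - 1e-15:
            best_thr, best_gap = float(thr), gap
    if best_thr is None:
        raise ValueError("no alt threshold makes any call")
    return best_thr
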