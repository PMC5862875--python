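"""Translocation candidate filtering, classification, and annotation.

Candidate rearrangements (from a split-read/discordant-pair caller) are
filtered by minimal-evidence thresholds on split-read support (SR),
discordant-pair support (PE), and their sum. Two tuning strategies exist:

- precision-first tuning against sample-level truth labels (the FISH-style
  setting for IGH translocations): exhaustive grid search maximizing
  precision, then recall, then preferring the least aggressive thresholds;
- a panel-of-normals mode (the MYC setting, where no orthogonal truth
  exists but artifacts recur in normal samples): the smallest thresholds
  under which zero normal-sample candidates survive.

Classification into canonical translocation classes (t(11;14), t(4;14), ...)
is a pure lookup of breakpoints against a region table, and breakpoints are
annotated with genes within a configurable window (default 1 Mb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "FilterThresholds",
    "SupportThresholdFilter",
    "tune_thresholds",
    "apply_thresholds",
    "tune_normal_panel",
    "classify_translocation",
    "annotate_breakpoints",
    "TRANSLOCATION_CLASSES",
]

TRANSLOCATION_CLASSES = [
    "t(11;14)", "t(4;14)", "t(8;14)", "t(6;14)", "t(14;20)", "t(14;16)",
    "t(14;22)", "MYC-ITX", "MYC-CTX", "other-IGH", "other",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Minimal-evidence thresholds and the performance they achieve."""

    min_sr: int
    min_pe: int
    min_total: int
    achieved_precision: float = float("nan")
    achieved_recall: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.min_sr, self.min_pe, self.min_total) < 0:
            raise ValueError("thresholds must be >= 0")


def _support(candidates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sr = candidates["sr"].to_numpy(dtype=int)
    pe = candidates["pe"].to_numpy(dtype=int)
    if (sr < 0).any() or (pe < 0).any():
        raise ValueError("SR/PE support must be non-negative")
    return sr, pe


def _threshold_grid(values: np.ndarray) -> np.ndarray:
    """Smallest representative of every distinct filtering behavior.

    Raising a threshold changes the retained set only as it passes an
    observed support value, so it suffices to test 0 and v+1 for each
    observed v — each the least threshold with its behavior.
    """
    return np.unique(np.concatenate([[0], values + 1]))


def apply_thresholds(
    candidates: pd.DataFrame, thresholds: FilterThresholds
) -> pd.DataFrame:
    """Retain candidates with sr >= min_sr, pe >= min_pe, sr+pe >= min_total."""
    sr, pe = _support(candidates)
    keep = (
        (sr >= thresholds.min_sr)
        & (pe >= thresholds.min_pe)
        & (sr + pe >= thresholds.min_total)
    )
    return candidates[keep]


def _search(
    sr: np.ndarray,
    pe: np.ndarray,
    labels: np.ndarray | None,
    normal_mask: np.ndarray | None,
) -> FilterThresholds:
    """Shared exhaustive grid search for both tuning strategies.

    With ``labels``: lexicographic objective (max precision, max recall,
    min threshold sum, then prefer constraining SR over PE over total —
    ascending (min_total, min_pe, min_sr)); triples retaining zero
    candidates are invalid. With ``normal_mask``: feasible triples are those
    retaining zero normal candidates; objective is the same threshold-size
    preference (least aggressive filter with the guarantee).
    """
    tot = sr + pe
    s_grid = _threshold_grid(sr)
    p_grid = _threshold_grid(pe)
    t_grid = _threshold_grid(tot)
    n_true = int(labels.sum()) if labels is not None else 0

    best_key = None
    best = None
    for s in s_grid:
        m1 = sr >= s
        for p in p_grid:
            m2 = m1 & (pe >= p)
            for t in t_grid:
                keep = m2 & (tot >= t)
                n_keep = int(keep.sum())
                if labels is not None:
                    if n_keep == 0:
                        continue  # "filter everything" is not a valid optimum
                    tp = int((keep & labels).sum())
                    precision = tp / n_keep
                    recall = tp / n_true
                    key = (-precision, -recall, s + p + t, t, p, s)
                else:
                    if int((keep & normal_mask).sum()) > 0:
                        continue
                    precision = recall = float("nan")
                    key = (s + p + t, t, p, s)
                if best_key is None or key < best_key:
                    best_key = key
                    best = FilterThresholds(int(s), int(p), int(t), precision, recall)
    return best


def tune_thresholds(
    candidates: pd.DataFrame, truth_labels: np.ndarray | pd.Series
) -> FilterThresholds:
    """Precision-first threshold tuning against per-candidate truth labels.

    Exhaustively searches (min_sr, min_pe, min_total) up to the observed
    maxima; maximizes precision, then recall, then prefers the least
    aggressive thresholds. Requires at least one true and one false label —
    with degenerate truth the objective is undefined and the caller should
    use :func:`apply_thresholds` with explicit values instead.
    """
    labels = np.asarray(truth_labels, dtype=bool)
    if len(labels) != len(candidates):
        raise ValueError("truth_labels must align with candidates")
    if labels.all() or not labels.any():
        raise ValueError(
            "tuning undefined with all-true or all-false truth labels; "
            "apply explicit thresholds via apply_thresholds instead"
        )
    sr, pe = _support(candidates)
    return _search(sr, pe, labels, None)


def tune_normal_panel(candidates: pd.DataFrame) -> FilterThresholds:
    """Smallest thresholds retaining zero normal-sample candidates.

    Candidates must carry an ``is_normal`` column. By construction no
    normal-sample candidate survives the returned thresholds; applying them
    to tumor candidates yields the somatic call set. With no normal
    candidates the thresholds degenerate to (0, 0, 0) with a warning.
    """
    if "is_normal" not in candidates.columns:
        raise ValueError("candidates need an is_normal column")
    normal = candidates["is_normal"].to_numpy(dtype=bool)
    if not normal.any():
        warnings.warn(
            "no normal-sample candidates; thresholds degenerate to (0,0,0)",
            stacklevel=2,
        )
        return FilterThresholds(0, 0, 0)
    sr, pe = _support(candidates)
    return _search(sr, pe, None, normal)


class SupportThresholdFilter(BaseEstimator):
    """Sklearn-style wrapper around the threshold tuner.

    ``strategy="precision"`` fits against boolean truth labels y;
    ``strategy="normal_panel"`` ignores y and requires an ``is_normal``
    column. ``predict`` returns the retained mask for a candidate table.
    """

    def __init__(self, strategy: str = "precision"):
        self.strategy = strategy

    def fit(self, X: pd.DataFrame, y=None):
        if self.strategy == "precision":
            if y is None:
                raise ValueError("precision strategy requires truth labels y")
            self.thresholds_ = tune_thresholds(X, y)
        elif self.strategy == "normal_panel":
            self.thresholds_ = tune_normal_panel(X)
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        sr, pe = _support(X)
        t = self.thresholds_
        return (sr >= t.min_sr) & (pe >= t.min_pe) & (sr + pe >= t.min_total)


# ---------------------------------------------------------------------------
# Classification and annotation


def _in_region(region, chrom: str, pos: int) -> bool:
    return region.chrom == chrom and region.start <= pos < region.end


def classify_translocation(
    candidate,
    region_table: pd.DataFrame,
    myc_min_separation: int = 100_000,
) -> str:
    """Assign a canonical translocation class from breakpoint positions.

    ``region_table`` rows (label, chrom, start, end) define the IGH locus,
    the MYC region, and each canonical partner window. An IGH-class label is
    assigned when one breakpoint is in IGH and the other in the partner
    window; MYC-ITX when both breakpoints are on the MYC chromosome with one
    in the MYC region and separation of at least ``myc_min_separation``;
    MYC-CTX when exactly one breakpoint is in the MYC region and the partner
    is on another chromosome without an IGH-class match.
    """
    regions = {r.label: r for r in region_table.itertuples()}
    if "IGH" not in regions:
        raise ValueError("region_table must define an IGH row")
    bps = [
        (str(candidate.chrom1), int(candidate.pos1)),
        (str(candidate.chrom2), int(candidate.pos2)),
    ]
    igh = regions["IGH"]
    in_igh = [_in_region(igh, c, p) for c, p in bps]
    if any(in_igh):
        partner = bps[0] if in_igh[1] else bps[1]
        for label, reg in regions.items():
            if label in ("IGH", "MYC"):
                continue
            if _in_region(reg, *partner):
                return label
        myc = regions.get("MYC")
        if myc is not None and _in_region(myc, *partner):
            return "t(8;14)"
        return "other-IGH"
    myc = regions.get("MYC")
    if myc is not None:
        in_myc = [_in_region(myc, c, p) for c, p in bps]
        if any(in_myc):
            (c1, p1), (c2, p2) = bps
            if c1 == myc.chrom and c2 == myc.chrom:
                if abs(p2 - p1) >= myc_min_separation:
                    return "MYC-ITX"
                return "other"
            return "MYC-CTX"
    return "other"


def annotate_breakpoints(
    candidate, gene_bed: pd.DataFrame, window: int = 1_000_000
) -> dict[str, list[str]]:
    """Genes within ``window`` bp of each breakpoint, nearest first.

    ``gene_bed`` columns: chrom, start, end, name (0-based half-open). A gene
    is reported when its interval intersects [pos - window, pos + window].
    """
    out = {}
    for side in ("a", "b"):
        chrom = str(getattr(candidate, f"chrom{1 if side == 'a' else 2}"))
        pos = int(getattr(candidate, f"pos{1 if side == 'a' else 2}"))
        sub = gene_bed[
            (gene_bed["chrom"] == chrom)
            & (gene_bed["start"] < pos + window)
            & (gene_bed["end"] > pos - window)
        ]
        dist = np.maximum(
            0, np.maximum(sub["start"] - pos, pos - (sub["end"] - 1))
        )
        out[side] = list(sub.assign(_d=dist).sort_values(["_d", "name"])["name"])
    return out
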