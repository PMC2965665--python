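"""Barcoding-gap analysis.

A DNA barcoding gap exists when the distribution of intraspecific
distances separates cleanly from the distribution of interspecific
(congeneric + intergeneric) distances, so that a single threshold t can
assign query sequences to species.  This module computes the two
headline fractions at a given threshold (share of intraspecific pairs
with d < t, share of interspecific pairs with d > t — strict
inequalities, boundary pairs counted separately), per-relation histograms
of relative frequencies, the list of conflicting species pairs, and a
grid scan that generalizes the fixed 5% rule.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core_seq import ValidationError
from .distance_k2p import RELATIONS, DistanceMatrix


@dataclass(frozen=True)
class GapAnalysisResult:
    threshold: float
    frac_intra_below: Optional[float]
    frac_inter_above: Optional[float]
    n_intra: int
    n_inter: int
    n_boundary: int
    histogram: dict
    conflict_pairs: tuple

    @property
    def n_misclassified(self) -> int:
        """Pairs on the wrong side of (or exactly at) the threshold."""
        wrong_intra = (round(self.frac_intra_below * self.n_intra)
                       if self.frac_intra_below is not None else 0)
        wrong_inter = (round(self.frac_inter_above * self.n_inter)
                       if self.frac_inter_above is not None else 0)
        return (self.n_intra - wrong_intra) + (self.n_inter - wrong_inter)


def _split_distances(m: DistanceMatrix):
    """Finite intra and pooled inter distances plus inter pair metadata."""
    intra, inter, inter_pairs = [], [], []
    for i, j, rel, dij in m.pairs():
        if not np.isfinite(dij):
            continue
        if rel == "intraspecific":
            intra.append(dij)
        else:
            inter.append(dij)
            inter_pairs.append((m.species[i] or m.taxa[i],
                                m.species[j] or m.taxa[j], dij))
    return np.asarray(intra), np.asarray(inter), inter_pairs


def histogram(m: DistanceMatrix, bin_width: float = 0.05) -> dict:
    """Per-relation binned relative frequencies over half-open bins
    [k*w, (k+1)*w).  Empty relation classes get empty histograms."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    out: dict = {}
    by_rel = m.distances_by_relation()
    for rel in RELATIONS:
        vals = by_rel[rel]
        if vals.size == 0:
            out[rel] = []
            continue
        idx = np.floor(vals / bin_width).astype(int)
        counts = np.bincount(idx)
        out[rel] = [(k * bin_width, (k + 1) * bin_width,
                     counts[k] / vals.size)
                    for k in range(len(counts)) if counts[k] > 0]
    return out


def gap_metrics(m: DistanceMatrix, t: float,
                bin_width: float = 0.05) -> GapAnalysisResult:
    """Exact counting at threshold t with strict inequalities.

    Pairs with d exactly equal to t are counted as neither below nor
    above (reported in ``n_boundary``); classes with no pairs yield an
    absent fraction (None), not 0.
    """
    if t <= 0:
        raise ValidationError("threshold must be positive")
    intra, inter, inter_pairs = _split_distances(m)
    n_boundary = int((intra == t).sum() + (inter == t).sum())
    frac_intra = float((intra < t).mean()) if intra.size else None
    frac_inter = float((inter > t).mean()) if inter.size else None
    conflicts: dict = {}
    for sp_a, sp_b, dij in inter_pairs:
        if dij < t:
            key = tuple(sorted((sp_a, sp_b)))
            conflicts[key] = min(conflicts.get(key, np.inf), dij)
    conflict_pairs = tuple(sorted(
        (a, b, float(d)) for (a, b), d in conflicts.items()))
    return GapAnalysisResult(
        threshold=t, frac_intra_below=frac_intra,
        frac_inter_above=frac_inter,
        n_intra=int(intra.size), n_inter=int(inter.size),
        n_boundary=n_boundary,
        histogram=histogram(m, bin_width),
        conflict_pairs=conflict_pairs,
    )


def scan_thresholds(m: DistanceMatrix, grid_step: float = 0.001
                    ) -> tuple[pd.DataFrame, float]:
    """Evaluate the gap metrics over t = step, 2*step, ..., max(d).

    The best threshold maximizes min(frac_intra_below, frac_inter_above);
    ties break to the smallest t.  Requires both relation classes to be
    populated.
    """
    if grid_step <= 0:
        raise ValidationError("grid_step must be positive")
    intra, inter, _ = _split_distances(m)
    if intra.size == 0 or inter.size == 0:
        raise ValidationError(
            "threshold scan needs both intra- and interspecific pairs")
    d_max = float(max(intra.max(), inter.max()))
    ts = np.arange(grid_step, d_max + grid_step, grid_step)
    intra_sorted = np.sort(intra)
    inter_sorted = np.sort(inter)
    # strict d < t  /  d > t, matching gap_metrics
    fi = np.searchsorted(intra_sorted, ts, side="left") / intra.size
    fo = (inter.size - np.searchsorted(inter_sorted, ts, side="right")
          ) / inter.size
    n_boundary = (np.searchsorted(intra_sorted, ts, side="right")
                  - np.searchsorted(intra_sorted, ts, side="left")
                  + np.searchsorted(inter_sorted, ts, side="right")
                  - np.searchsorted(inter_sorted, ts, side="left"))
    score = np.minimum(fi, fo)
    best_idx = int(np.argmax(score))  # first occurrence = smallest t
    table = pd.DataFrame({
        "t": ts, "frac_intra_below": fi, "frac_inter_above": fo,
        "n_boundary": n_boundary.astype(int),
    })
    return table, float(ts[best_idx])


def write_histogram(hist: dict, path) -> None:
    rows = [{"relation": rel, "bin_lo": lo, "bin_hi": hi, "rel_freq": f}
            for rel, bins in hist.items() for lo, hi, f in bins]
    pd.DataFrame(rows, columns=["relation", "bin_lo", "bin_hi",
                                "rel_freq"]).to_csv(path, sep="\t",
                                                    index=False)


def write_conflicts(result: GapAnalysisResult, path) -> None:
    rows = [{"species_a": a, "species_b": b, "min_d": d}
            for a, b, d in result.conflict_pairs]
    pd.DataFrame(rows, columns=["species_a", "species_b",
                                "min_d"]).to_csv(path, sep="\t", index=False)
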