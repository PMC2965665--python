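"""Pairwise Kimura 2-parameter (K2P) distances.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the observed proportions of transitional and transversional
differences over compared sites, the distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site]

Sites where either sequence carries a gap or an ambiguity code are skipped
per pair (pairwise deletion), so fragments of unequal usable length remain
comparable.  Pairs whose log arguments are non-positive are *saturated*:
they are reported as missing rather than clamped to an invented value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_seq import (Alignment, BarcodingError, SequenceSet,
                       SpecimenRecord, ValidationError, consensus,
                       records_by_sequence)
from .mt_translation import GeneticCode, INVERTEBRATE_MITO, best_frame

RELATIONS = ("intraspecific", "congeneric", "intergeneric")

_ENC = {b: i for i, b in enumerate("ACGT")}


def encode(residues: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3; gaps and ambiguity codes = 4 (excluded per pair)."""
    return np.fromiter((_ENC.get(ch, 4) for ch in residues),
                       dtype=np.int8, count=len(residues))


class SaturationError(BarcodingError):
    def __init__(self, P: float, Q: float):
        super().__init__(
            f"K2P saturated: 1-2P-Q={1 - 2 * P - Q:.4f}, "
            f"1-2Q={1 - 2 * Q:.4f} (P={P:.4f}, Q={Q:.4f})")
        self.P, self.Q = P, Q


class IncomparablePairError(BarcodingError):
    pass


@dataclass(frozen=True)
class PairCounts:
    n_sites: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_sites:
            raise ValidationError("more differences than compared sites")

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_sites

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_sites


def pair_counts(a: str, b: str) -> PairCounts:
    """Transition/transversion counts under pairwise deletion."""
    if len(a) != len(b):
        raise ValidationError(
            f"aligned lengths differ: {len(a)} vs {len(b)}")
    ea, eb = encode(a.upper()), encode(b.upper())
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    if n == 0:
        raise IncomparablePairError("no comparable sites after deletion")
    diff = valid & (ea != eb)
    # transitions are within the purine pair {A,G} (codes 0,2) or the
    # pyrimidine pair {C,T} (codes 1,3): code sum 2 or 4 with both even/odd
    ts = diff & (((ea == 0) & (eb == 2)) | ((ea == 2) & (eb == 0)) |
                 ((ea == 1) & (eb == 3)) | ((ea == 3) & (eb == 1)))
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return PairCounts(n_sites=n, n_transitions=n_ts, n_transversions=n_tv)


def k2p_from_pq(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(P, Q)
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # avoid -0.0


def k2p(counts: PairCounts) -> float:
    return k2p_from_pq(counts.P, counts.Q)


# ---------------------------------------------------------------------------
# Distance matrices

@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-taxon taxonomy labels.

    Missing (saturated or incomparable) entries are NaN and listed in
    ``excluded``.
    """

    taxa: list
    d: np.ndarray
    species: list
    genus: list
    n_sites: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    codon_partition: Optional[int] = None
    excluded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValidationError("matrix shape does not match taxa")

    def __len__(self) -> int:
        return len(self.taxa)

    def index(self, taxon: str) -> int:
        return self.taxa.index(taxon)

    def relation(self, i: int, j: int) -> str:
        if self.species[i] and self.species[i] == self.species[j]:
            return "intraspecific"
        if self.genus[i] and self.genus[i] == self.genus[j]:
            return "congeneric"
        return "intergeneric"

    def pairs(self):
        """Yield (i, j, relation, d) over the upper triangle, NaN included."""
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j, self.relation(i, j), self.d[i, j]

    def distances_by_relation(self) -> dict:
        out = {r: [] for r in RELATIONS}
        for _, _, rel, dij in self.pairs():
            if np.isfinite(dij):
                out[rel].append(dij)
        return {r: np.asarray(v) for r, v in out.items()}

    def is_complete(self) -> bool:
        n = len(self.taxa)
        return bool(np.isfinite(self.d[np.triu_indices(n, 1)]).all())

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, j, rel, dij in self.pairs():
            rows.append({
                "id_a": self.taxa[i], "id_b": self.taxa[j], "relation": rel,
                "n_sites": int(self.n_sites[i, j]),
                "P": self.P[i, j], "Q": self.Q[i, j],
                "d": dij,
            })
        return pd.DataFrame(rows, columns=["id_a", "id_b", "relation",
                                           "n_sites", "P", "Q", "d"])

    def write_phylip(self, path) -> None:
        """Square PHYLIP; missing entries are written as -1.0."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for i, t in enumerate(self.taxa):
                vals = " ".join(
                    f"{v:.6f}" if np.isfinite(v) else "-1.000000"
                    for v in self.d[i])
                fh.write(f"{t:<10s} {vals}\n")


def _codon_site_mask(length: int, frame: int, partition: int) -> np.ndarray:
    """Sites belonging to one codon position of the shared reading frame."""
    pos = np.arange(length)
    return (pos >= frame) & ((pos - frame) % 3 == partition - 1)


def alignment_reading_frame(aln: Alignment,
                            code: GeneticCode = INVERTEBRATE_MITO) -> int:
    """One reading frame per alignment: the best frame of the consensus."""
    return best_frame(consensus(aln), code=code,
                      sequence_id="consensus").frame


def distance_matrix(aln: Alignment | SequenceSet,
                    records: Sequence[SpecimenRecord],
                    codon_partition: Optional[int] = None,
                    code: GeneticCode = INVERTEBRATE_MITO) -> DistanceMatrix:
    """All-pairs K2P distances with pairwise deletion and relation labels.

    ``codon_partition`` in {1, 2, 3} restricts the compared sites to one
    codon position of the alignment's consensus reading frame.
    """
    if isinstance(aln, SequenceSet):
        aln = Alignment.from_sequences(aln)
    rec_map = records_by_sequence(records)
    for sid in aln.ids:
        if sid not in rec_map:
            raise ValidationError(f"no specimen record for sequence {sid!r}")
    X = np.vstack([encode(r) for r in aln.rows])
    if codon_partition is not None:
        if codon_partition not in (1, 2, 3):
            raise ValidationError("codon_partition must be 1, 2 or 3")
        frame = alignment_reading_frame(aln, code)
        X = X[:, _codon_site_mask(aln.length, frame, codon_partition)]
    n = len(aln.ids)
    A = X[:, None, :]
    B = X[None, :, :]
    valid = (A < 4) & (B < 4)
    diff = valid & (A != B)
    ts = diff & (((A == 0) & (B == 2)) | ((A == 2) & (B == 0)) |
                 ((A == 1) & (B == 3)) | ((A == 3) & (B == 1)))
    n_sites = valid.sum(axis=2)
    n_ts = ts.sum(axis=2)
    n_tv = diff.sum(axis=2) - n_ts
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_sites > 0, n_ts / np.maximum(n_sites, 1), np.nan)
        Q = np.where(n_sites > 0, n_tv / np.maximum(n_sites, 1), np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0),
                     -0.5 * np.log(np.maximum(w1, 1e-300))
                     - 0.25 * np.log(np.maximum(w2, 1e-300)) + 0.0,
                     np.nan)
        d[d == 0.0] = 0.0           # normalize -0.0
    np.fill_diagonal(d, 0.0)
    excluded = []
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isfinite(d[i, j]):
                reason = ("no comparable sites" if n_sites[i, j] == 0
                          else "saturated")
                excluded.append((aln.ids[i], aln.ids[j], reason))
    return DistanceMatrix(
        taxa=list(aln.ids), d=d,
        species=[rec_map[s].species for s in aln.ids],
        genus=[rec_map[s].genus for s in aln.ids],
        n_sites=n_sites, P=P, Q=Q,
        codon_partition=codon_partition, excluded=excluded,
    )


def partition_summaries(m: DistanceMatrix) -> dict:
    """The headline range statistics of a barcoding study.

    Per species the maximum intraspecific distance, per genus the minimum
    congeneric distance, and the global minimum intergeneric distance,
    each with the class-wide range.  A class with no pairs is reported as
    absent (None / empty dict), never as zero.
    """
    per_species: dict = {}
    per_genus: dict = {}
    by_rel = {r: [] for r in RELATIONS}
    for i, j, rel, dij in m.pairs():
        if not np.isfinite(dij):
            continue
        by_rel[rel].append(dij)
        if rel == "intraspecific":
            sp = m.species[i]
            per_species[sp] = max(per_species.get(sp, 0.0), dij)
        elif rel == "congeneric":
            g = m.genus[i]
            per_genus[g] = min(per_genus.get(g, math.inf), dij)
    def _range(vals):
        return (float(min(vals)), float(max(vals))) if vals else None
    return {
        "species_max_intra": per_species,
        "intra_range": _range(by_rel["intraspecific"]),
        "genus_min_congeneric": per_genus,
        "congeneric_range": _range(by_rel["congeneric"]),
        "min_intergeneric": (float(min(by_rel["intergeneric"]))
                             if by_rel["intergeneric"] else None),
        "intergeneric_range": _range(by_rel["intergeneric"]),
    }
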