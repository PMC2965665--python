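"""End-to-end sequence quality control and summary reporting.

Pipeline order mirrors how a barcoding lab vets new sequences:

1. translation screen — internal stop codons in the alignment's shared
   reading frame, and frameshift evidence (best frame retains stops, or
   an alignment gap run whose length is not a multiple of 3);
2. indel screen against the column-majority state of the amino-acid
   alignment (indels alone are a warning, not a removal: genuine
   length-variable COI fragments exist);
3. composition-outlier screen — sequences whose GC content deviates from
   the set median by more than a configured margin.  This stands in for
   a database-similarity search for foreign (e.g. bacterial) origin,
   which needs an external reference database; GC displacement is the
   strongest database-free signal for the same failure mode, and the
   report output records this substitution;
4. K2P distance matrix + neighbor-joining tree on the surviving
   sequences;
5. tree flags — long terminal branches and taxonomic misplacement.

A sequence fails when any configured *fatal* check fires; every removal
carries its reasons.  Length-deviant sequences (those that cannot join
the modal-length alignment) are pairwise-aligned against the alignment
consensus to locate their indels and classify them as frameshifting or
in-frame.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .core_seq import (Alignment, NucSequence, SequenceSet, SpecimenRecord,
                       ValidationError, consensus, gc_fraction,
                       records_by_sequence)
from .distance_k2p import distance_matrix
from .mt_translation import (GeneticCode, INVERTEBRATE_MITO, best_frame,
                             detect_indels, n_internal_stops, translate,
                             translate_alignment)
from .nj_tree import flag_tree_outliers, nj

CHECKS = ("stop_codon", "frameshift", "indel", "long_branch",
          "taxonomic_outlier", "composition_outlier")

#: long_branch and taxonomic_outlier are fatal only jointly (spelled
#: "tree_outlier"); an indel alone is a warning.
DEFAULT_FATAL = ("stop_codon", "frameshift", "composition_outlier",
                 "tree_outlier")


@dataclass(frozen=True)
class QCConfig:
    fatal_checks: tuple = DEFAULT_FATAL
    gc_margin: float = 0.15
    c_long: float = 3.0
    code: GeneticCode = INVERTEBRATE_MITO


@dataclass
class SequenceQC:
    sequence_id: str
    checks: dict
    verdict: str = "pass"
    reasons: list = field(default_factory=list)


@dataclass
class QCReport:
    per_sequence: dict
    frame: Optional[int]
    notes: list
    n_input: int
    n_pass: int

    def failed_ids(self) -> list[str]:
        return [s for s, q in self.per_sequence.items()
                if q.verdict == "fail"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in self.per_sequence.values():
            row = {"sequence_id": q.sequence_id, **q.checks,
                   "verdict": q.verdict, "reasons": ";".join(q.reasons)}
            rows.append(row)
        return pd.DataFrame(rows)


def composition_outlier(seqs: SequenceSet,
                        margin: float = 0.15) -> dict:
    """Flag sequences whose GC fraction deviates from the set median by
    more than ``margin`` (absolute)."""
    if len(seqs) < 5:
        return {s.id: False for s in seqs}
    gc = {s.id: gc_fraction(s.residues) for s in seqs}
    med = statistics.median(gc.values())
    return {sid: abs(v - med) > margin for sid, v in gc.items()}


def _gap_events_vs_consensus(seq: NucSequence, cons: str) -> list[int]:
    """Gap-run lengths (either direction) from a global pairwise alignment
    of a length-deviant sequence against the alignment consensus."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    aln = aligner.align(cons.replace("-", "N"), seq.residues)[0]
    t_blocks, q_blocks = aln.aligned
    runs = []
    for k in range(1, len(t_blocks)):
        dt = int(t_blocks[k][0] - t_blocks[k - 1][1])
        dq = int(q_blocks[k][0] - q_blocks[k - 1][1])
        if dt > 0:
            runs.append(dt)     # deletion in the query
        if dq > 0:
            runs.append(dq)     # insertion in the query
    return runs


def run_qc(seqs: SequenceSet, records: Sequence[SpecimenRecord],
           config: QCConfig = QCConfig()
           ) -> tuple[QCReport, SequenceSet]:
    """Run the full QC cascade; returns the report and the filtered set."""
    rec_map = records_by_sequence(records)
    for s in seqs:
        if s.id not in rec_map:
            raise ValidationError(f"no specimen record for sequence {s.id!r}")
    notes = [
        "composition-outlier screen stands in for a database-similarity "
        "search for foreign (non-nematode) origin",
    ]
    qc = {s.id: SequenceQC(s.id, {c: False for c in CHECKS}) for s in seqs}

    # --- partition by length; the modal length defines the aligned set
    lengths = [len(s) for s in seqs]
    modal = statistics.mode(lengths)
    aligned_ids = [s.id for s in seqs if len(s) == modal]
    deviant_ids = [s.id for s in seqs if len(s) != modal]
    aln = Alignment([i for i in aligned_ids],
                    [seqs[i].residues for i in aligned_ids])
    cons = consensus(aln)
    frame = best_frame(cons, code=config.code).frame

    # --- stage 1: translation screen
    for sid in aligned_ids:
        pep = translate(seqs[sid].residues, config.code, frame=frame)
        qc[sid].checks["stop_codon"] = n_internal_stops(pep) > 0
        rep = best_frame(seqs[sid], code=config.code)
        qc[sid].checks["frameshift"] = rep.frameshift_suspected
    for sid in deviant_ids:
        runs = _gap_events_vs_consensus(seqs[sid], cons)
        if any(r % 3 for r in runs):
            qc[sid].checks["frameshift"] = True
        elif runs:
            qc[sid].checks["indel"] = True
        rep = best_frame(seqs[sid], code=config.code)
        if rep.frameshift_suspected:
            qc[sid].checks["frameshift"] = True

    # --- stage 2: indel screen on the amino-acid alignment
    if len(aligned_ids) >= 4:
        aa = translate_alignment(aln, config.code, frame=frame)
        for rep in detect_indels(aa):
            if rep.events:
                qc[rep.sequence_id].checks["indel"] = True

    # --- stage 3: composition outliers
    for sid, flagged in composition_outlier(
            seqs, margin=config.gc_margin).items():
        qc[sid].checks["composition_outlier"] = flagged
    if len(seqs) < 5:
        notes.append("composition screen skipped: fewer than 5 sequences")

    def _fatal(checks: dict) -> list[str]:
        reasons = [c for c in ("stop_codon", "frameshift",
                               "composition_outlier")
                   if c in config.fatal_checks and checks[c]]
        if "tree_outlier" in config.fatal_checks and \
                checks["long_branch"] and checks["taxonomic_outlier"]:
            reasons.extend(["long_branch", "taxonomic_outlier"])
        if "indel" in config.fatal_checks and checks["indel"]:
            reasons.append("indel")
        return reasons

    # --- stages 4-5: distance matrix, NJ tree, tree flags on survivors
    tree_ids = [sid for sid in aligned_ids if not _fatal(qc[sid].checks)]
    if len(tree_ids) < 4:
        notes.append("tree-based checks skipped: fewer than 4 comparable "
                     "sequences")
    else:
        m = distance_matrix(seqs.subset(tree_ids),
                            [rec_map[sid] for sid in tree_ids],
                            code=config.code)
        if not m.is_complete():
            drop = {sid for a, b, _ in m.excluded for sid in (a, b)}
            notes.append("excluded from tree stage (saturated pairs): "
                         + ",".join(sorted(drop)))
            tree_ids = [sid for sid in tree_ids if sid not in drop]
            m = distance_matrix(seqs.subset(tree_ids),
                                [rec_map[sid] for sid in tree_ids],
                                code=config.code)
        if len(tree_ids) >= 4:
            tree = nj(m)
            flags = flag_tree_outliers(
                tree, [rec_map[sid] for sid in tree_ids],
                c_long=config.c_long)
            for sid, f in flags.items():
                qc[sid].checks["long_branch"] = f.long_branch
                qc[sid].checks["taxonomic_outlier"] = f.taxonomic_outlier

    # --- verdicts
    for q in qc.values():
        reasons = _fatal(q.checks)
        if reasons:
            q.verdict = "fail"
            q.reasons = reasons
    passed = [s.id for s in seqs if qc[s.id].verdict == "pass"]
    report = QCReport(per_sequence=qc, frame=frame, notes=notes,
                      n_input=len(seqs), n_pass=len(passed))
    return report, seqs.subset(passed)


# ---------------------------------------------------------------------------
# Sequencing-success tallies

@dataclass
class SequencingTally:
    per_primer: pd.DataFrame
    per_partition: pd.DataFrame


def sequencing_tally(reactions: pd.DataFrame | str) -> SequencingTally:
    """Success rates per primer and pooled per partition.

    ``reactions`` is a table (or TSV path) with columns ``attempt``,
    ``primer`` and boolean ``success`` — one row per sequencing reaction.
    The per-primer rate divides successful reactions by reactions run
    with that primer; the partition rate pools forward and reverse
    reactions of the partition.  Percentages are reported to 1 decimal.
    """
    from .insilico_pcr import PRIMER_PARTITION
    if isinstance(reactions, (str, bytes)) or hasattr(reactions, "read"):
        reactions = pd.read_csv(reactions, sep="\t")
    for col in ("attempt", "primer", "success"):
        if col not in reactions.columns:
            raise ValidationError(f"reactions table: missing column {col!r}")
    unknown = set(reactions["primer"]) - set(PRIMER_PARTITION)
    if unknown:
        raise ValidationError(f"unknown primer name(s): {sorted(unknown)}")
    df = reactions.copy()
    df["success"] = df["success"].astype(bool)
    df["partition"] = df["primer"].map(PRIMER_PARTITION)

    def _rate(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        k = int(g["success"].sum())
        return pd.Series({"n_reactions": n, "n_success": k,
                          "success_rate_pct": round(100.0 * k / n, 1)})

    per_primer = (df.groupby("primer").apply(_rate, include_groups=False)
                  .reset_index())
    per_partition = (df.groupby("partition")
                     .apply(_rate, include_groups=False).reset_index())
    return SequencingTally(per_primer=per_primer,
                           per_partition=per_partition)


# ---------------------------------------------------------------------------
# Variability summary

def variability_report(aln: Alignment,
                       records: Optional[Sequence[SpecimenRecord]] = None,
                       code: GeneticCode = INVERTEBRATE_MITO) -> dict:
    """Fragment variability: length range, alignment length, fractions of
    variable nucleotide and amino-acid columns, and the per-codon-position
    K2P distance ranges (requires records for the distance step)."""
    frame = best_frame(consensus(aln), code=code).frame
    lengths = [len(r.replace("-", "")) for r in aln.rows]

    def _variable_ratio(rows: list[str]) -> float:
        L = len(rows[0])
        var = 0
        for i in range(L):
            states = {r[i] for r in rows} - set("-NX")
            if len(states) > 1:
                var += 1
        return var / L if L else 0.0

    aa_rows = [translate(r, code, frame=frame) for r in aln.rows]
    out = {
        "n_sequences": aln.n_seqs,
        "seq_length_min": min(lengths),
        "seq_length_max": max(lengths),
        "alignment_length": aln.length,
        "nt_variable_ratio": _variable_ratio(aln.rows),
        "aa_variable_ratio": _variable_ratio(aa_rows),
    }
    if records is not None:
        for part in (1, 2, 3):
            m = distance_matrix(aln, records, codon_partition=part,
                                code=code)
            vals = np.concatenate([
                v for v in m.distances_by_relation().values()])
            out[f"k2p_range_pos{part}"] = (
                (float(vals.min()), float(vals.max())) if vals.size
                else None)
    return out
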