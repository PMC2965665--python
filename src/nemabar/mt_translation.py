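"""Translation under the invertebrate mitochondrial genetic code and
screening for pseudogene (numt) signatures.

Nuclear copies of mitochondrial genes are typically pseudogenized: they
accumulate internal stop codons, frame-shifting indels, or amino-acid
indels relative to the functional gene.  The checks here flag exactly
those signatures so downstream distance and tree analyses run on
sequences of verified mitochondrial origin.

The default code is NCBI translation table 5 (invertebrate mitochondrial):
relative to the standard code, TGA -> Trp, AGA/AGG -> Ser, ATA -> Met, and
only TAA/TAG terminate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .core_seq import (Alignment, NucSequence, ValidationError,
                       reverse_complement)

_BASES = "TCAG"

# Amino acids for the 64 codons in TCAG-major order (TTT, TTC, TTA, TTG,
# TCT, ...), transcribed from the published invertebrate mitochondrial code.
_TABLE5_AA = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG"

STOP = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A total mapping from the 64 codons to amino acids ('*' = stop)."""

    name: str
    codon_map: dict

    def __post_init__(self) -> None:
        if len(self.codon_map) != 64:
            raise ValidationError(
                f"genetic code {self.name!r} has {len(self.codon_map)} "
                "entries, expected 64")

    def is_stop(self, codon: str) -> bool:
        return self.codon_map.get(codon) == STOP


def _code_from_aa_string(name: str, aa64: str) -> GeneticCode:
    codons = [b1 + b2 + b3 for b1 in _BASES for b2 in _BASES for b3 in _BASES]
    return GeneticCode(name, dict(zip(codons, aa64)))


#: NCBI transl_table=5.
INVERTEBRATE_MITO = _code_from_aa_string(
    "invertebrate mitochondrial (transl_table=5)", _TABLE5_AA)


def translate(seq: NucSequence | str, code: GeneticCode = INVERTEBRATE_MITO,
              frame: int = 0, strand: Literal["+", "-"] = "+") -> str:
    """Translate one reading frame.

    The trailing partial codon is ignored.  A codon that is entirely gaps
    translates to '-'; any codon containing an ambiguity code or a partial
    gap translates to 'X' and never counts as a stop.
    """
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    if frame not in (0, 1, 2):
        raise ValidationError(f"frame must be 0, 1 or 2, got {frame}")
    if strand == "-":
        residues = reverse_complement(residues)
    elif strand != "+":
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    sub = residues[frame:]
    if len(sub) < 3:
        raise ValidationError(
            f"sequence shorter than one codon in frame {frame}")
    peptide = []
    for i in range(0, len(sub) - len(sub) % 3, 3):
        codon = sub[i:i + 3]
        if codon == "---":
            peptide.append("-")
        elif any(b not in "ACGT" for b in codon):
            peptide.append("X")
        else:
            peptide.append(code.codon_map[codon])
    return "".join(peptide)


def n_internal_stops(peptide: str) -> int:
    """Stops anywhere but the final codon (a trailing stop is terminal)."""
    return peptide[:-1].count(STOP)


@dataclass(frozen=True)
class TranslationReport:
    sequence_id: str
    frame: int
    strand: Literal["+", "-"]
    peptide: str
    n_internal_stops: int
    frameshift_suspected: bool


def internal_gap_runs(residues: str) -> list[int]:
    """Lengths of maximal internal '-' runs (terminal padding ignored)."""
    core = residues.strip("-")
    runs, cur = [], 0
    for ch in core:
        if ch == "-":
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    return runs


def best_frame(seq: NucSequence | str, code: GeneticCode = INVERTEBRATE_MITO,
               include_reverse: bool = False,
               sequence_id: str = "") -> TranslationReport:
    """Pick the reading frame that minimizes internal stop codons.

    Ties break to the lowest frame index (forward before reverse).  The
    frameshift flag is set when even the best frame retains internal stops,
    or when the aligned sequence has an internal gap run whose length is
    not a multiple of 3.
    """
    residues = seq.residues if isinstance(seq, NucSequence) else seq
    if isinstance(seq, NucSequence) and not sequence_id:
        sequence_id = seq.id
    core = residues.replace("-", "")
    if len(core) < 30:
        raise ValidationError(
            "sequence too short for frame selection (< 30 nt)")
    candidates: list[tuple[int, int, int, str, str]] = []
    strands = ["+", "-"] if include_reverse else ["+"]
    for si, strand in enumerate(strands):
        for frame in (0, 1, 2):
            pep = translate(core, code, frame=frame, strand=strand)
            candidates.append(
                (n_internal_stops(pep), si, frame, strand, pep))
    stops, _, frame, strand, pep = min(candidates, key=lambda t: t[:3])
    bad_gap = any(r % 3 for r in internal_gap_runs(residues))
    return TranslationReport(
        sequence_id=sequence_id, frame=frame, strand=strand, peptide=pep,
        n_internal_stops=stops,
        frameshift_suspected=stops > 0 or bad_gap,
    )


# ---------------------------------------------------------------------------
# Indel detection on amino-acid alignments

@dataclass(frozen=True)
class IndelEvent:
    aa_position: int          # 1-based column in the amino-acid alignment
    kind: Literal["insertion", "deletion"]
    length_aa: int


@dataclass(frozen=True)
class IndelReport:
    sequence_id: str
    events: tuple


def detect_indels(aa_alignment: Alignment) -> list[IndelReport]:
    """Report per-sequence indels relative to the column-majority state.

    A column is a *residue column* when more than half the rows hold a
    residue there, a *gap column* when more than half hold gaps.  A
    sequence gapping a run of residue columns carries a deletion of that
    run length; a sequence holding residues across a run of gap columns
    carries an insertion.
    """
    if aa_alignment.n_seqs < 4:
        raise ValidationError(
            "indel detection needs an alignment of at least 4 sequences")
    n, L = aa_alignment.n_seqs, aa_alignment.length
    col_class = []
    for i in range(L):
        gaps = aa_alignment.column(i).count("-")
        if gaps * 2 > n:
            col_class.append("gap")
        elif (n - gaps) * 2 > n:
            col_class.append("residue")
        else:
            col_class.append("tie")
    reports = []
    for sid, row in zip(aa_alignment.ids, aa_alignment.rows):
        events: list[IndelEvent] = []
        i = 0
        while i < L:
            is_del = row[i] == "-" and col_class[i] == "residue"
            is_ins = row[i] != "-" and col_class[i] == "gap"
            if not (is_del or is_ins):
                i += 1
                continue
            kind = "deletion" if is_del else "insertion"
            j = i
            while j < L and (
                (row[j] == "-" and col_class[j] == "residue") if is_del
                else (row[j] != "-" and col_class[j] == "gap")
            ):
                j += 1
            events.append(IndelEvent(aa_position=i + 1, kind=kind,
                                     length_aa=j - i))
            i = j
        reports.append(IndelReport(sequence_id=sid, events=tuple(events)))
    return reports


def translate_alignment(aln: Alignment, code: GeneticCode = INVERTEBRATE_MITO,
                        frame: int = 0) -> Alignment:
    """Row-wise translation of a nucleotide alignment in one shared frame."""
    return Alignment(aln.ids,
                     [translate(r, code, frame=frame) for r in aln.rows])


def write_indel_report(reports: Sequence[IndelReport], path) -> None:
    import pandas as pd
    rows = [{"sequence_id": r.sequence_id, "kind": e.kind,
             "aa_position": e.aa_position, "length_aa": e.length_aa}
            for r in reports for e in r.events]
    pd.DataFrame(rows, columns=["sequence_id", "kind", "aa_position",
                                "length_aa"]).to_csv(path, sep="\t",
                                                     index=False)
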