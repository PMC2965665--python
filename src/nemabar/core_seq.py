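"""Sequence and taxonomy data model.

IUPAC nucleotide handling, FASTA and specimen-table I/O, base-composition
statistics, and a minimal equal-length alignment container.

Internal coordinates are 0-based half-open; anything user-facing (reports,
indel positions) is 1-based inclusive, matching the convention of the
barcoding literature.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO

# ---------------------------------------------------------------------------
# IUPAC alphabet

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
#: Full residue alphabet; '-' is legal only in aligned context.
IUPAC_ALPHABET = frozenset(IUPAC_SETS) | {"-"}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}


class BarcodingError(Exception):
    """Base class for all errors raised by this package."""


class FastaParseError(BarcodingError):
    pass


class ValidationError(BarcodingError):
    pass


def normalize_residues(raw: str, where: str = "sequence") -> str:
    """Uppercase, map U->T, and reject any character outside the IUPAC set.

    Fails fast on corrupt data rather than silently masking it.
    """
    s = raw.upper().replace("U", "T")
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise FastaParseError(
            f"illegal residue(s) {sorted(bad)!r} in {where}"
        )
    if not s:
        raise FastaParseError(f"empty residues in {where}")
    return s


def reverse_complement(residues: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(residues))
    except KeyError as exc:  # pragma: no cover - guarded by normalize
        raise ValidationError(f"cannot complement residue {exc}") from exc


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence over the IUPAC alphabet ('-' allowed when aligned)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        object.__setattr__(
            self, "residues",
            normalize_residues(self.residues, where=f"record {self.id!r}"),
        )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        return self.residues.replace("-", "")

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, reverse_complement(self.residues),
                           self.description)


class SequenceSet:
    """Ordered collection of NucSequence with unique ids."""

    def __init__(self, sequences: Sequence[NucSequence] = ()) -> None:
        self._by_id: dict[str, NucSequence] = {}
        for s in sequences:
            self.add(s)

    def add(self, seq: NucSequence) -> None:
        if seq.id in self._by_id:
            raise FastaParseError(f"duplicate sequence id {seq.id!r}")
        self._by_id[seq.id] = seq

    def __iter__(self) -> Iterator[NucSequence]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __getitem__(self, seq_id: str) -> NucSequence:
        return self._by_id[seq_id]

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        return SequenceSet([self._by_id[i] for i in ids])


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a (multi-line) FASTA file into a SequenceSet.

    Residues are case-folded to uppercase and U is mapped to T; duplicate
    ids and non-IUPAC characters raise :class:`FastaParseError` naming the
    offending record.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
        if head not in (">", ""):
            raise FastaParseError(f"{path}: line 1: expected '>' header")
    seqs = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seqs.add(NucSequence(rec.id, str(rec.seq),
                                 description=rec.description))
        except BarcodingError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    return seqs


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    """Write canonical FASTA: uppercase residues wrapped at 60 columns."""
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id
            if s.description and s.description != s.id:
                header = s.description
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Composition

@dataclass(frozen=True)
class CompositionStats:
    frac_A: float
    frac_C: float
    frac_G: float
    frac_T: float
    n_sites_counted: int

    def as_dict(self) -> dict[str, float]:
        return {"A": self.frac_A, "C": self.frac_C,
                "G": self.frac_G, "T": self.frac_T}


def composition(seqs: SequenceSet | Sequence[NucSequence]) -> CompositionStats:
    """Pooled A/C/G/T proportions; ambiguity codes and gaps are excluded
    from the denominator."""
    counts = Counter()
    for s in seqs:
        counts.update(s.residues)
    n = sum(counts[b] for b in "ACGT")
    if n == 0:
        raise ValidationError("no unambiguous bases to count")
    return CompositionStats(
        frac_A=counts["A"] / n, frac_C=counts["C"] / n,
        frac_G=counts["G"] / n, frac_T=counts["T"] / n,
        n_sites_counted=n,
    )


def gc_fraction(residues: str) -> float:
    """GC proportion over unambiguous bases only."""
    n = sum(residues.count(b) for b in "ACGT")
    if n == 0:
        raise ValidationError("no unambiguous bases to count")
    return (residues.count("G") + residues.count("C")) / n


# ---------------------------------------------------------------------------
# Specimen taxonomy table

@dataclass(frozen=True)
class TruthFlags:
    """Synthetic ground truth attached to simulated specimens."""

    is_numt: bool = False
    is_contaminant: bool = False
    source_species: str = ""

    def __post_init__(self) -> None:
        if self.is_numt and self.is_contaminant:
            raise ValidationError(
                "a sequence cannot be both numt and contaminant")

    @property
    def is_artifact(self) -> bool:
        return self.is_numt or self.is_contaminant


@dataclass(frozen=True)
class SpecimenRecord:
    """One vouchered nematode specimen with its taxonomy labels."""

    voucher: str
    species: str
    genus: str
    higher_taxon: str
    location: str = ""
    sequence_id: Optional[str] = None
    truth: Optional[TruthFlags] = None

    def __post_init__(self) -> None:
        if self.species and not self.genus:
            raise ValidationError(
                f"specimen {self.voucher!r}: species set but genus empty")
        if self.genus and not self.higher_taxon:
            raise ValidationError(
                f"specimen {self.voucher!r}: genus set but higher_taxon empty")


SPECIMEN_COLUMNS = ["voucher", "species", "genus", "higher_taxon",
                    "location", "sequence_id"]


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen TSV.  An empty or '-' sequence_id denotes a
    specimen without a usable sequence (failed or ambiguous sequencing)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"specimen table {path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        sid = getattr(row, "sequence_id").strip()
        records.append(SpecimenRecord(
            voucher=row.voucher, species=row.species, genus=row.genus,
            higher_taxon=row.higher_taxon, location=row.location,
            sequence_id=None if sid in ("", "-") else sid,
        ))
    return records


def write_specimen_table(records: Sequence[SpecimenRecord],
                         path: str | Path) -> None:
    rows = [{
        "voucher": r.voucher, "species": r.species, "genus": r.genus,
        "higher_taxon": r.higher_taxon, "location": r.location,
        "sequence_id": r.sequence_id if r.sequence_id else "-",
    } for r in records]
    pd.DataFrame(rows, columns=SPECIMEN_COLUMNS).to_csv(
        path, sep="\t", index=False)


def records_by_sequence(records: Sequence[SpecimenRecord]
                        ) -> dict[str, SpecimenRecord]:
    out: dict[str, SpecimenRecord] = {}
    for r in records:
        if r.sequence_id is None:
            continue
        if r.sequence_id in out:
            raise ValidationError(
                f"sequence id {r.sequence_id!r} mapped by several specimens")
        out[r.sequence_id] = r
    return out


# ---------------------------------------------------------------------------
# Alignment container

class Alignment:
    """Equal-length rows of nucleotide or amino-acid characters."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]) -> None:
        if len(ids) != len(rows):
            raise ValidationError("ids and rows differ in number")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValidationError(
                f"alignment rows have unequal lengths {sorted(lengths)}")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]

    @classmethod
    def from_sequences(cls, seqs: SequenceSet) -> "Alignment":
        return cls([s.id for s in seqs], [s.residues for s in seqs])

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)


def consensus(aln: Alignment) -> str:
    """Column-majority consensus over unambiguous bases; 'N' where a column
    has no A/C/G/T, '-' where gaps dominate."""
    out = []
    for i in range(aln.length):
        col = aln.column(i)
        gaps = col.count("-")
        if gaps * 2 > len(col):
            out.append("-")
            continue
        counts = [(col.count(b), b) for b in "ACGT"]
        best = max(counts, key=lambda t: (t[0], -ord(t[1])))
        out.append(best[1] if best[0] > 0 else "N")
    return "".join(out)
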