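"""Degenerate-primer binding-site search and virtual PCR.

Primer/template matching uses IUPAC set-intersection semantics.  A
binding site tolerates up to ``max_mismatch`` mismatches over the primer
length but requires the 3 template bases facing the primer's 3' end to
match exactly — polymerase extension is far more sensitive to 3'-terminal
mispairing than to internal wobble, so the 3' anchor is the discriminating
rule.  Amplification enumerates forward/reverse site pairs, applies an
extension-length cap, and classifies the outcome the way a gel would be
read: expected band, expected plus aspecific bands, aspecific only, or no
product.

The primer registry ships the seven I3-M11 primers (JB series, anchored
to positions on the Drosophila yakuba COI sequence) and the universal
Folmer pair LCO1490/HCO2198.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .core_seq import (IUPAC_SETS, NucSequence, ValidationError,
                       reverse_complement)

# ---------------------------------------------------------------------------
# Primers

@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    orientation: Literal["forward", "reverse"]
    anchor_position: Optional[int] = None

    def __post_init__(self) -> None:
        seq = self.sequence.replace(" ", "").upper()
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValidationError(
                f"primer {self.name!r}: non-IUPAC character(s) {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(
                f"primer {self.name!r}: bad orientation {self.orientation!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        deg = 1
        for b in self.sequence:
            deg *= len(IUPAC_SETS[b])
        return deg


#: Registry of the published primers, keyed by name.
PRIMERS: dict[str, Primer] = {p.name: p for p in [
    Primer("JB3", "TTTTTTGGGCATCCTGAGGTTTAT", "forward", 2179),
    Primer("JB4.5", "TAAAGAAAGAACATAATGAAAATG", "reverse", 2597),
    Primer("JB5", "AGCACCTAAACTTAAAACATAATGAAAATG", "reverse", 2597),
    Primer("JB2", "ATGTTTTGATTTTACCWGCWTTYGGTGT", "forward", 2201),
    Primer("JB2s3", "ATGTTTTGATTTTACCWGSWTTTGG", "forward", 2201),
    Primer("JB5GED", "AGCACCTAAACTTAAAACATARTGRAARTG", "reverse", 2597),
    Primer("JB7GED", "ATCAGGATAATCCAAATAYTTWCGWGG", "reverse", 2780),
    Primer("LCO1490", "GGTCAACAAATCATAAAGATATTGG", "forward", 1490),
    Primer("HCO2198", "TAAACTTCAGGGTGACCAAAAAATCA", "reverse", 2198),
]}

#: Partition amplified by each registry primer.
PRIMER_PARTITION = {name: ("Folmer" if name.startswith(("LCO", "HCO"))
                           else "I3M11") for name in PRIMERS}

#: (min_len, expected_len, max_len) windows, primer-inclusive, derived
#: from the registry anchor positions.
I3M11_SIZE_WINDOW = (50, 448, 3000)    # JB3 (2179) .. JB5 end (2597+30)
FOLMER_SIZE_WINDOW = (50, 709, 3000)   # LCO1490 .. HCO2198 end


def read_primer_table(path) -> dict[str, Primer]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("name", "sequence", "orientation"):
        if col not in df.columns:
            raise ValidationError(f"primer table: missing column {col!r}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.name] = Primer(row.name, row.sequence, row.orientation)
    return out


# ---------------------------------------------------------------------------
# Matching

def iupac_match(primer_base: str, template_base: str) -> bool:
    """Symmetric set-intersection match between two IUPAC codes."""
    try:
        return bool(IUPAC_SETS[primer_base.upper()]
                    & IUPAC_SETS[template_base.upper()])
    except KeyError as exc:
        raise ValidationError(f"non-IUPAC character {exc}") from exc


def expand_degenerate(p: Primer) -> list[str]:
    """All concrete expansions, in lexicographic order."""
    choices = [sorted(IUPAC_SETS[b]) for b in p.sequence]
    return ["".join(t) for t in _iterproduct(*choices)]


_MASK = {b: sum(1 << "ACGT".index(x) for x in s)
         for b, s in IUPAC_SETS.items()}
_MASK["-"] = 0


def _mask_array(s: str) -> np.ndarray:
    try:
        return np.fromiter((_MASK[ch] for ch in s.upper()),
                           dtype=np.uint8, count=len(s))
    except KeyError as exc:
        raise ValidationError(f"non-IUPAC character {exc}") from exc


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    start: int          # template coordinates, half-open
    end: int
    strand: Literal["+", "-"]
    n_mismatches: int
    three_prime_clean: bool = True


def find_binding_sites(p: Primer, template: NucSequence,
                       max_mismatch: int = 2) -> list[BindingSite]:
    """All annealing positions with <= max_mismatch mismatches and an
    exact 3'-terminal triplet, sorted by template coordinate.

    Reverse primers are searched as their reverse complement on the plus
    strand; their 3' end then faces the *left* edge of the matched window.
    """
    if max_mismatch < 0:
        raise ValidationError("max_mismatch must be >= 0")
    search_seq = (p.sequence if p.orientation == "forward"
                  else reverse_complement(p.sequence))
    anchor_idx = (range(len(p) - 3, len(p)) if p.orientation == "forward"
                  else range(0, 3))
    L = len(search_seq)
    tmpl = template.residues
    n_win = len(tmpl) - L + 1
    if n_win <= 0:
        return []
    pmask = _mask_array(search_seq)
    tmask = _mask_array(tmpl)
    mism = np.zeros(n_win, dtype=np.int32)
    anchor_mism = np.zeros(n_win, dtype=np.int32)
    for j in range(L):
        no_match = (pmask[j] & tmask[j:j + n_win]) == 0
        mism += no_match
        if j in anchor_idx:
            anchor_mism += no_match
    hits = np.nonzero((mism <= max_mismatch) & (anchor_mism == 0))[0]
    strand = "+" if p.orientation == "forward" else "-"
    return [BindingSite(template_id=template.id, start=int(s),
                        end=int(s) + L, strand=strand,
                        n_mismatches=int(mism[s]))
            for s in hits]


# ---------------------------------------------------------------------------
# Virtual amplification

OUTCOME_CLASSES = ("expected_band", "expected_plus_aspecific",
                   "aspecific_only", "no_product")


@dataclass(frozen=True)
class PCROutcome:
    template_id: str
    outcome_class: str
    amplicon_lengths: tuple


def amplify(template: NucSequence, fwd: Primer, rev: Primer,
            max_mismatch: int = 2,
            size_window: tuple = I3M11_SIZE_WINDOW) -> PCROutcome:
    """Enumerate amplicons from every compatible forward/reverse site pair
    and classify the lane.

    ``size_window`` is (min_len, expected_len, max_len): products above
    max_len are suppressed (extension-limit proxy), below min_len ignored
    (unresolvable on gel); a product within +-10% of expected_len counts
    as the expected band, anything else as aspecific.
    """
    min_len, expected_len, max_len = size_window
    fsites = find_binding_sites(fwd, template, max_mismatch)
    rsites = find_binding_sites(rev, template, max_mismatch)
    lengths = []
    for f in fsites:
        for r in rsites:
            if f.start < r.end:
                length = r.end - f.start
                if min_len <= length <= max_len:
                    lengths.append(length)
    lengths.sort()
    tol = 0.10 * expected_len
    has_expected = any(abs(l - expected_len) <= tol for l in lengths)
    has_aspecific = any(abs(l - expected_len) > tol for l in lengths)
    if has_expected and has_aspecific:
        cls = "expected_plus_aspecific"
    elif has_expected:
        cls = "expected_band"
    elif has_aspecific:
        cls = "aspecific_only"
    else:
        cls = "no_product"
    return PCROutcome(template_id=template.id, outcome_class=cls,
                      amplicon_lengths=tuple(lengths))


def tally_success(outcomes: Sequence[PCROutcome]) -> dict:
    """Per-class counts and percentages (1 decimal) over species tested.

    ``success`` pools expected_band and expected_plus_aspecific — a lane
    with the right band is scored positive even with extra products.
    """
    if not outcomes:
        raise ValidationError("no PCR outcomes to tally")
    n = len(outcomes)
    counts = {c: sum(1 for o in outcomes if o.outcome_class == c)
              for c in OUTCOME_CLASSES}

    def cell(count: int) -> dict:
        return {"count": count, "pct": round(100.0 * count / n, 1)}

    return {
        "n": n,
        **{c: cell(counts[c]) for c in OUTCOME_CLASSES},
        "aspecific_any": cell(counts["expected_plus_aspecific"]
                              + counts["aspecific_only"]),
        "success": cell(counts["expected_band"]
                        + counts["expected_plus_aspecific"]),
    }


def write_outcomes(outcomes: Sequence[PCROutcome], path) -> None:
    rows = [{"template_id": o.template_id, "class": o.outcome_class,
             "amplicon_lengths": ",".join(map(str, o.amplicon_lengths))}
            for o in outcomes]
    pd.DataFrame(rows, columns=["template_id", "class",
                                "amplicon_lengths"]).to_csv(
        path, sep="\t", index=False)
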