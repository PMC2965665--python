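# nemabar — COI barcoding-gap analysis for free-living marine nematodes

Free-living marine nematodes are hard to identify morphologically, and the
usual rescue — DNA barcoding with the mitochondrial COI gene — is fragile in
this group: the universal Folmer (M1–M6) primers amplify poorly, and the
sequences one does obtain are riddled with pitfalls (bacterial contaminants
co-extracted with the worm, nuclear pseudogene copies of COI — *numts* —
carrying stop codons and frameshifts). `nemabar` implements the complete
analysis pipeline such a barcoding survey needs, as a tested Python library
plus a set of narrative analysis scripts:

- **in-silico PCR** with degenerate IUPAC primers (the taxon-specific
  JB-series primers for the I3-M11 partition of COI and the Folmer pair
  LCO1490/HCO2198 are built in), including 3′-anchor matching, amplicon
  enumeration and gel-style outcome tallies;
- **numt screening** by translation under the invertebrate mitochondrial
  genetic code (NCBI table 5: TGA→Trp, AGA/AGG→Ser, ATA→Met), frame
  selection, stop-codon and frameshift detection, and indel calls against
  the alignment majority;
- **K2P distances** with pairwise deletion, overall and per codon
  position: `d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)` with `P` and `Q` the observed
  transition and transversion proportions;
- **neighbor-joining trees** (Saitou–Nei, deterministic tie-breaking,
  Newick output) and tree-level QC flags for long-branch and taxonomically
  misplaced leaves;
- **barcoding-gap analysis**: intra- vs interspecific distance
  distributions, histograms, the classic 5 % threshold rule, conflicting
  species pairs, and a threshold scan;
- a **synthetic-data generator** that emulates the statistical structure of
  a real survey (AT-rich coding fragments, strong third-codon-position
  rate heterogeneity, hierarchical genus/species/specimen divergences,
  injected numts and GC-shifted contaminants with ground-truth labels), so
  every stage is testable without downloading anything.

## Worked example

The numbered scripts under `analysis/` run the whole survey on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1     # survey with ground truth
python analysis/02_insilico_pcr.py --seed 1 # virtual amplification panel
python analysis/03_qc.py                    # quality-control cascade
python analysis/04_distances.py             # K2P matrices + variability
python analysis/05_tree.py                  # NJ tree + tree flags
python analysis/06_barcode_gap.py           # gap metrics + threshold scan
```

With seed 1 this prints (abridged):

```
simulated 72 specimen sequences (10 numts, 4 contaminants)
  realized intra_range: (0.002551025941947755, 0.036709566560035)
  realized congeneric_range: (0.11736705259856976, 0.22213357125096328)
...
58/72 sequences pass QC
ground truth: 14/14 artifacts removed, 0 clean sequences lost
...
100.0% of 51 intraspecific pairs below 0.05
100.0% of 1602 interspecific pairs above 0.05
0 pairs exactly at the threshold
no species pairs conflict with the threshold
best threshold from scan: 0.037
```

Reading: the quality-control cascade removed every injected pseudogene and
contaminant while keeping all genuine sequences; among the survivors,
intraspecific K2P distances stay below the 5 % threshold and interspecific
ones above it, i.e. the data show a clean DNA barcoding gap, with the
scanned optimum just above the largest within-species distance.

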