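"""Neighbor-joining tree of the QC-passing sequences.

Builds the NJ tree from the K2P matrix, writes it as Newick, and reports
the tree-level QC flags (long terminal branches, taxonomic outliers).
"""
import argparse
from pathlib import Path

from nemabar.core_seq import Alignment, read_fasta, read_specimen_table
from nemabar.distance_k2p import distance_matrix
from nemabar.nj_tree import (flag_tree_outliers, nj, to_newick,
                             write_flag_report)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fasta", type=Path,
                    default=Path("results/sequences_passing_qc.fasta"))
    ap.add_argument("--specimens", type=Path,
                    default=Path("results/data/specimens.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    seqs = read_fasta(args.fasta)
    records = read_specimen_table(args.specimens)
    modal = max({len(s) for s in seqs},
                key=lambda L: sum(len(s) == L for s in seqs))
    seqs = seqs.subset([s.id for s in seqs if len(s) == modal])
    m = distance_matrix(Alignment.from_sequences(seqs), records)

    tree = nj(m)
    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "nj_tree.nwk").write_text(to_newick(tree) + "\n")
    flags = flag_tree_outliers(tree, records)
    write_flag_report(flags, args.outdir / "tree_flags.tsv")

    n_long = sum(f.long_branch for f in flags.values())
    n_out = sum(f.taxonomic_outlier for f in flags.values())
    print(f"NJ tree over {len(m)} leaves written to "
          f"{args.outdir}/nj_tree.nwk")
    print(f"{n_long} long-branch leaves, {n_out} taxonomic outliers")


if __name__ == "__main__":
    main()
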