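import numpy as np
import pytest

from nemabar.core_seq import ValidationError
from nemabar.distance_k2p import DistanceMatrix
from nemabar.nj_tree import (flag_tree_outliers, nj, to_newick)


def matrix_from_array(d, taxa, species=None, genus=None):
    n = len(taxa)
    d = np.asarray(d, dtype=float)
    species = species or [f"{t} sp" for t in taxa]
    genus = genus or list(taxa)
    return DistanceMatrix(taxa=list(taxa), d=d, species=species,
                          genus=genus, n_sites=np.full((n, n), 100),
                          P=np.zeros((n, n)), Q=np.zeros((n, n)))


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns (taxa,
    exact leaf-to-leaf path-distance matrix)."""
    import itertools
    nodes = {i: None for i in range(n_taxa)}
    edges = {}
    next_id = n_taxa
    active = list(range(n_taxa))
    parent = {}
    length = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        for child in (a, b):
            parent[child] = next_id
            length[child] = float(rng.uniform(0.05, 1.0))
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    # path distances via root paths
    def path_to_root(x):
        out = {}
        acc = 0.0
        while x in parent:
            out[x] = acc
            acc += length[x]
            x = parent[x]
        out[x] = acc
        return out
    D = np.zeros((n_taxa, n_taxa))
    paths = [path_to_root(i) for i in range(n_taxa)]
    anc = [set(p) for p in paths]
    for i, j in itertools.combinations(range(n_taxa), 2):
        common = anc[i] & anc[j]
        # lowest common ancestor = the common node with the smallest
        # distance-from-i among common ancestors
        lca = min(common, key=lambda x: paths[i][x] + paths[j][x])
        D[i, j] = D[j, i] = paths[i][lca] + paths[j][lca]
    return [f"t{i:02d}" for i in range(n_taxa)], D


def naive_nj(taxa, D):
    """Textbook O(n^3) neighbor joining with the same lexicographic
    tie-break; returns the leaf path-distance matrix of the result."""
    import itertools
    D = {(a, b): D[i][j] for i, a in enumerate(taxa)
         for j, b in enumerate(taxa)}
    nodes = list(taxa)
    children = {}
    key_of = {t: t for t in taxa}    # smallest leaf label beneath
    fresh = 0
    while len(nodes) > 3:
        k = len(nodes)
        r = {a: sum(D[(a, b)] for b in nodes if b != a) for a in nodes}
        best = None
        for a, b in itertools.combinations(sorted(nodes), 2):
            q = (k - 2) * D[(a, b)] - r[a] - r[b]
            key = (q, tuple(sorted((key_of[a], key_of[b]))))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        la = 0.5 * D[(a, b)] + (r[a] - r[b]) / (2 * (k - 2))
        lb = D[(a, b)] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la = max(la + lb, 0.0)
            lb = 0.0
        new = f"@{fresh}"
        fresh += 1
        key_of[new] = min(key_of[a], key_of[b])
        children[new] = [(a, la), (b, lb)]
        for c in nodes:
            if c in (a, b):
                continue
            D[(new, c)] = D[(c, new)] = 0.5 * (D[(a, c)] + D[(b, c)]
                                               - D[(a, b)])
        nodes = [c for c in nodes if c not in (a, b)] + [new]
    if len(nodes) == 3:
        a, b, c = nodes
        la = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
        lb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
        lc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
        root = "@root"
        children[root] = [(a, max(la, 0)), (b, max(lb, 0)),
                          (c, max(lc, 0))]
    else:
        a, b = nodes
        root = "@root"
        children[root] = [(a, D[(a, b)] / 2), (b, D[(a, b)] / 2)]

    # leaf path distances
    def leafdist(node):
        if node not in children:
            return {node: 0.0}
        merged = {}
        for child, ln in children[node]:
            sub = {k2: v + ln for k2, v in leafdist(child).items()}
            for x, dx in merged.items():
                for y, dy in sub.items():
                    pairs[(x, y)] = pairs[(y, x)] = dx + dy
            merged.update(sub)
        return merged

    pairs = {}
    leafdist(root)
    n = len(taxa)
    out = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                out[i, j] = pairs[(a, b)]
    return out


class TestNJ:
    def test_two_taxa_split_evenly(self):
        m = matrix_from_array([[0, 0.2], [0.2, 0]], ["A", "B"])
        t = nj(m)
        assert t.terminal_branch_lengths() == pytest.approx(
            {"A": 0.1, "B": 0.1})
        assert to_newick(t) == "(A:0.100000,B:0.100000);"

    def test_three_taxa_closed_form(self):
        m = matrix_from_array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                              ["A", "B", "C"])
        t = nj(m)
        assert t.terminal_branch_lengths() == pytest.approx(
            {"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxa_additive_example(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        m = matrix_from_array(d, ["A", "B", "C", "D"])
        t = nj(m)
        paths = t.leaf_distances()
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                assert paths.loc[a, b] == pytest.approx(d[i][j], abs=1e-9)
        term = t.terminal_branch_lengths()
        assert term == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_recovers_random_additive_trees(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 13))
            taxa, D = random_additive_tree(rng, n)
            t = nj(matrix_from_array(D, taxa))
            paths = t.leaf_distances().loc[taxa, taxa].to_numpy()
            np.testing.assert_allclose(paths, D, atol=1e-9)

    def test_agrees_with_naive_reference(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 11))
            D = rng.uniform(0.05, 1.0, size=(n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            taxa = [f"t{i:02d}" for i in range(n)]
            mine = nj(matrix_from_array(D, taxa)).leaf_distances()
            ref = naive_nj(taxa, D)
            np.testing.assert_allclose(mine.loc[taxa, taxa].to_numpy(),
                                       ref, atol=1e-9)

    def test_invariant_under_taxon_reordering(self, rng):
        n = 8
        taxa, D = random_additive_tree(rng, n)
        perm = rng.permutation(n)
        t1 = nj(matrix_from_array(D, taxa))
        t2 = nj(matrix_from_array(D[np.ix_(perm, perm)],
                                  [taxa[i] for i in perm]))
        p1 = t1.leaf_distances().loc[taxa, taxa].to_numpy()
        p2 = t2.leaf_distances().loc[taxa, taxa].to_numpy()
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_missing_entries_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        m = matrix_from_array(d, ["A", "B"])
        with pytest.raises(ValidationError, match="missing"):
            nj(m)

    def test_agrees_with_skbio(self, rng):
        """Independent-library cross-check on a generic random matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        n = 7
        taxa, D = random_additive_tree(rng, n)
        mine = nj(matrix_from_array(D, taxa)).leaf_distances()
        sk = skbio_nj(SkbioDM(D, ids=taxa))
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                assert mine.loc[a, b] == pytest.approx(
                    sk.find(a).distance(sk.find(b)), abs=1e-6)


class TestNewick:
    def test_roundtrip_via_dendropy(self, rng):
        import dendropy
        taxa, D = random_additive_tree(rng, 6)
        t = nj(matrix_from_array(D, taxa))
        newick = to_newick(t)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        tax = {x.label: x for x in parsed.taxon_namespace}
        mine = t.leaf_distances()
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                assert pdm.distance(tax[a], tax[b]) == pytest.approx(
                    mine.loc[a, b], abs=1e-5)

    def test_labels_with_spaces_are_quoted(self):
        m = matrix_from_array([[0, 0.2], [0.2, 0]], ["Onyx sp 1", "B"])
        assert "'Onyx sp 1'" in to_newick(nj(m))


class TestTreeOutlierFlags:
    def test_star_tree_has_no_flags(self, make_records):
        d = np.full((5, 5), 0.2)
        np.fill_diagonal(d, 0)
        taxa = list("abcde")
        m = matrix_from_array(d, taxa)
        t = nj(m)
        recs = make_records({x: f"Genus{x} sp" for x in taxa})
        flags = flag_tree_outliers(t, recs)
        assert not any(f.long_branch or f.taxonomic_outlier
                       for f in flags.values())

    def test_long_branch_from_other_order_gets_both_flags(
            self, make_records):
        # d, e form a close pair; x sits far from everything
        taxa = ["a", "b", "c", "d", "x"]
        d = np.array([
            [0.00, 0.02, 0.10, 0.10, 1.00],
            [0.02, 0.00, 0.10, 0.10, 1.00],
            [0.10, 0.10, 0.00, 0.02, 1.00],
            [0.10, 0.10, 0.02, 0.00, 1.00],
            [1.00, 1.00, 1.00, 1.00, 0.00],
        ])
        m = matrix_from_array(d, taxa)
        t = nj(m)
        recs = make_records(
            {x: f"Genus{x} sp" for x in taxa},
            {x: ("Chromadorida" if x == "x" else "Enoplida")
             for x in taxa})
        flags = flag_tree_outliers(t, recs)
        assert flags["x"].long_branch and flags["x"].taxonomic_outlier
        assert not any(f.long_branch for l, f in flags.items() if l != "x")

    def test_contaminant_leaf_flagged_long_branch(self, make_records):
        """Generator property: an injected GC-shifted contaminant sits on
        a conspicuously long terminal branch in the NJ tree."""
        from nemabar import SimConfig, make_dataset
        from nemabar.distance_k2p import distance_matrix
        hits = 0
        trials = 0
        for seed in range(40, 90):
            ds = make_dataset(SimConfig(seed=seed))
            contams = [r.sequence_id for r in ds.records
                       if r.truth.is_contaminant]
            if not contams:
                continue
            trials += 1
            ids = ds.clean_ids() + contams[:1]
            recs = [r for r in ds.records if r.sequence_id in set(ids)]
            m = distance_matrix(ds.sequences.subset(ids), recs)
            if not m.is_complete():
                continue
            flags = flag_tree_outliers(nj(m), recs)
            hits += flags[contams[0]].long_branch
            if trials >= 20:
                break
        assert trials >= 20 and hits == trials
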