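import numpy as np
import pytest

from nemabar.core_seq import NucSequence, ValidationError, reverse_complement
from nemabar.insilico_pcr import (PRIMERS, PCROutcome, Primer, amplify,
                                  expand_degenerate, find_binding_sites,
                                  iupac_match, tally_success)


class TestIupacMatch:
    @pytest.mark.parametrize("a,b,expected", [
        ("W", "A", True), ("W", "G", False),
        ("N", "A", True), ("N", "Y", True),
        ("S", "W", False),            # {G,C} and {A,T} are disjoint
        ("R", "Y", False), ("A", "A", True),
    ])
    def test_examples(self, a, b, expected):
        assert iupac_match(a, b) is expected
        assert iupac_match(b, a) is expected    # symmetric

    def test_non_iupac_is_error(self):
        with pytest.raises(ValidationError):
            iupac_match("A", "!")


class TestExpandDegenerate:
    def test_concrete_primer_is_itself(self):
        assert expand_degenerate(Primer("p", "ACG", "forward")) == ["ACG"]

    def test_jb2_expands_to_8(self):
        exp = expand_degenerate(PRIMERS["JB2"])
        assert len(exp) == 8 == PRIMERS["JB2"].degeneracy
        assert len(set(exp)) == 8
        assert exp == sorted(exp)                 # lexicographic
        assert all(set(e) <= set("ACGT") for e in exp)

    def test_nn_expands_to_16(self):
        assert len(expand_degenerate(Primer("p", "NN", "forward"))) == 16

    @pytest.mark.parametrize("name,deg", [
        ("JB3", 1), ("JB5", 1), ("JB2s3", 8), ("JB5GED", 8), ("JB7GED", 8),
    ])
    def test_registry_degeneracies(self, name, deg):
        assert PRIMERS[name].degeneracy == deg


def _embed(template_parts):
    return NucSequence("tmpl", "".join(template_parts))


def _rand(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestFindBindingSites:
    def test_exact_forward_site(self, rng):
        jb3 = PRIMERS["JB3"]
        tmpl = _embed([_rand(rng, 50), jb3.sequence, _rand(rng, 50)])
        (site,) = find_binding_sites(jb3, tmpl)
        assert (site.start, site.end, site.n_mismatches) == (50, 74, 0)
        assert site.strand == "+"

    def test_three_prime_terminal_mismatch_kills_site(self, rng):
        jb3 = PRIMERS["JB3"]
        broken = jb3.sequence[:-1] + ("A" if jb3.sequence[-1] != "A"
                                      else "C")
        tmpl = _embed([_rand(rng, 50), broken, _rand(rng, 50)])
        assert find_binding_sites(jb3, tmpl) == []

    def test_internal_mismatches_tolerated(self, rng):
        jb3 = PRIMERS["JB3"]
        seq = list(jb3.sequence)
        seq[5] = "A" if seq[5] != "A" else "C"
        seq[10] = "A" if seq[10] != "A" else "C"
        tmpl = _embed([_rand(rng, 20), "".join(seq), _rand(rng, 20)])
        (site,) = find_binding_sites(jb3, tmpl, max_mismatch=2)
        assert site.n_mismatches == 2
        assert find_binding_sites(jb3, tmpl, max_mismatch=1) == []

    def test_two_sites_in_coordinate_order(self, rng):
        jb3 = PRIMERS["JB3"]
        tmpl = _embed([_rand(rng, 10), jb3.sequence, _rand(rng, 30),
                       jb3.sequence, _rand(rng, 10)])
        sites = find_binding_sites(jb3, tmpl)
        assert [s.start for s in sites] == [10, 64]

    def test_reverse_primer_found_as_revcomp(self, rng):
        jb5 = PRIMERS["JB5"]
        tmpl = _embed([_rand(rng, 40), reverse_complement(jb5.sequence),
                       _rand(rng, 40)])
        (site,) = find_binding_sites(jb5, tmpl)
        assert (site.start, site.strand) == (40, "-")

    def test_template_shorter_than_primer(self):
        assert find_binding_sites(PRIMERS["JB3"],
                                  NucSequence("t", "ACGT")) == []

    def test_matches_expand_and_match_oracle(self, rng):
        """Degenerate-primer site search equals exhaustive expansion +
        per-expansion mismatch counting (degeneracy <= 16, <= 2 kb)."""
        for name in ("JB2", "JB2s3", "JB5GED", "JB7GED"):
            p = PRIMERS[name]
            assert p.degeneracy <= 16
            anchor = (range(len(p) - 3, len(p))
                      if p.orientation == "forward" else range(3))
            expansions = [
                e if p.orientation == "forward" else reverse_complement(e)
                for e in expand_degenerate(p)]
            tmpl = _rand(rng, 1500)
            # plant a mutated concrete copy to guarantee near-hits
            copy = list(expansions[0])
            copy[4] = "A" if copy[4] != "A" else "C"
            tmpl = tmpl[:700] + "".join(copy) + tmpl[700:]
            template = NucSequence("t", tmpl)
            got = {s.start for s in find_binding_sites(p, template,
                                                       max_mismatch=2)}
            expected = set()
            for pos in range(len(tmpl) - len(p) + 1):
                window = tmpl[pos:pos + len(p)]
                best = min(sum(a != b for a, b in zip(e, window))
                           for e in expansions)
                anchor_ok = any(
                    all(e[k] == window[k] for k in anchor)
                    for e in expansions)
                if best <= 2 and anchor_ok:
                    expected.add(pos)
            assert got == expected


class TestAmplify:
    def _build(self, rng, insert_len=400):
        fwd, rev = PRIMERS["JB3"], PRIMERS["JB5"]
        insert = _rand(rng, insert_len)
        tmpl = _embed([_rand(rng, 30), fwd.sequence, insert,
                       reverse_complement(rev.sequence), _rand(rng, 30)])
        expected_len = len(fwd) + insert_len + len(rev)
        return tmpl, fwd, rev, expected_len

    def test_expected_band(self, rng):
        tmpl, fwd, rev, exp = self._build(rng)
        out = amplify(tmpl, fwd, rev, size_window=(50, exp, 3000))
        assert out.outcome_class == "expected_band"
        assert out.amplicon_lengths == (exp,)

    def test_no_reverse_site_means_no_product(self, rng):
        fwd = PRIMERS["JB3"]
        tmpl = _embed([_rand(rng, 30), fwd.sequence, _rand(rng, 400)])
        out = amplify(tmpl, fwd, PRIMERS["JB5"])
        assert out.outcome_class == "no_product"

    def test_spurious_product_classifies_expected_plus_aspecific(self, rng):
        fwd, rev = PRIMERS["JB3"], PRIMERS["JB5"]
        # an extra reverse site close to the forward primer gives a
        # short spurious product next to the expected one
        tmpl = _embed([
            _rand(rng, 30), fwd.sequence, _rand(rng, 100),
            reverse_complement(rev.sequence), _rand(rng, 250),
            reverse_complement(rev.sequence), _rand(rng, 30)])
        exp = len(fwd) + 100 + len(rev) + 250 + len(rev)
        out = amplify(tmpl, fwd, rev, size_window=(50, exp, 3000))
        assert out.outcome_class == "expected_plus_aspecific"
        assert len(out.amplicon_lengths) == 2

    def test_strand_consistency(self, rng):
        """Reverse-complementing the template and swapping primer roles
        yields the same amplicon lengths."""
        tmpl, fwd, rev, exp = self._build(rng)
        out_fwd = amplify(tmpl, fwd, rev, size_window=(50, exp, 3000))
        flipped = NucSequence("t2", reverse_complement(tmpl.residues))
        fwd_as_rev = Primer(fwd.name, fwd.sequence, "reverse")
        rev_as_fwd = Primer(rev.name, rev.sequence, "forward")
        out_rev = amplify(flipped, rev_as_fwd, fwd_as_rev,
                          size_window=(50, exp, 3000))
        assert out_rev.amplicon_lengths == out_fwd.amplicon_lengths


class TestTallySuccess:
    def _outcomes(self, spec):
        out = []
        for cls, count in spec.items():
            out += [PCROutcome(f"{cls}{i}", cls, ()) for i in range(count)]
        return out

    def test_three_of_41_no_product_is_7_3_pct(self):
        t = tally_success(self._outcomes(
            {"no_product": 3, "expected_band": 38}))
        assert t["no_product"] == {"count": 3, "pct": 7.3}

    def test_thirteen_of_41_no_product_is_31_7_pct(self):
        t = tally_success(self._outcomes(
            {"no_product": 13, "expected_band": 28}))
        assert t["no_product"]["pct"] == 31.7

    def test_all_expected(self):
        t = tally_success(self._outcomes({"expected_band": 10}))
        assert t["success"] == {"count": 10, "pct": 100.0}
        assert t["no_product"]["pct"] == 0.0

    def test_percentages_recompute_from_counts(self):
        t = tally_success(self._outcomes(
            {"no_product": 3, "aspecific_only": 2,
             "expected_plus_aspecific": 5, "expected_band": 31}))
        assert t["success"]["count"] == 36
        assert t["success"]["pct"] == round(100 * 36 / 41, 1) == 87.8
        assert t["aspecific_any"]["count"] == 7

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError):
            tally_success([])
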