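"""Guide enumeration, truncation, 5'-G policies and cloning oligos."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

import truncguide as tg
from truncguide.guide_designer import (
    SGRNA_FWD_PRIMER,
    SGRNA_REV_PRIMER,
    SGRNA_TEMPLATE_LEFT,
    SGRNA_TEMPLATE_RIGHT,
)

from conftest import ON_TARGET_PAIRS


def brute_force_pams(seq, strands=("+", "-")):
    """Independent exhaustive NGG scan over every 3-mer of both strands."""
    seq = seq.upper()
    out = set()
    for p in range(len(seq) - 2):
        tri = seq[p : p + 3]
        if "+" in strands and tri[1:] == "GG":
            out.add((p, "+"))
        if "-" in strands and reverse_complement(tri)[1:] == "GG":
            out.add((p, "-"))
    return out


class TestFindPamSites:
    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), 200))
            got = {(p, s) for p, s in tg.find_pam_sites(seq)}
            assert got == brute_force_pams(seq)

    def test_printed_on_target_site(self):
        seq = "GCCGTCCAGCTCGACCAGGATGG"
        # only the terminal TGG leaves room for a 20 nt protospacer
        assert [tuple(p) for p in tg.find_pam_sites(seq, "+", min_flank=20)] == [(20, "+")]
        # the unfiltered scan also sees the internal AGG
        assert {p.pos for p in tg.find_pam_sites(seq, "+")} == {16, 20}

    def test_no_gg_dinucleotide(self):
        assert tg.find_pam_sites("AAAATTTT") == []

    def test_n_never_matches_and_bad_chars_rejected(self):
        assert tg.find_pam_sites("AANGAANG") == []
        with pytest.raises(ValueError, match="outside"):
            tg.find_pam_sites("ACGTX")


class TestDesignGuides:
    @pytest.mark.parametrize("name,spacer20,spacer17,pam", ON_TARGET_PAIRS)
    def test_reproduces_printed_spacers(self, name, spacer20, spacer17, pam):
        seq = spacer20 + pam
        (g20,) = tg.design_guides(seq, 20, "require_matched_G", strands="+")
        assert (g20.spacer, g20.pam) == (spacer20, pam)
        # select the candidate at the printed PAM (internal NGGs may add more)
        (g17,) = [
            g for g in tg.design_guides(seq, 17, "require_matched_G", strands="+")
            if g.start == 3
        ]
        assert (g17.spacer, g17.pam) == (spacer17, pam)

    def test_prepend_g_tags_non_g_protospacer(self):
        # 17 nt protospacer with a 5' A gets a mismatched lowercase g tag
        proto = "ATCCAGCTCGACCAGGA"
        seq = "TTT" + proto + "TGGAAA"
        (g,) = tg.design_guides(seq, 17, "prepend_g", strands="+")
        assert g.five_prime_tagged and g.spacer == "g" + proto
        assert g.total_len == 18 and g.matched_len == 17
        assert g.effective_flag

    def test_require_matched_g_filters(self):
        seq = "TTTATCCAGCTCGACCAGGATGGAAA"
        assert tg.design_guides(seq, 17, "require_matched_G", strands="+") == []

    def test_effectiveness_rule_sweep(self):
        # untagged: active from 17 nt matched; g-tagged: from 18 nt total
        # (protospacer crafted free of internal NGG so the site is unique)
        seq = "TTTTTTTGTCACAGTCGACTACGATGGAAA"
        for L in range(16, 21):
            (g,) = tg.design_guides(seq, L, "any", strands="+")
            assert g.effective_flag == (L >= 17)
        tagged_seq = "TTTTTTTATCACAGTCGACTACGATGGAAA"
        for L in (16, 17):
            (g,) = tg.design_guides(tagged_seq, L, "prepend_g", strands="+")
            assert g.five_prime_tagged and g.total_len == L + 1
            assert g.effective_flag == (g.total_len >= 18)

    def test_three_prime_preference_annotation(self):
        (g,) = tg.design_guides("GTCCAGCTCGACCAGGATGG", 17, "any", strands="+")
        assert g.three_prime_pref  # ends in A
        (g2,) = tg.design_guides("GTCCAGCTCGACCAGGTTGG", 17, "any", strands="+")
        assert not g2.three_prime_pref

    def test_reverse_strand_spacer_is_guide_oriented(self):
        seq = "GCCGTCCAGCTCGACCAGGATGG"
        rc = reverse_complement(seq)
        fwd = tg.design_guides(seq, 20, "any", strands="+")
        rev = tg.design_guides(rc, 20, "any", strands="-")
        assert [g.spacer for g in fwd] == [g.spacer for g in rev]
        assert all(g.strand == "-" for g in rev)
        # coordinates mirror: start_fwd = len(seq) - end_rev
        for f, r in zip(fwd, rev):
            assert f.start == len(seq) - (r.start + r.matched_len)

    def test_design_then_truncate_equals_direct_design(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 300))
        full = tg.design_guides(seq, 20, "any")
        direct = {(g.start, g.strand): g for g in tg.design_guides(seq, 17, "any")}
        for g in full:
            t = tg.truncate_guide(g, 17)
            d = direct[(t.start, t.strand)]
            assert t.spacer == d.spacer and t.pam == d.pam

    def test_completeness_vs_bruteforce_count(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 200))
            n_designable = 0
            for p, s in brute_force_pams(seq):
                flank = p if s == "+" else len(seq) - (p + 3)
                n_designable += flank >= 20
            assert len(tg.design_guides(seq, 20, "any")) == n_designable

    def test_n_sites_skipped_with_warning(self):
        seq = "TTTGTCCNGCTCGACCAGGATGGAAA"
        with pytest.warns(UserWarning, match="overlaps N"):
            assert tg.design_guides(seq, 17, "any", strands="+") == []

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            tg.design_guides("ACGT" * 10, 21, "any")
        with pytest.raises(ValueError):
            tg.design_guides("", 17, "any")
        with pytest.raises(ValueError):
            tg.design_guides("ACGT" * 10, 17, "bogus")


class TestTruncateGuide:
    @pytest.mark.parametrize("name,spacer20,spacer17,pam", ON_TARGET_PAIRS)
    def test_reproduces_all_printed_17nt_pairs(self, name, spacer20, spacer17, pam):
        (g20,) = tg.design_guides(spacer20 + pam, 20, "any", strands="+")
        assert tg.truncate_guide(g20, 17).spacer == spacer17

    def test_truncate_to_own_length_is_identity(self):
        (g,) = tg.design_guides("GACGTAGCCTTCGGGCATGGCGG", 20, "any", strands="+")
        assert tg.truncate_guide(g, 20) is g

    def test_cut_site_preserved(self):
        (g,) = tg.design_guides("GACGTAGCCTTCGGGCATGGCGG", 20, "any", strands="+")
        assert tg.truncate_guide(g, 17).cut_site == g.cut_site

    def test_truncate_errors(self):
        (g,) = tg.design_guides("GTAGCCTTCGGGCATGGCGG", 17, "any", strands="+")
        with pytest.raises(ValueError):
            tg.truncate_guide(g, 18)
        with pytest.raises(ValueError):
            tg.truncate_guide(g, 15)
        (tagged,) = tg.design_guides("TTTATCCAGCTCGACCAGGATGGAAA", 17, "prepend_g", strands="+")
        with pytest.raises(ValueError, match="tagged"):
            tg.truncate_guide(tagged, 16)


class TestCloningOligos:
    def test_seventeen_nt_spacer_example(self):
        (g,) = tg.design_guides("GTCCAGCTCGACCAGGATGG", 17, "any", strands="+")
        oligos = tg.build_cloning_oligos(g)
        assert oligos.insert == "TCCAGCTCGACCAGGA" and len(oligos.insert) == 16
        assert len(oligos.template) == 30 + 16 + 30
        assert oligos.template == SGRNA_TEMPLATE_LEFT + oligos.insert + SGRNA_TEMPLATE_RIGHT

    def test_scaffold_strings_exact(self):
        assert SGRNA_TEMPLATE_LEFT == "TATATATCTTGTGGAAAGGACGAAACACCG"
        assert SGRNA_TEMPLATE_RIGHT == "GTTTTAGAGCTAGAAATAGCAAGTTAAAAT"
        assert SGRNA_FWD_PRIMER == "TATATATCTTGTGGAAAGGACGAA"
        assert SGRNA_REV_PRIMER == "ATTTTAACTTGCTATTTCTAGCTCTAA"

    def test_twenty_nt_spacer_gives_19_nt_insert(self):
        (g,) = tg.design_guides("GCCGTCCAGCTCGACCAGGATGG", 20, "any", strands="+")
        assert len(tg.build_cloning_oligos(g).insert) == 19

    def test_tagged_spacer_accepted(self):
        (g,) = tg.design_guides("TTTATCCAGCTCGACCAGGATGGAAA", 17, "prepend_g", strands="+")
        assert tg.build_cloning_oligos(g).insert == g.spacer[1:].upper()

    def test_non_g_spacer_refused(self):
        (g,) = tg.design_guides("TTTATCCAGCTCGACCAGGATGGAAA", 17, "any", strands="+")
        with pytest.raises(ValueError, match="prepend_g"):
            tg.build_cloning_oligos(g)
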