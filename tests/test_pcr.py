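"""Degenerate-primer matching, amplification, and the splicing verdict."""

import itertools

import numpy as np
import pytest

from oysterlsu.formats import reverse_complement
from oysterlsu.pcr import (
    Primer,
    amplify,
    build_cdna,
    find_sites,
    iupac_match,
    load_primer_table,
    splicing_test,
    splicing_verdict_from_evidence,
)
from oysterlsu.pipeline import run_splice_fixture, splice_fixture


def random_template(rng, n=1000):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestIupacMatch:
    def test_w_matches_a_and_t(self):
        assert iupac_match("W", "A", 0) == (True, 0)
        assert iupac_match("W", "T", 0) == (True, 0)

    def test_w_rejects_g(self):
        assert iupac_match("W", "G", 0) == (False, 1)

    def test_degenerate_primer_realization(self):
        primer = "CTTTWGCAKMATGGCYTTWTGAG"
        template = primer.replace("W", "T", 1)
        template = template.replace("K", "G").replace("M", "A")
        template = template.replace("Y", "C").replace("W", "T")
        ok, mm = iupac_match(primer, template, 0)
        assert ok and mm == 0

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            iupac_match("X", "A", 0)


class TestFindSites:
    def test_planted_forward_site(self):
        rng = np.random.default_rng(0)
        t = random_template(rng)
        primer = Primer("p", "GACGTTACAGGTCCAGT", "forward")
        t = t[:41] + primer.sequence + t[41 + len(primer):]
        sites = [s for s in find_sites(t, primer) if s.mismatches == 0]
        assert any(s.position == 42 and s.strand == "+" for s in sites)

    def test_origin_spanning_site_on_circle(self):
        rng = np.random.default_rng(1)
        t = random_template(rng, 200)
        primer = Primer("p", "GACGTTACAGGTCCAGT", "forward")
        # plant across the origin: last 10 bases + first 7
        t = t[: 200 - 10] + primer.sequence[:10]
        t = primer.sequence[10:] + t[7:]
        sites = find_sites(t, primer, circular=True)
        assert any(s.position == 191 and s.mismatches == 0 for s in sites)
        assert not find_sites(t, primer, circular=False)

    def test_reverse_primer_found_as_revcomp(self):
        rng = np.random.default_rng(2)
        t = random_template(rng)
        rev = Primer("r", "GACGTTACAGGTCCAGT", "reverse")
        t = t[:99] + reverse_complement(rev.sequence) + t[99 + len(rev):]
        sites = [s for s in find_sites(t, rev) if s.mismatches == 0]
        assert any(s.position == 100 and s.strand == "-" for s in sites)

    def test_absent_primer_empty(self):
        assert find_sites("A" * 500, Primer("p", "GCGCGCGCGC", "forward")) == []

    def test_three_prime_mismatch_disqualifies(self):
        t = "A" * 50 + "GACGTTACAGGTCCAGT" + "A" * 50
        primer = Primer("p", "GACGTTACAGGTCCAGA", "forward")  # 3' terminal A
        assert all(s.position != 51 for s in find_sites(t, primer))
        # same mismatch count away from the 3' end is tolerated
        primer2 = Primer("p2", "AACGTTACAGGTCCAGT", "forward")
        assert any(s.position == 51 and s.mismatches == 1
                   for s in find_sites(t, primer2))


class TestAmplify:
    def test_planted_pair_product_length(self):
        rng = np.random.default_rng(3)
        t = random_template(rng, 1000)
        fwd = Primer("f", "GACGTTACAGGTCCAGT", "forward")
        rev_bind = "CAGGACTTACCGGATCA"  # + strand footprint of the reverse primer
        rev = Primer("r", reverse_complement(rev_bind), "reverse")
        # outer coordinates 101..200: product length 100
        t = t[:100] + fwd.sequence + t[117:183] + rev_bind + t[200:]
        products = amplify(t, fwd, rev)
        assert any(a.length == 100 for a in products)

    def test_derived_wrap_count(self):
        # fwd footprint starting at 91, rev footprint ending at 15 on a
        # 100-nt circle: positions 91..100 plus 1..15 = 25 nt
        rng = np.random.default_rng(5)
        t = random_template(rng, 100)
        fwd = Primer("f", "GACGTTACAGGTC" [:10], "forward")
        rev_bind = "CAGGACTTAC"
        rev = Primer("r", reverse_complement(rev_bind), "reverse")
        t = t[:90] + fwd.sequence + t[:0]  # fwd at 91..100
        t = t[:5] + rev_bind + t[15:]      # rev footprint at 6..15
        products = amplify(t, fwd, rev, circular=True)
        assert any(a.length == 25 for a in products)

    def test_no_product_beyond_max_len(self):
        rng = np.random.default_rng(6)
        t = random_template(rng, 9000)
        fwd = Primer("f", "GACGTTACAGGTCCAGT", "forward")
        rev_bind = "CAGGACTTACCGGATCA"
        rev = Primer("r", reverse_complement(rev_bind), "reverse")
        t = t[:100] + fwd.sequence + t[117:8000] + rev_bind + t[8017:]
        assert amplify(t, fwd, rev, max_len=5000) == []

    def test_rotation_invariance_on_circle(self):
        fx = splice_fixture(seed=0)
        genome = fx["genome"]
        fwd, rev = fx["primer_sets"]["internal_5"]
        reference = sorted(a.length for a in
                           amplify(genome.sequence, fwd, rev, circular=True))
        rng = np.random.default_rng(7)
        for _ in range(10):
            cut = int(rng.integers(1, len(genome)))
            rotated = genome.sequence[cut:] + genome.sequence[:cut]
            lengths = sorted(a.length for a in
                             amplify(rotated, fwd, rev, circular=True))
            assert lengths == reference


class TestBuildCdna:
    def test_rna_to_dna_with_tail(self):
        assert build_cdna([("t", "ACGU" + "AAAA")]) == [("t", "ACGTAAAA")]

    def test_templates_stay_separate(self):
        out = build_cdna([("five", "ACGU"), ("three", "GGCC")])
        assert len(out) == 2

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            build_cdna([])


class TestSplicingVerdict:
    def truth(self, i5, i3, span_c, span_g):
        if span_c:
            return "spliced_or_contiguous"
        if i5 and i3 and not span_g:
            return "not_spliced"
        return "inconclusive"

    def test_all_sixteen_evidence_combinations(self):
        for i5, i3, span_c, span_g in itertools.product([False, True], repeat=4):
            evidence = {
                "internal5_cdna": i5,
                "internal3_cdna": i3,
                "spanning_cdna": span_c,
                "spanning_genomic": span_g,
            }
            assert splicing_verdict_from_evidence(evidence) == self.truth(
                i5, i3, span_c, span_g
            )

    def test_fragmented_fixture_not_spliced(self):
        verdicts = run_splice_fixture(seed=0)
        assert verdicts["fragmented"].value == "not_spliced"

    def test_contiguous_control_detected(self):
        verdicts = run_splice_fixture(seed=0)
        v = verdicts["contiguous"]
        assert v.value == "spliced_or_contiguous"
        assert v.evidence["spanning_genomic"] and v.evidence["spanning_cdna"]

    def test_spliced_transcript_on_fragmented_genome(self):
        # if the two fragment transcripts were ligated, the spanning product
        # appears in cDNA but not genomic DNA
        fx = splice_fixture(seed=0)
        verdict = splicing_test(
            (fx["genome"].accession, fx["genome"].sequence),
            build_cdna([fx["spliced_transcript"]]) +
            build_cdna(fx["transcripts"]),
            fx["primer_sets"],
        )
        assert verdict.value == "spliced_or_contiguous"

    def test_missing_primer_set_rejected(self):
        fx = splice_fixture(seed=0)
        with pytest.raises(ValueError, match="spanning"):
            splicing_test(
                (fx["genome"].accession, fx["genome"].sequence),
                build_cdna(fx["transcripts"]),
                {"internal_5": fx["primer_sets"]["internal_5"],
                 "internal_3": fx["primer_sets"]["internal_3"]},
            )


class TestPrimerTable:
    def test_shipped_primers(self):
        rows = {r["name"]: r for r in load_primer_table()}
        assert rows["mt168-F"]["sequence"] == "GGATTCTGTTTGTCCGCAGCATT"
        assert rows["dCv-Ai-LSU-f"]["sequence"] == "CTTTWGCAKMATGGCYTTWTGAG"
        assert rows["dCv-Ai-LSU-r"]["sequence"] == "CACGGGGTCTTCTTGTCTWWCTTT"
        assert len(rows) == 6
        for r in rows.values():
            Primer(r["name"], r["sequence"], r["role"])  # all valid IUPAC
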