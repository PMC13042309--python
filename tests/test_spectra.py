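"""SNV classes, ts/tv, AT bias, context, consequence and indel lengths."""

from itertools import permutations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from malines.filtering import CandidateMutation
from malines.io import GeneAnnotation, GeneModel, GenomeRef
from malines.spectra import (
    SNV_CLASSES,
    at_bias,
    class_alt_base,
    classify_consequence,
    compatible_classes,
    indel_lengths,
    is_transition,
    snv_class,
    spectrum_table,
    triplet_context,
    ts_tv,
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def snv(ref, alt, pos=5, line="L1", contig="c1"):
    return CandidateMutation(line, contig, pos, "SNV", ref, alt)


class TestSnvClass:
    def test_named_examples(self):
        assert snv_class("A", "G") == "A:T>G:C" and is_transition("A", "G")
        assert snv_class("C", "A") == "G:C>T:A" and not is_transition("C", "A")

    def test_twelve_ordered_pairs_map_two_per_class(self):
        hits = {}
        for ref, alt in permutations("ACGT", 2):
            hits.setdefault(snv_class(ref, alt), []).append((ref, alt))
        assert set(hits) == set(SNV_CLASSES)
        assert all(len(v) == 2 for v in hits.values())

    @given(st.sampled_from([(r, a) for r, a in permutations("ACGT", 2)]))
    def test_strand_collapse_involution(self, pair):
        ref, alt = pair
        assert snv_class(ref, alt) == snv_class(_COMP[ref], _COMP[alt])

    def test_identity_substitution_rejected(self):
        with pytest.raises(ValueError):
            snv_class("A", "A")

    def test_class_alt_base_inverts_classification(self):
        for klass in SNV_CLASSES:
            for ref in compatible_classes(klass):
                alt = class_alt_base(klass, ref)
                assert snv_class(ref, alt) == klass


class TestTsTv:
    def test_balanced_counts(self):
        cands = [snv("A", "G"), snv("C", "T"), snv("A", "T"), snv("C", "A")]
        assert ts_tv(cands) == pytest.approx(1.0)

    def test_no_transitions(self):
        assert ts_tv([snv("A", "T"), snv("A", "C")]) == 0.0

    def test_no_transversions_undefined(self):
        assert ts_tv([snv("A", "G")]) is None

    def test_random_set_matches_bruteforce_recount(self):
        import numpy as np

        rng = np.random.default_rng(2)
        pairs = [(r, a) for r, a in permutations("ACGT", 2)]
        cands = [snv(*pairs[i]) for i in rng.integers(0, 12, size=100)]
        ts = sum(1 for c in cands if {c.ref, c.alt} in ({"A", "G"}, {"C", "T"}))
        tv = len(cands) - ts
        assert ts_tv(cands) == pytest.approx(ts / tv)


class TestAtBias:
    def test_symmetric_counts_on_balanced_genome(self):
        genome = GenomeRef({"c1": "ACGT" * 10})
        spectrum = {k: 3 for k in SNV_CLASSES}
        assert at_bias(spectrum, genome) == pytest.approx(1.0)

    def test_formula_arithmetic(self):
        genome = GenomeRef({"c1": "ACGT" * 10})  # gc == at
        spectrum = dict.fromkeys(SNV_CLASSES, 0)
        spectrum.update({"G:C>A:T": 10, "G:C>T:A": 10, "A:T>G:C": 2, "A:T>C:G": 2})
        assert at_bias(spectrum, genome) == pytest.approx(5.0)

    def test_invariant_under_genome_scaling(self):
        spectrum = dict.fromkeys(SNV_CLASSES, 4)
        g1 = GenomeRef({"c1": "AACG" * 5})
        g2 = GenomeRef({"c1": "AACG" * 50})
        assert at_bias(spectrum, g1) == pytest.approx(at_bias(spectrum, g2))

    def test_zero_gc_gain_undefined(self):
        genome = GenomeRef({"c1": "ACGT"})
        assert at_bias(dict.fromkeys(SNV_CLASSES, 0), genome) is None


class TestTripletContext:
    def test_tta_example_and_purine_collapse(self):
        genome = GenomeRef({"c1": "GTTAG"})
        # T>A at pos 3: triplet TTA, class A:T>T:A
        table = triplet_context([snv("T", "A", pos=3)], genome)
        assert table.counts == {("TTA", "A:T>T:A"): 1}
        # A>T at pos 4 (context TAG -> center purine, collapse CTA)
        genome2 = GenomeRef({"c1": "GTAAG"})
        table2 = triplet_context([snv("A", "T", pos=3)], genome2)
        assert list(table2.counts) == [("TTA", "A:T>T:A")]

    def test_contig_edge_goes_to_edge_bucket(self):
        genome = GenomeRef({"c1": "ACGTA"})
        table = triplet_context([snv("A", "G", pos=1)], genome)
        assert table.edge_count == 1 and not table.counts

    def test_marginal_reproduces_spectrum(self):
        import numpy as np

        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        genome = GenomeRef({"c1": seq})
        cands = []
        for pos in rng.integers(2, 500, size=80):
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            cands.append(snv(ref, alt, pos=int(pos)))
        table = triplet_context(cands, genome)
        assert table.marginal_spectrum() == spectrum_table(cands)


def _single_gene_annotation(cds_seq_plus, start=11, strand="+"):
    """One gene whose CDS occupies [start, start+len-1] on a padded contig."""
    end = start + len(cds_seq_plus) - 1
    gene = GeneModel("g1", "c1", start - 5, end + 5, strand, cds=[(start, end, 0)])
    return GeneAnnotation([gene])


def _brute_force_consequence(genome, ann, cand):
    """Translate the full mutated vs reference CDS with biopython."""
    from Bio.Seq import Seq

    gene = ann.genes["g1"]
    (s, e, _), = gene.cds
    ref_cds = genome.slice("c1", s, e)
    i = cand.pos - s
    alt_cds = ref_cds[:i] + cand.alt + ref_cds[i + 1:]
    if gene.strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
    ref_aa, alt_aa = str(Seq(ref_cds).translate()), str(Seq(alt_cds).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    diff = next(i for i in range(len(ref_aa)) if ref_aa[i] != alt_aa[i])
    return "stop_gained" if alt_aa[diff] == "*" else "missense"


class TestClassifyConsequence:
    def _setup(self, cds, strand="+"):
        contig = "AAAAACCCCC" + cds + "GGGGGTTTTT"
        genome = GenomeRef({"c1": contig})
        return genome, _single_gene_annotation(cds, start=11, strand=strand)

    def test_stop_gained_tat_to_taa(self):
        genome, ann = self._setup("ATGTATGGG")
        # TAT codon at 14-16; T>A at third base -> TAA stop
        cand = snv("T", "A", pos=16)
        cons = classify_consequence(cand, ann, genome)
        assert cons.label == "stop_gained" and cons.coding and cons.genic

    def test_synonymous_third_position(self):
        genome, ann = self._setup("ATGGCTAAA")
        cand = snv("T", "C", pos=16)  # GCT -> GCC, both Ala
        assert classify_consequence(cand, ann, genome).label == "synonymous"

    def test_intergenic(self):
        genome, ann = self._setup("ATGGCTAAA")
        cons = classify_consequence(snv("A", "G", pos=2), ann, genome)
        assert cons.label == "noncoding" and not cons.genic and not cons.coding

    def test_genic_noncoding_between_cds_and_gene_edge(self):
        genome, ann = self._setup("ATGGCTAAA")
        cons = classify_consequence(snv("C", "T", pos=8), ann, genome)
        assert cons.label == "genic_noncoding" and cons.genic and not cons.coding

    def test_indel_in_cds_is_genic_not_coding(self):
        genome, ann = self._setup("ATGGCTAAA")
        indel = CandidateMutation("L1", "c1", 14, "deletion", "GC", "G")
        cons = classify_consequence(indel, ann, genome)
        assert cons.in_cds and cons.genic and not cons.coding

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_bruteforce_translation_on_small_genes(self, strand):
        import numpy as np

        rng = np.random.default_rng(17 if strand == "+" else 18)
        for _ in range(30):
            n_codons = int(rng.integers(2, 11))
            cds = "ATG" + "".join(rng.choice(list("ACGT"), size=3 * (n_codons - 1)))
            genome, ann = self._setup(cds, strand=strand)
            pos = int(rng.integers(11, 11 + len(cds)))
            ref = genome.base("c1", pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            cand = snv(ref, alt, pos=pos)
            got = classify_consequence(cand, ann, genome).label
            expect = _brute_force_consequence(genome, ann, cand)
            assert got == expect, (strand, cds, pos, ref, alt)

    def test_cds_not_multiple_of_three_warns_and_stays_genic(self):
        contig = "AAAAACCCCC" + "ATGGCTAA" + "GGGGGTTTTT"  # 8 bp CDS
        genome = GenomeRef({"c1": contig})
        ann = _single_gene_annotation("ATGGCTAA", start=11)
        with pytest.warns(UserWarning, match="divisible by 3"):
            cons = classify_consequence(snv("T", "C", pos=13), ann, genome)
        assert cons.label == "genic_noncoding" and cons.genic


class TestIndelLengths:
    def _indel(self, mtype, length, pos):
        if mtype == "insertion":
            return CandidateMutation("L1", "c1", pos, mtype, "A", "A" + "T" * length)
        return CandidateMutation("L1", "c1", pos, mtype, "A" + "T" * length, "A")

    def test_mean_of_deletions(self):
        cands = [self._indel("deletion", n, 10 * n) for n in (2, 4, 9)]
        table = indel_lengths(cands)
        assert table.mean("deletion") == pytest.approx(5.0)

    def test_empty_type_undefined_mean(self):
        table = indel_lengths([self._indel("deletion", 3, 10)])
        assert table.mean("insertion") is None
        assert not table.insertion_hist

    def test_histogram_matches_mean_identity(self):
        import numpy as np

        rng = np.random.default_rng(6)
        lengths = rng.geometric(1 / 3, size=500)
        cands = [self._indel("insertion", int(l), 10 * i + 1)
                 for i, l in enumerate(lengths)]
        table = indel_lengths(cands)
        assert sum(table.insertion_hist.values()) == 500
        assert table.mean("insertion") == pytest.approx(float(np.mean(lengths)))
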