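"""Mutation spectra and functional classification.

SNVs are classified into the six strand-collapsed base-substitution
classes (A:T>T:A, A:T>C:G, A:T>G:C, G:C>A:T, G:C>T:A, G:C>C:G);
derived summaries include the transition/transversion ratio, the
composition-normalized AT bias, triplet sequence context, indel length
histograms, and a codon-level coding consequence
(missense/synonymous/stop_gained) against a gene annotation.

The AT bias here is the composition-normalized flux ratio

    [(GC>AT + GC>TA) / n_GC] / [(AT>GC + AT>CG) / n_AT]

i.e. the per-site rate of mutations gaining an A:T pair over the
per-site rate of mutations gaining a G:C pair. Published AT-bias values
may use a different (unstated) normalization, so this column is defined
by this package, not claimed to reproduce any external table.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .filtering import DELETION, INSERTION, SNV, CandidateMutation
from .io import GeneAnnotation, GeneModel, GenomeRef

__all__ = [
    "SNV_CLASSES",
    "TRANSITION_CLASSES",
    "snv_class",
    "is_transition",
    "class_alt_base",
    "compatible_classes",
    "spectrum_table",
    "ts_tv",
    "at_bias",
    "ContextTable",
    "triplet_context",
    "Consequence",
    "classify_consequence",
    "IndelLengthTable",
    "indel_lengths",
]

SNV_CLASSES = (
    "A:T>T:A",
    "A:T>C:G",
    "A:T>G:C",
    "G:C>A:T",
    "G:C>T:A",
    "G:C>C:G",
)
TRANSITION_CLASSES = frozenset({"A:T>G:C", "G:C>A:T"})

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

# class -> substitution on the purine-reference strand (A or G)
_PURINE_SUB = {
    "A:T>T:A": ("A", "T"),
    "A:T>C:G": ("A", "C"),
    "A:T>G:C": ("A", "G"),
    "G:C>A:T": ("G", "A"),
    "G:C>T:A": ("G", "T"),
    "G:C>C:G": ("G", "C"),
}


def snv_class(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"invalid SNV {ref}>{alt}")
    if ref in "CT":  # collapse onto the purine reference strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    for klass, (r, a) in _PURINE_SUB.items():
        if (r, a) == (ref, alt):
            return klass
    raise AssertionError("unreachable")


def is_transition(ref: str, alt: str) -> bool:
    return {ref.upper(), alt.upper()} in ({"A", "G"}, {"C", "T"})


def compatible_classes(klass: str) -> frozenset:
    """Reference bases at which a class can occur."""
    r, _ = _PURINE_SUB[klass]
    return frozenset({r, _COMPLEMENT[r]})


def class_alt_base(klass: str, ref: str) -> str:
    """Alt base produced by a class at a given reference base."""
    r, a = _PURINE_SUB[klass]
    if ref == r:
        return a
    if ref == _COMPLEMENT[r]:
        return _COMPLEMENT[a]
    raise ValueError(f"class {klass} cannot occur at reference base {ref}")


def spectrum_table(candidates: list[CandidateMutation]) -> dict[str, int]:
    """Counts over the 6 classes for the SNVs in a candidate list."""
    counts = {k: 0 for k in SNV_CLASSES}
    for c in candidates:
        if c.mtype == SNV:
            counts[snv_class(c.ref, c.alt)] += 1
    return counts


def ts_tv(candidates: list[CandidateMutation]) -> float | None:
    """Transition/transversion ratio; None when no transversion exists."""
    ts = tv = 0
    for c in candidates:
        if c.mtype != SNV:
            continue
        if is_transition(c.ref, c.alt):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def at_bias(spectrum: dict[str, int], genome: GenomeRef) -> float | None:
    """Composition-normalized AT-gaining over GC-gaining mutation flux."""
    gain_at = spectrum["G:C>A:T"] + spectrum["G:C>T:A"]
    gain_gc = spectrum["A:T>G:C"] + spectrum["A:T>C:G"]
    if genome.gc_count == 0 or genome.at_count == 0 or gain_gc == 0:
        return None
    return (gain_at / genome.gc_count) / (gain_gc / genome.at_count)


@dataclass
class ContextTable:
    """SNV counts keyed by (pyrimidine-centered triplet, class).

    Contig-edge SNVs (no flanking base on one side) land in the edge
    bucket and are excluded from the context totals; marginalizing the
    context counts over triplets reproduces the 6-class spectrum of the
    non-edge SNVs.
    """

    counts: Counter = field(default_factory=Counter)  # (triplet, class) -> n
    edge_count: int = 0

    def marginal_spectrum(self) -> dict[str, int]:
        out = {k: 0 for k in SNV_CLASSES}
        for (_, klass), n in self.counts.items():
            out[klass] += n
        return out


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def triplet_context(
    candidates: list[CandidateMutation], genome: GenomeRef
) -> ContextTable:
    """Tally SNVs by strand-collapsed reference triplet and class.

    Triplets are collapsed so their center base is a pyrimidine (C or
    T); a purine-centered triplet is reverse-complemented, matching the
    mutational-signature convention (e.g. T>A in TAA collapses to TTA).
    """
    table = ContextTable()
    for c in candidates:
        if c.mtype != SNV:
            continue
        L = genome.contig_length(c.contig)
        if c.pos <= 1 or c.pos >= L:
            table.edge_count += 1
            continue
        triplet = genome.slice(c.contig, c.pos - 1, c.pos + 1)
        if "N" in triplet:
            table.edge_count += 1
            continue
        if triplet[1] in "AG":
            triplet = _revcomp(triplet)
        table.counts[(triplet, snv_class(c.ref, c.alt))] += 1
    return table


@dataclass(frozen=True)
class Consequence:
    """Functional classification of a mutation.

    ``coding`` is True only for missense/synonymous/stop_gained SNVs
    (the published coding definition); indels overlapping a CDS carry
    ``in_cds=True`` and ``genic=True`` but are not counted as coding.
    """

    label: str  # missense|synonymous|stop_gained|genic_noncoding|noncoding
    coding: bool
    genic: bool
    in_cds: bool = False


def _spliced_cds(gene: GeneModel, genome: GenomeRef) -> str:
    parts = [genome.slice(gene.contig, s, e) for s, e, _ in gene.cds]
    concat = "".join(parts)
    return _revcomp(concat) if gene.strand == "-" else concat


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """Offset of a genomic position within the spliced CDS (5'->3')."""
    cum = 0
    total = sum(e - s + 1 for s, e, _ in gene.cds)
    for s, e, _ in gene.cds:  # sorted ascending
        if s <= pos <= e:
            plus_offset = cum + (pos - s)
            return total - 1 - plus_offset if gene.strand == "-" else plus_offset
        cum += e - s + 1
    return None


def _snv_cds_consequence(
    cand: CandidateMutation, gene: GeneModel, genome: GenomeRef
) -> str | None:
    total = sum(e - s + 1 for s, e, _ in gene.cds)
    if total % 3 != 0:
        warnings.warn(
            f"CDS length of {gene.gene_id} not divisible by 3; "
            "gene skipped for consequence"
        )
        return None
    offset = _cds_offset(gene, cand.pos)
    if offset is None:
        return None
    # apply the phase of the translation-order first CDS segment
    first = gene.cds[-1] if gene.strand == "-" else gene.cds[0]
    offset -= first[2]
    if offset < 0:
        return None
    spliced = _spliced_cds(gene, genome)
    alt = _COMPLEMENT[cand.alt] if gene.strand == "-" else cand.alt
    codon_i, within = divmod(offset, 3)
    ref_codon = spliced[3 * codon_i : 3 * codon_i + 3]
    if len(ref_codon) < 3:
        return None
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    return "missense"  # includes stop_lost / start_lost


_SEVERITY = {"stop_gained": 3, "missense": 2, "synonymous": 1}


def classify_consequence(
    candidate: CandidateMutation, genes: GeneAnnotation, genome: GenomeRef
) -> Consequence:
    """Classify one mutation against the annotation.

    SNVs inside a CDS are classified by codon translation on the
    CDS-containing frame; when several genes overlap the site, the most
    severe consequence wins (a mutation coding in any overlapping
    transcript counts as coding). Genes whose CDS length is not a
    multiple of 3 are skipped for consequence (the site stays genic).
    """
    genic = genes.is_genic(candidate.contig, candidate.pos)
    cds_genes = genes.cds_genes_at(candidate.contig, candidate.pos)
    in_cds = bool(cds_genes)
    if candidate.mtype != SNV:
        label = "genic_noncoding" if genic or in_cds else "noncoding"
        return Consequence(label=label, coding=False, genic=genic or in_cds, in_cds=in_cds)
    best: str | None = None
    for gene in cds_genes:
        cons = _snv_cds_consequence(candidate, gene, genome)
        if cons is not None and (best is None or _SEVERITY[cons] > _SEVERITY[best]):
            best = cons
    if best is not None:
        return Consequence(label=best, coding=True, genic=True, in_cds=True)
    if genic or in_cds:
        return Consequence(label="genic_noncoding", coding=False, genic=True, in_cds=in_cds)
    return Consequence(label="noncoding", coding=False, genic=False)


@dataclass
class IndelLengthTable:
    """Per-type histograms of absolute indel length, with means."""

    insertion_hist: Counter = field(default_factory=Counter)
    deletion_hist: Counter = field(default_factory=Counter)

    def mean(self, mtype: str) -> float | None:
        hist = self.insertion_hist if mtype == INSERTION else self.deletion_hist
        n = sum(hist.values())
        if n == 0:
            return None
        return sum(length * count for length, count in hist.items()) / n


def indel_lengths(candidates: list[CandidateMutation]) -> IndelLengthTable:
    table = IndelLengthTable()
    for c in candidates:
        if c.mtype == INSERTION:
            table.insertion_hist[abs(c.length_delta)] += 1
        elif c.mtype == DELETION:
            table.deletion_hist[abs(c.length_delta)] += 1
    return table
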