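"""Line-specific mutation detection and cross-contamination screening.

An *accumulated mutation* is a homozygous variant unique to one MA line,
interpreted as a new mutation fixed since the experiment began. A site
yields a candidate for a line only when all of the following hold
(thresholds configurable via :class:`FilterThresholds`; defaults match
the published detection procedure):

(i)   exactly one homozygous genotype class is carried by more than one
      line at the site (the ancestral class — with a single alt-hom line
      this means at least two ref-homozygous lines);
(ii)  the alternative homozygote occurs in exactly one line, with read
      depth DP >= 5 supporting the genotype;
(iii) no other line in the group is heterozygous for any alt allele;
(iv)  at least 10 lines of the group are reference-homozygous with
      support from more than 5 reads (DP > 5);
(v)   the genotype quality of the focal call is GQ > 20;
(vi)  no other linking accumulated SNV/indel of the same line lies
      within the linkage window (both members of such a pair removed;
      see :func:`remove_linked`).

Cross-contaminated line pairs are screened by counting shared
alternative-homozygote loci between every pair of lines over loci where
all lines are covered by more than five reads and fewer than 30% of the
lines are alt-homozygous (:func:`pairwise_sharing`), then flagging
robust outliers (:func:`flag_contaminated`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator

import numpy as np

from .io import ALT_HOM, HET, MISSING, REF_HOM, ConfigurationError, GroupConfig, VariantSite

__all__ = [
    "SNV",
    "INSERTION",
    "DELETION",
    "CandidateMutation",
    "FilterThresholds",
    "SharingMatrix",
    "classify_alleles",
    "find_candidates",
    "remove_linked",
    "pairwise_sharing",
    "flag_contaminated",
]

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"


def classify_alleles(ref: str, alt: str) -> str | None:
    """Mutation type implied by a ref/alt allele pair.

    Returns SNV for 1 bp substitutions, insertion/deletion by length
    difference, and None for equal-length multi-base substitutions
    (MNVs), which this pipeline does not score.
    """
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(alt) > len(ref):
        return INSERTION
    if len(alt) < len(ref):
        return DELETION
    return None


@dataclass
class CandidateMutation:
    """A line-specific accumulated mutation."""

    line_id: str
    contig: str
    pos: int  # 1-based VCF anchor
    mtype: str  # SNV / insertion / deletion
    ref: str
    alt: str
    consequence: str | None = None

    @property
    def length_delta(self) -> int:
        return len(self.alt) - len(self.ref)

    def key(self) -> tuple:
        return (self.contig, self.pos, self.line_id, self.ref, self.alt)


@dataclass(frozen=True)
class FilterThresholds:
    """Detection thresholds; defaults are the published values.

    ``min_dp_focal`` is "no less than five reads" (DP >= 5) on the focal
    alt-homozygote; ``min_dp_support`` is "more than five reads"
    (DP > 5, i.e. >= 6) on supporting ref-homozygotes — the asymmetry is
    deliberate and preserved. ``min_gq`` = 21 encodes GQ > 20.
    """

    min_dp_focal: int = 5
    min_dp_support: int = 6
    min_support_lines: int = 10
    min_gq: int = 21
    link_window: int = 100


def find_candidates(
    sites: Iterable[VariantSite],
    group: GroupConfig,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CandidateMutation]:
    """Apply criteria (i)-(v) to a stream of sites.

    Multi-allelic sites are considered jointly: any second alt-hom line
    (even for a different alt) violates (ii), and a het for any alt
    violates (iii). Missing genotypes count toward neither (iii)
    violations nor (iv) support. Criterion (vi) is a separate pass
    (:func:`remove_linked`) so that its window can be re-applied to
    merged candidate lists.
    """
    active = group.active_lines
    if len(active) < thresholds.min_support_lines + 1:
        raise ConfigurationError(
            f"group {group.group_name!r} has {len(active)} active lines; "
            f"criterion (iv) needs at least {thresholds.min_support_lines} "
            "supporting lines besides the focal one"
        )
    active_set = set(active)
    out: list[CandidateMutation] = []
    for site in sites:
        calls = [c for c in site.calls if c.line_id in active_set]
        alt_homs = [c for c in calls if c.gclass == ALT_HOM]
        if len(alt_homs) != 1:  # (ii): unique alt-homozygote line
            continue
        focal = alt_homs[0]
        if focal.dp < thresholds.min_dp_focal:  # (ii): DP >= 5
            continue
        if any(c.gclass == HET for c in calls):  # (iii)
            continue
        ref_homs = [c for c in calls if c.gclass == REF_HOM]
        if len(ref_homs) < 2:  # (i): ancestral class in >1 line
            continue
        n_support = sum(1 for c in ref_homs if c.dp >= thresholds.min_dp_support)
        if n_support < thresholds.min_support_lines:  # (iv)
            continue
        if focal.gq < thresholds.min_gq:  # (v): GQ > 20
            continue
        alt = site.alts[focal.alt_index]
        mtype = classify_alleles(site.ref, alt)
        if mtype is None:
            continue
        out.append(
            CandidateMutation(
                line_id=focal.line_id,
                contig=site.contig,
                pos=site.pos,
                mtype=mtype,
                ref=site.ref,
                alt=alt,
            )
        )
    return out


def remove_linked(
    candidates: list[CandidateMutation], window: int = 100
) -> list[CandidateMutation]:
    """Criterion (vi): drop linked same-line candidates.

    Any two candidates of the same line on the same contig within
    ``window`` bp (anchor distance <= window) are BOTH removed;
    candidates of different lines never interact.
    """
    by_line: dict[tuple[str, str], list[CandidateMutation]] = {}
    for c in candidates:
        by_line.setdefault((c.line_id, c.contig), []).append(c)
    doomed: set[int] = set()
    for group_cands in by_line.values():
        group_cands.sort(key=lambda c: c.pos)
        for a, b in zip(group_cands, group_cands[1:]):
            if b.pos - a.pos <= window:
                doomed.add(id(a))
                doomed.add(id(b))
    return [c for c in candidates if id(c) not in doomed]


@dataclass
class SharingMatrix:
    """Symmetric per-pair counts of shared alternative-homozygote loci.

    Eligibility requires every line covered by more than five reads, so
    the eligible-locus set is the same for every pair; it is stored once
    as ``n_eligible``.
    """

    line_ids: list[str]
    counts: dict[frozenset, int] = field(default_factory=dict)
    n_eligible: int = 0

    def pairs(self) -> Iterator[tuple[str, str]]:
        for a, b in combinations(self.line_ids, 2):
            yield a, b

    def get(self, a: str, b: str) -> int:
        return self.counts.get(frozenset((a, b)), 0)

    def increment(self, a: str, b: str) -> None:
        key = frozenset((a, b))
        self.counts[key] = self.counts.get(key, 0) + 1


def pairwise_sharing(
    sites: Iterable[VariantSite],
    group: GroupConfig,
    min_dp: int = 6,
    max_alt_hom_fraction: float = 0.30,
) -> SharingMatrix:
    """Count shared alt-homozygote loci per line pair.

    A locus is eligible iff every active line has DP > 5 and the
    fraction of alt-homozygous lines is below ``max_alt_hom_fraction``
    (strictly). For each eligible locus, every pair of lines that is
    alt-homozygous for the same alt allele is incremented.
    """
    active = group.active_lines
    active_set = set(active)
    matrix = SharingMatrix(line_ids=list(active))
    n = len(active)
    for site in sites:
        calls = [c for c in site.calls if c.line_id in active_set]
        if any(c.dp < min_dp for c in calls):
            continue
        alt_homs = [c for c in calls if c.gclass == ALT_HOM]
        if len(alt_homs) / n >= max_alt_hom_fraction:
            continue
        matrix.n_eligible += 1
        by_allele: dict[int, list[str]] = {}
        for c in alt_homs:
            by_allele.setdefault(c.alt_index, []).append(c.line_id)
        for lines in by_allele.values():
            for a, b in combinations(lines, 2):
                matrix.increment(a, b)
    return matrix


def flag_contaminated(
    matrix: SharingMatrix, k: float = 5.0
) -> list[tuple[str, str, int]]:
    """Flag line pairs whose shared-locus count is a robust outlier.

    The threshold is median + k * max(1.4826*MAD, 1) over all pair
    counts; the floor of one count on the MAD scale keeps the rule
    usable when most pairs share zero loci (MAD = 0), in which case a
    raw MAD rule would flag every nonzero pair. All-equal counts yield
    no flags. Flagged pairs are returned (a, b, count), highest count
    first, for manual exclusion via ``GroupConfig.excluded_lines``.
    """
    pairs = list(matrix.pairs())
    if len(pairs) < 3:
        raise ConfigurationError("need at least 3 line pairs to screen for outliers")
    counts = np.array([matrix.get(a, b) for a, b in pairs], dtype=float)
    if np.all(counts == counts[0]):
        return []
    med = float(np.median(counts))
    mad = float(np.median(np.abs(counts - med)))
    threshold = med + k * max(1.4826 * mad, 1.0)
    flagged = [
        (a, b, int(c)) for (a, b), c in zip(pairs, counts) if c > threshold
    ]
    flagged.sort(key=lambda t: -t[2])
    return flagged
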