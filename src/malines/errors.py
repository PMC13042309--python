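"""False-negative and false-positive estimation for mutation detection.

The false-negative harness plants random SNVs and indels into the
reference genome — only in regions with no detected mutation within a
200 bp flank — edits the reference, re-detects against the edited
reference, and scores recall per sample with the published matching
rules: a planted SNV counts as detected only if an alternative
homozygote with the same base change appears at the same locus; a
planted indel counts as detected if a variant of the same type appears
within 5 bp upstream (indel anchors are not always assignable uniquely
after realignment). The FN rate per sample and type is the fraction of
covered plantings (sample DP > 5 at the planted anchor) that were not
detected.

The false-positive rate comes from an ancestral line sequenced alongside
the MA panel: among all alternative-homozygote loci, the fraction
carried only by the ancestral line (which by construction accumulated
no line-specific mutations during the experiment).

Against an edited reference every sample is alt-homozygous at a planted
site, so re-detection is per sample (alt-hom with DP >= 5 and GQ > 20,
the focal-call thresholds of the main filter) rather than the six
line-specific criteria. A file-based interface (edited FASTA out,
variant calls in) lets a user substitute any external caller for the
built-in emulator.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .filtering import DELETION, INSERTION, SNV, CandidateMutation
from .io import ALT_HOM, GenomeRef, GroupConfig, VariantSite

__all__ = [
    "PlantedMutation",
    "Liftover",
    "plan_insertions",
    "apply_insertions",
    "match_detected",
    "fn_rate",
    "fp_rate_ancestral",
    "redetect_planted",
]


@dataclass
class PlantedMutation:
    """One planted mutation, with detection/coverage flags per scoring run."""

    contig: str
    pos: int  # 1-based, on the ORIGINAL reference
    mtype: str
    ref: str
    alt: str
    detected: bool = False
    covered: bool = True


class Liftover:
    """Coordinate map between the original and the edited reference.

    Built from the applied edit plan; for every planted edit anchor,
    lifting original -> edited -> original is the identity. Positions
    inside a deleted segment have no image and lift to None.
    """

    def __init__(self) -> None:
        # per contig: sorted breakpoints (original pos after which the
        # cumulative offset changes) and cumulative offsets
        self._breaks: dict[str, list[int]] = {}
        self._offsets: dict[str, list[int]] = {}
        self._deleted: dict[str, list[tuple[int, int]]] = {}

    def _add(self, contig: str, after_pos: int, delta: int) -> None:
        br = self._breaks.setdefault(contig, [])
        off = self._offsets.setdefault(contig, [])
        prev = off[-1] if off else 0
        br.append(after_pos)
        off.append(prev + delta)

    def to_edited(self, contig: str, pos: int) -> int | None:
        for s, e in self._deleted.get(contig, []):
            if s <= pos <= e:
                return None
        br = self._breaks.get(contig, [])
        i = bisect.bisect_right(br, pos - 1)  # breaks strictly before pos
        offset = self._offsets[contig][i - 1] if i > 0 else 0
        return pos + offset

    def to_original(self, contig: str, pos: int) -> int | None:
        br = self._breaks.get(contig, [])
        offs = self._offsets.get(contig, [])
        # invert: find the original position p with p + offset(p) == pos
        candidate = pos
        for b, o in zip(reversed(br), reversed(offs)):
            p = pos - o
            if p > b:
                candidate = p
                break
        else:
            candidate = pos
        return candidate if self.to_edited(contig, candidate) == pos else None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tafter_original_pos\tcumulative_offset\n")
            for contig in sorted(self._breaks):
                for b, o in zip(self._breaks[contig], self._offsets[contig]):
                    fh.write(f"{contig}\t{b}\t{o}\n")


def plan_insertions(
    genome: GenomeRef,
    detected: Sequence[CandidateMutation],
    n_snv: int,
    n_ins: int,
    n_del: int,
    flank: int = 200,
    seed: int = 0,
    indel_length_mean: float = 3.0,
) -> list[PlantedMutation]:
    """Sample a plan of mutations to plant into the reference.

    Positions are uniform over the genome, at least ``flank`` bp away
    from every detected mutation and from contig ends, and pairwise at
    least ``flank`` bp apart (so edits never interact and the matching
    window is unambiguous). Deletion lengths are capped at ``flank`` so
    a deleted segment cannot reach another planted site. Raises with the
    achievable count when eligible space runs out.
    """
    rng = np.random.default_rng(seed)
    contigs = list(genome.contigs)
    lengths = np.array([genome.contig_length(c) for c in contigs], dtype=float)
    if lengths.sum() == 0:
        raise ValueError("empty genome")
    p_contig = lengths / lengths.sum()
    detected_pos: dict[str, list[int]] = {}
    for d in detected:
        detected_pos.setdefault(d.contig, []).append(d.pos)
    for v in detected_pos.values():
        v.sort()
    planted_pos: dict[str, list[int]] = {c: [] for c in contigs}

    def _clear(contig: str, pos: int) -> bool:
        L = genome.contig_length(contig)
        if pos <= flank or pos > L - flank:
            return False
        for arr in (detected_pos.get(contig, []), planted_pos[contig]):
            i = bisect.bisect_left(arr, pos)
            for j in (i - 1, i):
                if 0 <= j < len(arr) and abs(arr[j] - pos) < flank:
                    return False
        return True

    plan: list[PlantedMutation] = []
    want = [(SNV, n_snv), (INSERTION, n_ins), (DELETION, n_del)]
    bases = np.array(list("ACGT"))
    for mtype, n in want:
        for k in range(n):
            for _try in range(20_000):
                ci = int(rng.choice(len(contigs), p=p_contig))
                contig = contigs[ci]
                L = genome.contig_length(contig)
                pos = int(rng.integers(1, L + 1))
                if not _clear(contig, pos):
                    continue
                if mtype == SNV:
                    ref = genome.base(contig, pos)
                    if ref == "N":
                        continue
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                elif mtype == INSERTION:
                    ref = genome.base(contig, pos)
                    if ref == "N":
                        continue
                    length = int(rng.geometric(1.0 / indel_length_mean))
                    alt = ref + "".join(rng.choice(bases, size=length))
                else:
                    length = min(int(rng.geometric(1.0 / indel_length_mean)), flank - 1)
                    if pos + length > L:
                        continue
                    ref = genome.slice(contig, pos, pos + length)
                    if "N" in ref:
                        continue
                    alt = ref[0]
                plan.append(PlantedMutation(contig=contig, pos=pos, mtype=mtype, ref=ref, alt=alt))
                bisect.insort(planted_pos[contig], pos)
                break
            else:
                raise RuntimeError(
                    f"insufficient eligible space: placed {len(plan)} of "
                    f"{n_snv + n_ins + n_del} planned mutations "
                    f"(failed while planting {mtype} #{k + 1})"
                )
    return plan


def apply_insertions(
    genome: GenomeRef, plan: Sequence[PlantedMutation]
) -> tuple[GenomeRef, Liftover]:
    """Apply a plan to the reference, right to left per contig.

    SNVs substitute one base; insertions add bases after the anchor;
    deletions remove the bases after the anchor. Returns the edited
    genome and an original->edited coordinate liftover.
    """
    by_contig: dict[str, list[PlantedMutation]] = {}
    for m in plan:
        by_contig.setdefault(m.contig, []).append(m)
    lift = Liftover()
    new_contigs: dict[str, str] = dict(genome.contigs)
    for contig, edits in by_contig.items():
        edits.sort(key=lambda m: m.pos)
        for a, b in zip(edits, edits[1:]):
            if b.pos - a.pos <= max(len(a.ref), len(a.alt)):
                raise ValueError(f"overlapping edits at {contig}:{a.pos} and {b.pos}")
        seq = list(genome.contigs[contig])
        for m in reversed(edits):
            i = m.pos - 1
            if "".join(seq[i : i + len(m.ref)]) != m.ref:
                raise ValueError(f"plan ref mismatch at {contig}:{m.pos}")
            seq[i : i + len(m.ref)] = list(m.alt)
        new_contigs[contig] = "".join(seq)
        # build liftover left to right
        for m in edits:
            delta = len(m.alt) - len(m.ref)
            if delta == 0:
                continue
            if m.mtype == DELETION:
                lift._deleted.setdefault(contig, []).append(
                    (m.pos + 1, m.pos + len(m.ref) - 1)
                )
                lift._add(contig, m.pos + len(m.ref) - 1, delta)
            else:
                lift._add(contig, m.pos, delta)
    return GenomeRef(new_contigs), lift


def match_detected(
    plan: Sequence[PlantedMutation],
    redetected: Sequence[CandidateMutation],
    indel_window: int = 5,
) -> list[PlantedMutation]:
    """Score a plan against re-detected variants (same coordinate frame).

    SNVs match only on identical locus and base change; indels match a
    detected variant of the same type at a position in
    [planted - indel_window, planted], nearest first. Matching is
    injective: each detected variant is consumed by at most one planted
    mutation.
    """
    by_contig: dict[str, list[CandidateMutation]] = {}
    for d in redetected:
        by_contig.setdefault(d.contig, []).append(d)
    for v in by_contig.values():
        v.sort(key=lambda d: d.pos)
    used: set[int] = set()
    out: list[PlantedMutation] = []
    for m in sorted(plan, key=lambda m: (m.contig, m.pos)):
        hit = False
        pool = by_contig.get(m.contig, [])
        if m.mtype == SNV:
            for d in pool:
                if (
                    id(d) not in used
                    and d.pos == m.pos
                    and d.mtype == SNV
                    and d.ref == m.ref
                    and d.alt == m.alt
                ):
                    used.add(id(d))
                    hit = True
                    break
        else:
            best = None
            for d in pool:
                if id(d) in used or d.mtype != m.mtype:
                    continue
                if m.pos - indel_window <= d.pos <= m.pos:
                    if best is None or abs(d.pos - m.pos) < abs(best.pos - m.pos):
                        best = d
            if best is not None:
                used.add(id(best))
                hit = True
        out.append(replace(m, detected=hit))
    return out


def fn_rate(
    plan: Sequence[PlantedMutation],
    coverage: Mapping[tuple[str, int], bool] | None = None,
) -> dict[str, float | None]:
    """Per-type FN fraction: (covered and not detected) / covered.

    ``coverage`` optionally overrides the plan's ``covered`` flags,
    keyed by (contig, pos). Types with zero covered plantings report
    None (undefined).
    """
    out: dict[str, float | None] = {}
    for mtype in (SNV, INSERTION, DELETION):
        subset = [m for m in plan if m.mtype == mtype]
        if coverage is not None:
            covered = [m for m in subset if coverage.get((m.contig, m.pos), False)]
        else:
            covered = [m for m in subset if m.covered]
        if not covered:
            out[mtype] = None
            continue
        missed = sum(1 for m in covered if not m.detected)
        out[mtype] = missed / len(covered)
    return out


def redetect_planted(
    plan: Sequence[PlantedMutation],
    coverage_mean: float = 30.0,
    gq_mean: float = 60.0,
    gq_sd: float = 0.0,
    missing_rate: float = 0.0,
    min_dp: int = 5,
    min_gq: int = 21,
    seed: int = 0,
) -> tuple[list[CandidateMutation], dict[tuple[str, int], bool]]:
    """Emulate re-detection of planted sites for one sample.

    Against the edited reference every sample is alt-homozygous at each
    planted site, so each planting is re-detected independently: the
    genotype is dropped to missing with ``missing_rate``, DP is
    Poisson(coverage_mean), GQ a clamped normal, and the call is
    reported iff alt-hom with DP >= ``min_dp`` and GQ >= ``min_gq``.
    Returns (detected variants, coverage flags keyed by (contig, pos))
    where covered means DP > 5 at the planted anchor.
    """
    rng = np.random.default_rng(seed)
    detected: list[CandidateMutation] = []
    coverage: dict[tuple[str, int], bool] = {}
    for m in plan:
        dp = int(rng.poisson(coverage_mean))
        gq = int(np.clip(round(rng.normal(gq_mean, gq_sd) if gq_sd > 0 else gq_mean), 0, 99))
        coverage[(m.contig, m.pos)] = dp > 5
        if rng.random() < missing_rate:
            continue
        if dp >= min_dp and gq >= min_gq:
            detected.append(
                CandidateMutation(
                    line_id="sample",
                    contig=m.contig,
                    pos=m.pos,
                    mtype=m.mtype,
                    ref=m.ref,
                    alt=m.alt,
                )
            )
    return detected, coverage


def fp_rate_ancestral(
    sites: Iterable[VariantSite],
    ancestral_line: str,
    group: GroupConfig,
) -> tuple[float | None, int, int]:
    """FP fraction from an ancestral line.

    Among loci with at least one alternative-homozygote call (ancestral
    line included), returns the fraction carried ONLY by the ancestral
    line, as (fraction, n_ancestral_only, n_alt_hom_loci). Sites passed
    in are assumed restricted to the region eligible for mutation
    calling. Returns (None, 0, 0) when no alt-hom locus exists.
    """
    n_total = 0
    n_ancestral_only = 0
    for site in sites:
        alt_hom_lines = [c.line_id for c in site.calls if c.gclass == ALT_HOM]
        if not alt_hom_lines:
            continue
        n_total += 1
        if alt_hom_lines == [ancestral_line]:
            n_ancestral_only += 1
    if n_total == 0:
        return None, 0, 0
    return n_ancestral_only / n_total, n_ancestral_only, n_total
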