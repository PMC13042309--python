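"""Mutation-rate estimation.

The per-line mutation rate for each type is

    rate = n_mutations / (generations * callable_length)

where the callable length counts positions at which more than half of
the group's lines have more than five reads (DP > 5) — the same depth
rule used by the detection criteria, so numerator and denominator refer
to the same portion of the genome. Candidates falling outside the
callable mask are excluded from rate numerators (and reported), keeping
the estimator unbiased on synthetic data.

Group summaries report mean rates with a 95% confidence interval,
by default 1.96 * SD / sqrt(n) across lines (an "sd" option reports
+/- SD instead); both are labeled in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .filtering import DELETION, INSERTION, SNV, CandidateMutation
from .io import GenomeRef, GroupConfig
from . import spectra as _spectra

__all__ = [
    "CallableMask",
    "LineRates",
    "GroupSummary",
    "callable_length",
    "per_line_rates",
    "group_summary",
    "fold_change",
    "round_half_away",
]

MTYPES = (SNV, INSERTION, DELETION)


@dataclass
class CallableMask:
    """Positions callable for a group, as per-contig boolean arrays.

    Index 0 of each array corresponds to position 1.
    """

    mask: dict[str, np.ndarray]

    @property
    def callable_length(self) -> int:
        return int(sum(m.sum() for m in self.mask.values()))

    def contains(self, contig: str, pos: int) -> bool:
        m = self.mask.get(contig)
        if m is None or not 1 <= pos <= len(m):
            return False
        return bool(m[pos - 1])


def callable_length(
    depths: Mapping[str, np.ndarray],
    group: GroupConfig,
    depth_line_ids: Sequence[str] | None = None,
    min_dp: int = 6,
) -> CallableMask:
    """Compute the callable mask from a per-site per-line depth track.

    ``depths`` maps contig -> (n_lines, L) arrays. A position is
    callable iff strictly more than half of the group's active lines
    have DP > 5 there (DP >= ``min_dp``). If ``depth_line_ids`` is
    given, rows are subset to the group's active lines; otherwise the
    rows are assumed to be exactly the active lines.
    """
    if not depths:
        raise ValueError(
            "no depth track available: provide emitted invariant records or a "
            "synthetic depth track (e.g. DepthTrack from emulate_calling)"
        )
    active = group.active_lines
    mask: dict[str, np.ndarray] = {}
    for contig, arr in depths.items():
        if depth_line_ids is not None:
            rows = [depth_line_ids.index(l) for l in active]
            arr = arr[rows, :]
        elif arr.shape[0] != len(active):
            raise ValueError(
                f"depth track has {arr.shape[0]} rows but group has "
                f"{len(active)} active lines; pass depth_line_ids"
            )
        n_covered = (arr >= min_dp).sum(axis=0)
        mask[contig] = n_covered > len(active) / 2.0
    return CallableMask(mask=mask)


@dataclass
class LineRates:
    """Counts and per-site per-generation rates for one line."""

    line_id: str
    n_snv: int = 0
    n_ins: int = 0
    n_del: int = 0
    rate_snv: float = 0.0
    rate_ins: float = 0.0
    rate_del: float = 0.0

    def count(self, mtype: str) -> int:
        return {SNV: self.n_snv, INSERTION: self.n_ins, DELETION: self.n_del}[mtype]

    def rate(self, mtype: str) -> float:
        return {SNV: self.rate_snv, INSERTION: self.rate_ins, DELETION: self.rate_del}[
            mtype
        ]


def per_line_rates(
    candidates: Iterable[CandidateMutation],
    mask: CallableMask,
    group: GroupConfig,
) -> tuple[list[LineRates], list[CandidateMutation]]:
    """Per-line counts and rates; returns (rates, dropped_candidates).

    Candidates outside the callable mask are excluded from counts and
    returned in the second element.
    """
    L = mask.callable_length
    if L == 0:
        raise ValueError("callable length is 0; rates undefined")
    G = group.generations
    counts = {l: {t: 0 for t in MTYPES} for l in group.active_lines}
    dropped: list[CandidateMutation] = []
    for c in candidates:
        if c.line_id not in counts:
            continue
        if not mask.contains(c.contig, c.pos):
            dropped.append(c)
            continue
        counts[c.line_id][c.mtype] += 1
    rates = [
        LineRates(
            line_id=l,
            n_snv=ct[SNV],
            n_ins=ct[INSERTION],
            n_del=ct[DELETION],
            rate_snv=ct[SNV] / (G * L),
            rate_ins=ct[INSERTION] / (G * L),
            rate_del=ct[DELETION] / (G * L),
        )
        for l, ct in counts.items()
    ]
    return rates, dropped


@dataclass
class GroupSummary:
    """One summary row per MA group (counts, rates with CI, spectra ratios)."""

    group_name: str
    n_lines: int
    totals: dict[str, int]
    mean_rate: dict[str, float]
    ci95: dict[str, float | None]
    ci_kind: str  # "sem" (1.96*SEM) or "sd"
    ts_tv: float | None = None
    coding_noncoding: float | None = None
    genic_intergenic: float | None = None
    at_bias: float | None = None
    mean_ins_len: float | None = None
    mean_del_len: float | None = None


def _ci_half_width(values: np.ndarray, kind: str) -> float | None:
    if len(values) < 2:
        return None
    sd = float(np.std(values, ddof=1))
    if kind == "sd":
        return sd
    return 1.96 * sd / math.sqrt(len(values))


def group_summary(
    group_name: str,
    rates: list[LineRates],
    candidates: list[CandidateMutation],
    genome: GenomeRef | None = None,
    annotation=None,
    ci: str = "sem",
) -> GroupSummary:
    """Aggregate per-line rates and candidate properties for one group.

    ``genome`` enables the AT-bias column; ``annotation`` (plus genome)
    enables the coding/noncoding and genic/intergenic ratios, computed
    with the published coding rule (missense/synonymous/stop_gained).
    """
    if len(rates) < 2:
        raise ValueError("group summary needs at least 2 lines")
    if ci not in ("sem", "sd"):
        raise ValueError("ci must be 'sem' or 'sd'")
    totals = {t: sum(r.count(t) for r in rates) for t in MTYPES}
    mean_rate = {t: float(np.mean([r.rate(t) for r in rates])) for t in MTYPES}
    ci95 = {
        t: _ci_half_width(np.array([r.rate(t) for r in rates]), ci) for t in MTYPES
    }
    summary = GroupSummary(
        group_name=group_name,
        n_lines=len(rates),
        totals=totals,
        mean_rate=mean_rate,
        ci95=ci95,
        ci_kind=ci,
        ts_tv=_spectra.ts_tv(candidates),
    )
    lengths = _spectra.indel_lengths(candidates)
    summary.mean_ins_len = lengths.mean(INSERTION)
    summary.mean_del_len = lengths.mean(DELETION)
    if genome is not None:
        summary.at_bias = _spectra.at_bias(_spectra.spectrum_table(candidates), genome)
        if annotation is not None:
            coding = genic = 0
            for c in candidates:
                cons = _spectra.classify_consequence(c, annotation, genome)
                coding += cons.coding
                genic += cons.genic
            n = len(candidates)
            if n - coding > 0:
                summary.coding_noncoding = coding / (n - coding)
            if n - genic > 0:
                summary.genic_intergenic = genic / (n - genic)
    return summary


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(means: Sequence[float], decimals: int = 1) -> float:
    """max(mean)/min(mean) over group means, rounded half away from zero."""
    if len(means) < 2:
        raise ValueError("fold change needs at least 2 group means")
    lo, hi = min(means), max(means)
    if lo <= 0:
        raise ValueError("fold change undefined: smallest mean is not positive")
    return round_half_away(hi / lo, decimals)
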