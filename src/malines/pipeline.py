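"""End-to-end orchestration: simulate -> filter -> rates -> spectra -> compare.

``run_pipeline`` drives a complete synthetic MA experiment (or a
pre-existing VCF) through detection, rate estimation, spectrum
characterization, group comparison and (when ground truth exists)
precision/recall scoring, writing one TSV per stage plus a summary
table shaped like a per-group results table. All thresholds are
serialized into the report header for provenance, and outputs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from . import spectra as msp
from .filtering import (
    DELETION,
    INSERTION,
    SNV,
    FilterThresholds,
    find_candidates,
    flag_contaminated,
    pairwise_sharing,
    remove_linked,
)
from .rates import callable_length, fold_change, group_summary, per_line_rates
from .simulate import SimParams, emulate_calling, generate_founder, simulate_lines, write_toy_annotation
from .stats import fisher_exact_rxc, variance_f_test, wilcoxon_rank_sum

logger = logging.getLogger("malines")

__all__ = ["RunConfig", "run_pipeline", "read_run_config"]


@dataclass
class RunConfig:
    """Pipeline configuration with published threshold defaults."""

    seed: int = 0
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    sharing_min_dp: int = 6  # "more than five reads"
    sharing_max_alt_hom_fraction: float = 0.30
    fn_flank: int = 200
    indel_match_window: int = 5
    ci: str = "sem"
    n_mc: int = 10_000
    n_genes: int = 50
    # simulate mode: one SimParams per group (group name -> params)
    groups: dict[str, SimParams] = field(default_factory=dict)


def read_run_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig.

    Group simulation parameters use ``group.<name>.<simparam>`` keys;
    thresholds use their FilterThresholds field names; everything else
    maps onto RunConfig fields directly.
    """
    cfg = RunConfig()
    thresholds: dict[str, int] = {}
    group_kv: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = (p.strip() for p in line.split("=", 1))
            parts = key.split(".")
            if parts[0] == "group" and len(parts) == 3:
                group_kv.setdefault(parts[1], {})[parts[2]] = value
            elif key in {f.name for f in dataclasses.fields(FilterThresholds)}:
                thresholds[key] = int(value)
            elif hasattr(cfg, key):
                current = getattr(cfg, key)
                setattr(cfg, key, type(current)(value))
            else:
                raise mio.FormatError(f"unknown config key {key!r}")
    if thresholds:
        cfg.thresholds = FilterThresholds(**thresholds)
    sim_fields = {f.name: f.type for f in dataclasses.fields(SimParams)}
    for name, kv in group_kv.items():
        kwargs = {}
        for k, v in kv.items():
            if k not in sim_fields:
                raise mio.FormatError(f"unknown SimParams field {k!r}")
            kwargs[k] = type(getattr(SimParams(), k))(v)
        kwargs.setdefault("seed", cfg.seed)
        kwargs.setdefault("line_prefix", f"{name}_")
        cfg.groups[name] = SimParams(**kwargs)
    return cfg


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic pipeline; returns a dict of key results.

    Per-criterion attrition (counts in/out of the unique-alt-hom,
    no-het, support, GQ and linkage steps) is logged at stage
    granularity so the filter's behavior is auditable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "provenance.tsv", "w") as fh:
        fh.write("parameter\tvalue\n")
        fh.write(f"seed\t{config.seed}\n")
        for f in dataclasses.fields(FilterThresholds):
            fh.write(f"{f.name}\t{getattr(config.thresholds, f.name)}\n")
        for name in (
            "sharing_min_dp",
            "sharing_max_alt_hom_fraction",
            "fn_flank",
            "indel_match_window",
            "ci",
            "n_mc",
        ):
            fh.write(f"{name}\t{getattr(config, name)}\n")

    results: dict = {"groups": {}}
    summaries = {}
    per_line = {}
    group_candidates = {}
    for gi, (name, params) in enumerate(sorted(config.groups.items())):
        sub_seed = int(np.random.default_rng([config.seed, gi]).integers(2**31))
        params = params.with_(seed=sub_seed)
        logger.info("group %s: simulating (seed %d)", name, params.seed)
        genome = generate_founder(params)
        truth = simulate_lines(genome, params)
        gdir = outdir / name
        calls = emulate_calling(genome, truth, params, gdir)
        truth.to_tsv(gdir / "truth.tsv")
        gff = write_toy_annotation(
            genome, n_genes=config.n_genes, seed=params.seed, out_path=gdir / "genes.gff3"
        )
        annotation = mio.read_gff(gff)
        group_cfg = mio.GroupConfig(
            group_name=name, line_ids=calls.line_ids, generations=params.generations
        )

        sites = list(mio.read_vcf_matrix(calls.vcf_path, group_cfg))
        raw = find_candidates(sites, group_cfg, config.thresholds)
        cands = remove_linked(raw, config.thresholds.link_window)
        logger.info(
            "group %s: %d sites -> %d candidates after (i)-(v) -> %d after linkage",
            name, len(sites), len(raw), len(cands),
        )
        for c in cands:
            c.consequence = msp.classify_consequence(c, annotation, genome).label
        mio.write_candidates(cands, gdir / "candidates.tsv")

        sharing = pairwise_sharing(
            sites, group_cfg, config.sharing_min_dp, config.sharing_max_alt_hom_fraction
        )
        flags = flag_contaminated(sharing)
        _write_tsv(
            gdir / "sharing_flags.tsv",
            ["line_a", "line_b", "shared_loci"],
            [list(f) for f in flags],
        )

        mask = callable_length(calls.depth.depth, group_cfg, depth_line_ids=calls.line_ids)
        rates, dropped = per_line_rates(cands, mask, group_cfg)
        summary = group_summary(name, rates, cands, genome=genome, annotation=annotation, ci=config.ci)
        summaries[name] = summary
        per_line[name] = rates
        group_candidates[name] = cands

        truth_keys = {r.key() for r in truth.all_records()}
        cand_keys = {c.key() for c in cands}
        tp = len(truth_keys & cand_keys)
        precision = tp / len(cand_keys) if cand_keys else None
        recall = tp / len(truth_keys) if truth_keys else None

        spectrum = msp.spectrum_table(cands)
        _write_tsv(
            gdir / "spectrum.tsv",
            ["class", "count"],
            [[k, v] for k, v in spectrum.items()],
        )
        _write_tsv(
            gdir / "rates.tsv",
            ["line", "n_snv", "n_ins", "n_del", "rate_snv", "rate_ins", "rate_del"],
            [
                [r.line_id, r.n_snv, r.n_ins, r.n_del, r.rate_snv, r.rate_ins, r.rate_del]
                for r in sorted(rates, key=lambda r: r.line_id)
            ],
        )
        results["groups"][name] = {
            "n_candidates": len(cands),
            "callable_length": mask.callable_length,
            "precision": precision,
            "recall": recall,
            "dropped_outside_mask": len(dropped),
            "flagged_pairs": flags,
            "summary": summary,
        }

    _write_tsv(
        outdir / "table1.tsv",
        [
            "group", "n_lines", "SNV", "insertion", "deletion", "ts_tv",
            "coding_noncoding", "genic_intergenic", "at_bias",
            "u_snv", "ci_snv", "u_ins", "ci_ins", "u_del", "ci_del", "ci_kind",
        ],
        [
            [
                s.group_name, s.n_lines, s.totals[SNV], s.totals[INSERTION],
                s.totals[DELETION], s.ts_tv, s.coding_noncoding, s.genic_intergenic,
                s.at_bias, s.mean_rate[SNV], s.ci95[SNV], s.mean_rate[INSERTION],
                s.ci95[INSERTION], s.mean_rate[DELETION], s.ci95[DELETION], s.ci_kind,
            ]
            for s in summaries.values()
        ],
    )

    names = sorted(summaries)
    comparison_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for mtype in (SNV, INSERTION, DELETION):
                ra = [r.rate(mtype) for r in per_line[a]]
                rb = [r.rate(mtype) for r in per_line[b]]
                w = wilcoxon_rank_sum(ra, rb)
                f = variance_f_test(ra, rb)
                comparison_rows.append([a, b, mtype, "wilcoxon", w.statistic, w.p_value])
                comparison_rows.append([a, b, mtype, "f_test", f.statistic, f.p_value])
            sa = msp.spectrum_table(group_candidates[a])
            sb = msp.spectrum_table(group_candidates[b])
            table = np.array(
                [[sa[k] for k in msp.SNV_CLASSES], [sb[k] for k in msp.SNV_CLASSES]]
            )
            fe = fisher_exact_rxc(table, seed=config.seed, n_mc=config.n_mc)
            comparison_rows.append([a, b, "spectrum", "fisher_mc", fe.statistic, fe.p_value])
    _write_tsv(
        outdir / "comparison.tsv",
        ["group_a", "group_b", "quantity", "test", "statistic", "p_value"],
        comparison_rows,
    )
    if len(names) >= 2:
        means = [summaries[n].mean_rate[SNV] for n in names]
        if min(means) > 0:
            results["fold_change_snv"] = fold_change(means)
    results["summaries"] = summaries
    return results
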