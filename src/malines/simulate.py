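"""Synthetic mutation-accumulation experiments.

This module generates everything the downstream pipeline consumes — a
founder genome, per-line accumulated mutations with ground truth, a
multi-sample VCF plus per-site depth track emulating a short-read
genotyping run, and a toy gene annotation — so the whole analysis is
testable without any sequencing data.

The accumulation model follows single-worm descent: each line is an
independent lineage bottlenecked to one selfing hermaphrodite per
generation, so every surviving mutation is modeled as instantly fixed
homozygous in its line. Per line and mutation type, counts are
Poisson(mu * L * G); SNV classes are drawn from a configurable 6-class
spectrum (the class is drawn first and a position with a compatible
reference base is then sampled, so empirical class frequencies converge
to the configured spectrum regardless of genome composition); indel
lengths are geometric with a configurable mean. Heterozygous segregation
and drift inside the one-individual bottleneck are deliberately not
modeled: the detection criteria only score homozygous mutations.

The desk-scale default is a 1 Mb genome with rates inflated 100x over
the observed per-site per-generation rates so that expected counts are
large enough to test; set ``mu_*`` to the uninflated values for
realistic (but near-empty) runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .filtering import DELETION, INSERTION, SNV
from .io import GenomeRef
from .spectra import SNV_CLASSES, class_alt_base, compatible_classes

__all__ = [
    "SimParams",
    "TruthRecord",
    "TruthTable",
    "DepthTrack",
    "SimulatedCalls",
    "SimulationError",
    "generate_founder",
    "simulate_lines",
    "emulate_calling",
    "write_toy_annotation",
]


class SimulationError(RuntimeError):
    pass


# Default 6-class spectrum, shaped like the observed nematode MA spectrum
# (transition fraction ~0.55, i.e. ts/tv ~ 1.2). Order follows SNV_CLASSES:
# A:T>T:A, A:T>C:G, A:T>G:C, G:C>A:T, G:C>T:A, G:C>C:G.
DEFAULT_SPECTRUM = (0.18, 0.08, 0.22, 0.33, 0.13, 0.06)


@dataclass(frozen=True)
class SimParams:
    """Parameters of a synthetic MA experiment.

    Rates are per site per generation. Defaults are desk-scale: 1 Mb
    founder, 20 lines, 100 generations, and mutation rates 100x the
    observed ~2.2e-9 SNV / 2.9e-10 insertion / 4.5e-10 deletion rates,
    giving a testable expected ~22 SNVs per line.
    """

    genome_length: int = 1_000_000
    gc_content: float = 0.42
    n_lines: int = 20
    generations: int = 100
    mu_snv: float = 2.23e-7
    mu_ins: float = 2.90e-8
    mu_del: float = 4.51e-8
    spectrum: tuple[float, ...] = DEFAULT_SPECTRUM
    indel_length_mean: float = 3.0
    coverage_mean: float = 30.0
    gq_mean: float = 60.0
    gq_sd: float = 0.0
    het_miscall_rate: float = 0.0
    missing_rate: float = 0.0
    min_spacing: int = 1  # min distance between same-line mutations, bp
    contamination: tuple[str, str, float] | None = None  # (line_a, line_b, frac)
    contig_name: str = "chr1"
    line_prefix: str = "L"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum) - 1.0) > 1e-8 or len(self.spectrum) != 6:
            raise ValueError("spectrum must be 6 probabilities summing to 1")
        for r in (self.mu_snv, self.mu_ins, self.mu_del):
            if r < 0:
                raise ValueError("mutation rates must be >= 0")
        for f in (self.gc_content, self.het_miscall_rate, self.missing_rate):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def line_ids(self) -> list[str]:
        return [f"{self.line_prefix}{i:02d}" for i in range(1, self.n_lines + 1)]

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TruthRecord:
    line_id: str
    contig: str
    pos: int  # 1-based; VCF anchor for indels
    mtype: str
    ref: str
    alt: str
    generation: int

    def key(self) -> tuple:
        return (self.contig, self.pos, self.line_id, self.ref, self.alt)


@dataclass
class TruthTable:
    """Planted ground truth: per-line accumulated mutations."""

    by_line: dict[str, list[TruthRecord]] = field(default_factory=dict)

    def all_records(self) -> list[TruthRecord]:
        return [r for recs in self.by_line.values() for r in recs]

    def size(self) -> int:
        return sum(len(v) for v in self.by_line.values())

    def counts_by_type(self) -> dict[str, int]:
        out = {SNV: 0, INSERTION: 0, DELETION: 0}
        for r in self.all_records():
            out[r.mtype] += 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("line\tcontig\tpos\ttype\tref\talt\tgeneration\n")
            for r in sorted(
                self.all_records(), key=lambda r: (r.contig, r.pos, r.line_id)
            ):
                fh.write(
                    f"{r.line_id}\t{r.contig}\t{r.pos}\t{r.mtype}\t"
                    f"{r.ref}\t{r.alt}\t{r.generation}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("line\t")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                table.by_line.setdefault(f[0], []).append(
                    TruthRecord(f[0], f[1], int(f[2]), f[3], f[4], f[5], int(f[6]))
                )
        return table


def _rng(params: SimParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stage])


def generate_founder(params: SimParams) -> GenomeRef:
    """Random founder genome with the requested expected GC fraction."""
    if params.genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    rng = _rng(params, 1)
    p_gc = params.gc_content / 2.0
    p_at = (1.0 - params.gc_content) / 2.0
    seq = rng.choice(
        np.array(list("ACGT")), size=params.genome_length, p=[p_at, p_gc, p_gc, p_at]
    )
    return GenomeRef({params.contig_name: "".join(seq)})


class _LineOccupancy:
    """Tracks per-line occupied positions to enforce minimum spacing."""

    def __init__(self, min_spacing: int):
        self.min_spacing = min_spacing
        self._positions: list[int] = []

    def ok(self, pos: int, span: int = 0) -> bool:
        import bisect

        i = bisect.bisect_left(self._positions, pos)
        for j in (i - 1, i):
            if 0 <= j < len(self._positions):
                if abs(self._positions[j] - pos) < max(self.min_spacing, 1) or (
                    span and pos <= self._positions[j] <= pos + span
                ):
                    return False
        return True

    def add(self, pos: int) -> None:
        import bisect

        bisect.insort(self._positions, pos)


def simulate_lines(genome: GenomeRef, params: SimParams) -> TruthTable:
    """Accumulate mutations independently in each line.

    Positions are uniform over non-N sites, subject to a per-line
    minimum spacing (``params.min_spacing``; 1 means only exact
    collisions are forbidden). Each record carries the generation in
    which it arose (uniform over 1..G — with neutral fixation the
    origin time does not affect the final state).
    """
    rng = _rng(params, 2)
    contig = params.contig_name
    seq = genome.contigs[contig]
    L = len(seq)
    G = params.generations
    table = TruthTable()
    expected = {
        SNV: params.mu_snv * L * G,
        INSERTION: params.mu_ins * L * G,
        DELETION: params.mu_del * L * G,
    }
    spectrum = np.asarray(params.spectrum)
    max_tries = 10_000

    for line in params.line_ids:
        occ = _LineOccupancy(params.min_spacing)
        records: list[TruthRecord] = []
        n_by_type = {t: rng.poisson(lam) for t, lam in expected.items()}
        for mtype, n in n_by_type.items():
            for _ in range(n):
                if mtype == SNV:
                    klass = SNV_CLASSES[rng.choice(6, p=spectrum)]
                    bases = compatible_classes(klass)
                    for _try in range(max_tries):
                        pos = int(rng.integers(1, L + 1))
                        ref = seq[pos - 1]
                        if ref in bases and occ.ok(pos):
                            break
                    else:
                        raise SimulationError("could not place SNV (genome too full)")
                    alt = class_alt_base(klass, ref)
                    rec = TruthRecord(
                        line, contig, pos, SNV, ref, alt, int(rng.integers(1, G + 1))
                    )
                else:
                    length = int(rng.geometric(1.0 / params.indel_length_mean))
                    for _try in range(max_tries):
                        pos = int(rng.integers(1, L + 1))
                        if mtype == DELETION and pos + length > L:
                            continue
                        span = length if mtype == DELETION else 0
                        segment = seq[pos - 1 : pos + span]
                        if "N" in segment:
                            continue
                        if occ.ok(pos, span=span):
                            break
                    else:
                        raise SimulationError("could not place indel (genome too full)")
                    anchor = seq[pos - 1]
                    if mtype == INSERTION:
                        ins = "".join(
                            rng.choice(np.array(list("ACGT")), size=length)
                        )
                        ref, alt = anchor, anchor + ins
                    else:
                        ref, alt = seq[pos - 1 : pos + length], anchor
                    rec = TruthRecord(
                        line, contig, pos, mtype, ref, alt, int(rng.integers(1, G + 1))
                    )
                occ.add(rec.pos)
                records.append(rec)
        table.by_line[line] = records

    if params.contamination is not None:
        src, dst, frac = params.contamination
        if src not in table.by_line or dst not in table.by_line:
            raise SimulationError("contamination lines not in simulated panel")
        dst_positions = {r.pos for r in table.by_line[dst]}
        for r in table.by_line[src]:
            if rng.random() < frac and r.pos not in dst_positions:
                table.by_line[dst].append(
                    TruthRecord(dst, r.contig, r.pos, r.mtype, r.ref, r.alt, r.generation)
                )
                dst_positions.add(r.pos)
    return table


@dataclass
class DepthTrack:
    """Per-site per-line read depth (lines x genome length), per contig."""

    line_ids: list[str]
    depth: dict[str, np.ndarray]  # contig -> (n_lines, L) array

    def dp(self, line_id: str, contig: str, pos: int) -> int:
        return int(self.depth[contig][self.line_ids.index(line_id), pos - 1])

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            line_ids=np.array(self.line_ids),
            **{f"depth_{c}": a for c, a in self.depth.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "DepthTrack":
        data = np.load(path)
        line_ids = [str(x) for x in data["line_ids"]]
        depth = {
            k[len("depth_") :]: data[k] for k in data.files if k.startswith("depth_")
        }
        return cls(line_ids=line_ids, depth=depth)


@dataclass
class SimulatedCalls:
    """Output of the genotyping emulator."""

    vcf_path: Path
    depth: DepthTrack
    n_dropped: int  # carrier genotypes emitted as missing
    line_ids: list[str]


def _vcf_header(genome: GenomeRef, line_ids: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, seq in genome.contigs.items():
        header.contigs.add(name, length=len(seq))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for line in line_ids:
        header.add_sample(line)
    return header


def _draw_gq(rng: np.random.Generator, params: SimParams) -> int:
    gq = rng.normal(params.gq_mean, params.gq_sd) if params.gq_sd > 0 else params.gq_mean
    return int(np.clip(round(gq), 0, 99))


def emulate_calling(
    genome: GenomeRef,
    truth: TruthTable,
    params: SimParams,
    out_dir: str | Path,
    vcf_name: str = "calls.vcf",
) -> SimulatedCalls:
    """Emulate multi-sample genotyping of the panel against the founder.

    Every truth mutation becomes a VCF record with its carrier line
    alt-homozygous (unless dropped to missing with ``missing_rate``);
    other lines are ref-homozygous, except that with probability
    ``het_miscall_rate`` a non-carrier is miscalled heterozygous. DP per
    call comes from a Poisson(coverage_mean) whole-genome depth track
    (returned for callable-length computation); GQ is a clamped normal
    around ``gq_mean``. Output is deterministic under a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(params, 3)
    line_ids = list(truth.by_line.keys())
    depth = DepthTrack(
        line_ids=line_ids,
        depth={
            c: rng.poisson(params.coverage_mean, size=(len(line_ids), len(s))).astype(
                np.uint16
            )
            for c, s in genome.contigs.items()
        },
    )

    # collate truth by (contig, pos, ref): carriers of each alt
    sites: dict[tuple[str, int, str], dict[str, list[str]]] = {}
    for rec in truth.all_records():
        sites.setdefault((rec.contig, rec.pos, rec.ref), {}).setdefault(
            rec.alt, []
        ).append(rec.line_id)

    vcf_path = out_dir / vcf_name
    header = _vcf_header(genome, line_ids)
    n_dropped = 0
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
        for (contig, pos, ref), alts in sorted(sites.items()):
            alt_alleles = sorted(alts)
            carrier_allele = {
                line: i + 1
                for i, alt in enumerate(alt_alleles)
                for line in alts[alt]
            }
            rec = vf.new_record(
                contig=contig, start=pos - 1, alleles=tuple([ref] + alt_alleles)
            )
            for li, line in enumerate(line_ids):
                s = rec.samples[line]
                dp = int(depth.depth[contig][li, pos - 1])
                if rng.random() < params.missing_rate:
                    s["GT"] = (None, None)
                    if line in carrier_allele:
                        n_dropped += 1
                    continue
                if line in carrier_allele:
                    s["GT"] = (carrier_allele[line], carrier_allele[line])
                elif rng.random() < params.het_miscall_rate:
                    s["GT"] = (0, 1)
                else:
                    s["GT"] = (0, 0)
                s["DP"] = dp
                s["GQ"] = _draw_gq(rng, params)
            vf.write(rec)
    return SimulatedCalls(
        vcf_path=vcf_path, depth=depth, n_dropped=n_dropped, line_ids=line_ids
    )


def write_toy_annotation(
    genome: GenomeRef,
    n_genes: int,
    seed: int,
    out_path: str | Path | None = None,
    genic_fraction: float = 0.5,
) -> Path:
    """Write a toy GFF3: non-overlapping genes, one CDS each.

    Genes jointly cover about ``genic_fraction`` of the genome; each
    gene's CDS is the gene body trimmed to a multiple of 3 (so codon
    consequence classification is well defined). Strands alternate
    deterministically from the seed.
    """
    rng = np.random.default_rng([seed, 4])
    out_path = Path(out_path) if out_path is not None else Path("toy_genes.gff3")
    lines = ["##gff-version 3"]
    gene_idx = 0
    for contig, seq in genome.contigs.items():
        L = len(seq)
        if n_genes == 0 or L < 30:
            continue
        n_here = n_genes
        gene_len = max(30, int(genic_fraction * L / n_here))
        gap = max(1, (L - n_here * gene_len) // (n_here + 1))
        cursor = 1 + int(rng.integers(0, max(1, gap)))
        for _ in range(n_here):
            start = cursor
            end = min(start + gene_len - 1, L)
            if end - start + 1 < 30:
                break
            gene_idx += 1
            gid = f"gene{gene_idx}"
            strand = "+" if rng.random() < 0.5 else "-"
            cds_len = ((end - start + 1) // 3) * 3
            cds_start, cds_end = start, start + cds_len - 1
            lines.append(
                f"{contig}\ttoy\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
            )
            lines.append(
                f"{contig}\ttoy\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}"
            )
            lines.append(
                f"{contig}\ttoy\tCDS\t{cds_start}\t{cds_end}\t.\t{strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}.t1"
            )
            cursor = end + 1 + gap
            if cursor >= L:
                break
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return out_path
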