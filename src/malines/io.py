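"""Readers and writers for the standard formats the pipeline touches.

Everything downstream works on the in-memory types defined here: a
:class:`GenomeRef` (the coordinate authority), a stream of
:class:`VariantSite` objects (one multi-sample VCF record restricted to
a group of MA lines), a :class:`GeneAnnotation` for genic/coding
queries, and a flat :class:`GroupConfig` mapping lines to groups.

Coordinates are 1-based inclusive throughout (VCF/GFF convention).
Indels are carried with their VCF anchor base and are assumed to be
left-aligned by the upstream caller; no re-normalization happens here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomeRef",
    "GenotypeCall",
    "VariantSite",
    "GroupConfig",
    "GeneModel",
    "GeneAnnotation",
    "ConfigurationError",
    "FormatError",
    "REF_HOM",
    "HET",
    "ALT_HOM",
    "MISSING",
    "read_genome",
    "write_genome",
    "read_vcf_matrix",
    "read_gff",
    "write_candidates",
    "read_candidates",
    "read_group_config",
]

# genotype classes
REF_HOM = "ref_hom"
HET = "het"
ALT_HOM = "alt_hom"
MISSING = "missing"

_VALID_BASES = frozenset("ACGTN")


class ConfigurationError(ValueError):
    """A group/sample configuration problem (e.g. sample absent from the VCF)."""


class FormatError(ValueError):
    """A malformed input file (e.g. missing FORMAT tag, duplicate contig)."""


class GenomeRef:
    """Reference genome: contig sequences plus base-composition tallies.

    Sequences are upper-cased on load and restricted to the alphabet
    {A, C, G, T, N}. Composition tallies (GC / AT / N counts) are kept
    per contig and genome-wide; the AT+GC+N counts always sum to the
    genome length, and the tallies are invariant under contig order.
    """

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs: dict[str, str] = {}
        self.composition: dict[str, dict[str, int]] = {}
        for name, seq in contigs.items():
            seq = str(seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            self.contigs[name] = seq
            self.composition[name] = {
                "gc": seq.count("G") + seq.count("C"),
                "at": seq.count("A") + seq.count("T"),
                "n": seq.count("N"),
            }

    @property
    def gc_count(self) -> int:
        return sum(c["gc"] for c in self.composition.values())

    @property
    def at_count(self) -> int:
        return sum(c["at"] for c in self.composition.values())

    @property
    def n_count(self) -> int:
        return sum(c["n"] for c in self.composition.values())

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def base(self, contig: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.contigs[contig][pos - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Sequence for a 1-based inclusive interval."""
        return self.contigs[contig][start - 1 : end]


def read_genome(fasta_path: str | Path) -> GenomeRef:
    """Load a FASTA file into a :class:`GenomeRef`.

    Raises :class:`FormatError` on duplicate contig names.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r} in {fasta_path}")
        contigs[rec.id] = str(rec.seq)
    return GenomeRef(contigs)


def write_genome(genome: GenomeRef, fasta_path: str | Path, width: int = 70) -> None:
    """Write a :class:`GenomeRef` as FASTA (fixed line width, contig order kept)."""
    with open(fasta_path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site, with its VCF DP and GQ."""

    line_id: str
    gclass: str  # one of REF_HOM, HET, ALT_HOM, MISSING
    dp: int = 0
    gq: int = 0
    alt_index: int | None = None  # 0-based index into VariantSite.alts

    def __post_init__(self) -> None:
        if self.gclass in (HET, ALT_HOM) and self.alt_index is None:
            raise ValueError("alt_index required for het/alt_hom calls")


@dataclass
class VariantSite:
    """One multi-sample VCF record restricted to a group of lines."""

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    calls: tuple[GenotypeCall, ...]

    def call(self, line_id: str) -> GenotypeCall:
        for c in self.calls:
            if c.line_id == line_id:
                return c
        raise KeyError(line_id)


@dataclass
class GroupConfig:
    """One MA group: its lines, generation count, and excluded lines.

    Excluded lines (contaminated or swapped samples) are dropped before
    any criterion is evaluated; they do not contribute support, hets,
    or depth anywhere downstream.
    """

    group_name: str
    line_ids: list[str]
    generations: int
    excluded_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.line_ids) < 2:
            raise ConfigurationError(
                f"group {self.group_name!r} needs at least 2 lines"
            )
        if self.generations <= 0:
            raise ConfigurationError("generations must be positive")

    @property
    def active_lines(self) -> list[str]:
        return [l for l in self.line_ids if l not in self.excluded_lines]


def _classify_gt(gt: tuple | None) -> tuple[str, int | None]:
    if gt is None or all(a is None for a in gt):
        return MISSING, None
    alleles = [a for a in gt if a is not None]
    if all(a == 0 for a in alleles):
        return REF_HOM, None
    if len(set(alleles)) == 1 and len(alleles) >= 2:
        return ALT_HOM, alleles[0] - 1
    # mixed (or half-missing with a non-ref allele): heterozygous
    first_alt = next(a for a in alleles if a > 0)
    return HET, first_alt - 1


def read_vcf_matrix(
    vcf_path: str | Path, group: GroupConfig
) -> Iterator[VariantSite]:
    """Stream a multi-sample VCF as :class:`VariantSite` objects.

    Genotype classes derive from GT (0/0 -> ref_hom, 0/1 -> het,
    1/1 -> alt_hom, ./. -> missing); multi-allelic records are kept
    whole, with ``alt_index`` pointing at the called alt. A missing DP
    with a present GT is treated as DP=0 (fails every depth threshold).
    """
    with pysam.VariantFile(str(vcf_path)) as vf:
        for tag in ("GT", "DP", "GQ"):
            if tag not in vf.header.formats:
                raise FormatError(f"VCF {vcf_path} lacks FORMAT tag {tag}")
        samples = set(vf.header.samples)
        for line in group.active_lines:
            if line not in samples:
                raise ConfigurationError(
                    f"sample {line!r} of group {group.group_name!r} "
                    f"not found in VCF {vcf_path}"
                )
        for rec in vf:
            calls = []
            for line in group.active_lines:
                s = rec.samples[line]
                gclass, alt_index = _classify_gt(s.get("GT"))
                dp = s.get("DP")
                gq = s.get("GQ")
                calls.append(
                    GenotypeCall(
                        line_id=line,
                        gclass=gclass,
                        dp=int(dp) if dp is not None else 0,
                        gq=int(gq) if gq is not None else 0,
                        alt_index=alt_index,
                    )
                )
            yield VariantSite(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts or ()),
                calls=tuple(calls),
            )


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)


class GeneAnnotation:
    """Gene and CDS intervals, queryable by point position (1-based)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._cds_trees: dict[str, IntervalTree] = {}
        for g in genes:
            gt = self._gene_trees.setdefault(g.contig, IntervalTree())
            gt[g.start : g.end + 1] = g.gene_id
            ct = self._cds_trees.setdefault(g.contig, IntervalTree())
            for s, e, _ in g.cds:
                ct[s : e + 1] = g.gene_id

    def genes_at(self, contig: str, pos: int) -> list[GeneModel]:
        tree = self._gene_trees.get(contig)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in sorted(tree[pos], key=lambda i: i.data)]

    def is_genic(self, contig: str, pos: int) -> bool:
        tree = self._gene_trees.get(contig)
        return bool(tree is not None and tree[pos])

    def cds_genes_at(self, contig: str, pos: int) -> list[GeneModel]:
        tree = self._cds_trees.get(contig)
        if tree is None:
            return []
        ids = sorted({iv.data for iv in tree[pos]})
        return [self.genes[i] for i in ids]

    def is_cds(self, contig: str, pos: int) -> bool:
        tree = self._cds_trees.get(contig)
        return bool(tree is not None and tree[pos])


def read_gff(gff_path: str | Path) -> GeneAnnotation:
    """Load gene and CDS features from a GFF3 file.

    CDS features without a parent gene trigger a warning and are kept
    as orphan single-CDS gene models (they still count as genic/CDS).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.id
        genes[gid] = GeneModel(
            gene_id=gid,
            contig=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
        )

    def _owner(feat) -> str | None:
        # walk up Parent chain (CDS -> mRNA -> gene, or CDS -> gene)
        seen = set()
        queue = list(feat.attributes.get("Parent", []))
        while queue:
            pid = queue.pop(0)
            if pid in seen:
                continue
            seen.add(pid)
            if pid in genes:
                return pid
            try:
                parent = db[pid]
            except Exception:
                continue
            queue.extend(parent.attributes.get("Parent", []))
        return None

    n_orphan = 0
    for feat in db.features_of_type("CDS"):
        gid = _owner(feat)
        phase = int(feat.frame) if feat.frame not in (None, ".") else 0
        if gid is None:
            n_orphan += 1
            gid = f"orphan_cds_{feat.seqid}_{feat.start}"
            genes[gid] = GeneModel(
                gene_id=gid,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        genes[gid].cds.append((feat.start, feat.end, phase))
    if n_orphan:
        warnings.warn(f"{n_orphan} CDS feature(s) without a parent gene kept as orphans")
    for g in genes.values():
        g.cds.sort()
    return GeneAnnotation(list(genes.values()))


_CANDIDATE_COLUMNS = ["contig", "pos", "line", "type", "ref", "alt", "consequence"]


def write_candidates(candidates: Iterable, out_path: str | Path) -> None:
    """Write candidate mutations as a TSV sorted by (contig, pos, line).

    An empty list yields a header-only file. The ``consequence`` column
    is "." unless a consequence label has been attached.
    """
    rows = [
        {
            "contig": c.contig,
            "pos": c.pos,
            "line": c.line_id,
            "type": c.mtype,
            "ref": c.ref,
            "alt": c.alt,
            "consequence": getattr(c, "consequence", None) or ".",
        }
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    if len(df):
        df = df.sort_values(["contig", "pos", "line"], kind="stable")
    df.to_csv(out_path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list:
    """Read back a candidate TSV written by :func:`write_candidates`."""
    from .filtering import CandidateMutation  # local import: avoid cycle

    df = pd.read_csv(
        path, sep="\t", dtype={"contig": str, "ref": str, "alt": str, "line": str}
    )
    out = []
    for row in df.itertuples(index=False):
        c = CandidateMutation(
            line_id=row.line,
            contig=row.contig,
            pos=int(row.pos),
            mtype=row.type,
            ref=row.ref,
            alt=row.alt,
        )
        if row.consequence != ".":
            c.consequence = row.consequence
        out.append(c)
    return out


def read_group_config(path: str | Path) -> dict[str, GroupConfig]:
    """Parse a flat key-value group configuration file.

    Recognized keys (one ``key = value`` pair per line, '#' comments)::

        sample.<line_id>.group = <group_name>
        group.<group_name>.generations = <int>
        group.<group_name>.excluded = <comma-separated line ids>
    """
    members: dict[str, list[str]] = {}
    generations: dict[str, int] = {}
    excluded: dict[str, list[str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"cannot parse config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            parts = key.split(".")
            if parts[0] == "sample" and len(parts) == 3 and parts[2] == "group":
                members.setdefault(value, []).append(parts[1])
            elif parts[0] == "group" and len(parts) == 3:
                if parts[2] == "generations":
                    generations[parts[1]] = int(value)
                elif parts[2] == "excluded":
                    excluded[parts[1]] = [
                        v.strip() for v in value.split(",") if v.strip()
                    ]
                else:
                    raise FormatError(f"unknown config key {key!r}")
            else:
                raise FormatError(f"unknown config key {key!r}")
    groups = {}
    for name, lines in members.items():
        if name not in generations:
            raise ConfigurationError(f"group {name!r} has no generations entry")
        groups[name] = GroupConfig(
            group_name=name,
            line_ids=lines,
            generations=generations[name],
            excluded_lines=excluded.get(name, []),
        )
    return groups
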