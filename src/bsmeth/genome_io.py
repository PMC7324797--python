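"""Genome sequence and gene-annotation handling.

Reads FASTA genomes and gene/exon GFF3 annotations, and derives the
exon / intron / intergenic partition used for feature-stratified
methylation reporting.  All internal coordinates are 0-based half-open;
the on-disk formats (FASTA irrelevant, GFF3 1-based inclusive) are
converted at the read/write boundary and nowhere else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomeSequence",
    "GeneModel",
    "FeatureAnnotation",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "classify_position",
    "nucleotide_frequencies",
    "ContextFrequencyTable",
]

VALID_BASES = frozenset("ACGTN")

#: feature-class codes used in the per-contig position masks
INTERGENIC, EXON, INTRON = 0, 1, 2
_CLASS_NAMES = {INTERGENIC: "intergenic", EXON: "exon", INTRON: "intron"}


class FormatError(ValueError):
    """A malformed input file (bad FASTA/GFF3/CX content)."""


@dataclass
class GenomeSequence:
    """An ordered collection of contigs, uppercase over {A,C,G,T,N}."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not cid:
                raise FormatError("empty contig id")
            if len(seq) < 1:
                raise FormatError(f"contig {cid!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {cid!r} contains illegal characters {sorted(bad)}"
                )

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_ids(self) -> list[str]:
        return list(self.contigs)


@dataclass
class GeneModel:
    """A gene span with its exons; introns are the within-span gaps.

    Coordinates are 0-based half-open on the contig.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id}: end must exceed start")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene span"
                )
            if e <= s:
                raise FormatError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


class FeatureAnnotation:
    """Gene models plus a per-contig map position -> feature class.

    Every position belongs to exactly one of exon / intron / intergenic;
    where genes overlap, exon takes precedence over intron over
    intergenic.  Genic means exon-or-intron.
    """

    def __init__(self, genes: list[GeneModel], contig_lengths: dict[str, int]):
        self.genes = list(genes)
        self.contig_lengths = dict(contig_lengths)
        self._masks: dict[str, np.ndarray] = {
            cid: np.zeros(n, dtype=np.uint8) for cid, n in contig_lengths.items()
        }
        # paint introns first, then exons, so exon wins within and across genes
        for g in self.genes:
            if g.contig not in self._masks:
                raise FormatError(f"gene {g.gene_id} on unknown contig {g.contig!r}")
            if g.end > self.contig_lengths[g.contig]:
                raise FormatError(
                    f"gene {g.gene_id} extends past contig {g.contig!r} "
                    f"(length {self.contig_lengths[g.contig]})"
                )
            m = self._masks[g.contig]
            m[g.start : g.end][m[g.start : g.end] == INTERGENIC] = INTRON
        for g in self.genes:
            m = self._masks[g.contig]
            for s, e in g.exons:
                m[s:e] = EXON

    @classmethod
    def from_genome(cls, genes: list[GeneModel], genome: GenomeSequence) -> "FeatureAnnotation":
        return cls(genes, {c: genome.length(c) for c in genome.contig_ids()})

    def mask(self, contig: str) -> np.ndarray:
        return self._masks[contig]

    def classify(self, contig: str, pos: int) -> str:
        if contig not in self._masks:
            raise KeyError(f"unknown contig {contig!r}")
        if not 0 <= pos < self.contig_lengths[contig]:
            raise IndexError(
                f"position {pos} out of range for contig {contig!r} "
                f"(length {self.contig_lengths[contig]})"
            )
        return _CLASS_NAMES[int(self._masks[contig][pos])]

    def regions(self, feature_class: str) -> list[tuple[str, int, int]]:
        """Maximal runs of one class, as (contig, start, end) half-open."""
        if feature_class == "genome":
            return [(c, 0, n) for c, n in self.contig_lengths.items()]
        if feature_class == "genic":
            wanted = {EXON, INTRON}
        else:
            code = {v: k for k, v in _CLASS_NAMES.items()}.get(feature_class)
            if code is None:
                raise ValueError(f"unknown feature class {feature_class!r}")
            wanted = {code}
        out = []
        for cid, m in self._masks.items():
            hit = np.isin(m, list(wanted)).astype(np.int8)
            d = np.diff(np.concatenate(([0], hit, [0])))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            out.extend((cid, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def class_sizes(self) -> dict[str, int]:
        sizes = {"exon": 0, "intron": 0, "intergenic": 0}
        for m in self._masks.values():
            counts = np.bincount(m, minlength=3)
            sizes["intergenic"] += int(counts[INTERGENIC])
            sizes["exon"] += int(counts[EXON])
            sizes["intron"] += int(counts[INTRON])
        return sizes


def classify_position(annotation: FeatureAnnotation, contig: str, pos: int) -> str:
    """Feature class ('exon' | 'intron' | 'intergenic') at a 0-based position."""
    return annotation.classify(contig, pos)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    contigs: dict[str, str] = {}
    for rec in records:
        if rec.id in contigs:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    for cid, seq in contigs.items():
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {cid!r} has illegal characters {sorted(bad)} "
                f"(first on line {_find_bad_line(path, bad)})"
            )
    return GenomeSequence(contigs)


def _find_bad_line(path, bad_chars: set[str]) -> int:
    bad_upper = {c.upper() for c in bad_chars} | {c.lower() for c in bad_chars}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.rstrip("\n")) & bad_upper:
                return lineno
    return -1


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _parse_attributes(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_gff3(path, genome: GenomeSequence) -> FeatureAnnotation:
    """Read `gene` and `exon` features into a :class:`FeatureAnnotation`.

    Exons are attached to their gene via the ``Parent`` attribute.
    Coordinates are validated against the genome's contig lengths.
    """
    gene_rows: dict[str, dict] = {}
    exon_rows: list[tuple[str, str, int, int]] = []  # parent, contig, start0, end
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            if ftype not in ("gene", "exon"):
                continue
            if contig not in genome:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            s1, e1 = int(start), int(end)
            if s1 < 1 or e1 > genome.length(contig) or e1 < s1:
                raise FormatError(
                    f"{path}:{lineno}: coordinates {s1}..{e1} out of bounds "
                    f"for contig {contig!r} (length {genome.length(contig)})"
                )
            a = _parse_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if not gid:
                    raise FormatError(f"{path}:{lineno}: gene without ID attribute")
                if gid in gene_rows:
                    raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                gene_rows[gid] = {
                    "contig": contig,
                    "strand": strand,
                    "start": s1 - 1,
                    "end": e1,
                    "exons": [],
                }
            else:
                parent = a.get("Parent")
                if not parent:
                    raise FormatError(f"{path}:{lineno}: exon without Parent attribute")
                exon_rows.append((parent, contig, s1 - 1, e1))
    for parent, contig, s0, e0 in exon_rows:
        if parent not in gene_rows:
            raise FormatError(f"{path}: exon Parent {parent!r} not a known gene")
        g = gene_rows[parent]
        if contig != g["contig"]:
            raise FormatError(f"{path}: exon of {parent!r} on wrong contig")
        if s0 < g["start"] or e0 > g["end"]:
            raise FormatError(f"{path}: exon [{s0},{e0}) outside span of gene {parent!r}")
        g["exons"].append((s0, e0))
    genes = [
        GeneModel(gid, g["contig"], g["strand"], g["start"], g["end"], g["exons"])
        for gid, g in gene_rows.items()
    ]
    return FeatureAnnotation.from_genome(genes, genome)


def write_gff3(annotation: FeatureAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            fh.write(
                f"{g.contig}\tbsmeth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\tbsmeth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# nucleotide / k-mer frequencies

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_BASES = "ACGT"
_DINUCS = [a + b for a in _BASES for b in _BASES]
_TRINUCS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


@dataclass
class ContextFrequencyTable:
    """Overlapping-window mono/di/trinucleotide counts for a region set.

    Windows containing N are excluded from both the counts and the
    window totals, so frequencies within each k-mer order sum to 1
    whenever any valid window exists.
    """

    mono_counts: dict[str, int]
    di_counts: dict[str, int]
    tri_counts: dict[str, int]
    n_mono: int
    n_di: int
    n_tri: int
    label: str = "genome"

    @property
    def empty(self) -> bool:
        return self.n_mono == 0

    def freq(self, kmer: str) -> float:
        kmer = kmer.upper()
        table, total = {
            1: (self.mono_counts, self.n_mono),
            2: (self.di_counts, self.n_di),
            3: (self.tri_counts, self.n_tri),
        }[len(kmer)]
        if total == 0:
            return float("nan")
        return table.get(kmer, 0) / total

    def __add__(self, other: "ContextFrequencyTable") -> "ContextFrequencyTable":
        def merge(a, b):
            return {k: a.get(k, 0) + b.get(k, 0) for k in set(a) | set(b)}

        return ContextFrequencyTable(
            merge(self.mono_counts, other.mono_counts),
            merge(self.di_counts, other.di_counts),
            merge(self.tri_counts, other.tri_counts),
            self.n_mono + other.n_mono,
            self.n_di + other.n_di,
            self.n_tri + other.n_tri,
            label=self.label,
        )


def _count_region(codes: np.ndarray):
    valid = codes < 4
    mono = np.bincount(codes[valid], minlength=4)
    c0, c1 = codes[:-1], codes[1:]
    dv = (c0 < 4) & (c1 < 4)
    di = np.bincount((c0[dv].astype(np.intp) * 4 + c1[dv]), minlength=16)
    if len(codes) >= 3:
        t0, t1, t2 = codes[:-2], codes[1:-1], codes[2:]
        tv = (t0 < 4) & (t1 < 4) & (t2 < 4)
        tri = np.bincount(
            t0[tv].astype(np.intp) * 16 + t1[tv].astype(np.intp) * 4 + t2[tv],
            minlength=64,
        )
        n_tri = int(tv.sum())
    else:
        tri = np.zeros(64, dtype=np.intp)
        n_tri = 0
    return mono, int(valid.sum()), di, int(dv.sum()), tri, n_tri


def nucleotide_frequencies(
    genome: GenomeSequence,
    regions: list[tuple[str, int, int]] | None = None,
    label: str = "genome",
) -> ContextFrequencyTable:
    """Pooled plus-strand k-mer frequencies over a region set.

    Windows never span a region boundary; counts and window totals are
    summed over regions before frequencies are formed.  ``regions`` are
    (contig, start, end) 0-based half-open; omitted means whole genome.
    """
    if regions is None:
        regions = [(c, 0, genome.length(c)) for c in genome.contig_ids()]
    if not regions:
        raise ValueError("empty region set")
    mono = np.zeros(4, dtype=np.int64)
    di = np.zeros(16, dtype=np.int64)
    tri = np.zeros(64, dtype=np.int64)
    n1 = n2 = n3 = 0
    for contig, start, end in regions:
        if contig not in genome:
            raise KeyError(f"region on unknown contig {contig!r}")
        if not (0 <= start < end <= genome.length(contig)):
            raise ValueError(f"region ({contig},{start},{end}) out of bounds")
        seq = genome[contig][start:end]
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        m, nm, d, nd, t, nt = _count_region(codes)
        mono += m
        di += d
        tri += t
        n1 += nm
        n2 += nd
        n3 += nt
    return ContextFrequencyTable(
        {b: int(mono[i]) for i, b in enumerate(_BASES)},
        {k: int(di[i]) for i, k in enumerate(_DINUCS)},
        {k: int(tri[i]) for i, k in enumerate(_TRINUCS)},
        n1,
        n2,
        n3,
        label=label,
    )
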