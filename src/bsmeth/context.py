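"""Cytosine sequence-context classification and observed/expected ratios.

A cytosine's context is decided by the two bases that follow it 5'->3'
on its own strand: CpG if the next base is G; otherwise CHG if the base
after next is G; otherwise CHH (H = A, C or T).  Minus-strand cytosines
appear as G on the reference (plus) strand and are read leftwards with
complementation.  A context is UNDEFINED when an N or the contig edge
falls inside the trinucleotide.

The O/E ratios compare the observed frequency of a context against the
frequency expected from base composition under independence; values
below 1 indicate depletion (the classical CpG O/E of invertebrate
genomes, extended here to CHG and CHH):

    CpG_O/E = F_CpG / (F_C * F_G)
    CHG_O/E = (F_CAG + F_CTG + F_CCG) / (F_C * (1 - F_G) * F_G)
    CHH_O/E = sum_{H1,H2 in {A,C,T}} F_CH1H2 / (F_C * (1 - F_G)^2)

where F is a plus-strand frequency over overlapping windows and
(1 - F_G) is the total frequency of non-G bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genome_io import ContextFrequencyTable, FeatureAnnotation, GenomeSequence

__all__ = [
    "ContextClass",
    "OeRatios",
    "classify_context",
    "enumerate_cytosines",
    "cytosine_table",
    "oe_cpg",
    "oe_chg",
    "oe_chh",
    "oe_profile",
    "CHH_TRINUCLEOTIDES",
    "CHG_TRINUCLEOTIDES",
]


class ContextClass(str, Enum):
    CpG = "CpG"
    CHG = "CHG"
    CHH = "CHH"
    UNDEFINED = "UNDEFINED"

    @classmethod
    def from_bismark(cls, label: str) -> "ContextClass":
        return {"CG": cls.CpG, "CHG": cls.CHG, "CHH": cls.CHH}[label]

    @property
    def bismark(self) -> str:
        return {"CpG": "CG", "CHG": "CHG", "CHH": "CHH"}[self.value]


CHG_TRINUCLEOTIDES = ("CAG", "CTG", "CCG")
CHH_TRINUCLEOTIDES = tuple(
    "C" + h1 + h2 for h1 in "ACT" for h2 in "ACT"
)  # the nine canonical C-H-H trimers

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def classify_context(
    genome: GenomeSequence, contig: str, pos: int, strand: str
) -> ContextClass:
    """Context of the cytosine at 0-based ``pos`` on the given strand.

    On the minus strand the reference base at ``pos`` must be G (a
    cytosine on the reverse complement).
    """
    seq = genome[contig]
    base = seq[pos]
    if strand == "+":
        if base != "C":
            raise ValueError(f"{contig}:{pos}+ is {base}, not a plus-strand cytosine")
        nxt = seq[pos + 1] if pos + 1 < len(seq) else "N"
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
        down1, down2 = nxt, nxt2
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{contig}:{pos}- is {base}, not a minus-strand cytosine")
        down1 = _COMP[seq[pos - 1]] if pos - 1 >= 0 else "N"
        down2 = _COMP[seq[pos - 2]] if pos - 2 >= 0 else "N"
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if down1 == "G":
        return ContextClass.CpG
    if down1 == "N":
        return ContextClass.UNDEFINED
    if down2 == "G":
        return ContextClass.CHG
    if down2 == "N":
        return ContextClass.UNDEFINED
    return ContextClass.CHH


_CTX_LABELS = np.array(["CpG", "CHG", "CHH", "UNDEFINED"])


def _classify_strand(codes: np.ndarray, positions: np.ndarray, minus: bool) -> np.ndarray:
    """Vectorised context codes (0=CpG,1=CHG,2=CHH,3=UNDEF) for one strand."""
    n = len(codes)
    pad = np.full(2, 4, dtype=codes.dtype)
    if not minus:
        ext = np.concatenate([codes, pad])
        d1 = ext[positions + 1]
        d2 = ext[positions + 2]
        g_code = 2  # G on plus strand
    else:
        ext = np.concatenate([pad, codes])
        d1 = ext[positions + 2 - 1]  # pos-1 in padded coords
        d2 = ext[positions + 2 - 2]
        g_code = 1  # complement of C is G: downstream-G means reference C
    out = np.full(len(positions), 2, dtype=np.uint8)  # default CHH
    out[d1 == g_code] = 0  # CpG
    undef = (d1 == 4) | ((d1 != g_code) & (d2 == 4))
    chg = (d1 != g_code) & (d1 != 4) & (d2 == g_code)
    out[chg] = 1
    out[undef] = 3
    return out


def cytosine_table(genome: GenomeSequence) -> pd.DataFrame:
    """All cytosines on both strands as a DataFrame.

    Columns: contig, pos (0-based), strand, context, tri (5'->3' on the
    cytosine's strand).  Sorted by (contig, pos, strand) with '+'
    before '-'; contigs in lexicographic order.
    """
    from .genome_io import _CODE

    frames = []
    for contig in sorted(genome.contig_ids()):
        seq = genome[contig]
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        plus_pos = np.flatnonzero(codes == 1)  # C
        minus_pos = np.flatnonzero(codes == 2)  # G
        ctx_p = _classify_strand(codes, plus_pos, minus=False)
        ctx_m = _classify_strand(codes, minus_pos, minus=True)
        tri_p = _tri_strings(seq, plus_pos, minus=False)
        tri_m = _tri_strings(seq, minus_pos, minus=True)
        df = pd.DataFrame(
            {
                "contig": contig,
                "pos": np.concatenate([plus_pos, minus_pos]),
                "strand": ["+"] * len(plus_pos) + ["-"] * len(minus_pos),
                "context": np.concatenate([_CTX_LABELS[ctx_p], _CTX_LABELS[ctx_m]]),
                "tri": tri_p + tri_m,
            }
        )
        df = df.sort_values(
            ["pos", "strand"], ascending=[True, True], kind="mergesort"
        ).reset_index(drop=True)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "strand", "context", "tri"])
    return pd.concat(frames, ignore_index=True)


def _tri_strings(seq: str, positions: np.ndarray, minus: bool) -> list[str]:
    padded = "NN" + seq + "NN"
    if not minus:
        return [padded[p + 2 : p + 5] for p in positions]
    return [_revcomp(padded[p : p + 3]) for p in positions]


def enumerate_cytosines(genome: GenomeSequence):
    """Yield (contig, pos, strand, ContextClass, trinucleotide) per cytosine."""
    table = cytosine_table(genome)
    for row in table.itertuples(index=False):
        yield (row.contig, int(row.pos), row.strand, ContextClass(row.context), row.tri)


# ---------------------------------------------------------------------------
# observed / expected ratios

@dataclass
class OeRatios:
    label: str
    cpg_oe: float
    chg_oe: float
    chh_oe: float
    n_windows: int = 0

    @property
    def defined(self) -> bool:
        return not any(math.isnan(x) for x in (self.cpg_oe, self.chg_oe, self.chh_oe))


def oe_cpg(freq: ContextFrequencyTable) -> float:
    """CpG observed/expected: F_CpG / (F_C * F_G)."""
    if freq.empty:
        return float("nan")
    denom = freq.freq("C") * freq.freq("G")
    if denom == 0 or math.isnan(denom):
        return float("nan")
    return freq.freq("CG") / denom


def oe_chg(freq: ContextFrequencyTable) -> float:
    """CHG observed/expected: (F_CAG + F_CTG + F_CCG) / (F_C (1-F_G) F_G)."""
    if freq.empty:
        return float("nan")
    fg = freq.freq("G")
    denom = freq.freq("C") * (1.0 - fg) * fg
    if denom == 0 or math.isnan(denom):
        return float("nan")
    num = sum(freq.freq(t) for t in CHG_TRINUCLEOTIDES)
    return num / denom


def oe_chh(freq: ContextFrequencyTable) -> float:
    """CHH observed/expected: sum of nine F_CHH / (F_C (1-F_G)^2)."""
    if freq.empty:
        return float("nan")
    fg = freq.freq("G")
    denom = freq.freq("C") * (1.0 - fg) ** 2
    if denom == 0 or math.isnan(denom):
        return float("nan")
    num = sum(freq.freq(t) for t in CHH_TRINUCLEOTIDES)
    return num / denom


REGION_CLASSES = ("genome", "genic", "intergenic", "exon", "intron")


def oe_profile(
    genome: GenomeSequence,
    annotation: FeatureAnnotation,
    region_classes: tuple[str, ...] = REGION_CLASSES,
) -> pd.DataFrame:
    """O/E ratios per region class, frequencies pooled across regions.

    Returns a DataFrame with columns region_class, n_windows, cpg_oe,
    chg_oe, chh_oe; empty classes yield NaN ratios.
    """
    from .genome_io import nucleotide_frequencies

    rows = []
    for cls in region_classes:
        regions = annotation.regions(cls)
        if not regions:
            rows.append(
                {"region_class": cls, "n_windows": 0, "cpg_oe": float("nan"),
                 "chg_oe": float("nan"), "chh_oe": float("nan")}
            )
            continue
        freq = nucleotide_frequencies(genome, regions, label=cls)
        rows.append(
            {
                "region_class": cls,
                "n_windows": freq.n_tri,
                "cpg_oe": oe_cpg(freq),
                "chg_oe": oe_chg(freq),
                "chh_oe": oe_chh(freq),
            }
        )
    return pd.DataFrame(rows)
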