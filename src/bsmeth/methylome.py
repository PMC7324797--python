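"""Cytosine-level methylation calls: CX report I/O and stratified summaries.

A methylome sample holds one row per strand-specific cytosine with
methylated / unmethylated call counts.  Methylation levels are
call-weighted: percent = 100 * sum(methylated) / sum(all calls) over
the sites in a stratum, so zero-coverage sites are listed but never
enter a denominator.  Replicate summaries report the unweighted mean
and sample (n-1) SD of a statistic across biological replicates.

On disk the format is the Bismark cytosine (CX) report: a headerless
7-column TSV of contig, 1-based position, strand, methylated calls,
unmethylated calls, context (CG/CHG/CHH) and trinucleotide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import ContextClass, cytosine_table
from .genome_io import FeatureAnnotation, FormatError, GenomeSequence

__all__ = [
    "CytosineSite",
    "MethylomeSample",
    "MethylationSummary",
    "ReplicateSummary",
    "read_cx_report",
    "write_cx_report",
    "global_methylation_percent",
    "methylation_by_feature",
    "strand_report",
    "replicate_summary",
]

CX_COLUMNS = ["contig", "pos", "strand", "meth", "unmeth", "context", "tri"]

_BISMARK_TO_INTERNAL = {"CG": "CpG", "CHG": "CHG", "CHH": "CHH"}
_INTERNAL_TO_BISMARK = {v: k for k, v in _BISMARK_TO_INTERNAL.items()}


@dataclass
class CytosineSite:
    """A single strand-specific cytosine (positions 0-based internally)."""

    contig: str
    pos: int
    strand: str
    meth: int
    unmeth: int
    context: ContextClass
    tri: str

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth

    @property
    def level(self) -> float:
        return self.meth / self.coverage if self.coverage else float("nan")


@dataclass
class MethylomeSample:
    """One biological replicate's cytosine-level methylation calls.

    ``sites`` columns: contig, pos (0-based), strand, meth, unmeth,
    context ('CpG'/'CHG'/'CHH'), tri; sorted by (contig, pos, strand),
    '+' before '-', no duplicate keys.
    """

    sample_id: str
    group: str
    replicate: str
    sites: pd.DataFrame
    context_mismatches: int = 0

    def __post_init__(self) -> None:
        if list(self.sites.columns) != CX_COLUMNS:
            self.sites = self.sites[CX_COLUMNS]
        if (self.sites["meth"] < 0).any() or (self.sites["unmeth"] < 0).any():
            raise FormatError(f"sample {self.sample_id}: negative call counts")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def coverage(self) -> pd.Series:
        return self.sites["meth"] + self.sites["unmeth"]

    def site(self, i: int) -> CytosineSite:
        r = self.sites.iloc[i]
        return CytosineSite(
            r["contig"], int(r["pos"]), r["strand"], int(r["meth"]),
            int(r["unmeth"]), ContextClass(r["context"]), r["tri"],
        )


@dataclass
class MethylationSummary:
    """Pooled call counts and percent methylation for one stratum."""

    label: str
    meth_calls: int
    total_calls: int

    @property
    def percent(self) -> float:
        if self.total_calls == 0:
            return float("nan")
        return 100.0 * self.meth_calls / self.total_calls

    @property
    def defined(self) -> bool:
        return self.total_calls > 0


@dataclass
class ReplicateSummary:
    """Mean +/- sample SD of a statistic across biological replicates."""

    label: str
    values: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1))


def _sort_sites(df: pd.DataFrame) -> pd.DataFrame:
    # '+' sorts before '-' in ASCII, which matches the wanted strand order
    return df.sort_values(
        ["contig", "pos", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def read_cx_report(
    path,
    genome: GenomeSequence | None = None,
    sample_id: str | None = None,
    group: str = "",
    replicate: str = "",
) -> MethylomeSample:
    """Load a Bismark CX cytosine report.

    Positions are converted to the internal 0-based convention and the
    context column to internal labels.  With a genome supplied, contexts
    are re-derived from the sequence and disagreements counted in
    ``context_mismatches``.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CX_COLUMNS,
            dtype={"contig": str, "strand": str, "context": str, "tri": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CX_COLUMNS)
    if len(df):
        if df["tri"].isna().any():
            raise FormatError(f"{path}: expected 7 tab-separated columns")
        for col in ("pos", "meth", "unmeth"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[["pos", "meth", "unmeth"]].isna().any().any():
            raise FormatError(f"{path}: malformed numeric columns (expected 7 columns)")
        if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
            raise FormatError(f"{path}: negative call counts")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise FormatError(
                f"{path}: invalid strand {df.loc[bad_strand, 'strand'].iloc[0]!r}"
            )
        bad_ctx = ~df["context"].isin(_BISMARK_TO_INTERNAL)
        if bad_ctx.any():
            raise FormatError(
                f"{path}: invalid context {df.loc[bad_ctx, 'context'].iloc[0]!r}"
            )
        dup = df.duplicated(["contig", "pos", "strand"])
        if dup.any():
            r = df[dup].iloc[0]
            raise FormatError(
                f"{path}: duplicate site ({r['contig']},{r['pos']},{r['strand']})"
            )
        df["pos"] = df["pos"].astype(np.int64) - 1  # disk is 1-based
        df["meth"] = df["meth"].astype(np.int64)
        df["unmeth"] = df["unmeth"].astype(np.int64)
        df["context"] = df["context"].map(_BISMARK_TO_INTERNAL)
        df = _sort_sites(df)
    mismatches = 0
    if genome is not None and len(df):
        ref = cytosine_table(genome)
        ref = ref[ref["context"] != "UNDEFINED"]
        merged = df.merge(
            ref[["contig", "pos", "strand", "context"]],
            on=["contig", "pos", "strand"],
            how="left",
            suffixes=("", "_ref"),
        )
        known = merged["context_ref"].notna()
        mismatches = int((merged.loc[known, "context"] != merged.loc[known, "context_ref"]).sum())
    sid = sample_id if sample_id is not None else str(path)
    return MethylomeSample(sid, group, replicate, df, context_mismatches=mismatches)


def write_cx_report(sample: MethylomeSample, path) -> None:
    """Write a sample as a sorted 7-column CX report (1-based positions).

    Zero-coverage sites are retained; write -> read is the identity.
    """
    df = _sort_sites(sample.sites.copy())
    df["pos"] = df["pos"] + 1
    df["context"] = df["context"].map(_INTERNAL_TO_BISMARK)
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# summaries

def _context_mask(df: pd.DataFrame, context) -> pd.Series:
    if context is None:
        return pd.Series(True, index=df.index)
    label = context.value if isinstance(context, ContextClass) else str(context)
    return df["context"] == label


def global_methylation_percent(
    sample: MethylomeSample, context: ContextClass | str | None = None
) -> MethylationSummary:
    """Call-weighted percent methylation, optionally restricted to a context."""
    df = sample.sites[_context_mask(sample.sites, context)]
    meth = int(df["meth"].sum())
    total = int((df["meth"] + df["unmeth"]).sum())
    label = "global" if context is None else f"global/{context}"
    return MethylationSummary(label, meth, total)


def methylation_by_feature(
    sample: MethylomeSample,
    annotation: FeatureAnnotation,
    partition: str = "genic",
) -> list[MethylationSummary]:
    """Per-feature-class methylation, per context and pooled.

    ``partition`` is 'genic' (genic vs intergenic) or 'exonic'
    (exon / intron / intergenic).  Every site is assigned to exactly
    one stratum via the annotation's position map.
    """
    if partition not in ("genic", "exonic"):
        raise ValueError("partition must be 'genic' or 'exonic'")
    df = sample.sites
    missing = sorted(set(df["contig"]) - set(annotation.contig_lengths))
    if missing:
        raise FormatError(f"contigs absent from annotation: {missing}")
    cls = np.empty(len(df), dtype=object)
    for contig, idx in df.groupby("contig", sort=False).indices.items():
        mask = annotation.mask(contig)
        codes = mask[df["pos"].to_numpy()[idx]]
        names = np.array(["intergenic", "exon", "intron"])[codes]
        cls[idx] = names
    if partition == "genic":
        cls = np.where(np.isin(cls, ["exon", "intron"]), "genic", cls)
    out = []
    strata = pd.DataFrame(
        {"stratum": cls, "context": df["context"].to_numpy(),
         "meth": df["meth"].to_numpy(), "cov": (df["meth"] + df["unmeth"]).to_numpy()}
    )
    order = (
        ["genic", "intergenic"] if partition == "genic"
        else ["exon", "intron", "intergenic"]
    )
    for stratum in order:
        sub = strata[strata["stratum"] == stratum]
        out.append(
            MethylationSummary(
                f"{stratum}/all", int(sub["meth"].sum()), int(sub["cov"].sum())
            )
        )
        for ctx in ("CpG", "CHG", "CHH"):
            s2 = sub[sub["context"] == ctx]
            out.append(
                MethylationSummary(
                    f"{stratum}/{ctx}", int(s2["meth"].sum()), int(s2["cov"].sum())
                )
            )
    return out


def strand_report(sample: MethylomeSample) -> dict:
    """Per-strand methylation level and share of methylated calls.

    The two candidate readings of a strand asymmetry are both reported:
    the difference in percent methylation (top minus bottom) and the
    difference in each strand's share of all methylated calls.
    """
    df = sample.sites
    out: dict = {}
    per = {}
    for strand, name in (("+", "top"), ("-", "bottom")):
        sub = df[df["strand"] == strand]
        meth = int(sub["meth"].sum())
        total = int((sub["meth"] + sub["unmeth"]).sum())
        per[name] = MethylationSummary(f"strand/{name}", meth, total)
    total_meth = per["top"].meth_calls + per["bottom"].meth_calls
    for name in ("top", "bottom"):
        s = per[name]
        out[f"{name}_percent"] = s.percent
        out[f"{name}_share_of_methylated"] = (
            100.0 * s.meth_calls / total_meth if total_meth else float("nan")
        )
    out["percent_difference"] = out["top_percent"] - out["bottom_percent"]
    out["share_difference"] = (
        out["top_share_of_methylated"] - out["bottom_share_of_methylated"]
    )
    return out


def replicate_summary(samples: list[MethylomeSample], statistic) -> ReplicateSummary:
    """Apply ``statistic`` per replicate; report mean +/- sample SD.

    ``statistic`` maps a sample to a float or to a MethylationSummary
    (whose percent is used).  All samples must share one group label.
    """
    if not samples:
        raise ValueError("no samples")
    groups = {s.group for s in samples}
    if len(groups) > 1:
        raise ValueError(f"mixed group labels: {sorted(groups)}")
    values = []
    for s in samples:
        v = statistic(s)
        if isinstance(v, MethylationSummary):
            v = v.percent
        values.append(float(v))
    return ReplicateSummary(groups.pop() or "group", values)
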