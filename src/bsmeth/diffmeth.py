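"""Replicate-aware differential methylation between two groups.

The model is beta-binomial: within group g, replicate r's methylated
calls at a locus are Binomial(n_r, p_r) with p_r drawn around the group
mean p_g with overdispersion phi_g (phi = 0 is pure binomial).  The
group mean is estimated by pooling calls across replicates,

    p_hat_g = sum_r x_r / sum_r n_r,

with estimated sampling variance

    V_g = p_hat_g (1 - p_hat_g) * W_g / (N_g^2 - W_g),
    W_g = sum_r n_r (1 + (n_r - 1) phi_g),   N_g = sum_r n_r,

where the N_g^2 - W_g denominator makes the p(1-p) plug-in unbiased
(at phi = 0 it is the familiar p_hat q_hat / (N - 1)) and measurably
improves type-I calibration over naive N_g^2 scaling.  The per-locus
Wald statistic is (p_hat_1 - p_hat_2) / sqrt(V1 + V2)
referred to the standard normal.  phi is estimated once per group by a
method-of-moments fit pooled across all tested loci (truncated at 0),
so no smoothing or shrinkage across neighbouring loci is applied.

Candidate regions are built from significant loci (raw p < alpha):
consecutive significant loci on one contig are chained while the gap
between them is at most the merge distance and their mean differences
share a sign; the region spans the chained loci and its members are all
tested loci inside the span.  A region is kept when it has enough
member sites, enough length, and a high enough significant fraction.
Regions are ranked by the area statistic — the sum of member Wald
statistics — largest magnitude first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome_io import EXON, INTRON, FeatureAnnotation
from .methylome import MethylomeSample

__all__ = [
    "DiffConfig",
    "DmlResult",
    "DmRegion",
    "filter_covered_loci",
    "estimate_dispersion",
    "wald_test_dml",
    "call_dmr",
    "map_regions_to_genes",
    "dml_test",
]


@dataclass
class DiffConfig:
    """Thresholds for locus filtering, testing and region calling."""

    min_coverage: int = 10
    require_genic: bool = True
    context: str = "CpG"
    alpha: float = 0.05
    merge_distance: int = 100
    min_sites: int = 3
    min_length: int = 50
    pct_sig: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        for name in ("min_coverage", "merge_distance", "min_sites", "min_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DmlResult:
    """Per-locus Wald test result (positions 0-based internally)."""

    contig: str
    pos: int
    strand: str
    mu1: float
    mu2: float
    diff: float
    se: float
    stat: float
    p: float
    significant: bool


@dataclass
class DmRegion:
    """A called differentially methylated region (1-based inclusive)."""

    contig: str
    start: int
    end: int
    n_sites: int
    frac_significant: float
    area_stat: float
    mean_diff: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _coverage_frame(sample: MethylomeSample, tag: str) -> pd.DataFrame:
    df = sample.sites
    return pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": df["pos"],
            "strand": df["strand"],
            f"meth_{tag}": df["meth"],
            f"cov_{tag}": df["meth"] + df["unmeth"],
        }
    )


def _aligned_counts(
    group_a: list[MethylomeSample], group_b: list[MethylomeSample]
) -> pd.DataFrame:
    """Inner-join all replicates on site key; keep context from group A."""
    merged = None
    tags = []
    for i, s in enumerate(group_a):
        tag = f"a{i}"
        tags.append(tag)
        f = _coverage_frame(s, tag)
        if merged is None:
            f = f.assign(context=s.sites["context"].to_numpy())
            merged = f
        else:
            merged = merged.merge(f, on=["contig", "pos", "strand"], how="inner")
    for i, s in enumerate(group_b):
        tag = f"b{i}"
        tags.append(tag)
        merged = merged.merge(
            _coverage_frame(s, tag), on=["contig", "pos", "strand"], how="inner"
        )
    merged.attrs["tags"] = tags
    return merged


def filter_covered_loci(
    group_a: list[MethylomeSample],
    group_b: list[MethylomeSample],
    annotation: FeatureAnnotation | None,
    config: DiffConfig,
) -> pd.DataFrame:
    """Sites testable under the coverage/context/feature filter.

    Keeps sites of the configured context that are genic (when
    required) and covered at >= ``min_coverage`` in every replicate of
    both groups.  Returns the aligned count table (one row per
    surviving site, meth/cov columns per replicate), sorted by
    (contig, pos, strand).
    """
    if not group_a or not group_b:
        raise ValueError("each group needs at least one replicate")
    m = _aligned_counts(group_a, group_b)
    tags = m.attrs["tags"]
    keep = m["context"] == config.context
    for t in tags:
        keep &= m[f"cov_{t}"] >= config.min_coverage
    if config.require_genic:
        if annotation is None:
            raise ValueError("require_genic needs an annotation")
        genic = np.zeros(len(m), dtype=bool)
        for contig, idx in m.groupby("contig", sort=False).indices.items():
            mask = annotation.mask(contig)
            codes = mask[m["pos"].to_numpy()[idx]]
            genic[idx] = np.isin(codes, (EXON, INTRON))
        keep &= genic
    out = (
        m[keep]
        .sort_values(["contig", "pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    out.attrs["tags"] = tags
    return out


def estimate_dispersion(meth: np.ndarray, cov: np.ndarray) -> float:
    """Pooled method-of-moments beta-binomial overdispersion phi.

    ``meth`` and ``cov`` are (loci x replicates) count arrays for one
    group.  For each locus the within-locus residual sum of squares
    around the pooled proportion has expectation p q (c0 + c1 phi)
    under the beta-binomial model; summing the moment equations over
    loci and solving for phi gives the estimate, truncated at 0.
    Returns 0 when fewer than 2 replicates are available.
    """
    meth = np.asarray(meth, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if meth.ndim != 2 or meth.shape != cov.shape:
        raise ValueError("meth and cov must be matching 2-D arrays")
    if meth.shape[1] < 2:
        return 0.0
    N = cov.sum(axis=1)
    ok = N > 0
    meth, cov, N = meth[ok], cov[ok], N[ok]
    p = meth.sum(axis=1) / N
    inner = (p > 0) & (p < 1)
    if not inner.any():
        return 0.0
    meth, cov, N, p = meth[inner], cov[inner], N[inner], p[inner]
    q = 1.0 - p
    resid = ((meth - cov * p[:, None]) ** 2).sum(axis=1)
    s = resid / (p * q)
    M2 = (cov**2).sum(axis=1)
    B = (cov * (cov - 1.0)).sum(axis=1)
    nb = (cov**2 * (cov - 1.0)).sum(axis=1)
    c0 = N - M2 / N
    c1 = B * (1.0 + M2 / N**2) - 2.0 * nb / N
    denom = c1.sum()
    if denom <= 0:
        return 0.0
    phi = (s.sum() - c0.sum()) / denom
    return float(max(phi, 0.0))


def _group_stats(meth: np.ndarray, cov: np.ndarray, phi: float):
    N = cov.sum(axis=1)
    p = np.divide(meth.sum(axis=1), N, out=np.zeros_like(N, dtype=float), where=N > 0)
    w = (cov * (1.0 + (cov - 1.0) * phi)).sum(axis=1)
    # unbiased-in-p(1-p) denominator: N^2 - w (reduces to N-1 scaling at phi=0);
    # fall back to N^2 in the degenerate case w >= N^2 (single replicate, phi ~ 1)
    denom = np.where(N**2 - w > 0, N**2 - w, N**2)
    var = np.divide(p * (1.0 - p) * w, denom, out=np.zeros_like(p), where=N > 0)
    return p, var, N


def wald_test_dml(
    meth_a: np.ndarray,
    cov_a: np.ndarray,
    meth_b: np.ndarray,
    cov_b: np.ndarray,
    phi_a: float,
    phi_b: float,
    keys: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus Wald test of group methylation proportions.

    Count arrays are (loci x replicates).  Loci with zero total
    coverage in either group are skipped (column ``skipped`` marks
    them; their statistics are NaN).  When both pooled proportions are
    equal and lie on the boundary {0,1} the statistic is defined as 0
    and p as 1.  A Benjamini-Hochberg adjusted p is reported alongside
    but significance is assessed on the raw p.
    """
    meth_a, cov_a = np.asarray(meth_a, float), np.asarray(cov_a, float)
    meth_b, cov_b = np.asarray(meth_b, float), np.asarray(cov_b, float)
    p1, v1, n1 = _group_stats(meth_a, cov_a, phi_a)
    p2, v2, n2 = _group_stats(meth_b, cov_b, phi_b)
    skipped = (n1 == 0) | (n2 == 0)
    diff = p1 - p2
    se = np.sqrt(v1 + v2)
    stat = np.zeros_like(diff)
    nonzero = se > 0
    stat[nonzero] = diff[nonzero] / se[nonzero]
    # boundary case: both proportions equal at 0 or 1 -> no evidence
    boundary = (~nonzero) & np.isclose(p1, p2)
    stat[boundary] = 0.0
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p[skipped] = np.nan
    stat = np.where(skipped, np.nan, stat)
    out = pd.DataFrame(
        {
            "mu1": p1,
            "mu2": p2,
            "diff": diff,
            "se": se,
            "stat": stat,
            "p": p,
            "skipped": skipped,
        }
    )
    tested = ~skipped
    p_adj = np.full(len(out), np.nan)
    if tested.any():
        p_adj[tested] = stats.false_discovery_control(p[tested], method="bh")
    out["p_adj"] = p_adj
    out["significant"] = (out["p"] < alpha) & tested
    if keys is not None:
        out = pd.concat(
            [keys[["contig", "pos", "strand"]].reset_index(drop=True), out], axis=1
        )
    return out


def dml_test(
    group_a: list[MethylomeSample],
    group_b: list[MethylomeSample],
    annotation: FeatureAnnotation | None,
    config: DiffConfig | None = None,
) -> pd.DataFrame:
    """Filter loci, estimate per-group dispersion, run the Wald test.

    Returns the DML table sorted by (contig, pos, strand), with the
    estimated dispersions attached as ``attrs['phi_a']``/``'phi_b'``.
    """
    config = config or DiffConfig()
    table = filter_covered_loci(group_a, group_b, annotation, config)
    tags = table.attrs["tags"]
    a_tags = [t for t in tags if t.startswith("a")]
    b_tags = [t for t in tags if t.startswith("b")]
    meth_a = table[[f"meth_{t}" for t in a_tags]].to_numpy()
    cov_a = table[[f"cov_{t}" for t in a_tags]].to_numpy()
    meth_b = table[[f"meth_{t}" for t in b_tags]].to_numpy()
    cov_b = table[[f"cov_{t}" for t in b_tags]].to_numpy()
    phi_a = estimate_dispersion(meth_a, cov_a)
    phi_b = estimate_dispersion(meth_b, cov_b)
    out = wald_test_dml(
        meth_a, cov_a, meth_b, cov_b, phi_a, phi_b, keys=table, alpha=config.alpha
    )
    out.attrs["phi_a"] = phi_a
    out.attrs["phi_b"] = phi_b
    out.attrs["n_filtered"] = len(table)
    return out


def call_dmr(dml: pd.DataFrame, config: DiffConfig | None = None) -> list[DmRegion]:
    """Greedy region calling over a position-sorted DML table.

    Significant loci seed chains; a chain grows while the next
    significant locus on the same contig is within the merge distance
    and its difference does not oppose the chain's sign.  The region
    spans the chain and counts every tested locus inside the span; it
    is kept when n_sites >= min_sites, length >= min_length and the
    significant fraction >= pct_sig.  Output is sorted by |areaStat|
    descending, ties broken by (contig, start).
    """
    config = config or DiffConfig()
    if len(dml) == 0:
        return []
    regions: list[DmRegion] = []
    tested = dml[~dml["skipped"]] if "skipped" in dml.columns else dml
    for contig, sub in tested.groupby("contig", sort=True):
        sub = sub.sort_values(["pos", "strand"], kind="mergesort")
        pos = sub["pos"].to_numpy()
        diff = sub["diff"].to_numpy()
        stat = sub["stat"].to_numpy()
        sig = sub["significant"].to_numpy()
        sig_idx = np.flatnonzero(sig)
        if len(sig_idx) == 0:
            continue
        chains: list[list[int]] = []
        cur = [int(sig_idx[0])]
        cur_sign = np.sign(diff[sig_idx[0]])
        for j in sig_idx[1:]:
            j = int(j)
            gap = pos[j] - pos[cur[-1]]
            s = np.sign(diff[j])
            compatible = cur_sign == 0 or s == 0 or s == cur_sign
            if gap <= config.merge_distance and compatible:
                cur.append(j)
                if cur_sign == 0:
                    cur_sign = s
            else:
                chains.append(cur)
                cur = [j]
                cur_sign = s
        chains.append(cur)
        for chain in chains:
            lo, hi = chain[0], chain[-1]
            members = slice(lo, hi + 1)  # all tested loci inside the span
            n_sites = hi - lo + 1
            n_sig = int(sig[members].sum())
            frac = n_sig / n_sites
            start0, end0 = int(pos[lo]), int(pos[hi])
            length = end0 - start0 + 1
            if (
                n_sites >= config.min_sites
                and length >= config.min_length
                and frac >= config.pct_sig
            ):
                regions.append(
                    DmRegion(
                        contig=str(contig),
                        start=start0 + 1,
                        end=end0 + 1,
                        n_sites=n_sites,
                        frac_significant=frac,
                        area_stat=float(np.nansum(stat[members])),
                        mean_diff=float(np.nanmean(diff[members])),
                    )
                )
    regions.sort(key=lambda r: (-abs(r.area_stat), r.contig, r.start))
    return regions


def map_regions_to_genes(
    regions: list[DmRegion], annotation: FeatureAnnotation
) -> pd.DataFrame:
    """Genes overlapped (>=1 bp) by at least one region, with summed areaStat.

    Returns a DataFrame (gene_id, n_regions, area_stat) sorted by
    |area_stat| descending; the number of rows is the DME count.
    """
    trees: dict[str, IntervalTree] = {}
    for g in annotation.genes:
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g.gene_id)
    hits: dict[str, dict] = {}
    for r in regions:
        tree = trees.get(r.contig)
        if tree is None:
            continue
        for iv in tree.overlap(r.start - 1, r.end):  # back to 0-based half-open
            d = hits.setdefault(iv.data, {"n_regions": 0, "area_stat": 0.0})
            d["n_regions"] += 1
            d["area_stat"] += r.area_stat
    rows = [
        {"gene_id": gid, "n_regions": d["n_regions"], "area_stat": d["area_stat"]}
        for gid, d in hits.items()
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "n_regions", "area_stat"])
    if len(df):
        df = df.reindex(
            df["area_stat"].abs().sort_values(ascending=False, kind="mergesort").index
        ).reset_index(drop=True)
    return df
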