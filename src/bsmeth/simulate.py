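"""Synthetic bisulfite methylomes with planted, recoverable parameters.

The generator emulates the statistical structure of a low-methylation
insect methylome: i.i.d. genome sequence at a configurable GC content,
non-overlapping gene models with alternating exons and introns,
per-stratum methylation probabilities keyed by sequence context,
feature class and strand, beta-binomial variability across biological
replicates, negative-binomial sequencing coverage, optional bisulfite
conversion error, and planted differentially methylated regions
between two groups.  Everything is deterministic under the config
seed, and every emitted site carries a truth record.

The named presets plant the published summary levels of the Russian
wheat aphid WGBS study design this package targets: per-context CpG /
CHG / CHH levels of 5.19 / 0.27 / 0.34 %, genic / intergenic levels of
1.58 / 0.808 %, and a uniform genome-wide level of 1.126 %, each with
three biological replicates at 30x mean coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .context import cytosine_table
from .genome_io import FeatureAnnotation, GeneModel, GenomeSequence
from .methylome import CX_COLUMNS, MethylomeSample

__all__ = [
    "PlantedDmr",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genome",
    "apply_cpg_depletion",
    "simulate_annotation",
    "simulate_methylome",
    "simulate_dataset",
    "preset",
    "PRESET_NAMES",
]

CONTEXTS = ("CpG", "CHG", "CHH")
FEATURES = ("exon", "intron", "intergenic")
STRANDS = ("+", "-")


@dataclass
class PlantedDmr:
    """A planted region with its own per-group methylation probability."""

    contig: str
    start: int  # 0-based half-open
    end: int
    rates: dict[str, float]  # group label -> probability inside the region


@dataclass
class SimulationConfig:
    seed: int = 42
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"c1": 100_000})
    gc: float = 0.5
    cpg_depletion: float = 1.0  # multiplier on P(G | previous C); 1 = none
    gene_count: int = 20
    exons_per_gene: int = 4
    exon_length: int = 400
    intron_length: int = 200
    #: success probability per (context, feature, strand) stratum
    rates: dict[tuple[str, str, str], float] = field(default_factory=dict)
    phi: float = 0.0
    coverage_mean: float = 30.0
    coverage_overdispersion: float = 0.1
    nonconversion: float = 0.0  # unmethylated C surviving conversion
    inappropriate_conversion: float = 0.0  # methylated C converted anyway
    groups: tuple[str, ...] = ("SA1",)
    replicates: int = 3
    dmrs: list[PlantedDmr] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.rates.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("stratum probabilities must lie in [0,1]")
        if self.phi < 0 or self.coverage_mean <= 0:
            raise ValueError("phi must be >= 0 and coverage mean positive")

    @property
    def gene_length(self) -> int:
        return (
            self.exons_per_gene * self.exon_length
            + (self.exons_per_gene - 1) * self.intron_length
        )

    def rate(self, context: str, feature: str, strand: str) -> float:
        return self.rates[(context, feature, strand)]


def uniform_rates(
    by_context: dict[str, float] | None = None,
    by_feature: dict[str, float] | None = None,
    global_p: float | None = None,
) -> dict[tuple[str, str, str], float]:
    """Build a full stratum-rate table from one marginal specification."""
    given = sum(x is not None for x in (by_context, by_feature, global_p))
    if given != 1:
        raise ValueError("specify exactly one of by_context/by_feature/global_p")
    out = {}
    for c in CONTEXTS:
        for f in FEATURES:
            for s in STRANDS:
                if by_context is not None:
                    p = by_context[c]
                elif by_feature is not None:
                    p = by_feature["genic" if f in ("exon", "intron") else "intergenic"]
                else:
                    p = global_p
                out[(c, f, s)] = float(p)
    return out


@dataclass
class SimulationTruth:
    """Planted parameters aligned with one emitted sample."""

    group: str
    replicate: str
    site_probability: np.ndarray  # planted p per emitted site (pre-dispersion)
    stratum_percent: pd.DataFrame  # context x feature x strand planted percents
    dmrs: list[PlantedDmr]


# ---------------------------------------------------------------------------
# genome and annotation

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def simulate_genome(config: SimulationConfig) -> GenomeSequence:
    """I.i.d. genome at the configured GC fraction, optional CpG depletion."""
    rng = _rng(config, 0)
    gc = config.gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contigs = {}
    for cid, n in config.contig_lengths.items():
        codes = rng.choice(4, size=n, p=probs).astype(np.uint8)
        seq = _BASE_BYTES[codes].tobytes().decode("ascii")
        contigs[cid] = seq
    genome = GenomeSequence(contigs)
    if config.cpg_depletion < 1.0:
        genome = apply_cpg_depletion(
            genome, None, config.cpg_depletion, _rng(config, 1)
        )
    return genome


def apply_cpg_depletion(
    genome: GenomeSequence,
    regions: list[tuple[str, int, int]] | None,
    factor: float,
    rng: np.random.Generator,
) -> GenomeSequence:
    """Thin CpG dinucleotides by redrawing the G of a CG pair.

    Each G preceded by C (within ``regions``, or everywhere when None)
    is kept with probability ``factor`` and otherwise redrawn uniformly
    from {A,C,T}.  A single left-to-right pass; redraws may create new
    CG pairs downstream, so the realised depletion is approximate.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError("depletion factor must be in [0,1]")
    contigs = {}
    for cid, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        in_scope = np.zeros(len(arr), dtype=bool)
        if regions is None:
            in_scope[:] = True
        else:
            for rc, s, e in regions:
                if rc == cid:
                    in_scope[s:e] = True
        cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G")) & in_scope[1:]
        idx = np.flatnonzero(cg) + 1
        redraw = idx[rng.random(len(idx)) >= factor]
        arr[redraw] = np.frombuffer(b"ACT", dtype=np.uint8)[
            rng.integers(0, 3, size=len(redraw))
        ]
        contigs[cid] = arr.tobytes().decode("ascii")
    return GenomeSequence(contigs)


def simulate_annotation(
    genome: GenomeSequence, config: SimulationConfig
) -> FeatureAnnotation:
    """Evenly spaced non-overlapping genes with alternating exons/introns."""
    n_contigs = len(config.contig_lengths)
    per_contig = config.gene_count // n_contigs
    extra = config.gene_count - per_contig * n_contigs
    genes: list[GeneModel] = []
    gidx = 0
    for k, (cid, clen) in enumerate(config.contig_lengths.items()):
        n_here = per_contig + (1 if k < extra else 0)
        if n_here == 0:
            continue
        gl = config.gene_length
        if n_here * gl > clen:
            raise ValueError(f"contig {cid} too short for {n_here} genes of {gl} bp")
        gap = (clen - n_here * gl) // (n_here + 1)
        cursor = gap
        for j in range(n_here):
            start = cursor
            exons = []
            x = start
            for e in range(config.exons_per_gene):
                exons.append((x, x + config.exon_length))
                x += config.exon_length + config.intron_length
            end = start + gl
            strand = "+" if (gidx % 2 == 0) else "-"
            genes.append(GeneModel(f"g{gidx:04d}", cid, strand, start, end, exons))
            gidx += 1
            cursor = end + gap
    return FeatureAnnotation.from_genome(genes, genome)


# ---------------------------------------------------------------------------
# methylome

_FEATURE_NAMES = np.array(["intergenic", "exon", "intron"])


def _planted_probabilities(
    cyto: pd.DataFrame,
    annotation: FeatureAnnotation,
    config: SimulationConfig,
    group: str,
) -> np.ndarray:
    p = np.full(len(cyto), np.nan)
    feature = np.empty(len(cyto), dtype=object)
    for contig, idx in cyto.groupby("contig", sort=False).indices.items():
        mask = annotation.mask(contig)
        feature[idx] = _FEATURE_NAMES[mask[cyto["pos"].to_numpy()[idx]]]
    ctx = cyto["context"].to_numpy()
    strand = cyto["strand"].to_numpy()
    for (c, f, s), rate in config.rates.items():
        sel = (ctx == c) & (feature == f) & (strand == s)
        p[sel] = rate
    for dmr in config.dmrs:
        if group not in dmr.rates:
            continue
        sel = (
            (cyto["contig"].to_numpy() == dmr.contig)
            & (cyto["pos"].to_numpy() >= dmr.start)
            & (cyto["pos"].to_numpy() < dmr.end)
        )
        p[sel] = dmr.rates[group]
    if np.isnan(p).any():
        missing = cyto.loc[np.isnan(p), ["context", "strand"]].iloc[0]
        raise ValueError(
            f"no stratum rate configured for context={missing['context']!r} "
            f"strand={missing['strand']!r}"
        )
    return p


def simulate_methylome(
    genome: GenomeSequence,
    annotation: FeatureAnnotation,
    config: SimulationConfig,
    group: str,
    replicate: int,
    _cyto: pd.DataFrame | None = None,
) -> tuple[MethylomeSample, SimulationTruth]:
    """One replicate's CX-valid methylome plus its truth record.

    Per cytosine: planted probability p from the stratum table (DMR
    overrides applied for the given group); replicate-level
    p_r ~ Beta(mean p, dispersion phi); coverage ~ negative binomial;
    methylated calls ~ Binomial(n, p_r (1 - eps_conv) + (1 - p_r)
    eps_nonconv).  Cytosines with undefined context (contig edge / N)
    are not emitted.
    """
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}")
    for dmr in config.dmrs:
        if dmr.contig not in genome or dmr.end > genome.length(dmr.contig):
            raise ValueError(f"planted DMR outside genome bounds: {dmr}")
    cyto = cytosine_table(genome) if _cyto is None else _cyto
    cyto = cyto[cyto["context"] != "UNDEFINED"].reset_index(drop=True)
    p = _planted_probabilities(cyto, annotation, config, group)
    gi = config.groups.index(group)
    rng = _rng(config, 100, gi, int(replicate))
    if config.phi > 0:
        inner = (p > 0) & (p < 1)
        p_r = p.copy()
        a = p[inner] * (1.0 - config.phi) / config.phi
        b = (1.0 - p[inner]) * (1.0 - config.phi) / config.phi
        p_r[inner] = rng.beta(a, b)
    else:
        p_r = p
    if config.coverage_overdispersion > 0:
        k = 1.0 / config.coverage_overdispersion
        cov = rng.negative_binomial(k, k / (k + config.coverage_mean), size=len(p))
    else:
        cov = rng.poisson(config.coverage_mean, size=len(p))
    q = p_r * (1.0 - config.inappropriate_conversion) + (1.0 - p_r) * config.nonconversion
    meth = rng.binomial(cov, q)
    sites = pd.DataFrame(
        {
            "contig": cyto["contig"],
            "pos": cyto["pos"],
            "strand": cyto["strand"],
            "meth": meth.astype(np.int64),
            "unmeth": (cov - meth).astype(np.int64),
            "context": cyto["context"],
            "tri": cyto["tri"],
        }
    )[CX_COLUMNS]
    sample = MethylomeSample(
        sample_id=f"{group}_rep{replicate}",
        group=group,
        replicate=str(replicate),
        sites=sites,
    )
    truth = SimulationTruth(
        group=group,
        replicate=str(replicate),
        site_probability=p,
        stratum_percent=pd.DataFrame(
            [
                {"context": c, "feature": f, "strand": s, "percent": 100.0 * r}
                for (c, f, s), r in config.rates.items()
            ]
        ),
        dmrs=list(config.dmrs),
    )
    return sample, truth


def simulate_dataset(config: SimulationConfig):
    """Genome, annotation and every group x replicate methylome.

    Returns (genome, annotation, samples, truths) with samples keyed by
    (group, replicate index).
    """
    genome = simulate_genome(config)
    annotation = simulate_annotation(genome, config)
    cyto = cytosine_table(genome)
    samples: dict[tuple[str, int], MethylomeSample] = {}
    truths: dict[tuple[str, int], SimulationTruth] = {}
    for group in config.groups:
        for rep in range(1, config.replicates + 1):
            s, t = simulate_methylome(
                genome, annotation, config, group, rep, _cyto=cyto
            )
            samples[(group, rep)] = s
            truths[(group, rep)] = t
    return genome, annotation, samples, truths


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("context", "feature", "global", "dmr-null", "dmr-alt")

#: published summary levels the presets plant (percent / 100)
CONTEXT_RATES = {"CpG": 0.0519, "CHG": 0.0027, "CHH": 0.0034}
FEATURE_RATES = {"genic": 0.0158, "intergenic": 0.00808}
GLOBAL_RATE = 0.01126
DMR_EFFECT = 0.30


def _profiling_geometry(seed: int) -> dict:
    return dict(
        seed=seed,
        contig_lengths={f"c{i}": 250_000 for i in range(1, 5)},
        gc=0.5,
        gene_count=180,  # ~40% genic: 180 genes x 2200 bp on 1 Mb
        exons_per_gene=4,
        exon_length=400,
        intron_length=200,
        phi=0.02,
        coverage_mean=30.0,
        coverage_overdispersion=0.1,
        replicates=3,
    )


def preset(name: str, seed: int = 42) -> SimulationConfig:
    """A ready-made :class:`SimulationConfig` for one study condition.

    ``context``  — per-context CpG/CHG/CHH levels 5.19/0.27/0.34 %.
    ``feature``  — genic 1.58 % vs intergenic 0.808 %, all contexts.
    ``global``   — uniform 1.126 % at every cytosine.
    ``dmr-null`` — two groups with identical rates (calibration).
    ``dmr-alt``  — dmr-null plus planted genic DMRs of +0.30 difference.
    """
    if name == "context":
        return SimulationConfig(
            **_profiling_geometry(seed),
            rates=uniform_rates(by_context=CONTEXT_RATES),
            groups=("SA1",),
        )
    if name == "feature":
        return SimulationConfig(
            **_profiling_geometry(seed),
            rates=uniform_rates(by_feature=FEATURE_RATES),
            groups=("SA1",),
        )
    if name == "global":
        return SimulationConfig(
            **_profiling_geometry(seed),
            rates=uniform_rates(global_p=GLOBAL_RATE),
            groups=("SA1",),
        )
    if name in ("dmr-null", "dmr-alt"):
        geom = _profiling_geometry(seed)
        geom["contig_lengths"] = {"c1": 250_000, "c2": 250_000}
        geom["gene_count"] = 90
        cfg = SimulationConfig(
            **geom,
            rates=uniform_rates(by_context=CONTEXT_RATES),
            groups=("SA1", "SAM"),
        )
        if name == "dmr-alt":
            cfg.dmrs = _plant_dmrs(cfg, n_dmrs=20, length=200)
        return cfg
    raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def _plant_dmrs(config: SimulationConfig, n_dmrs: int, length: int) -> list[PlantedDmr]:
    """Place DMRs inside gene bodies (first exon interior), every k-th gene."""
    genome_lengths = config.contig_lengths
    # reproduce the deterministic gene layout without building the genome
    n_contigs = len(genome_lengths)
    per_contig = config.gene_count // n_contigs
    extra = config.gene_count - per_contig * n_contigs
    spans = []
    for k, (cid, clen) in enumerate(genome_lengths.items()):
        n_here = per_contig + (1 if k < extra else 0)
        gl = config.gene_length
        gap = (clen - n_here * gl) // (n_here + 1)
        cursor = gap
        for _ in range(n_here):
            spans.append((cid, cursor, cursor + gl))
            cursor += gl + gap
    step = max(1, len(spans) // n_dmrs)
    base = CONTEXT_RATES["CpG"]
    dmrs = []
    for cid, s, e in spans[::step][:n_dmrs]:
        start = s + 100  # interior of the first exon
        dmrs.append(
            PlantedDmr(
                cid, start, start + length,
                rates={"SAM": min(base + DMR_EFFECT, 1.0)},
            )
        )
    return dmrs


def config_to_dict(config: SimulationConfig) -> dict:
    """YAML-serialisable form of a config (tuple keys flattened)."""
    d = asdict(config)
    d["rates"] = {"|".join(k): v for k, v in config.rates.items()}
    d["groups"] = list(config.groups)
    d["dmrs"] = [
        {"contig": m.contig, "start": m.start, "end": m.end, "rates": m.rates}
        for m in config.dmrs
    ]
    return d
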