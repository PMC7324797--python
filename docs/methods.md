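# Methods

## Scope and data model

The package operates on cytosine-level methylation calls (Bismark CX
cytosine reports: contig, 1-based position, strand, methylated calls,
unmethylated calls, context, trinucleotide), a genome FASTA, and a gene/exon
GFF3.  Internally all coordinates are 0-based half-open; the 1-based
on-disk conventions of GFF3 and CX are converted only in the readers and
writers, so round trips are byte-exact.  Every genomic position belongs to
exactly one feature class — exon, intron or intergenic — with exon taking
precedence over intron where genes overlap (the annotation reports a single
exon/intron split, so a deterministic precedence is required; genic means
exon-or-intron).

## Context classification

A cytosine's context is read 5′→3′ on its own strand: the next base G gives
CpG; otherwise a G two bases downstream gives CHG; otherwise CHH.  Minus-
strand cytosines appear as G on the reference and are read leftwards with
complementation.  An N or a contig edge inside the trinucleotide leaves the
context undefined; such sites are excluded from simulation output and from
summaries.  CpG takes precedence (a C followed by G is CpG even though it
also matches C?G patterns).

## Observed/expected ratios

O/E ratios compare the observed frequency of a context against the
frequency expected from base composition under independence:

    CpG_O/E = F_CpG / (F_C F_G)
    CHG_O/E = (F_CAG + F_CTG + F_CCG) / (F_C (1−F_G) F_G)
    CHH_O/E = Σ_{H1,H2∈{A,C,T}} F_CH1H2 / (F_C (1−F_G)²)

Frequencies are computed on the plus strand over overlapping windows
(CpG content is strand-symmetric, so a single strand suffices); windows
containing N are excluded from both numerator and denominator, which avoids
deflating frequencies in gappy assemblies; windows never span a region
boundary, and counts are pooled across all regions of a class before the
ratio is formed (no per-contig averaging).  The CHH numerator is the nine
canonical C-H-H trinucleotides.  Written this way each denominator is
exactly the independence expectation of its numerator, so on i.i.d.
sequence of any base composition all three ratios converge to 1 — the
property that makes values below 1 interpretable as depletion.  Zero
denominators yield NaN-flagged results rather than errors.

## Methylation summaries

Methylation level is call-weighted: percent = 100 · Σ methylated calls /
Σ all calls over the sites in a stratum.  This matches genome-total
reporting ("methylated calls over total calls") and makes strata exactly
additive: the per-partition counts sum to the global counts.  Per-site
averaging is deliberately not the default (it weights a 1× site as much as
a 100× site).  Zero-coverage sites are kept in files — the CX convention
lists every cytosine — but never enter a denominator.  Replicate summaries
apply a statistic per biological replicate and report the unweighted mean
and sample (n−1) SD.  Because a reported strand asymmetry can mean either
"difference in percent methylation" or "difference in each strand's share
of methylated calls", the strand report emits both, with top = reference
plus strand.

## Differential methylation

Only loci of the configured context (default CpG) that are genic (default)
and covered at ≥ min_coverage (default 10) in **every** replicate of
**both** groups are tested.  The model is beta-binomial: replicate r of
group g contributes x_r ~ Binomial(n_r, p_r) with p_r varying around the
group mean with overdispersion φ_g.  The group proportion is pooled,
p̂_g = Σx_r / Σn_r, with estimated variance

    V_g = p̂_g(1−p̂_g) · W_g / (N_g² − W_g),   W_g = Σ n_r(1+(n_r−1)φ_g)

The N²−W denominator (reducing to the familiar p̂q̂/(N−1) at φ = 0) makes
the p(1−p) plug-in unbiased; in null simulations at 30× with three
replicates it measurably improves type-I calibration over naive N²
scaling.  The Wald statistic (p̂_1−p̂_2)/√(V_1+V_2) is referred to the
standard normal, two-sided; when both proportions are equal on the boundary
{0,1} the statistic is defined as 0.  φ is estimated once per group by a
method-of-moments fit pooled across all tested loci (per-locus residual
sums of squares around the pooled proportion have expectation
p q (c0 + c1 φ) under the model; summing the moment equations and solving
gives φ̂, truncated at 0).  No smoothing or shrinkage across neighbouring
loci is applied: in sparse, low-methylation genomes pseudo-replicates from
nearby loci are unreliable, and the un-smoothed test keeps the per-locus
null exact.  Benjamini–Hochberg adjusted p-values are reported alongside,
but significance for region seeding uses the raw p < α (default 0.05).

Calibration note: with the unbiased variance the empirical size tracks α
closely at moderate methylation levels (within Monte-Carlo error at both
α = 0.05 and 0.01 in seeded null simulations at p = 0.3); at very low
methylation levels (~5 %) the α = 0.05 size remains accurate while far-tail
sizes become slightly conservative because counts are small and discrete.

Regions: significant loci seed chains; a chain extends while the next
significant locus on the same contig lies within the merge distance
(default 100 bp) and its difference does not oppose the chain's sign (a
region mixing hyper- and hypo-methylation is not a coherent region).  The
region spans the chained loci; its members are all tested loci inside the
span.  A region is kept when it has ≥ min_sites members (default 3), spans
≥ min_length bp (default 50) and has a significant fraction ≥ pct_sig
(default 0.5).  The area statistic is the sum of member Wald statistics;
output is ordered by |areaStat| descending with coordinate tie-breaks, so
identical inputs give identical output.  A gene overlapped by ≥1 bp of any
region is a DME.  The sign constraint is enforced on the significant
(seeding) loci; non-significant members with noise-level opposite
differences do not veto a region.

## Synthetic methylomes

The generator emulates the statistical structure of the target study:
i.i.d. genome at a configured GC fraction (optional CpG thinning by
redrawing the G of CG pairs, applicable genome-wide or within chosen
regions such as exons), evenly spaced non-overlapping genes with
alternating exons and introns, and per-site calls drawn as
coverage n ~ NegativeBinomial(mean, overdispersion),
p_r ~ Beta(mean p, dispersion φ) per replicate and site, and
methylated ~ Binomial(n, p_r(1−ε_conv) + (1−p_r)ε_nonconv).  The planted
probability p comes from a (context × feature × strand) table, overridden
inside planted DMRs for the targeted group.  Replicate-level beta draws
match the dispersion model the Wald test estimates, which makes parameter
recovery a fair test of the estimator rather than of a mismatched model.

Defaults mirror the study conditions: three replicates per group, 30×
mean coverage with negative-binomial overdispersion 0.1 (realistic
heterogeneity that leaves the estimands untouched), conversion error 0
(no conversion-efficiency control is modelled by default; both error rates
are configurable), and replicate dispersion φ = 0.02 across all presets.
The presets plant the published summary levels as per-site probabilities:

| preset    | planted values                                    | genome |
|-----------|---------------------------------------------------|--------|
| context   | CpG 5.19 %, CHG 0.27 %, CHH 0.34 %                | 4 × 250 kb, ~40 % genic |
| feature   | genic 1.58 %, intergenic 0.808 % (all contexts)   | same |
| global    | uniform 1.126 % at every cytosine                 | same |
| dmr-null  | context rates, two identical groups               | 2 × 250 kb |
| dmr-alt   | dmr-null + 20 genic DMRs of +0.30 in group SAM    | same |

Genome sizes were chosen so the pooled estimates resolve the planted
values: ~125 k CpG records for the context preset (Monte-Carlo SE below
0.01 percentage points on the CpG level), ~600 k intergenic cytosine
records for the feature preset (SE below 0.002 points on the intergenic
level), ~1 M cytosine records for the global preset, and ~20–24 k genic
CpG loci surviving the 10× filter in the dmr presets.  Everything is
deterministic under the config seed (child generators are spawned per
group × replicate), and every emitted site carries a truth record.

What the simulation does **not** emulate: sequence repeats and TE
structure, per-read error profiles and M-bias, context-dependent coverage,
spatial correlation of methylation along chromosomes, and between-replicate
global-level shifts beyond the per-site beta dispersion (the study's
reported ±0.3-point SD across replicates partly reflects library-level
effects that average out in this model).  Passing recovery tests therefore
demonstrates estimator correctness under the stated stochastic model, not
robustness to alignment artefacts.

## Assay formulas

Relative 5mC % = [(sample OD − negative OD)/S] ÷ [(positive OD − negative
OD) × 2/P] × 100, with S the sample DNA (ng) and P the positive-control
amount (ng); the printed kit formula's grouping is ambiguous, and this
reading — the standard form of the kit calculation, under which the result
is a percentage of input DNA — is implemented.  The factor 2 reflects the
kit's 50 %-methylated positive control; the 5hmC formula is identical with
factor 5.  DNMT activity = (sample OD − blank OD)/(µg protein × h) × 1000.
Pfaffl relative expression = E_t^ΔCq(t) / E_r^ΔCq(r), ΔCq = Cq(control) −
Cq(sample), one ratio per reference gene (L27, L32).  Negative computed
percentages are reported with a flag, not clamped, to preserve QC
information.  Efficiencies must lie in [1, 2].  ANOVA and post-hoc tests on
assay outputs are ordinary stock statistics and are left to scipy/statsmodels.

## Numerical and interface choices

- Lexicographic contig order and '+'-before-'−' strand order everywhere;
  all sorts are stable, so identical inputs yield identical outputs.
- The DML table reports NaN statistics for loci skipped for zero group
  coverage (they cannot occur after the default filter, but the test
  function is usable standalone).
- CLI summary outputs carry a `#`-prefixed provenance header (version,
  config hash, seed); CX/FASTA/GFF3/BED outputs are left header-free to
  stay format-exact.
- The GFF3 reader handles the gene/exon subset with ID/Parent links and
  validates coordinates against the genome, reporting file and line on
  error; FASTA goes through Biopython.

## Known limitations

- The Wald test is asymptotic; at coverage far below 10× or α far in the
  tail its size drifts (conservative at low methylation, anti-conservative
  without the unbiased-variance denominator).
- Dispersion is pooled across loci per group; loci with genuinely
  heterogeneous dispersion are not shrunk individually.
- DMR boundaries are the outermost significant loci, not refined by the
  non-significant flanks.
- Assay calculators take plate ODs and qPCR efficiencies/Cq values as
  given; no standard-curve fitting or Cq calling from fluorescence.
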