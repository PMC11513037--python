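# Methods

This note documents the models behind `tgctevo`, the choices made where
the design was genuinely open, and what the synthetic-data experiments
do and do not establish.

## Coordinates and data model

All internal positions are 1-based; segments are closed intervals
`[start, end]`, matching VCF and Battenberg-style tables.  BEDPE input
is converted on read (`pos = bedpe_start + 1`) and back on write.  Sex
chromosomes are excluded from ploidy and LOH-fraction summaries by
default, since X/Y hemizygosity in male genomes would inflate the
apparent LOH fraction; callers can opt back in.  Subclonal segment
states (clonal fraction < 0.5) do not enter the LOH fraction: the
majority state of a locus determines its contribution.

## WGD classification

A sample is placed in the plane of average tumour ploidy ψ
(length-weighted mean total copy number over autosomes) versus fraction
of autosomal genome with minor copy number zero, x.  Samples with
ψ > 2.9 − 2x are WGD; equality is non-WGD (strict inequality, locked by
boundary tests).  The rule is a fixed linear discriminant, not fitted
here.

## Multiplicity and timing model

Mutations are assumed to accrue independently on each genome copy,
uniformly in *molecular time* — the unit interval from tumour-lineage
origin to the last clonal time point.  A mutation on a copy duplicated
at time t is itself duplicated.  For the single-gain states this gives
expected multiplicity-2 / multiplicity-1 clonal counts:

| state | n₂ rate | n₁ rate | estimator |
|-------|---------|---------|-----------|
| 2:1   | μLt     | μL(3−2t)| t̂ = 3n₂/(2n₂+n₁) |
| 2:0   | μLt     | 2μL(1−t)| t̂ = 2n₂/(2n₂+n₁) |
| 2:2   | 2μLt    | 4μL(1−t)| t̂ = 2n₂/(2n₂+n₁) |

(μ = clonal mutation rate per Mb per copy per unit time, L = segment
length in Mb.)  Each estimator is unbiased in expectation: substituting
the rates recovers t exactly.  Timing is restricted to 2:0, 2:1, 2:2 —
the states with closed forms; higher amplifications are out of scope.
Only SNVs enter timing (indel multiplicities are less reliable at
typical depths); estimates are clipped to [0, 1]; CIs are percentile
bootstraps over the segment's mutations (default 200 replicates,
seeded).

Multiplicity per variant maximises the binomial likelihood of the
tumour alt count under f(m) = mρ/(2(1−ρ)+n_tρ) over m ∈ {1..major_cn};
likelihood ties break toward smaller m, which is conservative toward
"late".  The CCF is the m-conditional moment estimate clipped to
[0, 1.5]; a variant is clonal when its Clopper-Pearson VAF interval,
transformed to CCF scale, reaches 1.

WGD timing pools n₂/n₁ over 2:2 segments (2:0 optionally, via
`include_cnloh` — a 2:0 state in a WGD genome arises from pre-doubling
LOH and times the doubling, but a 2:0 in a non-doubled genome does
not, so the default is conservative).  The bootstrap resamples
segments, not mutations: segments share the single doubling event and
are the natural exchangeable unit.  A clock-like restriction (C>T at
CpG plus the flat C>T/T>C remainder) is available but off by default;
with all channels simulated as clock-like, both modes coincide on
synthetic data.

Pre-WGD burden is the count of clonal multiplicity-2 SNVs in
WGD-consistent segments; both the raw count and a genome-extrapolated
value (scaled by assessable/informative length) are reported, since
either convention is defensible.  The cell-division estimate divides
the burden by a user-supplied mutation rate per primordial-germ-cell
division; there is deliberately no default — the constant comes from
external measurements the caller must cite.

Synchronous/asynchronous gain patterns: a WGD sample with ≥ 3 timed
gained segments and ≥ 20 informative mutations is synchronous when the
length-weighted fraction of gained genome whose timing CI overlaps the
WGD time reaches 0.75, else asynchronous; fewer data give
"uninformative" and non-WGD samples "near_diploid".  The thresholds
are exposed in the function signature; the CI-overlap operationalisation
is this package's own construction.

## CCF clustering

The Dirichlet-process machinery used by full subclonal-reconstruction
tools is replaced by a one-dimensional binomial mixture over CCF
centres, fitted by EM for K = 1..5 and selected by BIC.  Clustering
here only feeds clonal/subclonal labels; it is not a subclonal
phylogeny.

## Somatic filters

The panel-of-normals filter tests the 2×2 table [tumour ref, tumour
alt; PoN ref, PoN alt] with a two-sided Fisher exact test (the
sidedness is a choice; two-sided is the safer reading) and *keeps* a
variant when p < α — a significant difference means the signal is
tumour-specific rather than a recurrent artefact.  α defaults to 1e-5,
reflecting genome-scale multiplicity of tested sites, and is
configurable.  Variants with zero tumour alt reads are filtered
outright.  Threshold filters remove germline AF ≥ 1%, cohort somatic
frequency ≥ 5% (both inclusive), and flagged indel-noise windows;
missing annotation tables simply disable the corresponding filter.
Mappability/repeat masks are consumed as site flags, not recomputed.

Per-cluster signature activity is the inner product of the cluster's
mutation-type proportions with the decomposed per-type signature
probabilities; with a row-stochastic matrix the activities form a
convex combination.

## Permutation enrichment

Recurrence per 1 Mb bin = number of distinct samples with ≥ 1
overlapping event of that kind.  The null repositions each event
uniformly at random on its own chromosome, preserving its length and
each sample's event count — chromosome-level event propensity is kept,
genome-wide shuffling is deliberately avoided.  Empirical p-values use
the (1 + exceedances)/(n_perm + 1) form; BH correction is applied
within event kind (gain/LOH/HD have different marginal rates);
adjacent significant bins merge into regions.  Because recurrence is
integer-valued, the achieved level sits slightly below the nominal α;
the calibration experiment measures it at ~0.035-0.04 for α = 0.05
with 50 samples, comfortably valid.

## Event ordering

Per-sample constraints: two timed events are ordered when their timing
CIs are disjoint; early-class clonal driver mutations precede their
segment's gain; subclonal events follow all clonal events.  "All
possible tumour phylogenies" is operationalised as random linear
extensions of this DAG (topological sort with uniform choice among
available events) — the extensions span exactly the total orders
consistent with the per-sample evidence.  Each of the (default 1000,
seeded) iterations draws one extension per sample, fits one
Plackett-Luce model by minorisation-maximisation (convergence 1e-8 or
500 iterations; a 0.1-pseudo-win prior keeps never-preferred events at
small positive worth), and records each event's normalised rank
(rank/(E−1)) in the worth ordering; fitting one model per iteration
rather than pooling keeps iterations exchangeable.  Reported relative
times are normalised ranks, matching a bounded early-to-late timing
axis, not raw worths.

## HLA rules

All five thresholds are strict inequalities, exactly as worded (AI
p < 0.01; lost CN < 0.5; lost CI upper bound < 0.7; kept CN > 0.75;
mismatched sites > 10), and a 2⁵ boundary truth table locks the
behaviour.  Homozygous genes are non-evaluable.  The AI p-value is
consumed from the input by default; a paired t-test over
per-mismatch-site log coverage ratios is available when site-level
data exist.  The lost/kept binder comparison uses a two-sided exact
binomial sign test with null probability 0.5 — the simplest test of
"no preferential loss"; binder calls are taken from the input table
(binding prediction is external).

## SV consensus

Slop (400 bp) and rescue window (3 kb) are strict ≤ comparisons on
breakpoint distances; the merged record uses median member breakpoints,
and the rescue distance is measured from the median breakpoint — either
breakpoint may rescue.  Merging is a connected-components operation on
an undirected graph (same type, both breakpoints within slop), so it is
symmetric and independent of input order.

## Synthetic-data generator

The generator emulates: allele-specific segment profiles restricted to
{0:0, 1:0, 1:1, 2:0, 2:1, 2:2} with one event per chromosome; clonal
mutations Poisson per state-specific molecular-clock rate (or an exact
informative count for recovery experiments); subclonal mutations at
configurable CCFs; binomial read counts at Poisson depth around the
expected VAF (no overdispersion by default — matching the estimators'
assumptions; a beta-binomial knob would probe robustness and is noted
as future work); cohorts sharing latent event times (each event on its
own chromosome so every carried event is independently timeable); HLA
gene reports drawn around balanced/imbalance/LOH truth states;
three-caller SV call sets with detection probability, breakpoint
jitter and caller-private false calls.  Defaults mirror the TGCT-like
regime: ~100× tumour depth, purity 0.4-0.9, near-ubiquitous early WGD
(probability 0.95, t = 0.05), and a clonal rate of 0.12 mutations per
Mb per copy per unit time, which in a doubled genome yields ~0.5
substitutions/Mb total burden.  Identical seed and config produce
byte-identical output files.

What it does not emulate: sequencing error and mapping artefacts,
stacked copy-number events on one chromosome, subclonal copy number,
kataegis/clustered mutation processes, germline variation, and
realistic trinucleotide spectra.  Passing recovery tests therefore
demonstrate estimator correctness under the model's own assumptions,
not robustness to real-data artefacts.

## Problem sizes

The recovery experiments use: 200 segments × 1000 informative
mutations (gain timing); ~3000 clonal SNVs per tumour over five
chromosomes (WGD timing at t ∈ {0.05, 0.1, 0.3}); 8 events × 50
samples × 1000 ordering iterations; 20 null cohorts × 1000
permutations over four chromosomes (calibration).  These sizes were
chosen so each experiment is statistically decisive while the whole
suite stays fast enough for routine development runs.

## Known limitations

* Timing assumes all gains are single-step and clonal; subclonal gains
  and higher amplifications are out of scope.
* The binomial read model understates real overdispersion; CIs are
  accordingly optimistic on real data.
* The ordering model treats per-sample constraints as hard; measurement
  error that produces a wrong disjoint-CI constraint is not revisable
  downstream (rare at the simulated depths).
* Permutation p-values are conservative for sparsely hit bins; with
  1000 permutations the smallest attainable q after BH across ~900
  bins limits detection to regions spanning many bins or stronger
  recurrence.
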