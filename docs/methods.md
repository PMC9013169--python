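# Methods

## Design and model

The package analyses an F2 intercross between two fully homozygous,
highly divergent parents (the reference design: *G. hirsutum* TM-1 ×
*G. barbadense* Hai7124, 249 F2 plants at ~5.3× sequencing depth).
Genotypes are coded AA (maternal homozygote), AB, BB throughout, and
every F2 locus is expected to segregate 1:2:1.

### Marker filters

Only aa × bb sites — both parents homozygous for different alleles —
are informative in an F2 and are retained. F2 minor-allele frequency
(computed over called alleles only; missing calls contribute nothing)
must be ≥ 0.05 and the fraction of individuals with a call ≥ 0.30;
both boundaries are inclusive keeps, removal is strict (<). The three
filters are applied jointly, which makes the operation idempotent.
Multi-allelic records are dropped at intake because interval calling
is strictly biallelic.

### Interval calling and bins

Each individual's genotype per 100-kb physical interval is called from
the summed parental allele support f = nA/(nA+nB) over the SNPs in the
interval: AA if f ≥ 0.90, BB if f ≤ 0.10, AB if 0.25 ≤ f ≤ 0.75,
missing when total support < 3 reads or f falls in an ambiguous band.
The thresholds are chosen to tolerate ~5× depth with ~1% per-read
error while leaving a deliberate ambiguous band; all are exposed as
function parameters.

Two resolution rules apply to isolated missing intervals:

* identical flanking calls fill the gap (plain imputation);
* **different** flanking calls mark a recombination breakpoint
  interval — its allele ratio necessarily sits between the two flank
  expectations (AA = 1, AB = 0.5, BB = 0), and the interval is
  assigned to the flank whose expectation is nearer. Without this
  rule, roughly 30% of crossovers fall in intervals whose mixed ratio
  lands in the ambiguous band; the recombinant individuals would be
  censored from adjacent-bin recombination estimates and chromosome
  map lengths would be underestimated by the same ~30%. With it, the
  breakpoint is localized to within one interval and, in the noiseless
  limit, the assignment provably equals the interval-midpoint truth.

Bins are maximal runs of consecutive intervals whose population
genotype vectors agree, scanned greedily left-to-right with missing
calls acting as wildcards that are filled from the flanking evidence
as the run extends. The wildcard rule prevents shallow-depth gaps from
shattering bins; greediness makes the result deterministic.

A consequence of interval-grid genotyping is breakpoint quantization:
inside the single interval containing a crossover, the call may sit on
either side of the true midpoint genotype (observed mismatch ~0.1% of
calls at 10 SNPs/interval, all confined to crossover intervals). Bin
boundaries are therefore accurate to one interval (100 kb).

### Segregation distortion

Each bin's called genotype counts are χ²-tested against 1:2:1 (df 2).
Bias is attributed to the parent whose homozygote class most exceeds
expectation, or to the heterozygote when only AB is in excess.
Distorted bins (P < 0.001) are removed before map building
(`drop_distorted`); segregation-distortion regions — runs of ≥ 3
consecutive distorted bins, never spanning chromosomes — are reported
from the pre-filter test set. "Closely linked" is read as consecutive
in map order, the only operational reading.

### Genetic map

Bins remain anchored in reference physical order; no de novo marker
ordering is attempted (the reference design shows good collinearity
between genetic and physical order, and re-ordering is a different
problem). Adjacent-bin recombination fractions are maximum-likelihood
estimates via EM over the 9 joint genotype classes; the only latent
quantity is the phase of double heterozygotes, which contribute
2r²/((1−r)²+r²) expected recombinant gametes each. Estimates are
clipped to [0, 0.4999] and converted to cM with Kosambi (default;
d = 25·ln((1+2r)/(1−2r))) or Haldane (d = −50·ln(1−2r)). Kosambi is
the customary default of the mapping software this package replaces;
the choice is exposed.

Per-chromosome summaries report bin counts, cM length, average
spacing (length/bins), average bin length, gaps > 10 cM, cM/Mb rate
and hot-region counts. Subgenome (A/D prefix) and grand totals sum
counts and lengths; average bin length totals use the unweighted mean
of chromosome values, matching the convention of published bin-map
tables; the total rate is total cM over the physical span implied by
the bins (published grand rates computed against full assembly sizes,
including sequence not covered by bins, are not derivable from such
tables and can differ by a few percent).

The recombination landscape assigns each inter-bin interval the rate
ΔcM/ΔMb between bin midpoints (midpoints because bins have physical
extent). Intervals above 1.0 cM/Mb are recombination hot regions;
adjacent qualifying intervals merge into one region, so the region
count depends on this contiguity convention.

### Interval mapping

Haley–Knott regression with a single-QTL model: at each scan position
(1-cM grid plus every marker position), each individual's genotype
probabilities (pAA, pAB, pBB) are computed conditionally on its
flanking bin genotypes under a no-interference meiosis model (exact
enumeration over the two gametes' haplotype configurations; missing
flanks are marginalized, reducing to the 1:2:1 prior when both are
missing). The phenotype is regressed on x_a = pAA − pBB and
x_d = pAB; LOD = (n/2)·log₁₀(RSS₀/RSS₁), PVE = 100·(1 − RSS₁/RSS₀).
At a fully informative marker this reduces exactly to the group-mean
contrasts â = (ȳ_AA − ȳ_BB)/2, d̂ = ȳ_AB − (ȳ_AA + ȳ_BB)/2.

QTLs are local maxima with LOD ≥ 2.5 (the conventional fixed
threshold for this design, kept as a constant rather than derived per
scan). Candidate peaks are accepted in decreasing LOD order; a peak
within 20 cM of an accepted one must be separated by a ≥ 1.5-LOD
valley. Support intervals are the 1.5-LOD drop around the peak,
reported with flanking bins and their physical span — this package's
own definition, stated because published interval columns rarely
define theirs. Names follow q<Trait>-<Chromosome>, suffixed -1, -2 in
map order when one trait has several QTLs on a chromosome. Gene
action is classified from |d/a|: ≤ 0.20 additive, (0.20, 0.80]
partial dominance, (0.80, 1.20] dominant, > 1.20 overdominant (the
printed rubric's 0.20/0.21 gap resolved as a contiguous partition;
a = 0 with d ≠ 0 is overdominant by the infinite-ratio convention).

Single-QTL scans produce correlated shoulder peaks near strong QTLs;
this is inherent, not a defect, and the peak-calling rule accepts
those that clear the separation criterion. `fit(cofactors=True)`
offers a composite-interval-mapping flavour: forward selection of
background markers at P_in = 0.001 and residualization on selected
markers outside a 10-cM window of the scan position.

### Phenotype statistics

Replicate measurements are averaged per individual before population
statistics. Summaries use sample SD (n−1), adjusted Fisher–Pearson
skewness G1 and excess kurtosis G2 (the SPSS convention, identical to
pandas defaults), and CV% = 100·sd/mean (undefined at mean 0).
Mid-parent heterosis is MH = 100·(F1 − MP)/MP with MP the parental
midpoint; over-parent heterosis compares against the larger parental
mean. Generation comparisons use one-way ANOVA plus pairwise Welch
t-tests (unequal variances — a robust default the source protocol did
not specify); correlations are Pearson on pairwise-complete F2
records. Pigment concentrations follow the 95%-ethanol extract
equations (Ca = 13.95·D665 − 6.88·D649; Cb = 24.96·D649 − 7.32·D665;
Cx·c = (1000·D470 − 2.05·Ca − 144.8·Cb)/245) and leaf content is
C·V/(1000·W); negative concentrations are flagged as physically
impossible readings rather than silently clipped.

### Candidate screen

Genes whose spans overlap any QTL physical interval (intervals may be
stored reversed; both orders accepted) and which contain ≥ 1
nonsynonymous variant are candidates. An optional promoter window
(2 kb upstream, strand-aware, off by default — no published window
exists to copy) admits upstream variants. Haplotype–phenotype
association is a Welch two-tailed t-test between exactly two groups,
starred * P < 0.01 and ** P < 0.001. Expression-based narrowing is
represented only as a generic hook (`flag_stage_dominant`) because the
tissue atlas it needs is an external resource.

## Simulator

The simulator emulates the study conditions: defaults n = 249,
5.3 reads/SNP, 1% per-read error. Meioses have no crossover
interference — counts are Poisson(L/100) with uniform positions
(Haldane model), matching the probability formulas used downstream;
each F2 is two independent F1 gametes. The physical↔genetic
coordinate map is linear per chromosome. Read depth is Poisson per
SNP, independent across sites (adequate for shotgun data at this
depth; it ignores mappability and GC structure). Phenotypes are
Σ(planted QTL genotype values, AA = +a, AB = d, BB = −a) plus
Gaussian noise; parental and F1 cohorts are generated with the same
noise model. What passing tests therefore do **not** show: robustness
to reference bias, segregation distortion of biological origin,
structural variation, depth heterogeneity along the genome, or
genotype-by-environment effects (replicate structure is i.i.d. noise
only; the two-year field repetition of the reference design is not
modelled as an environment effect).

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: 100-interval
chromosomes (10 Mb at the 100-kb grid), n = 200–500 individuals,
50,000 bins for test calibration, 200 replicates for
recombination-fraction recovery, 50–100 replicates for scan recovery,
100 permutations over a 10 × 100-cM genome at a 2-cM scan step.
EM tolerance is 1e-8 (max 200 iterations, monotone in practice);
likelihood-oracle comparisons use a 5000-point grid on [0, 0.4999].
Haley–Knott fits use least squares with RSS floored at 1e-12·RSS₀ to
keep LOD finite at perfect fits; LOD is invariant to affine phenotype
transforms. Degenerate inputs: constant phenotypes scan to an all-zero
profile with a warning; chromosomes with < 2 bins yield zero-length
linkage groups with a warning; zero physical spans are skipped in the
landscape; flank configurations that are impossible under the model
(contradictory flanks at r = 0, caused only by genotyping error) fall
back to the 1:2:1 prior.

## Known limitations

* Breakpoints are quantized to the 100-kb grid; per-SNP breakpoint
  refinement (sliding a window SNP-by-SNP) is out of scope.
* The genome-wide permutation null of the 2-df Haley–Knott scan has a
  95th-percentile max LOD near 3.6 on a dense 1000-cM map (n = 250) —
  a fixed LOD 2.5 threshold is therefore anti-conservative
  genome-wide, as the acceptance script's permutation rate documents.
  The threshold is kept at 2.5 deliberately, as the convention of the
  design this package reproduces.
* The EM recombination-fraction estimator assumes codominant,
  error-free bin genotypes; genotyping error inflates r slightly
  (map inflation of a few percent at 5× depth with 1% error).
* `summarize_qtls` subgenome assignment keys on the chromosome's
  leading letter (A*/D*), the tetraploid-cotton convention.
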