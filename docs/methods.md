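# Methods

## Scoring model

The raw score is a composite likelihood-ratio statistic on allele counts.
The background repository contributes x_u alternate chromosomes out of n_b;
the proband contributes x_a ∈ {1 (het), 2 (hom)} out of n_t = 2. Under the
null, proband and background share one binomial frequency, estimated as
p = (x_u + x_a)/(n_b + n_t); under the alternative each has its own MLE
(p_u = x_u/n_b, p_a = x_a/n_t). Binomial coefficients cancel in the ratio
and are omitted. The log ratio is oriented so that variants *rarer than the
background predicts* score high: the alternative log likelihood minus the
null, plus ln(a/h), the log impact ratio. Consequences of this construction,
all covered by tests:

- λ is always finite: plug-in MLEs never put zero probability on observed
  counts (0·ln 0 = 0). A variant absent from the background scores via
  x_u = 0, no frequency smoothing needed.
- λ = ln(a/h) exactly when p_u = p_a (the frequency evidence vanishes and
  the impact evidence remains, additively).
- λ is non-increasing in x_u (up to 50% frequency) and λ_hom > λ_het for
  rare variants in well-sampled backgrounds.
- Including or excluding the proband's own c ∈ {1, 2} chromosomes from the
  background shifts λ by an amount that vanishes as n_b grows (the
  (n−c)/(x−c) ≈ n/x regime); at n_b = 10⁵ the shift is under 0.004 nats,
  which is why the database never subtracts the proband's contribution.

Scoring is single-proband (n_t = 2) by design; x_a/n_t are kept general in
the code contract but multi-proband pooling is out of scope.

### Variants absent from the background

Unseen variants are treated as absent from the background *sample*:
x_u = 0 with n_b equal to the median AN across the database (configurable).
The median is the least surprising stand-in for per-site coverage that was
never observed.

### Transcript aggregation

Each transcript annotation is scored with its own change type; the variant
reports the transcript maximizing the het-state score — the conventional
most-severe-consequence rule. Unannotated variants are scored with impact 1
and, when gene models are supplied, assigned a gene and region by
coordinate overlap; otherwise they fall into the intergenic class.

## Impact parameters

a(type, bin) is the proportion of change type *type* at conservation *bin*
among disease-causing training variants; h is the same over population
variants. Types: missense, stop-gain, stop-loss, start-loss, splice-site,
synonymous, in-frame indel (length difference ≡ 0 mod 3), frameshift indel,
non-coding change, intergenic change. Estimation uses additive smoothing,

    a(type, bin) = (count + pc) / (N + pc·K),   K = #types × #bins,

with pseudocount pc = 1 by default so every cell is strictly positive;
pc = 0 is allowed for exact proportion checks, but unobserved cells then
make the ratio undefined and raise. Distinct variant keys are counted once.
Conservation uses 2 bins split at 0.5 (conserved vs not) by default; the
bin index is floor(c·n_bins) clamped at the top.

Empirical tables key missense by its kind, not by amino-acid pair: with
training sets of realistic desk scale, per-pair cells would be hopelessly
sparse. Pair-level resolution is delegated to the `blosum` mode, which maps
a BLOSUM62 substitution score s to the ratio exp(−s/2), clipped to
[0.1, 10] — any strictly monotone decreasing positive map serves, and only
monotonicity is load-bearing (and tested). Non-missense types get fixed
ratios in blosum mode following the usual severity ordering (truncating 8,
splice/start-loss 6, stop-loss 4, in-frame 3, synonymous 0.5, non-coding
and intergenic 1). `off` mode returns exactly 1 everywhere, reducing the
score to pure frequency evidence.

## Percentile normalization

Raw het-state scores of the whole background, grouped per gene and effect
class (coding / non-coding; synonymous, intronic and UTR changes count as
non-coding; everything outside gene bodies pools into one intergenic
class), form cumulative rank distributions. The percentile of s among n
background scores is 100·(#{< s} + ½·#{= s})/n — mid-ranks, so scoring a
background set against its own CRD has mean exactly 50 — with linear
interpolation between distinct scores and saturation at 0/100 outside the
observed range (percentiles are ranks, not densities; no extrapolation).
Hom scores map through the same (het-built) CRD, so the hom percentile of a
rare variant reads as "where would this raw score sit among background
variants". Genes with fewer than 10 background variants in a class fall
back to the pooled class-wide CRD, flagged on the output. Percentiles are
only comparable within an effect class; raw scores compare across classes.

## Coordinate and key conventions

VCF positions are 1-based; BED/bedGraph intervals half-open; conversions
happen only at the I/O boundary. Region masks drop a record when its POS
falls in [start, end). Multi-allelic rows split into one record per alt;
symbolic alleles are skipped with a warning. Alleles are reduced to a
minimal representation (shared suffix then prefix trimmed) before keying,
so padded and unpadded spellings of the same indel collide; true
left-alignment against a reference FASTA is not performed — the pipeline
never carries the reference sequence — so indels differing by placement
within a repeat run remain distinct keys. Conservation of a multi-base
reference span is the maximum over the span (conservative toward detecting
constrained sites); uncovered positions default to 0 (configurable).
Unknown consequence terms classify as intergenic with a warning rather than
failing, since any variant anywhere must remain scorable.

## Evaluation statistics

ROC sweeps all distinct thresholds with "score ≥ threshold ⇒ called
pathogenic"; AUC is the trapezoid integral, equal to the tie-corrected
rank-sum probability (tested against an independent rank-sum computation).
Youden's J = Sn + Sp − 1 is reported against (score − min)/(max − min), a
normalization that keeps negative raw scores in [0, 1]; the optimal
threshold is the lowest score attaining max J, and accuracy = (J + 1)/2.
Clinical utility is accuracy at a threshold times the fraction of variants
scored at all; unscorable items are excluded from ROC/J but counted here
and in the "not scored" column of call-rate tables. Mean-score-versus-
frequency profiles use logarithmic frequency bins with empty bins omitted.

## Synthetic study system

The generator emulates the statistical structure the method relies on, at
a size chosen to exercise every code path in seconds:

- 50 genes of 3 kb (40% coding, single CDS) separated by 2 kb intergenic
  gaps, on one chromosome; 500 diploid individuals.
- Gene burden: per-gene log-normal rate multipliers (σ = 0.4).
- Densities: 12 coding, 24 non-coding, 4 intergenic variants/kb — intronic
  variation denser than exonic, as in real genomes.
- Allele frequencies: Beta(0.2, 4) truncated to [1/(2N), 0.5] — heavy at
  rare alleles, with no claim of demographic realism; genotypes are
  Hardy-Weinberg binomial draws, and AC/AN record the realized counts
  (sites with zero realized copies are dropped).
- Conservation: per-base Beta draws, coding Beta(6,2), non-coding
  Beta(2,6), intergenic Beta(1,9), emitted as 1-bp bedGraph intervals for
  exact round-tripping.
- Pathogenic test variants (500): true frequency ≤ 10⁻³ (absent from the
  emitted background), placed at unused coding positions with conservation
  ≥ 0.6, with damaging types (30% stop-gain, 30% frameshift, 30% drastic
  missense with BLOSUM62 ≤ −2, 10% splice). Benign test variants (500) are
  background variants re-presented with their realized frequencies.
- Impact training sets are generated independently of the test set: a
  disease set with the damaging-type mixture at conserved coding sites and
  a population set mirroring the background type distribution.

Every generator is a pure function of its config; the same seed yields
byte-identical files.

What passing the synthetic benchmark shows: the pipeline's components
compose correctly and recover designed-in separation (AUC ≥ 0.95 at the
default configuration). What it does not show: performance on real data —
the generator has no sequencing error, no population stratification, no
linkage, no annotation noise, no balancing selection, and its pathogenic
variants are separable by construction. Real-data operating points
(thresholds, call rates) must be calibrated on real resources.

## Numerical and design choices

- Binomial log likelihoods via `scipy.special.xlogy` (exact 0·ln 0 = 0);
  impossible observations return −inf rather than raising, but never occur
  with plug-in MLEs.
- CRDs store distinct scores with their mid-rank percentiles; save/load of
  the database round-trips floats via `repr` (lossless).
- The database file is a versioned, sorted, plain TSV with a JSON header
  and an explicit end marker (truncation is detected), rather than a
  compressed binary format: correctness and diffability over compactness
  at desk scale.
- The impact mode used to build the background CRDs is recorded in the
  database and enforced at scoring time; mixing modes would make raw
  scores incommensurable with the CRDs.
- Ties in evaluation thresholds are grouped (one threshold per distinct
  score); the optimal-threshold tie-break picks the lowest score.
- Repository contents (and the synthetic background) are scored in the
  het state; CRDs are built from het scores only, and hom scores map
  through the same curve.

## Known limitations

- No multi-proband or pedigree-aware scoring; no gene-level burden test.
- Indel keys are minimal-representation, not reference-left-aligned.
- Empirical impact tables need training sets of at least a few hundred
  variants to beat the pseudocount floor.
- Percentiles saturate at 0/100 outside the background score range, so
  extreme novel variants in small genes are capped.
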