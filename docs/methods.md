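# Methods

## The design being modelled

Two divergent chicken breeds (a commercial broiler line and a transgenic
layer line) are crossed; F1 brothers and sisters are mated; F2 birds are
phenotyped by expression profiling of cultured macrophages with and
without LPS stimulation. Sibling mating drives alleles carried by single
grandparents toward homozygosity: a variant heterozygous in one F0 bird is
homozygous in 1/16 of F2 progeny, and a variant for which the two F0 birds
are homozygous for opposite alleles segregates het × het in every F1
mating, giving 25% homozygotes. The analyses in this package are the
screens that exploit this: null-expression-allele detection from extreme
between-bird variation, dosage-group classification, Z dosage-compensation
ratios, LPS response counting, co-expression clustering and family
contrasts.

## Simulation model

`simulate_cohort` generates the whole design from a single
`SimulationConfig`:

1. **Founders.** Each gene gets one biallelic cis locus. A fraction
   `breed_fixed_fraction` (default 0.3) of autosomal loci are near-fixed
   for opposite alternative alleles: the high breed's frequency is drawn
   from U(0.95, 1), the low from U(0, 0.05), and the realized
   minority-allele count is capped at ⌊0.05 · n_alleles⌋ so near-fixation
   is a property of the panel itself, not just of the sampling law.
   A fraction `het_null_fraction` (default 0.1) of autosomal genes outside
   the mesenchyme module carry a null (zero-effect) alternative allele
   heterozygous in exactly one founder, annotated with a loss-of-function
   consequence drawn with the relative prevalence of stop-gained,
   stop-lost, start-lost and splice-site classes typical of such panels.
   Remaining loci carry common variation (both breeds U(0.1, 0.9)).

2. **Pedigree and gene drop.** F0 broiler × layer pairs; `n_f1_pairs`
   (default 15, one per F2 family) brother–sister F1 pairs allocated
   round-robin over the F0 crosses; `n_f2_per_family` (default 2) profiled
   F2 birds per family with random 1:1 sexes. Transmission is Mendelian:
   one allele per parent per autosomal locus; sons receive one Z from each
   parent, daughters the sire's Z and the dam's W. The default cohort (30
   F2 birds, 60 paired samples) approximates the scale of a hatchling
   profiling experiment over 15 families; real studies profile an
   irregular subset of families, which we replace by a regular 2-per-family
   design.

3. **Expression.** Expected TPM of gene *g* in sample *s* is the product
   of
   - the **cis term**: the sum of per-copy allele effects (half the
     baseline drawn log-uniformly from `baseline_tpm_range`, default
     25–250 TPM, per functional allele; 0 for a null allele; non-null
     autosomal alternative alleles carry a cis fold-effect of 2^U(−1,1)),
   - the **dosage term** for Z genes: males sum two copies, females one
     copy times `dosage_compensation_factor` ∈ [1, 2] (default 4/3, so
     the expected male/female ratio is 2 / factor = 1.5); W genes emit
     exactly 0 in males,
   - the **LPS term** for stimulated samples: 2^lfc with lfc ~ N(2.5, 0.5)
     for induced and N(−2.5, 0.5) for repressed genes; for the
     `trans_module_size` (default 40) trans-target genes the lfc is
     multiplied by `trans_effect_per_alt_allele`^(alt copies at the trans
     locus) (default 1.5), which makes the module's induction co-vary
     across birds and therefore co-cluster,
   - the **mesenchyme term**: the `mesenchyme_module_size` (default 30)
     contamination genes are scaled by a per-sample fraction drawn from
     `mesenchyme_fraction_range` (default U(0.02, 0.5)), emulating the
     variable mesenchymal content of hatchling bone-marrow cultures,
   - multiplicative log-normal noise 2^N(0, `noise_sd_log2`) (default
     0.2, a typical between-replicate spread for bulk RNA-seq TPM at
     moderate expression).

   Columns are *not* renormalized to 10⁶ by default, so planted effects
   are exactly recoverable; `renormalize_tpm` turns on the (1 − fraction)
   coupling of non-mesenchyme genes for realism at the cost of
   testability.

All randomness flows from one master seed through named per-stage
substreams (founders / pedigree / gene drop / expression), so identical
configs are byte-for-byte reproducible and each stage is independently
reproducible.

### What the generator does not emulate

Read-level noise, alignment and quantification artefacts, batch effects,
linkage between loci (every locus segregates independently), dominance or
epistasis, TPM compositional coupling (off by default, see above), and
viability selection (a low-fitness family is analysed downstream, not
simulated mechanistically). Passing tests therefore demonstrate that the
screens recover the planted structure under the stated statistical model,
not that they are robust to artefacts absent from it.

## Screening statistics and numerical choices

- **Detection filter:** retain iff max over samples ≥ 10 TPM (removal of
  "maximum expression < 10" and "expressed > 10 TPM" are unified at the
  ≥ 10 boundary).
- **Max/min ratio:** computed on raw TPM; min = 0 is reported as an
  infinite sentinel with both extremes preserved. A pseudocount of 0.5 TPM
  is used *inside* log and fold computations only.
- **Extreme variation:** max > 20 and min < 1 TPM, both strict.
- **Dosage groups:** samples are sorted and split into k ∈ {1, 2, 3}
  contiguous groups on log2(TPM + 0.5), minimising
  n·log(SSE/n) + penalty·k·log(n) (penalty weight 1 by default, a BIC-style
  charge per group); ties prefer fewer groups. The additivity score
  |m₁ − (m₀ + m₂)/2| / m₂ is 0 for a perfectly additive 0/1/2-copy gene.
  A **candidate null** call additionally requires the lowest group to lie
  entirely below 1 TPM *and* to be separated from the next group by at
  least max(5 × group max, 2 TPM). The gap requirement is what
  distinguishes a discrete genotype class from the lower tail of a
  continuous gradient (e.g. mesenchymal contamination), and is the reason
  the screen makes no false null calls at zero noise. The screen is
  restricted to autosomes: W genes trivially show a near-zero male class
  and Z hemizygosity confounds the 0x/1x/2x logic, so sex-linked genes are
  reported with their chromosome class by the extreme-variation flag but
  not called.
- **Sex ratios:** per-gene mean(male)/mean(female) on genes expressed in
  both sexes; the summary is the median across genes of the class, and a
  gene is "dosage compensated" when a 1000-replicate nonparametric
  bootstrap 95% interval of its ratio covers 1.
- **LPS response:** strictly paired by individual (unpaired samples are
  excluded with a warning); fold = (mean LPS + 0.5)/(mean control + 0.5);
  induced iff fold > 2 (strict), repressed iff fold < 1/2.
- **Family contrast:** per-stratum means; eligible iff either mean > 1 TPM
  (strict); up iff ratio > 1.5, down iff ratio < 0.67 — the conventional
  0.67 is used literally rather than 1/1.5, so up/down are exactly
  symmetric only under reciprocal bounds (both are configurable). The
  pseudocount enters only when the denominator mean is 0. Control and LPS
  strata are never pooled.
- **Variant filtration:** quality minima pass at equality (≥); the missing
  rate is computed after genotype-quality masking, over samples that carry
  the locus, and the ceiling passes at equality (≤). Multi-allelic records
  are split into biallelic records on load; calls involving a third allele
  become missing in the split record. Missing genotypes are excluded from
  allele-frequency denominators and mean-imputed only inside the PCA;
  hemizygous calls contribute one allele to frequencies and are tallied
  separately from the diploid classes.

## Markov clustering

Canonical MCL on the thresholded correlation graph: edge weights are the
Pearson r (binary weights optional; the weighted form is the default since
the choice is not determined by convention), self-loops equal each node's
maximum incident weight, columns are normalized, and the iteration
alternates expansion (matrix square) with inflation (entrywise power
1.7, renormalization), pruning entries below 10⁻⁵ (each column always
keeps its maximum) until the matrix changes by < 10⁻⁶ in max-norm or 200
iterations (non-convergence returns the current clustering with an
explicit warning). Clusters are the connected components of the converged
support; groups smaller than 3 are reported as unclustered, and clusters
are numbered by decreasing size with lexicographic tie-break. Correlations
are computed on raw TPM by default with a log2(TPM + 1) option; the
analysis drivers use the log scale, where the planted module structure is
multiplicative. The test suite validates the implementation against an
independent straight-loop reference on a 20-graph fixture suite and checks
component locality and column-stochasticity invariants.

Enrichment replaces web annotation services with local hypergeometric
upper-tail tests per gene set and Benjamini–Hochberg adjustment across
sets.

## Problem sizes

The default study (520 genes, 30 F2 birds, 60 samples) and the 200,000
replicate gene-drop runs were chosen so a complete analysis, the full test
suite and the acceptance script each run in well under a minute to a few
minutes on a single CPU; all sizes scale through `SimulationConfig`.

## Known limitations

- Null recovery sensitivity is defined over nulls that actually segregate
  to homozygosity among profiled birds; with 30 profiled birds and
  unselected F1 pairs only a minority of planted nulls reach that state
  (1/16 per bird in families descending from the carrier). Selecting F1
  pairs by genotype (`select_f1_pairs`) is how a real program, and a
  larger simulation, raises that yield.
- The dosage-group classifier assumes at most three classes; a locus with
  more than two functional alleles of distinct effect would be folded into
  the nearest three-group approximation.
- Z-locus segregation expectations are returned sex-stratified; the
  package does not model Z inactivation heterogeneity, only a single
  multiplicative compensation factor.
- The enrichment module tests over-representation only (one-sided).
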