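# Methods

## The copying model

The engine is a haploid Li–Stephens HMM.  States are the N reference
haplotypes; observations are the target's 0/1 alleles at the S typed sites.

* **Emission**: P(o | h = k) = 1 − ε on a match, ε on a mismatch, with
  ε ∈ (0, 0.5).  Default ε = 10⁻³, the scale of a genotyping error rate and
  the conventional choice for this model family.
* **Transition**: between adjacent typed sites, jump to a uniformly chosen
  haplotype with probability q_i = 1 − exp(−4·Ne·g_i / N), else stay.
  g_i is the genetic distance in Morgans, taken from a genetic map when
  supplied and otherwise from a constant 1 cM/Mb.  Default Ne = 10⁴.
  These are the canonical published defaults; none of them is sharply
  identified by desk-scale data, and all are exposed on `HmmParams`.
* **Posteriors**: scaled forward–backward (per-site renormalisation rather
  than log space — exact after row normalisation, and considerably faster).
  Rows of the posterior matrix sum to 1 within 10⁻⁸ by construction.
* **Untyped sites**: donor weights are linearly interpolated between the
  flanking typed sites in *physical* position (barcodes are placed 1 bp
  downstream of a tagged site, so bp is the natural axis; genetic-map
  interpolation would move barcode weights off the tagged site whenever map
  distance and bp distance disagree).  Beyond the first/last typed site the
  nearest row is copied.  The haplotype dosage at an untyped site is the
  weighted mean of the reference alleles, hence always in [0, 1].

Correctness is anchored to an exhaustive hidden-path enumeration oracle on
instances with N ≤ 4, S ≤ 5 (agreement to 10⁻¹⁰; in practice machine
precision).

### The recombination scale under panel reduction

When a strategy removes groups, `run_with_assignment` keeps the transition
scale of the *full* panel: q_i and the per-donor jump mass q_i/N use the
augmented panel's haplotype count, not the reduced subset's (the scaled
forward–backward renormalises the slightly substochastic kernel).  Two
reasons.  First, comparability: the baseline and every reduced run share
the same copying dynamics, so dosage differences reflect the panel content,
not an N-dependent rate change.  Second, it makes panel reduction
*monotone*: removing haplotypes that carry (near-)zero posterior mass
perturbs the remaining dosages only by that mass — measured below 10⁻⁹ in
the acceptance checks — whereas rescaling q to the reduced N would shift
every transition at order q regardless of the removed group's relevance.
A standalone `forward_backward` call on a panel uses that panel's own N,
i.e. the standard parameterisation.

## Barcodes

Tagged-site selection applies, in order: panel-wide MAF > 0.2; greedy
left-to-right LD pruning so each retained pair within a 1 Mb window has
r² < 0.02 (deterministic and order-stable; the window bounds the cost);
and the shoulder rule — any candidate with another panel site within 1 bp
downstream is dropped so the barcode position is free.  MAF is computed on
the reference panel, the natural universe when targets are held out.

Each batch inserts one synthetic record per group at tagged position + 1,
allele 1 exactly on that group's haplotypes, REF/ALT written as A/T (no
biological meaning), flagged `SYNTH`.  Synthetic records are untyped and
excluded from every metric.  Neutrality of the injection is structural —
untyped records cannot enter the forward–backward pass — and is asserted
exactly (difference 0.0) rather than approximately.

Because the groups partition the panel and dosages are convex combinations
of indicator alleles, the group dosages of a batch sum to 1 (closure,
within interpolation round-off), and a batch's dosage vector equals the
group posterior mass at the tagged site up to the interpolation weight
λ = 1/(next typed position − tagged position).

Global proportions are barcode sums scaled to 1, reported per individual
(mean of its two haplotypes) by default.

## Strategies

* **Chunks** hold approximately equal numbers of typed sites; boundaries
  fall midway between the flanking typed sites, so every site maps to
  exactly one chunk.  Each chunk is imputed with a 250 kb buffer on each
  side that feeds the HMM but is never reported.  The default chunk size
  is ~300 typed sites, chosen so a default scenario yields a handful of
  chunks whose span stays below the mean admixture tract length and which
  each hold tens of barcodes — the regime a genome-scale run split into a
  few hundred chunks operates in.  With chunks much longer than tracts, or
  with only a few barcodes per chunk, the 0.9 threshold starts to misfire:
  short true contributions can fall between barcodes.
* **Informed choice** applies the 0.9 threshold to *haplotype-level*
  barcode dosages (the pseudo-individual route divides by 2 first, so the
  threshold reads naturally on [0, 1]); the threshold is exposed.  If no
  group passes in a chunk, the argmax group is retained — the strategy's
  intent is minimal panels, and an empty panel is not an option; the
  fallback is logged.  A chunk with no barcodes retains all groups.
* **Global threshold** keeps groups with per-individual proportion > 0.01,
  one set for both haplotypes across all chunks; the proportions may come
  from the barcodes or from an external ancestry-deconvolution table.
* The baseline that reduced runs are compared against is the *same chunked
  machinery* with every group retained, so "no-op reduction = baseline" is
  exact (bit-identical) rather than up to chunk-edge effects.

## Evaluation

AR2 is operationalised as the squared Pearson correlation between imputed
genotype dosages and true genotype counts pooled over the (variant,
individual) pairs of a MAC bin; the same formula per individual gives the
individual-level AR2.  Pooling (rather than averaging per-variant R²)
keeps the statistic defined for bins dominated by rare variants, where
most variants individually have near-constant truth.  A bin whose pooled
truth is constant is reported as undefined, as is any per-individual AR2
with constant truth.  The implementation is cross-checked against an
independently coded covariance-over-variances formula to 10⁻¹².

Hard calls round dosages to the nearest of {0, 1, 2}; exact half-way values
round up (declared, tested, and configurable only by pre-transforming the
dosages).  Confusion tables count truth × call over all individuals and
variants at MAC 0–3 in the combined target group; per-cell percentage
changes between runs are 100·(reduced − baseline)/baseline.

## The simulator

What it emulates: K differentiated populations via Balding–Nichols
frequencies (ancestral frequency uniform on (0.05, 0.95); group frequency
Beta with mean p and variance scaled by Fst); within-population LD via
founder haplotypes copied in mosaics with a per-bp switch rate (default
5×10⁻⁶, i.e. ~200 kb founder segments); admixed targets as tract mosaics
with exponential tract lengths and known truth; a genotyping-array subset
(common sites, MAF ≥ 0.05, evenly thinned to 30% of sites); and
group-private MAC 1–3 variants standing in for recent mutations.  All
randomness derives from one seed; runs are bit-identical.

Default scenario: 5 groups × 40 haplotypes, 4000 sites on 8 Mb, Fst 0.1,
20 target individuals admixed 75/15/5/3/2 with 2 Mb mean tracts — a
desk-scale analogue of imputing recently admixed individuals against a
continental panel, scaled to preserve the ratios that matter for the
method (tract length vs chunk span, barcodes per chunk) rather than
absolute genome size.

Targets copy haplotypes that remain in the panel (plus a 0.1% copy-error
rate so they are never exact duplicates).  That makes imputation close to
its easy mode: the true donor is available, posteriors concentrate, and
rare-variant false positives are vanishingly rare.  For the rare-variant
study, `simulate_held_out_study` instead draws the copying donors from a
per-group reserve that is excluded from the reference panel — targets then
come from the panel's populations without their exact haplotypes being
present, which is the realistic regime in which an irrelevant group's
private alleles can be borrowed and mis-imputed.  The packaged
`private_rare_scenario` uses three groups at Fst 0.05 (moderately
differentiated, so borrowing happens), targets admixed 70/30 over the
first two, and 120 private MAC 1–3 variants on the third, irrelevant
group.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: coalescent genealogies and realistic LD
decay, variable recombination maps, genotyping and phasing error in the
targets, allele-frequency spectra (Balding–Nichols over-represents common
variation), and genome-scale site counts.  Directional conclusions (the
informed-choice strategy does not degrade accuracy; it reduces
false-positive heterozygotes at target-monomorphic sites) reproduce at
desk scale; absolute counts and percentages do not transfer.

## Numerical and degenerate cases

* Exact 0.5/1.5 genotype dosages hard-call upward; dosage sums are clipped
  into [0, 2] for round-off at the boundaries (tolerance 10⁻⁹) before
  rounding.
* Zero tagged sites: injection is a no-op and the workflow warns rather
  than fails; proportion estimation requires ≥ 1 batch.
* A panel with one haplotype yields posterior 1 everywhere; a single typed
  site is accepted by the engine (no transitions), though the I/O layer
  requires S ≥ 2 for meaningful interpolation.
* Missing or unphased genotypes are errors by design: the panels this
  models are complete and phased.

## Known limitations

One chromosome per run (the chunking assumes a single linear coordinate
system); no multi-allelic records, no BCF, no streaming of
chromosome-scale files; no PBWT-style state compression, so N is expected
in the hundreds, not hundreds of thousands; phasing of targets is assumed
given.  The two-pass donor re-weighting idea (prioritising globally
relevant groups *within* the HMM rather than by panel pruning) is out of
scope.
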