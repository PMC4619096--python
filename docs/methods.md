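# Methods

## The problem

A study animal genotyped on a low-density SNP chip (the typed set *T*) has
the vast majority of its genome-wide SNPs untyped (the set *U*).  Given a
reference panel of individuals genotyped at the higher density *T∪U*,
population-based imputation fills the untyped genotypes by exploiting
linkage disequilibrium: short haplotype stretches are shared
identical-by-descent, so a study sample's typed haplotype context identifies
reference haplotypes that likely carry its untyped alleles.  Running the
base imputation engine once from *T* to *T∪U* is *one-step* imputation, with
genotype-concordance accuracy acc₁.

## Two-step piecemeal imputation

Empirically, imputing through an intermediate medium-density array can beat
a direct one-step run.  The piecemeal framework *constructs* such an
intermediate array computationally instead of using a manufactured chip:

1. **Add-one experiments.**  For each untyped marker m_i, run a two-step
   imputation *T → T∪{m_i} → T∪U*.  The per-marker accuracies a_ij of that
   run measure m_i's *potential* for helping every other untyped marker; the
   diagonal a_ii is the one-step accuracy of m_i itself from *T*.  The
   vector v_i = ⟨a_i1, …, a_i|U|⟩ is m_i's feature vector, and the stacked
   vectors form the |U|×|U| feature matrix.
2. **Marker clustering.**  Markers with similar feature vectors are
   interchangeable, so k-means (Lloyd's algorithm, k-means++ seeding, best
   of 10 restarts by within-cluster sum of squares) groups *U* into clusters
   C₁…C_k.  The Davies–Bouldin index is reported as a diagnostic; the
   operative choice of k is by downstream accuracy (below).
3. **Target clusters (tracts).**  For cluster C_i, a marker m_j belongs to
   the tract TC_i iff the mean of a_ij over the members of C_i (defined
   entries only) is ≥ the baseline.  The default threshold is the global
   one-step accuracy acc₁ (`global_acc1`); a `per_marker` mode thresholds
   against each marker's own one-step accuracy instead, because
   "imputed at least as well as one-step" admits both readings.  Tracts may
   overlap and need not cover *U*.
4. **Selection.**  The representative m_i* of C_i maximizes the mean
   add-one accuracy over TC_i (its *contribution*); ties break by genomic
   order.  An empty tract selects nothing.  T plus the selected markers
   M = {m₁*, …, m_k*} is the pseudo-array.
5. **Assembly.**  At application time each selected marker contributes one
   *piece*: an add-one two-step run whose calls are kept only on its tract.
   A single one-step run supplies a fallback call for every untyped marker.
   Each (sample, marker) call covered by ≥1 piece is decided by majority
   vote over the covering pieces; when the top count is tied the fallback
   call wins if it is among the tied dosages, otherwise the smallest tied
   dosage does; uncovered markers keep the fallback.  Typed calls always
   pass through unchanged, so a model whose tracts are all empty is
   bit-identical to one-step — the framework can only act where it claims
   to help.

Training runs inside an n-fold cross validation (default 5): each fold is
rotated as the masked study set against the remaining folds as reference,
the per-fold feature matrices are averaged entrywise (undefined entries
excluded; an entry undefined in every fold stays undefined), and each
candidate k in the grid is scored by the fold-averaged piecemeal accuracy
acc_π.  The best k wins (smallest on ties).  Independent testing applies
the frozen model to held-out samples, reporting acc_π next to acc₁.

**Per-piece versus joint first step.**  At test time the first step could
impute all of M jointly and then run a single second step.  The default
follows the training-time protocol — one add-one run per piece, assembled
by vote — which is the reading consistent with the tract definition;
`two_step_pseudo_array()` provides the joint-M alternative for comparison.

**Staircases.**  Chaining piecemeal legs across nested density tiers
(e.g. 20 → 80 → 300 markers here; 6K → 50K → HD → sequence in cattle
practice) gives multi-step imputation, each leg's output becoming the next
leg's typed input.  A leg may be the `ONE_STEP` sentinel: a direct base run,
the usual choice for the final leg to sequence density, where training
storage is prohibitive and one-step is already strong.

## Base imputation engines

The framework is engine-agnostic; the engine contract is: fill every
missing study call at reference-typed markers with a dosage, never alter a
typed call, be deterministic for fixed inputs.  Built-ins:

- **MajorityImputer** — per-marker reference mode, ties toward the smaller
  dosage.  LD-blind; useful as a floor and for closed-form oracles.
- **KNNGenotypeImputer** — for each missing call, take the
  `window_typed_markers` typed markers nearest the target position on the
  same chromosome (default 11, odd so the focal neighborhood is centered;
  truncated at chromosome ends; counted in markers, not base pairs, so tier
  density does not change neighborhood semantics), compute Hamming distance
  to every reference with a call at the target, let the `k_neighbors`
  closest (default 5; distance ties by reference order) vote, and return the
  dosage mode (ties toward the smaller dosage).  This is a deliberately
  transparent LD-aware engine, not a reimplementation of any published
  haplotype-clustering or long-range-phasing model.
- **ExternalCommandImputer** — a subprocess adapter (VCF round-trip) for
  wiring in external engines.  It inherits the external program's
  randomness and is therefore exempt from the determinism contract and
  excluded from the test surface; typed calls are restored after the
  round-trip to uphold the contract regardless of engine behavior.

## Synthetic populations

`simulate_truth` emulates exactly the statistical structure the method
exploits.  A pool of `n_founder_haplotypes` founder haplotypes (default 4)
is drawn with per-marker allele frequencies uniform on
[maf_min, 1 − maf_min] (default maf_min 0.1), the allele count clipped so
the empirical founder MAF respects the floor.  Each individual carries two
mosaic haplotypes: the founder index is redrawn uniformly between adjacent
markers with probability `recomb_prob_per_interval` (default 0.02).  LD
arises purely from the finite shared founder pool — the identical-by-descent
sharing that coalescent theory predicts — without simulating a genealogy.
Genotype error flips each call to one of the other two dosages with
probability `error_rate` (default 0.01).  Marker positions are uniform,
distinct and sorted on one chromosome; nested tiers (default 20/80/300 of
300 markers, echoing the 6K ⊂ 50K ⊂ HD ⊂ sequence nesting of real chip
hierarchies at desk scale) are cut by uniform spacing or seeded random
subsampling.  Reference and study individuals come from the same founder
pool, mirroring the within-breed setting in which this kind of imputation
is done.

What the generator does *not* emulate: mutation, pedigree structure,
selection, realistic map distances, allele-frequency spectra of real chips,
or cross-breed divergence.  Passing tests therefore demonstrate the
correctness and internal consistency of the procedure — not field accuracy
on real livestock data, which depends on the engine and panel in use.

Two analytically transparent regimes anchor the test-bench:

- *Perfect recovery*: zero recombination, zero error, 2 founders.  Every
  genotype is determined by the founder pair, so a 1-NN engine with any
  distance-zero reference neighbor attains accuracy 1.0 through training,
  testing and staircases — an exact upper-bound oracle.
- *Equivalence guard*: with all tracts empty the piecemeal output must be
  bit-identical to one-step on any instance.

## Defaults, numerical choices, edge cases

- Genotypes are unphased alt-allele dosages {0,1,2}; missing is −1 in
  memory, "NA" in TSV, "./." in VCF.  Phase is discarded on input: the
  procedure operates on genotypes.
- Accuracy is exact-dosage genotype concordance.  Calls with missing truth
  are excluded from the denominator; an imputed-missing call with known
  truth counts as wrong.  Zero evaluable calls yield NaN (undefined), which
  propagates into feature entries as UNDEFINED.
- Undefined feature entries are excluded from fold averaging, thresholds and
  contributions; for Euclidean distances (clustering, Davies–Bouldin) they
  are imputed as column means (an all-undefined column becomes a constant,
  distance-neutral).
- k-means: restarts 10, max_iter 300, seeded; each k in a sweep derives its
  own seed as `seed + k`.  k selection uses CV piecemeal accuracy, smallest
  k on ties; the Davies–Bouldin score is recorded as a diagnostic only.
- A non-empty tract whose members all have undefined contributions selects
  the genomically first member (keeps "selected iff tract non-empty").
- The tie order everywhere (dosage modes toward the smaller dosage,
  neighbor ties by reference order, selection ties by genomic order, vote
  ties by fallback-then-smaller) exists so that every run is bit-for-bit
  reproducible.
- Fold assignment is a seeded shuffle plus round-robin; an optional strata
  map (a generic stand-in for subpopulation labels such as country of
  origin) deals round-robin within each stratum so labels spread across
  folds.  The synthetic generator defines no strata.
- Models serialize as versioned JSON (panels, clustering, tracts,
  selections, baselines, training sample ids); feature matrices as
  versioned TSV, one file per fold if persisted.  Both are plain text by
  design at this scale.

## Benchmark sizes

The standard benchmark (also what `scripts/acceptance.py` recomputes) uses
60 reference and 20 study diploids on 300 markers with tiers 20/80/300,
training 20→80 (|U| = 60) by 5-fold CV over a cluster grid 5..30 step 5,
then independent testing and a two-leg staircase to the 300-marker tier.
These sizes are the package's desk-scale working point: large enough that
the k-NN engine leaves genuine headroom between acc₁ and 1.0 for the
piecemeal step to claim, small enough that the full train-and-test cycle is
interactive (seconds, one CPU).  The cluster-sweep protocol check uses a
separate 130-marker instance so the canonical 5..100-by-5 grid (20 entries)
is exercised on a 100-marker U.

## Known limitations

- The built-in engines are intentionally simple; absolute accuracies here
  say nothing about what a production engine would reach, only the relative
  piecemeal-versus-one-step comparison is meaningful.
- Multi-allelic sites, phasing, dosage probabilities, X-chromosome ploidy
  and genome-scale storage management are out of scope.
- Add-one experiments cost |U| two-step runs per fold; at genome scale this
  is the dominant (and in practice storage-bound) phase.  Rows of the
  feature matrix are independent by construction, so they can be computed
  in any order or in parallel without changing the result.
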