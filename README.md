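# disconseq

**Sequencing lesion-driven regional structural disconnection from
cross-sectional data.**

White-matter lesions (as in multiple sclerosis) sever tractography
streamlines and thereby disconnect grey-matter regions. Which regions become
disconnected *first* as disability grows — and which follow — cannot be read
off a single scan, and longitudinal cohorts long enough to watch the process
are rare. `disconseq` estimates that ordering from a single cross-sectional
cohort, for researchers studying lesion-network effects and disease staging.

## What it computes

1. **Regional structural disconnectivity.** Given a normative streamline
   database with a parcellation, a binary lesion mask is scored per region as

   *x*ₚ = (streamlines connected to region *p* that pass through the lesion) /
   (streamlines connected to region *p*),

   a fraction in [0, 1]. A streamline "connects" a region iff an endpoint
   voxel carries its parcellation label; it is "disrupted" iff any traversed
   voxel is lesioned. Subjects without a lesion of the scored class get 0.

2. **Data-driven region selection.** Disconnectivity is log-transformed
   (`log(x + ε)`), groups are compared per region with pooled-variance
   Student *t* tests (BH-corrected), and each of 100 stratified bootstraps
   re-ranks regions by *t*; the top-*k* (default 20) regions by average rank
   enter the model. Age and sex are regressed out of the selected metrics.

3. **A discriminative event-based model (EBM).** An *event* E*ₚ* is region
   *p*'s biomarker leaving the healthy distribution for the pathological one.
   Per region a two-component Gaussian mixture supplies P(*x*ₚₙ | E*ₚ*) and
   P(*x*ₚₙ | ¬E*ₚ*); with a prior P(*k*) over each subject's latent stage
   *k* (number of events passed), the likelihood of an event order *S* is

   P(X | S) = ∏ₙ Σₖ P(*k*) · ∏ₚ≤ₖ P(*x*₍S(p)n₎ | E) · ∏ₚ>ₖ P(*x*₍S(p)n₎ | ¬E).

   The maximum-likelihood permutation is found by greedy pairwise-swap ascent
   from random restarts (provably equal to exhaustive enumeration at small
   P); mixtures and order are then refined jointly by coordinate ascent.
   100 stratified bootstraps refit everything and yield the positional-
   variance diagram, event centres with standard errors, a one-sample *t*
   test of final-position frequencies against chance (1/P), and a posterior
   stage for every subject.

Because no suitable public cohort ships with lesion masks at this scale, the
package includes a first-class synthetic module that plants a known event
sequence — directly as biomarker matrices, and geometrically as lesion masks
on a toy tractogram — so every stage can be validated against ground truth.

## Worked example

`examples/04_fit_sequence.py` plants a 12-region order in a 300-subject
cohort (2 SD component separation), fits the model and bootstraps it:

```
recovered order: region_009 -> region_012 -> region_005 -> region_008 -> region_006 -> region_001 -> region_002 -> region_010 -> region_003 -> region_011 -> region_007 -> region_004
planted order:   region_009 -> region_012 -> region_005 -> region_008 -> region_006 -> region_001 -> region_002 -> region_010 -> region_003 -> region_011 -> region_007 -> region_004
Kendall tau vs truth: 1.000  (1.0 = identical order)
log-likelihood of the fitted sequence: 7057.2
randomness test: t = 18.72, one-sided p = 5.4e-10 (small p: the order is reproducibly non-random across bootstraps)

event centres (mean bootstrap position, 1-based) +/- SE:
  region_009:  1.10 +/- 0.04
  region_012:  1.90 +/- 0.04
  ...
```

The recovered permutation matches the planted one exactly (Kendall τ = 1);
the event centres advance in near-integer steps with small standard errors,
and the randomness test rejects the hypothesis that positions are assigned
by chance. The other scripts in `examples/` cover cohort simulation, lesion
scoring, region selection, the full pipeline, and the joint analysis of two
lesion-mask classes (e.g. rim vs rimless lesions as 2×P namespaced metrics).

## Command line

A thin CLI wraps the library for shell use:

```bash
disconseq simulate --n-subjects 482 --n-regions 86 --seed 7 --out sim/
disconseq score --streamlines db.trk --parcellation parc.nii.gz \
                --subject-table subjects.tsv --out scores.tsv
disconseq select --cohort sim/cohort.tsv --top-k 20 --out selection.tsv
disconseq ebm --cohort sim/cohort.tsv --n-boot 100 --out ebm/ --plots
disconseq run --config run.yaml          # end-to-end from a config file
disconseq compare-classes --config run.yaml --masks-a prl.tsv --masks-b nonprl.tsv
```

Configs are YAML/JSON; flags override the file; a single master seed makes
runs byte-for-byte reproducible.

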