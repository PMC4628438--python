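# Methods

## Scope and model

`aflpkit` analyses dominant-marker (AFLP) fingerprints of isolate
collections in which reproduction is assumed clonal or nearly so. The
observable is a per-band fluorescence intensity (RFU) for every isolate ×
technical replicate × fragment-size bin (locus); the inferential chain is
presence calling → locus filtering → Dice distance → UPGMA with
locus-bootstrap support → haplotype grouping → frequency tests. Because a
dominant marker cannot distinguish a heterozygote from a dominant
homozygote, no allele-frequency model is fitted anywhere; all inference is
on band-sharing similarity and exact profile identity.

## Band calling

A band is called present iff `max(i₁,i₂) ≥ t_high` and
`min(i₁,i₂) ≥ t_low` (defaults 100 and 50 RFU). This closed form is
equivalent to the four-branch prose rule it implements (both confident;
disagreement with the weaker replicate still reliable; both below
confident; either below the floor) and is symmetric and monotone in each
intensity. The boundary cases (exactly 100, exactly 50) are not fixed by
the prose convention the rule descends from; we make both thresholds
*inclusive* for presence and expose them as `ScoringThresholds`. A locus
absent from an isolate's records is a zero-intensity band in both
replicates, since fragment-analysis exports conventionally omit absent
peaks rather than writing zeros.

## Locus repeatability filtering

"Repeatable and consistent" is operationalised as three separately logged
criteria:

* `conflict_fraction ≤ max_conflict` (default 0.05) — the fraction of
  isolates with a *strong* disagreement (one replicate ≥ t_high, the
  other < t_low). Mid-zone disagreements are already resolved by the
  calling rule and are not counted.
* polymorphism — monomorphic loci carry no information for Dice/UPGMA.
* plate-control consistency — the designated control isolate, run on
  every plate, must receive identical calls on all plates.

This reproduces the intent of a raw-candidate → retained-locus reduction
(e.g. 230 → 30) without claiming to recover any particular study's exact
locus set, which would require the unpublished raw intensities. Whether a
real study's reduction also used the plate control is typically unstated;
both criteria are therefore independent switches.

The record container keys uniqueness on (isolate, replicate, plate,
locus): the plate-control isolate legitimately recurs across plates with
the same replicate numbers, and any *other* isolate found on two plates is
an error at scoring time.

## Distance and clustering

Dice distance `1 − 2a/(2a+b+c)` ignores shared absences. Two all-zero
profiles get distance 0 by default — they are identical observations, and
this keeps "distance 0 ⇔ same haplotype" exact; `zero_policy="error"`
gives the strict behaviour. Jaccard is available behind a flag for
sensitivity analysis only.

UPGMA uses size-weighted average linkage with merge height = distance/2,
so trees are ultrametric by construction (verified to 1e-9 in tests).
Tie-breaking is deterministic: each cluster is labelled by its
lexicographically smallest leaf and the smallest label pair merges first.
Bootstrap resamples **loci** with replacement — the exchangeable unit in a
binary character matrix — recomputing distances and the tree per
replicate; supports are reported on the full-data tree (primary output)
and a >50 % majority-rule consensus is built from the same clade
frequencies (secondary, mirroring the classic Neighbor/Consense
workflow). Consensus node heights are mean replicate merge heights,
clamped so a parent is never below a child; majority clades are pairwise
compatible so the consensus always exists.

**Significant clusters.** No universal bootstrap threshold exists for
"significant"; the default is the conventional 95 %, configurable, and
every reported count names its threshold. One subtlety follows from
deterministic tie-breaking: isolates with *identical* profiles merge at
height 0 in an arbitrary but reproducible order, so those internal
resolutions inherit 100 % support from the algorithm's determinism, not
from signal. `count_significant_clusters` therefore counts a maximal
zero-height clade (a haplotype group) once by default;
`collapse_identical=False` gives the literal per-node count.

## Haplotypes

A haplotype is an exact-identity profile class (no tolerance); a
`max_mismatches > 0` mode (single-linkage closure of the ≤ k-mismatch
graph) exists for sensitivity analysis only, because published haplotype
counts in this setting imply exact matching. There is no missing-data
state: the calling rule always yields 0 or 1.

## Frequency tests

Plain Pearson χ² via `scipy.stats` (no Yates correction), as an r×c
contingency test of homogeneity (expected = row total × column total /
grand total, df = (r−1)(c−1)) and a one-way goodness-of-fit against
uniform or explicit expected shares (df = k−1). Expected cells below 5
are logged as a warning but never alter the result. An all-zero row or
column leaves expected counts undefined and is an error.

On the bundled survey table the contingency test gives χ² = 56.8770
(df = 4) and the by-crop goodness-of-fit 12.8636 (df = 2). The analogous
by-area goodness-of-fit on the margin totals (34, 71, 27) gives 25.4091
(df = 2); the value 35.9563 sometimes quoted for that comparison is not
recoverable from the count table under either test formulation, and the
package reports what its formulas produce.

## Synthetic-data generator

`simulate` emulates the study design the pipeline targets: clonal
lineages with Bernoulli(p_present) band profiles; isolates inheriting
their lineage profile with independent per-locus flips (`mutation_rate`);
log-normal intensities (strictly positive and right-skewed like real
fluorescence) with medians 800 RFU for present bands and 10 RFU for
background — well clear of the 100/50 thresholds — and log-scale spreads
0.4; per-replicate dropout (`dropout_prob`, default 0.05) replacing a
present band's signal with a background draw, so the calling rule's
disagreement branch is actually exercised; multiplicative log-normal
plate factors (sd 0.1) shared by all bands on a plate, detectable via the
control isolate that is re-run on every plate; and area × crop metadata
mixing a uniform draw (weight 1 − association_strength) with a
lineage-preferred habitat cell (weight association_strength).

Defaults are the target study's conditions: 93 isolates, 230 candidate
loci, 78 lineages, 3 areas × 3 crops, 3 plates, dual replicates,
association_strength 0 (no habitat structure). The noise parameters the
design does not pin down (sigmas, dropout, plate sd) are single
field-plausible choices, documented here, not fitted to any dataset.

What the generator does **not** emulate: electrophoretic size-calling
error, co-migration homoplasy (two different fragments in one size bin),
sequence evolution, and locus-specific noise heterogeneity. Passing tests
therefore demonstrate correctness of the *pipeline* under a clean
generative model, not robustness to every artefact of real capillary
data.

`simulate_contingency` draws multinomial r×c tables; `association = 0`
gives independent margins (the null used for type-I calibration), and
association > 0 concentrates each row's mass on a preferred column.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small configurations — 12–40
isolates, 15–60 loci, 25–200 bootstrap replicates, 10,000 Monte-Carlo
null tables — chosen as the smallest sizes at which each property is
sharply decided (block separation, exact recovery, 3-SE calibration
bands). The pipeline itself has no such limits; 1000-replicate bootstraps
at ~100 isolates run in seconds to minutes.

Numerical conventions: heights are clamped monotone against float noise;
distance matrices are symmetrised exactly; Newick branch lengths are
written to 6 decimals with internal labels carrying integer-rounded
supports; PHYLIP names longer than 10 characters are renamed via an
explicit map (collision is an error, never silent truncation). One global
pipeline seed derives per-stage seeds by hashing, so stages can be rerun
in isolation.

## Known limitations

* Exact reproduction of any particular study's retained-locus set or
  dendrogram requires that study's raw intensities; the package
  reproduces the *procedure* and its summary statistics.
* The study-scale haplotype example (`datasets.synthetic_survey_matrix`)
  is a synthetic stand-in constructed to match summary structure
  (93 × 30, 78 haplotypes, 11 shared among 2–4 isolates); it is not a
  deposited matrix.
* Bootstrap support on the full-data tree and consensus membership answer
  slightly different questions near 50 %; both are reported.
* The χ² tests are asymptotic; with many near-empty cells an exact test
  would be preferable, and the package only warns.
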