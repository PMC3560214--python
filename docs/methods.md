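# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, and the design decisions taken where the problem
left room for choice.

## Target-decoy filtering

A composite forward+reverse database search yields PSMs whose accessions
may be forward, reverse (prefix `REV_`), or a mixture. A PSM is treated as
a decoy only if *every* accession is a reverse entry: a peptide shared
with any forward protein is a forward identification. The false-positive
rate of a retained set is the standard composite-search estimator
`FPR = 2·N_rev/(N_rev + N_fwd)`, capped at 1; it is undefined (an error)
on an empty set, and an empty retained set is reported with FPR 0 by
convention.

The gate semantics are deliberate: ion score is a strict lower bound
(a score of exactly 40 fails a ">40" gate), probability is inclusive
(p = 0.90 passes "≥ 0.90"), mass tolerances are strict bounds on the
absolute error (parent errors arrive signed), and missed cleavages are
inclusive. Threshold optimization searches only the ion-score gate over a
user grid, holding the secondary gates fixed, and maximizes the number of
retained *forward peptides* — distinct (peptide, charge) pairs — subject
to the FPR ceiling. Ties break toward the lower achieved FPR, then the
higher (more conservative) threshold. PSM-level and peptide-level counts
and FPRs are both reported; the PSM-level FPR is canonical. If no grid
point meets the ceiling, the minimum-FPR point is returned flagged as a
constraint failure rather than silently relaxing the bound.

## Signal fractions and enrichment

Group signal sums the intensities of ions whose assigned peptide maps to
at least one group member; shared-peptide ions count fully toward every
matching group (no razor splitting), so fractions of overlapping groups
can sum above 1 — reports carry that caveat rather than redistributing
signal. The total includes unassigned ions by default (a flag restricts it
to identified ions), because the denominator of interest is everything the
instrument measured.

Between two runs, enrichment of a group is reported two ways. The plain
ratio of fractions matches how such enrichment is usually quoted. The
odds ratio `(f₁/(1−f₁))/(f₂/(1−f₂))` is the estimator used for parameter
recovery: if every group member's intensity is scaled by k in one run, the
odds ratio moves by exactly k while the fraction ratio saturates as the
group's share grows. Both appear in the pipeline report.

The Mann–Whitney U test is exact by complete enumeration of all
C(n+m, n) group assignments with midranks for ties, two-sided around the
null mean nm/2, and refuses combined sizes above 12 where a normal
approximation is the right tool. With triplicates against triplicates the
smallest attainable two-sided p is 0.1 (2 of 20 assignments); p-values
below that floor cannot arise from this test at n = 3, so none are
reported.

## Gel-band concordance

Band MW windows come from the marker lane by linear interpolation of
log10(MW) against migration position — the standard SDS-PAGE migration
model; edges outside the outermost markers are clamped to the nearest
marker MW and flagged. Classification is strict on both sides
("above"/"below" the window), so a theoretical MW exactly on a bound is
concordant. Per band, the mean and sample SD (n−1) of member theoretical
MWs are reported, plus the share of MS signal from each class; the
concordant share closes the partition so the three percentages sum to
exactly 100. A protein identified in two bands contributes its per-band
signal to each independently. Theoretical MWs use average (not
monoisotopic) residue masses from a pinned constants table, since the use
case is concordance with gel migration of bulk protein; sequences
containing X have undefined mass and are excluded with a warning. An
overall signal-weighted degraded percentage is reported alongside the
per-band values, since "overall" aggregation is otherwise ambiguous.

## Overlap and over-representation

Venn region counts are exact set arithmetic on pre-normalized identifiers
(uppercase, isoform suffix after "-" stripped). A marker family counts as
found when at least one identified accession maps to it. The
over-representation test draws B random lists of the query's size without
replacement from the reference proteome (a protein list has no
duplicates) and uses the add-one empirical p-value
`(1 + #{null ≥ obs})/(B + 1)`, which is valid for permutation nulls and
cannot reach zero: with B = 100 the floor is 1/101 ≈ 0.0099. Reported
p-values at the floor mean "more extreme than every null draw", not a
sub-resolution significance level; B is a flag for finer resolution.

## Interactomics

An interaction is a distinct unordered protein pair with one side in each
surface set, checked in both orientations of each undirected edge; a pair
supported by several database records counts once, and a self-edge of a
protein present on both surfaces counts as one interaction partnering it
on both sides. The PPI edge list is a user input and its path is recorded
in the report — interaction counts are only as reproducible as the edge
list's provenance.

## MRM quantification

Fragment matching sums every trace point within ±tolerance (default
0.05 Da, configurable; no peak-shape fitting) per signature fragment.
Retention-time gating is available but off by default. Presence is called
when at least `min_fragments_matched` (default 3 of 4) fragments carry
signal. Relative levels divide each sample's summed transition signal by
the median of the untreated controls; the median is the lower-middle
observed value for even counts, so the anchor is always a real
measurement and the control median normalizes to exactly 1.

## Synthetic-data model

The generator emulates the statistical structure of the real experiment,
not its chemistry: no chromatography, isotope envelopes or spectral noise.

* **Scores.** Forward and decoy ion scores are Gumbel-distributed
  (location-shifted; heavy right tail, as maxima-based search scores
  behave), defaults mean 52/SD 13 forward and mean 18/SD 6 decoy.
  Peptide probabilities follow a logistic curve in the score with small
  Gaussian jitter, or a uniform range when a study calls for decoupled
  probabilities. About 5% of rows deliberately violate each secondary
  gate (parent error, fragment error, missed cleavages) so every gate is
  exercised.
* **Intensities.** Log-normal (σ = 0.7 ≈ half a decade spread, typical of
  MS1 features), with 1 + Poisson(3) peptides per protein and 10%
  unassigned features. Marker-family proteins (whole families until 10%
  of the roster is covered) are scaled by `marker_enrichment` (default
  3.3) in the vesicle run only.
* **Gel lane.** Ten log-spaced bands from 250 down to 10 kDa. Each
  protein's full vesicle signal lands in the band containing its
  theoretical MW; on top, `degraded_fraction` (default 0.20) of each
  band's signal is assigned to donors above the band's upper bound, and a
  fixed 5% to donors below the lower bound, both with multiplicative
  log-normal noise (σ = 0.1) so recovery is an estimate, not an identity.
  Small heavy (>270 kDa) and light (<9 kDa) sub-populations guarantee
  donors for the outermost bands.
* **Annotations.** Eight functional category tags; the identified list
  includes membrane-traffic proteins with probability 0.85 versus 0.50
  otherwise, planting a detectable over-representation. Surface flags are
  Bernoulli(0.35).
* **Interactome.** A 300-protein target surface; each cross-surface pair
  carries an edge with probability `edge_density` (default 0.05, a sparse
  density in the range typical of curated PPI neighborhoods), plus decoy
  edges touching intracellular proteins that must never be counted.
* **MRM.** Traces hold 60 log-normal background points kept at least
  0.2 Da away from any signature fragment; spiked traces add three points
  within ±0.02 Da of each fragment. Three untreated controls (spike scale
  ≈ 1) and three treated samples (scale 3–6) emulate a treatment series;
  a blank trace contains background only. The FC5 signature peptide and
  its transitions are inserted verbatim.

Identical seed and configuration produce byte-identical serialized
bundles. Because intensities, categories and edges are generated exactly
from the stated families, passing recovery tests shows the estimators
invert the generative model; it does not certify behaviour under real
matrix effects, ionization suppression, or annotation errors.

## Problem sizes and tolerances

Recovery checks run at a 2,000-protein roster over 10 seeds, where the
enrichment odds-ratio estimator has a relative standard error of a few
percent (tested within ±15%) and the degraded-signal estimate is tested
within ±5 percentage points. Oracle comparisons (exact FPR arithmetic,
grid-enumeration optimizer, exact Mann–Whitney, hypergeometric limit of
the permutation p at B = 10,000, brute-force interaction counting) use
exact equality or ±0.01 on probabilities. The exact Mann–Whitney uses an
absolute tie tolerance of 1e−12 on U deviations to keep midrank ties
stable in floating point.

## Known limitations

* No q-value or posterior-error modelling beyond the composite-search FPR;
  no rescoring.
* No XIC construction or cross-run normalization beyond fraction-of-total.
* Categories are flat tags; no ontology traversal or term propagation.
* Interaction counts depend entirely on the supplied edge list.
* The mzML reader ingests MS1 centroids (32/64-bit, zlib or raw) in the
  400–2000 m/z acquisition window; it is not a general-purpose mzML
  parser (no chromatograms, no selected-ion lists).
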