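# Methods

## Data model

A *clonotype* is a unique rearrangement identified by the triple
(`v_call`, `j_call`, `cdr3_nt`) with a positive UMI-corrected count — one
count per observed molecule, not per raw read. Amino-acid junctions are
carried when the junction is in frame and must equal the translation of the
nucleotide junction; out-of-frame clonotypes keep `cdr3_aa = None` and are
retained in diversity and subsampling by default (they are genuine
molecules in the sequenced population; a `productive_only()` filter is
available when an analysis needs in-frame clones, and annotation skips
aa-less clonotypes automatically). Duplicate keys are merged by summing
counts at read time, so frequencies always sum to 1 over the validated
table. Frequencies are fractions of total reads (Σ counts), not of unique
clonotypes: clonal dominance is a property of read mass.

Two table dialects are read and written: AIRR rearrangement TSV
(`v_call`, `j_call`, `junction`, `junction_aa`, `duplicate_count`) and a
Decombinator-style comma-separated frequency file (V, J, V-deletions,
J-deletions, insert, count; an optional tag map resolves numeric indices to
gene names). The frequency dialect has no explicit CDR3 column, so the
insert sequence serves as the junction identifier there; deletion counts
are preserved but excluded from clonotype identity.

## Diversity statistics

The Gini coefficient uses the discrete Lorenz estimator
`G = Σᵢ (2i − n − 1) x₍ᵢ₎ / (n Σx)` over counts sorted ascending. No
small-sample correction (no n/(n−1) factor) is applied: the uncorrected
estimator is exactly twice the trapezoid-rule area between the diagonal and
the Lorenz polyline and returns exactly 0 for equal counts, which is the
interpretation the classification thresholds rely on. Shannon entropy is
reported in bits (base 2) everywhere. A monoclonal sample returns Gini 0
and Shannon 0 with an explicit degeneracy flag, because a 0 from a
single-clone repertoire must not be read as evenness.

## Subsampling and the minimum representative depth

Subsampling draws reads without replacement from the read population (each
clonotype contributes `count` indistinguishable reads), i.e. a multivariate
hypergeometric draw; at full depth this is the identity, so normalized
curves end at exactly 1 with zero standard error. Rarefaction covers
1–100% of total reads at 1% steps with 30 replicate subsamples per step
(defaults; both configurable), reporting mean and standard error
(sd/√replicates) of Gini and Shannon, each normalized to its 100% value.
Replicate generators are spawned from the master seed keyed by
(percent, replicate), so results are bit-reproducible and independent of
execution order.

The depth rule interprets the normalized-Gini decline on the unit square
(depth fraction vs normalized Gini), where straight-line depreciation has
gradient exactly 1. Choices the rule's prose description leaves open are
fixed as follows and are configurable where noted:

* Gradient = forward difference `(g(p+1) − g(p))/0.01`, attributed to
  percent p; a gradient above the threshold (default 1.1) qualifies.
* Qualifying percents are grouped into maximal runs of consecutive
  integers; runs are ranked by their smallest member and the lowest run is
  selected — the shallowest region where subsampling distorts the
  abundance distribution.
* Minimum percent = largest member of the selected run + 1 (a run ending at
  20% yields 21%). An empty qualifying set yields 1%: the rule only raises
  the floor on evidence of distortion.
* Percent → reads by ceiling, capped at the sample total, so the chosen
  depth never falls below the floor.
* Samples whose full-depth Gini or Shannon is 0 cannot be normalized and
  are flagged degenerate; the depth rule refuses them rather than guessing.

The cohort common depth maximizes `|{i : min_depthᵢ ≤ D ≤ totalᵢ}|` over
absolute read depths. The inclusion count is piecewise constant and only
changes at interval endpoints, so the search over the endpoint candidate
set is exact; ties break to the largest depth (equal inclusion, more reads
retained per sample). Samples whose totals fall below the chosen depth are
excluded from depth-matched comparisons rather than analyzed at full depth,
and are listed in the report.

## Virtual spectratypes

Length histograms are over nucleotide junction lengths, weighted by read
frequency (configurable to unique-clonotype weighting), grouped by V
subfamily extracted from the gene call (`TRBV5-1*01` → `TRBV5`;
unresolvable calls are binned as "unassigned"). A peak is a length bin
holding more than 1% of its family's mass (configurable floor). In-frame
repertoires show the classical 3-nt peak spacing.

Gaussian-ness of a family is `1 − L1/2` between the observed shape and a
Gaussian fitted by the frequency-weighted mean and SD, discretized on the
arithmetic grid spanning the observed lengths. The grid step is the gcd of
observed length differences capped at 3 nt — the codon spacing classical
spectratypes resolve — so two distant spikes are charged for the empty
bins between them instead of trivially fitting a two-point "Gaussian".
Single-bin histograms score 0 with a degeneracy flag (the SD is undefined
and a lone spike is the least Gaussian clinical shape). An L1 score was
chosen over a formal normality test because the clinical judgement is
about shape, not sampling significance, and a bounded score thresholds
cleanly.

Classification uses the median peak count per family and the fraction of
families with score ≥ `t_gauss`: Normal iff median ≥ 8 and fraction ≥ 0.75;
Abnormal iff median ≤ 5 or fraction ≤ 0.4; otherwise Almost_normal (all
comparisons inclusive; all five thresholds configurable). The ≥ 8
peaks-per-family convention follows common clinical spectratyping practice;
the exact clinical cut-offs behind the three-group scheme are not published,
so these defaults are explicit stand-ins.

## Tracking and annotation

Tracking takes the union of each timepoint's top-n clonotypes (ties broken
lexicographically by junction then gene calls) and looks every union member
up at every timepoint, so a clone that falls out of the top-n later still
has its full trajectory recorded. Persistence means detection at ≥ 2
timepoints by exact nucleotide identity.

Annotation matches `cdr3_aa` exactly; the default policy additionally
requires V agreement at gene-family resolution, the common matching
convention for beta-chain databases, which suppresses spurious public-clone
hits. The CDR3-only policy reproduces the permissive behaviour that
surfaces implausible annotations (e.g. HIV-reactive labels in seronegative
patients) and is useful precisely to demonstrate why results are reported
as *binding potential* — the repertoire fraction whose CDR3 matches
database entries for a species, with a clonotype counted once per species —
never as specificity.

## Synthetic repertoires

`simulate_repertoire` draws expected clone frequencies (fixed fractions for
expanded clones; lognormal or geometric sizes, renormalized over the
residual mass, for the baseline) and then samples reads multinomially, so
every table has exactly the requested depth. CDR3s are random in-frame
junctions with TGT…TTT (C…F) flanks and no internal stops, lengths drawn
per V family from a Gaussian profile (rounded to codon multiples) or a
spiked profile; all identities are drawn distinct so expanded clones are
unambiguous ground truth.

Default study conditions, chosen to emulate the measured extremes of
reconstitution data:

* *Cord control*: richness 6000, lognormal(0, 0.2) sizes, no expansions,
  200k reads — mean Gini ≈ 0.15 and Shannon ≈ 12.5 bits, inside the
  reported healthy-control bounds (Gini < 0.2, Shannon > 12). Richness and
  depth matter jointly here: Shannon > 12 bits needs several thousand
  effective clones, while Gini < 0.2 needs enough reads per clone that
  sampling noise does not masquerade as inequality.
* *Post-transplant*: richness 1500, lognormal(0, 0.8) baseline, 12 expanded
  clones carrying 45% of reads in geometrically decaying fractions, 100k
  reads — Gini ≈ 0.68, Shannon ≈ 7.8 bits.
* *Spectratype presets*: a polyclonal profile (Gaussian lengths, mean 45 nt,
  SD 6 nt) and an oligoclonal one (1–3 spiked lengths per family, seeded
  per family) for classifier recovery.

`calibrate_to_target_gini` bisects on total expansion mass (split equally
over the expanded clones) against the mean Gini of 10 seeded count
simulations; the baseline template uses a mild lognormal(0, 0.1) so targets
down to ≈ 0.1 are reachable from below. `simulate_reconstitution_series`
interpolates richness, depth and expansion mass linearly in month between
an initial and final parameter set, keeps baseline identities in a fixed
pool, and carries each expanded clone between consecutive months with the
persistence probability.

What the generator does **not** emulate: V(D)J recombination biases and
convergent (public) sequence generation, PCR/sequencing error clonotypes,
out-of-frame rearrangements, alpha-beta pairing, and any mechanistic
thymic-output dynamics. Tests passing on synthetic cohorts therefore
validate the statistical machinery under the stated abundance and length
structure, not the upstream clonotyping or the biology of real patients.

## Problem sizes and determinism

The test and example workloads use cohorts of 3–4 samples at 3k–200k reads
and 100–6000 clonotypes, rarefaction with 5–30 replicates, 10-seed
calibration averages, and 100-seed-per-class label-recovery runs; these
sizes give stable statistics (Monte-Carlo tolerances of 2–3 standard
errors) with fast turnaround. All randomness flows from explicit seeds
through `numpy` `SeedSequence` spawning, and the pipeline writes
floating-point output through a fixed `%.6g` format, so reports are
byte-identical across reruns with the same master seed.

## Known limitations

* The depth rule's gradient conventions (forward difference, threshold
  units, empty-set fallback) are documented interpretations of a prose
  description; alternatives (central differences, two-sided thresholds)
  would shift floors by a few percent.
* Spectratype classification thresholds are stand-ins; on real clinical
  data they should be re-derived against PCR spectratype calls.
* Gene-name handling extracts IMGT-style subfamilies by prefix; exotic
  allele strings fall into "unassigned" rather than being resolved against
  a germline reference.
* Cohort depth optimization treats every sample equally; there is no
  weighting by clinical priority when inclusion ties are broken.
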