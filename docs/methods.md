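# Methods

This note records the models, parameter choices and numerical conventions
behind `proxiquant`, and what the synthetic test bed does and does not show
about real data.

## Data model and ingest

A PSM table carries, per peptide-spectrum match: protein accession(s),
peptide sequence, charge, search q-value, co-isolation interference (%),
run (TMT plex), optional fraction, and one reporter intensity per channel.
Zero or negative reporter intensities are treated as missing: their log2 is
undefined and a non-positive corrected S/N carries no usable quantitative
signal. They are counted in the ingest report.

Quality filters follow common isobaric practice: co-isolation ≤ 70 %
(inclusive), search q < 0.01 (strict), unique peptides only. Both cutoffs
are configurable; the inclusive/strict split mirrors the usual phrasing of
these thresholds. Shared (multi-accession) peptides are discarded outright,
never redistributed among their proteins.

**Quantifiability.** A protein enters summarization with at least two
distinct unique (peptide, charge) features — two unique peptides, or one
peptide observed at two charges, both qualify. Features are counted
per protein across fractions and runs (the most permissive reading; scope
is configurable only through the PSM table handed in). Proteins whose
unique evidence collapses to a single feature go to the *single-PSM rescue*
set: they are carried through the identical summarization and reference
normalization (a one-row median polish is an identity) and reported
descriptively with per-condition observation counts, but excluded from
inferential testing. Proteins seen only through shared peptides are
dropped.

## Summarization: median polish

Per protein and run, all retained PSM rows (fractions pooled) form a
PSM × channel matrix of log2 intensities, decomposed by Tukey's two-way
median polish; protein abundance in a channel is the overall effect plus
that channel's column effect.

Numerical conventions: row sweep first; after each sweep the median of the
opposite effect vector is folded into the overall term; even-length medians
are midpoints of the two central order statistics; missing cells are
skipped; convergence when the largest absolute effect update in a sweep is
below 1e-4 (configurable), at most 100 sweeps. All-missing columns stay
missing; all-missing rows are dropped. With missing data the polish fixed
point is not unique (flat directions exist: a constant can move between
column-effect subsets); results are deterministic given the sweep
convention. For throughput, proteins with equal PSM-row counts within a run
are polished as one vectorised stack; the stack keeps sweeping until its
worst member converges, so stacked and solo runs of the same matrix agree
to the convergence tolerance, not to machine precision.

## Normalizations

* **Global peptide median normalization** (off by default): per
  run × channel, the median log2 PSM intensity is shifted to the grand
  median of all run × channel medians. It is deliberately off for designs
  where construct-level loading differences are themselves biology (e.g.
  comparing enrichment across constructs) and on for cross-cell-type
  comparisons.
* **Reference normalization** (on by default): per protein, each run is
  shifted so its mean reference-channel abundance equals the protein's
  grand mean of per-run reference abundances. Anchoring to the grand mean
  (not the first run) preserves overall scale. Runs where the protein lacks
  a reference value are left unshifted and flagged `unanchored`; proteins
  quantified in a single run survive with that flag. Within-run differences
  between channels are invariant by construction.
* **Protein median normalization** (optional): sample columns are shifted
  so all observed medians agree; idempotent.

## Moderated statistics

Per protein, condition means and a pooled within-condition variance s² with
d = Σ(n_g − 1) df. The variance prior (d₀, s₀²) is estimated across
proteins by method of moments on z = log s² using digamma/trigamma
identities, with the trigamma inverse solved by Newton iteration; when the
observed spread of z does not exceed the χ² sampling prediction the prior
is degenerate (d₀ = ∞, s₀² = exp of the mean adjusted z). The finite-d₀
branch reproduces the standard R reference implementation to 6+ digits (see
`tests/test_modstats.py`). Moderated variance s̃² = (d₀s₀² + ds²)/(d₀ + d);
proteins with d = 0 shrink fully to the prior; two-sided p from t on
d₀ + d df (normal when d₀ = ∞). BH adjustment is applied within each named
contrast, implemented directly from the step-up definition (it is the
decision statistic of the whole workflow) and checked against both a
brute-force oracle and statsmodels.

**Calibration on multi-run designs.** Inference runs on
reference-normalized per-sample abundances rather than a joint mixed model
with run effects. Two error components are then shared by all samples of a
run: the reference channel's own summarization error (subtracted from the
whole run), and run-level offsets caused by different retained-PSM sets per
run. Both inflate the pooled within-group variance yet cancel from
run-balanced contrasts, so realized type-I error is *conservative* (about
0.02 at a nominal 0.05 in the two-plex null simulations) and never
anticonservative; on single-run designs the pooled moderated t is
calibrated at nominal level. Power remains above 0.9 for the effect sizes
of interest (see the acceptance checks).

## Two-filter classification

Filter 1 (specificity): retained ⇔ log2FC > 0 **and** q < 0.05 in the
(construct − Cre-negative control) contrast. The significance rule is BH q
only. Filter 2 (compartment): nucleus ⇔ H2B − NES significantly positive;
membrane ⇔ H2B − LCK significantly negative (three-construct mode);
two-compartment mode labels Filter-2 failures cytosol/non-H2B. When the
nuclear and membrane rules both nominally fire, the membrane call wins: a
genuinely nuclear protein cannot be depleted against the membrane
construct, so a significantly negative H2B − LCK outweighs the H2B − NES
evidence; the two calls are therefore mutually exclusive. A protein absent
from the H2B − NES table but present in H2B − LCK is processed on that
basis alone and flagged.

Contaminant lists are plain text (one accession per line, `#tag` lines set
provenance) and removal is a set difference with per-tag attribution; the
generation of such lists from single-cell atlases is out of scope.
Alternative cutoffs (top-k by log2FC with a deterministic
log2FC-desc / q-asc / accession-asc tie-break, or a static inclusive
threshold) are provided for designs where a rank or effect-size rule is
preferred over q values.

## Downstream analyses

* **Stratified DE** re-runs moderated contrasts inside each compartment
  stratum, each with its own prior and BH family, flagging by a p- or
  q-rule.
* **Transcript DEG merging**: a gene qualifies from a test-based source
  when adj. p < 0.05 and |log2FC| > 1, or unconditionally from a
  cluster-membership source; duplicates collapse by gene symbol keeping all
  source tags; direction conflicts are kept and flagged; gene↔accession
  mapping is a user-supplied two-column table (no network lookups).
* **Proteome–transcriptome correlation**: Pearson r over the shared
  accessions (≥ 3 required), two-sided p via the t transform.
* **Annotation enrichment**: plain hypergeometric upper tail against the
  identified-protein background with BH across terms — not the modified
  one-tailed Fisher (EASE) variant some GO tools use, so p values here are
  exactly valid but slightly larger on small overlaps. Being discrete,
  the p distribution under random foregrounds is sub-uniform; tests check
  the exact identity P(p ≤ p_k) = p_k at achievable cutoffs rather than a
  continuous-uniformity statistic.
* **QC**: leading-log2FC MDS (pairwise top-n = 500 largest absolute
  differences, complete proteins only, classical Torgerson scaling, axis
  sign fixed by the largest-magnitude coordinate), per-condition %CV
  computed on log2 intensities (as is conventional despite the unit
  oddity), and pairwise-complete replicate Pearson correlation.

## Synthetic experiment generator

Additive log2 model per PSM and channel: baseline + peptide offset +
capture term + DE term + batch + channel + noise. The capture term for
construct k on protein p is `scale · log2(Σ_comp w_k[comp]·mix_p[comp] +
leak)`; Cre-negative samples see only the leak; nonspecific bead binders
and endogenously biotinylated proteins are captured equally in every sample
(true Cre± difference zero). Reference channels carry the linear-scale mean
of all study samples — identical across runs in expectation, the basis of
reference normalization. Missingness is a detection floor (MNAR) plus
uniform MCAR, both small by default since the analysis never imputes.
Charge, search q, co-isolation and shared-peptide status are drawn
independently of intensity; they exist to exercise the ingest filters.

Defaults (the simulated study conditions): two TMT-10 plexes; CTRL n = 6,
constructs n = 4; 10 % bead binders, 5 % endogenous biotin; on-target
capture 1.0, off-target 0.1, leak 0.02, scale 1.0; noise sd 0.25, batch sd
0.5, channel sd 0.1, peptide sd 1.0, baseline 14 ± 2 (log2); PSM counts
1 + NegBin(2, 0.5) per protein per run; detection floor 3.0, MCAR 2 %.
Compartment mixtures are symmetric Dirichlet(0.05): proteins are
overwhelmingly single-localized with a small dual-localized minority, the
regime in which a dominant-compartment protein carries at least ~1 log2
unit of construct enrichment — the regime the two-filter rules assume.
Activity effects (+0.8 log2 by default) can be restricted to proteins
dominant in a chosen compartment to emulate stimulus-driven nuclear
regulation.

What the generator does **not** emulate: reporter-ion ratio compression
from co-isolation (the metadata field is sampled, not mechanistic), isotope
impurity, peptide-specific missingness coupled to hydrophobicity or length,
correlated protein complexes, or real protein identity; passing tests
demonstrate the statistical machinery behaves as designed under its assumed
error model, not that any particular biological list is correct.

## Problem sizes used in checks

The acceptance checks run at the sizes the properties are stated for:
1000 random matrices for polish-oracle agreement, 20 × 5000 variances for
prior recovery, 1000 p-vectors for BH, 200 simulations of 2000-protein
experiments for FDR control and stratified power, 100 simulations for
reference-normalization bias, one 2000-protein experiment for
classification recovery, and a 3000-protein end-to-end determinism run.
`scripts/acceptance.py` reports the same quantities at moderately reduced
replicate counts (its `n` fields) chosen so the whole script stays within a
few minutes on one CPU.

## Known limitations

* No mixed-effects model across runs; the reference-normalized per-sample
  approach is conservative on multi-run designs (see above).
* No imputation anywhere; heavily missing proteins simply carry fewer
  observations and wider intervals.
* The hypergeometric enrichment ignores GO-DAG topology and annotation
  redundancy.
* The membrane/nucleus sign rule cannot distinguish a cytosol-dominant
  protein with substantial membrane co-localization from a membrane
  protein; such dual-localized proteins are the principal source of
  classification error in simulations and are acknowledged as inherently
  ambiguous.
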