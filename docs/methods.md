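# Methods

## Scope and data model

The package starts at the denoised ASV count table (ASVs × samples,
integer reads) with a per-ASV taxonomy table and per-sample metadata
describing a couple-paired design: each couple contributes one female
(vaginal) and one male (penile skin) participant, each sampled before and
after intercourse, alongside extraction blanks, no-template controls (NTCs)
and a mock community. Replicate swabs are assumed resolved upstream to one
sequenced sample per participant-timepoint; duplicate specimens are
rejected rather than arbitrated. Unassigned taxonomy ranks are normalized
to the single sentinel `unclassified`.

## Contaminant filtering (prevalence method)

For each ASV a 2×2 presence table is formed over biological specimens and
pooled negative controls (blanks plus NTCs by default; `include_ntc=False`
restricts to blanks; mock samples are excluded from both groups). Presence
is `count > 0` — no minimum-read floor, though one is configurable
(`min_reads_presence`). The score is the one-sided tail probability that
the control prevalence is at least as extreme as observed: half the
chi-squared (1 df, no continuity correction) p-value when all expected
cells are ≥ 5, and the exact hypergeometric tail
P(X ≥ k_controls | N, K, n_controls) otherwise — which is the relevant
branch at the 3–6 controls a sequencing run realistically carries, where
the chi-squared approximation breaks down. An ASV absent from every
control scores 1 by convention. ASVs scoring below the threshold (default
0.05) are removed before any analysis. Batch structure is ignored: all
controls are pooled in a single pass.

## Diversity

**Shannon index** uses natural log (nats): H = −Σ pᵢ ln pᵢ over taxa with
pᵢ > 0. **Rank-sum test** (two-sided): exact by enumeration of the
rank-sum distribution (dynamic programming over subset sums) when both
groups have ≤ 10 observations and no ties; otherwise the tie-corrected
normal approximation without continuity correction,
Var(W) = n₁n₂/12 · (n + 1 − Σ(t³−t)/(n(n−1))). Group comparisons are
unpaired; couple pairing is not exploited (a `paired` switch is reserved).

**Bray-Curtis** is computed on counts after the 0.1 % relative-abundance
filter, with no further transformation. The filter retains an ASV iff its
relative abundance strictly exceeds the threshold in at least one sample;
it is idempotent and scoped to the beta-diversity inputs only — alpha
diversity and transfer analysis run on the unfiltered
post-decontamination table (a `filter_alpha` switch applies it there too).

**PCoA**: Gower double-centering B = −½ J D² J, symmetric
eigendecomposition, coordinates = eigenvectors × √λ for positive
eigenvalues. Negative eigenvalues (expected for non-Euclidean Bray-Curtis)
are reported but excluded from coordinates and from the
proportion-explained denominator; no Cailliez/Lingoes correction. Axis
signs are fixed by making the largest-magnitude loading positive, so
embeddings are stable across runs up to nothing at all.

**PERMANOVA** (one factor): SS_T = Σ_{i<j} d²ᵢⱼ/N, SS_W = Σ_groups
(within-group Σ d²)/n_g, pseudo-F = (SS_B/(a−1))/(SS_W/(N−a)),
R² = SS_B/SS_T, and p = (1 + #{F_perm ≥ F_obs})/(1 + n_permutations) under
unrestricted label permutations drawn from a seeded generator — so p has
granularity 1/(n_permutations+1) and is bit-reproducible given the seed.
The degenerate SS_W = 0 case reports the smallest attainable p with a
warning. Sex and couple effects are separate one-factor tests, not a
two-factor model. An exhaustive-enumeration variant is provided for small
two-group designs.

## Community state types

CST I/II/III/V are assigned when the defining species (*L. crispatus*,
*L. gasseri*, *L. iners*, *L. jensenii*) is the unique argmax of the
species-level relative-abundance profile **and** exceeds the dominance
threshold; everything else, including argmax ties, is CST IV. The
threshold default of 0.30 is a declared convention of this package — the
five-type framework itself does not fix one — it is configurable and
recorded in the output, and raising it can only move samples toward
CST IV.

## Transfer analysis

Per participant, **baseline community** = support(before) ∩ support(after)
at the presence floor (default 1 read). An ASV is **cohort-unique** to a
participant iff it occurs in that participant's baseline and no other.
Classification of each partner's after-sample support is a partition:
retained (in own before), transferred (absent own before, present partner
before), introduced (absent both befores); before-only ASVs are reported
separately as lost. Transfer detection deliberately uses raw before/after
supports, not baselines, while uniqueness is evaluated on baselines
(`uniqueness_on="before_support"` switches the latter for sensitivity
analysis). For a transferred ASV, uniqueness is assessed with respect to
the donor against all participants excluding the recipient — who may have
just received it. Percent-unique fields are 100·unique/total rounded half
away from zero to one decimal, `NA` when the total is zero.

**Contributor genera**: genus g is a male contributor iff its relative
abundance falls in the male after vs. before AND rises in the female,
both beyond a tolerance δ (default 0.5 percentage points, suppressing
multinomial noise; δ = 0 gives pure strictness); mirrored for female
contributors. The per-couple rule operates on one couple's four samples;
the cohort-level variant applies the same rule to group-mean abundances
per sex × timepoint.

## Synthetic cohorts

The simulator emulates the paired design, not any particular dataset.
Each participant carries a random subset of a niche pool: the vaginal pool
holds the four CST-defining lactobacilli plus diverse anaerobes (20 ASVs
over 14 species), the penile-skin pool is richer (34 ASVs over 28
species, plus 3 shared taxa), and separate pools supply environmental
(introduction events), reagent-contaminant and mock taxa. Carried taxa
get log-normal relative abundances renormalized to the simplex — the
simplest model with realistic rank-abundance curves. CST I/II/III/V
females receive their dominant species at uniform(0.70, 0.95) total
relative abundance; CST IV females carry anaerobes with lactobacilli
suppressed.

After-intercourse composition is the mixture
(1−m)·own_before + m·partner_before per direction, plus `n_introduced`
environmental taxa (the same set in both partners, at 0.1–1 % mass each),
then reagent contaminants (per-specimen carryover probability, default
0.15, at 0.2–1 % mass), then one multinomial draw at a negative-binomial
read depth (mean 8,292, dispersion 10 — overdispersed like real runs).
Condom use rescales the mixing proportions (default ×0.3 female→male,
×0.05 male→female: a barrier attenuates male-to-female transfer far more).
Blanks contain only contaminant taxa (prevalence 0.9 per blank), NTCs
near-zero reads, and the mock sample is an exact multinomial draw of the
8-species profile at its own depth. Default cohort: 12 couples with
mixing proportions spread over 0.05–0.2 and CSTs cycling through the five
types. A single seeded generator with a fixed draw order makes output
bit-identical across runs.

**Ground truth** records every planted event. Planted transfers are
enumerated from realized supports: each ASV detected in the donor's
before sample, absent from the recipient's, and carrying positive
transferred mass q in the recipient's after composition, with closed-form
detection probability 1−(1−q)^depth. Recovery sensitivity is scored on
events whose detection probability reaches 0.99 (configurable): an event
below that threshold is a statement about sequencing depth, not about the
caller, though recovering one is still credited. A transfer call outside
the planted set is a false positive; it is *explainable* when the ASV is
a planted contaminant or introduced taxon, and non-explainable otherwise.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: sequencing error, chimeras and 16S
copy-number variation; menstrual-cycle and longitudinal dynamics;
strain-level identity of shared ASVs; and realistic cohort-level ASV
richness. The niche pools are shared across participants, so
cohort-unique ASVs are rare in simulated cohorts (per-couple unique
percentages near zero), unlike full-length-16S field data where a large
fraction of ASVs occur in a single participant; uniqueness logic is
therefore validated on constructed fixtures with planted unique sets
rather than on the simulator's defaults.

## Numerical choices and degenerate inputs

All-zero sample columns raise named errors wherever proportions are
needed; all-zero NTCs are tolerated (controls are never normalized).
Identical groups in PERMANOVA (SS_W = 0) warn and report the floor
p-value. PCoA requires n ≥ 3 and a validated symmetric zero-diagonal
matrix. Eigenvalues within 1e-10 (relative) of zero are treated as null
axes. Percent rounding is half away from zero. The pipeline derives all
stage seeds from the single run seed (simulation: seed; PERMANOVA by sex:
seed+1; by couple: seed+2).

## Problem sizes

Monte-Carlo checks use 20 seeds for transfer recovery, 100 seeds for the
contaminant filter's operating characteristics, and 1,000 (test) / 500
(acceptance script) null simulations for PERMANOVA calibration — sizes at
which Monte-Carlo standard errors are several times smaller than the
property bounds being checked; the whole suite runs in seconds.
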