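# sexome

Analysis toolkit for couple-paired genital-microbiome ("sexome") studies:
detecting the transfer of bacteria between sexual partners from 16S rRNA
amplicon sequence variant (ASV) tables sampled *before* and *after*
intercourse.

The package targets the study design used in forensic sexome research: a
cohort of couples, one vaginal and one penile-skin swab per partner per
timepoint, sequenced alongside extraction blanks, no-template controls and a
defined 8-species mock community. It takes the denoised ASV count table as
its starting point (read-level processing is out of scope) and provides:

- **Contaminant removal** — the prevalence method: each ASV's 2×2
  presence table (specimens vs. negative controls) is scored by a one-sided
  chi-squared tail, falling back to the exact hypergeometric tail whenever an
  expected cell is below 5 (always the case with a handful of controls);
  ASVs scoring below 0.05 are removed.
- **Diversity** — Shannon index *H* = −Σᵢ pᵢ ln pᵢ with Wilcoxon rank-sum
  group comparisons; Bray-Curtis dissimilarity BC(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ);
  principal coordinates analysis (Gower double-centering); one-factor
  PERMANOVA with pseudo-F = (SS_B/(a−1))/(SS_W/(N−a)), R² = SS_B/SS_T and a
  seeded permutation p-value.
- **Community state typing** — each female before-intercourse sample is
  assigned CST I/II/III/V when *L. crispatus* / *L. gasseri* / *L. iners* /
  *L. jensenii* is the single most abundant species above a dominance
  threshold (default 0.30), otherwise CST IV.
- **Transfer analysis** — per participant, the *baseline community* is the
  set of ASVs present at both timepoints; every after-sample ASV is
  classified as retained (in own before), transferred (absent own before,
  present partner before) or introduced (absent both befores); cohort-unique
  ASVs, per-couple summary rows (totals / uniques / percent unique per
  direction) and contributor genera (opposite-signed abundance shifts in the
  two partners) follow.
- **A synthetic-cohort simulator** — CST-structured vaginal communities,
  richer penile-skin communities, planted directional transfer with
  closed-form detection probabilities, introduced environmental taxa,
  reagent contaminants, controls and the mock community, with full ground
  truth, so that every stage is testable without sequencing data.

## Worked example

Simulate a 12-couple cohort at realistic read depth and run every stage:

```bash
sexome run --simulate --outdir worked --seed 7
```

`worked/couple_summary.tsv` holds one row per couple in the style of a
baseline-and-transfer summary table:

```
couple_id  female_baseline_total  female_baseline_pct  fm_transfer_total  mf_transfer_total
C01        9                      0.0                  9                  27
C02        9                      0.0                  7                  25
C03        11                     0.0                  9                  21
```

(the female vaginal baseline is much smaller than the male penile-skin
baseline, and both directions show transferred ASVs; percent columns give
the cohort-unique fraction of each count). `worked/permanova.tsv` reports
the community-level effects on the 0.1 %-filtered Bray-Curtis distances:

```
factor     pseudo_F  r_squared  p_value  n_permutations
sex        12.265    0.211      0.001    999
couple_id  2.706     0.453      0.001    999
```

— sex and couple pairing both structure the communities, with couple
explaining the larger share of variance. `worked/alpha_comparisons.tsv`
shows the male/female Shannon comparison (p ≈ 2.9e-9; penile-skin samples
are consistently more diverse than vaginal ones), and `worked/cst.tsv` the
per-female community state types:

```
sample_id  cst  dominant_taxon           dominant_relabund
C01_F_B    I    Lactobacillus crispatus  0.865
C02_F_B    III  Lactobacillus iners      0.943
C03_F_B    IV   Gardnerella vaginalis    0.514
```

`worked/transfer_calls.tsv` lists every directional transfer call with the
donor-before and recipient-after relative abundances, and
`worked/contaminants.tsv` the prevalence scores (here 6 of 81 ASVs flagged,
all planted reagent contaminants).

The same stages run on real tables:

```bash
sexome run --counts counts.tsv --taxonomy taxonomy.tsv --metadata metadata.tsv \
    --outdir results --seed 1
```

## Layout

- `sexome.cohort` — count/taxonomy/metadata tables, TSV/FASTA IO, relative
  abundance, low-abundance filtering, rank aggregation
- `sexome.decontam` — prevalence-method contaminant scoring and removal
- `sexome.diversity` — Shannon, rank-sum, Bray-Curtis, PCoA, PERMANOVA
- `sexome.cst` — community state type assignment
- `sexome.transfer` — baselines, uniqueness, transfer classification,
  couple summaries, contributor genera, ground-truth recovery
- `sexome.simulate` — the synthetic cohort generator and mock community
- `sexome.pipeline` / `sexome.cli` — orchestration, exports, `sexome` CLI

See `docs/methods.md` for the models, parameter defaults and limitations.
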