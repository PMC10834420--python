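# clonmosaic

Somatic mosaicism analysis for multi-region tissue sampling.

Normal and benign tissues are mosaics of small somatic clones. When an
organ is sampled as many microdissected, nearly-clonal areas — for
example prostate trio sampling (one tumor area plus ipsilateral and
contralateral nontumor areas per case) or dense 3D grids of up to ~58
areas — shallow whole-genome sequencing of each area turns clone
biology into statistics on variant allele frequencies (VAF).
`clonmosaic` implements that analysis end to end, for people studying
clonal expansion, field effects and embryonic lineage structure in
nontumor tissue:

* **Filtering** — population-AF, exact-binomial and trio germline
  rules, a beta-binomial cross-sample test for recurrent low-VAF
  artifacts, and indel read-support/paralog filters. Records are
  flagged, never deleted.
* **Clonality** — clone size per area from the VAF peak or the median
  cell fraction of clonal mutations; mutant copy number
  `n_mut = v·(ρ·c_t + (1−ρ)·c_n)/ρ`; exact-binomial-CI clonal calls;
  shared/private × clonal/subclonal (SC/PC/SS/PS) classes per case.
* **Signatures** — SBS96 spectra and non-negative least-squares
  refitting of a seven-signature panel (SBS1, 2, 3, 5, 13, 18, 92) with
  aging/APOBEC/ROS/HRD presence calls.
* **Lineage** — early embryonic mutations (high-VAF mosaic variants
  shared by more than two areas), a two-state maximum-likelihood sample
  phylogeny, first-generation lineage labels, and a layered / mixed /
  indeterminate spatial pattern call on the 3D grid.
* **Spatial statistics** — age–burden regression, zonal (PZ/CZ/TZ)
  Kruskal–Wallis, lateral/antero-posterior/vertical asymmetry tests,
  paired ipsilateral-vs-contralateral comparisons, driver and RTK/RAS
  convergence summaries.
* **Synthetic cohorts** — a fully ground-truthed generator emulating
  the trio and grid designs (burden slopes 16 and 43.4 mutations per
  year per clone, clone fractions 0.36/0.41/0.77, WGS depth ~16 / panel
  ~997, injected germline and artifact confounders, EEMs propagated on
  an embryonic lineage tree in layered or mixed spatial patterns).

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a 4-case trio cohort and run the full pipeline:

```
$ clonmosaic simulate --out cohort --seed 42 --n-cases 4
$ clonmosaic run --vcf cohort/variants.vcf --samples cohort/samples.tsv \
      --out results --design trio --seed 42
{
 "input": 33759,
 "pop_af": 0,
 "trio_germline": 122,
 "artifact_betabinom": 98,
 "indel_support": 1590,
 "passed": 31949
}
```

Of 33,759 candidate sites, 122 were flagged germline (shared by all
three areas of a case at heterozygous VAF), 98 as recurrent cross-sample
artifacts (many carriers, tightly dispersed low VAF), and 1,590 indel
records lacked read support; 31,949 sites pass every filter. Per-area
clone sizes land where the generator put them — nontumor areas in the
0.3–0.4 cell-fraction range, tumor areas near 0.8:

```
$ head -4 results/clones.tsv
sample_id   clone_size  method      n_mutations_used  low_confidence
CASE01_N1   0.2857      median_ccf  820               False
CASE01_N2   0.4000      median_ccf  801               False
CASE01_T    0.7842      median_ccf  3830              False
```

`results/` also contains `mutation_classes.tsv` (SC/PC/SS/PS per
mutation), `exposures.tsv` and `presence.tsv` (signature refits),
`report.json` (regression, proximity and driver statistics) and
`manifest.json` (per-stage accounting; rerunning with the same seed
reproduces every file byte for byte). For a grid cohort
(`--design grid3d`) the run adds per-case lineage labels, a Newick tree
and `pattern.json` with the layered/mixed call and per-axis Cramér's V
scores.

The same steps are available stage by stage
(`clonmosaic {simulate,filter,clonality,signatures,lineage,spatial,report,run}`)
and as library functions.

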