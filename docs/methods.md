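# Methods

`clonmosaic` analyses somatic mosaicism in normal and benign tissue from
multi-region sampling designs: many microdissected areas (each a nearly
clonal patch of epithelium, 5,000–10,000 cells) per organ, sequenced at
shallow whole-genome depth (~16x) with optional deep-panel validation
(~997x). This note records the models, the defaults and why, what the
synthetic cohorts do and do not capture, and the numerical choices.

## Read-count model

Every read-level computation assumes binomial sampling: a variant with
true allele fraction *v* observed at depth *d* ~ max(Poisson(d̄), 1)
yields alt counts ~ Binomial(*d*, *v*). A heterozygous mutation carried
by a clone occupying cell fraction *f* of a diploid area has
*v* = *f*/2. The generator, the filters, the clonality estimates and the
confidence intervals all share this model; it ignores mapping bias,
strand artifacts and overdispersion from library amplification, which is
why recurrent artifact sites are modelled explicitly instead (below).

## Variant filtering cascade

Order: population-AF → germline → beta-binomial artifact → indel support.
Germline removal runs before artifact fitting because genuine germline
sharing otherwise dominates the cross-sample dispersion estimate.

* **Population AF** — flag when the annotated population frequency
  exceeds 0.01 (strict inequality).
* **Trio germline** (trio designs) — flag a variant detected (≥1 alt
  read) in *all* samples of a case with mean VAF > 0.3. At 16x this
  catches ≥95% of heterozygous germline while touching almost no
  clone-private somatic variant.
* **Pooled binomial germline** (grid designs) — alt/depth pooled across
  all areas of the case, exact two-sided binomial test
  (minimum-likelihood method) against p₀ = 0.5; germline when the test
  does *not* reject (p ≥ α = 0.01) and the pooled VAF lies in
  [0.3, 0.7]. Pooling restores power that a per-sample test lacks at
  16x, and mosaic (subset-carrier) mutations dilute below the window.
* **Beta-binomial artifact** — per site across all cohort samples, fit
  the overdispersion ρ of a beta-binomial with the pooled mean by
  bounded 1-D likelihood search (ρ ∈ [1e-6, 0.89]). A site is artifact
  when it has ≥3 carrier samples, ρ < 0.1 (counts tightly binomial
  around a shared low mean — the signature of a recurrent technical
  error) and pooled mean VAF < 0.25 (the guard keeps germline-like
  half-VAF sharing in the germline filters' domain). Genuine
  clone-restricted variants show bursty support and fit high ρ.
* **Indel support** — indels with fewer than 7 total reads or fewer than
  2 variant reads in a sample, plus optional user-supplied paralog
  intervals (BED, converted to 1-based inclusive on read).

Records are flagged, never deleted; the flag set only grows and the
cascade is idempotent. α, windows, ρ cutoff and carrier minimum are all
configuration.

## Clone size and clonality

Mutant copy number for VAF *v*, clone/purity fraction ρ, local total
copy number c_t and normal copy number c_n:

    n_mut = v · (ρ·c_t + (1−ρ)·c_n) / ρ

CCF point estimate: n_mut itself while n_mut ≤ 1, else n_mut divided by
its nearest integer, capped at 1. Copy number defaults to diploid and can
be supplied as a segment table.

**Clonal call.** A mutation is *compatible with clonal* when the exact
(Clopper–Pearson, 95%) binomial interval of its VAF, pushed through the
formula above, reaches one mutant copy (CCF upper bound ≥ 0.9). At 16x
that interval alone is nearly always compatible with clonality, so the
pipeline's operating rule adds the standard majority-of-clone condition:
the CCF *point* estimate must also reach 0.5. The pure CI rule remains
the default of `call_clonal_status`; estimation and classification pass
`point_threshold=0.5`. Both thresholds are configuration.

**Clone size.** Two estimators. `vaf_peak`: twice the argmax of a
fixed-bandwidth (0.03) Gaussian kernel density over VAF, on a 0.002
grid. `median_ccf` (default for reported values): the peak estimate
anchors per-mutation clonal assignments; the clone size is the median
diploid cell fraction (2·VAF) of the mutations assigned clonal,
re-anchored once on its own result. Estimates below 0.15 are flagged
low-confidence (no resolvable clone). On samples with ≥1,000 mutations
this recovers true fractions 0.2–0.9 with median absolute error ~0.01
at 16x and <0.005 at 997x.

**Sharing classes.** Within a case, a sample carries a mutation when
alt ≥ 2 and VAF ≥ 0.02 (dropout guard at 16x). SC = ≥2 carriers, clonal
in all; SS = ≥2 carriers, subclonal somewhere; PC/PS = single carrier,
clonal/subclonal. The classes partition every detected mutation.

## Mutational signatures

Spectra use the standard SBS96 pyrimidine-strand encoding. Exposures are
non-negative least squares of the normalized spectrum on a 96×7 profile
matrix, renormalized to sum one — the plain refitting objective, applied
per sample or per mutation class. Presence of a signature group (aging
SBS1/5, APOBEC SBS2/13, ROS SBS18, HRD SBS3) is any member weight
≥ 0.05 (configurable; a presence criterion has to be declared somewhere,
and 5% of a sample's mutations is a conventional floor).

The bundled profile table is a **self-authored stylized stand-in**, not
the COSMIC catalogue: each signature gets its field-known dominant
context block (SBS1: C>T at CpG; SBS2: C>T at TpC; SBS13: C>G at TpC;
SBS18: C>A; SBS5: broad T>C; SBS92: T>C at ApT; SBS3: flat) over a flat
background, yielding a well-conditioned matrix (κ ≈ 7.8). Tests also use
random profile matrices so correctness never depends on the bundled
numbers; users can drop in any column-stochastic 96×k table.

## Early embryonic mutations and lineages

Each microdissected area is treated as one clone. An EEM is a mutation
carried by **more than two** samples (≥3), with median carrier VAF
≥ 0.2 (high-frequency mosaic, resembling germline) and not shared by
≥90% of samples at germline-like VAF (that is germline's domain).
Carrier call: alt ≥ 2 and VAF ≥ 0.1. All thresholds configurable.

First-generation lineages are the earliest mutually exclusive EEM
clades: EEMs are grouped greedily in decreasing carrier-count order,
joining a group when ≥60% of their carriers lie inside its founding set
(embryonic nesting), else founding a new group; samples are labelled by
majority EEM membership, carriers of none are "early mutation-absent".
Founding sets overlapping by Jaccard > 0.2 mark the model inconsistent.

**Sample phylogeny.** Two-state (presence/absence) maximum likelihood:
symmetric binary-change model, per-character Felsenstein pruning, one
shared branch length optimized by bounded scalar search. Exhaustive
topology search for ≤7 leaves; above that, neighbour-joining on Hamming
distances followed by nearest-neighbour-interchange hill climbing with
strict-improvement acceptance (deterministic). A nucleotide substitution
model would be wrong here — the characters are mutation presence calls,
not aligned bases.

**Spatial pattern.** With integer grid coordinates (x lateral, negative
= left; y antero-posterior; z vertical layer), compute Cramér's V
between lineage label and each axis stratum. *Layered*: vertical V ≥ τ
(0.5) and every layer's majority lineage holds ≥ κ (0.8) of its
samples. *Mixed*: ≥ half the layers contain ≥2 lineages, the lateral
score is the largest axis score **and itself reaches τ**. The magnitude
requirement on the lateral score is deliberate: an argmax alone is a
direction, not evidence — under random labels some axis is always
maximal, and without the τ floor roughly a third of null cases would be
called mixed. With it, random labelings are indeterminate in ≥95% of
trials while both archetypes (pure alternating layers; left/right split
within every layer) classify correctly by construction.

## Statistics

Mann–Whitney U is exact (full enumeration) when the smaller group has
≤8 observations and there are no ties, otherwise the tie-corrected
normal approximation; Kruskal–Wallis with tie correction; Pearson
chi-square without continuity correction; OLS with t-based slope
intervals. The ipsilateral/contralateral comparison is a paired
sign-flip permutation test on within-case differences (exact to 12
pairs, seeded Monte-Carlo beyond). Raw p-values are reported, matching
the practice of reporting unadjusted tests in this setting; a
Benjamini–Hochberg helper exists for batch reports. Midline samples
(x = 0) are excluded from lateral contrasts.

Calibration note: empirical size is checked at n = 30 per group for the
rank tests and at deep-panel depth for the exact binomial test. At 16x
the binomial null is so discrete that *no* procedure can attain size
near 0.05 (the nearest attainable level at n = 16 is 0.021); at that
depth only the conservative bound P(p ≤ α) ≤ α holds, which the test
suite verifies separately.

## Synthetic cohorts

The generator is first-class, tested code and the source of every
ground-truthed experiment. Defaults encode the study conditions:

| parameter | default | origin |
|---|---|---|
| design | 20 trio cases / 3D grid cases | sampling design |
| burden slope (normal / BPH) | 16 / 43.4 mut·yr⁻¹·clone⁻¹ | age-burden regression |
| clone fraction (normal / BPH / tumor) | 0.36 / 0.41 / 0.77 | VAF-peak clone sizes |
| depth (WGS / panel) | 16 / 997 | sequencing design |
| ROS presence prob (normal / BPH / tumor) | 0.22 / 0.23 / 0.90 | signature presence rates |
| driver rate (normal / BPH) | 4.9 / 6.3 nonsilent per sample | driver counts |
| ages | Uniform(50, 80) yr | cohort ages untabulated; configurable |
| subclonal fraction; CCF | 0.25; Uniform(0.1, 0.5) | chosen once as realistic low-VAF tail |
| shared-somatic fraction | 0.05 | sharing is rare between distant areas |
| germline / artifact sites | 30 per case / 10 per cohort | confounder channel |
| artifact true VAF; recurrence | U(0.01, 0.05); 90% of samples | recurrent low-VAF error model |
| EEM mosaic VAF | Normal(0.40, 0.04), clipped [0.25, 0.5] | near-het mosaic levels |

Trinucleotide contexts are drawn from per-sample mixtures over the
bundled profiles (SBS18 enters a sample's mixture with the tissue's ROS
probability at weight 0.18); reference trinucleotide frequencies are
uniform. Zones are deterministic rings on (x, y): TZ innermost, CZ, PZ
outer. Telomere lengths are tissue-shifted Gaussians consumed as
metadata. Copy number is diploid by default with optional injected
arm-scale segments.

What the generator does **not** emulate: mapping/alignment error beyond
the recurrent-site model, copy-number-driven VAF distortion (unless
segments are injected), shared subclonal structure between areas,
non-uniform genome context composition, and contamination between
microdissected areas. Passing tests therefore demonstrate correct
recovery under the declared statistical model, not robustness to every
real-data pathology.

## Problem sizes and numerical choices

Tested experiment sizes: 20-case trio cohorts (~160k sites) for filter
and classification recovery; 50 samples × 1,200 mutations spanning
fractions 0.2–0.9 for clone-size error; 2,000–5,000 replicates for test
calibration; 100 random mixtures at 5,000 draws for signature recovery;
50 random ≤6-leaf instances against a brute-force state-summation
oracle plus a noise-free 8-leaf recovery for trees; 100 seeded grid
cohorts per spatial pattern (with a light somatic background — the
pattern call depends on EEMs and coordinates, not on burden). Grid/NNI
tree searches, KDE argmax and the beta-binomial ρ search are
deterministic; NNI accepts strict improvements only, exhaustive search
breaks likelihood ties by enumeration order; the ρ likelihood fixes the
mean at the pooled fraction rather than profiling it (one-parameter
search, adequate because artifact discrimination needs dispersion, not
mean precision). Degenerate inputs: all-identical presence rows return
a star tree with a warning; empty spectra, single zones, one-sided axes
and constant ages raise errors; constant burdens return slope 0 with
R² = 0.

## Known limitations

* Per-mutation clonal/subclonal discrimination at 16x is power-limited;
  mid-range subclones (CCF 0.4–0.5) are intrinsically ambiguous, which
  bounds sharing-class agreement near 90% under the default mixture.
  Deep-panel depth removes the ambiguity.
* The ML tree uses a single shared branch length; it ranks topologies
  well for presence/absence characters but branch lengths are not
  interpretable as time.
* NNLS refitting inherits the identifiability of the supplied profile
  matrix; flat signatures (SBS3/SBS5-like) trade off against each other
  at low mutation counts.
* EEM detection assumes each area is clonal enough that a mosaic
  mutation's VAF reflects its embryonic cell-fraction; heavily
  polyclonal areas would dilute carriers below the VAF threshold.
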