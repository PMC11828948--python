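# Methods

## Scope and data model

`cas13gi` analyses pooled dual-perturbation Cas13d proliferation screens.
The unit of measurement is the *construct*: an ordered pair of elements
(single 23-nt spacers or 3-guide same-gene arrays) in expression positions 1
and 2. Three library strategies are supported:

| strategy | positions | enumeration |
|---|---|---|
| `U6-g1-g2` | two spacers concatenated behind one mU6 promoter | every element × every NTC, both positions: `2·E·N` |
| `U6-g1-U6-g2` | spacer on mU6, spacer on hU6 | full ordered cross `E²` |
| `U6-a1-U6-a2` | 3-guide array on mU6, 3-guide array on hU6 | full ordered cross `A²` |

With the canonical panel (6 genes × 27 guides + 30 NTCs) these give 11,520,
36,864 and 4,096 constructs (64 arrays: 9 per gene built as
rank-k-of-each-selection-group, plus 10 random NTC arrays). The concatenated
enumeration `2·E·N` counts NTC–NTC ordered pairs once per position block;
the duplicated block is kept as distinct cloning products (id suffix `--r`)
so that the printed total of 11,520 is the number of library elements. When
counting reads, sequence-identical duplicates credit the first occurrence.

A screen is a construct × sample integer count matrix with exactly one
baseline (t0) sample and `R` endpoint replicates per condition arm
(untreated, treated), harvested after `days` of growth.

## Fitness statistic (tau)

Preprocessing per screen: constructs whose mean baseline count is below
`low_count_fraction` (default 0.10) × the grand-mean baseline count are
removed; a pseudocount (default 1) is added; each sample is divided by its
own mean so column means are exactly 1.

For construct *x* and endpoint sample *t*:

```
tau_x = log2[(N_t^x / N_t0^x) / (N_t^NTC / N_t0^NTC)]
```

The NTC aggregate is the mean frequency over NTC–NTC constructs (a median
is available). Each sample's taus are then centred on that sample's NTC–NTC
mean tau. Centring makes the aggregate choice irrelevant: any per-sample
positive constant inside the log cancels, which the tests verify
numerically. "Exactly zero" assertions use 1e−9; tau/GI arithmetic is double
precision.

## GI scores

The single-perturbation phenotype φ of element *e* in orientation *o*
(position 1 or 2) and condition *c* is the mean centred tau over all
constructs pairing *e* with an NTC partner in the other position, across
that condition's replicates. Orientations use disjoint construct sets, so
position-dependent behaviour is visible rather than averaged away.

Guide-level GI per double construct, condition and replicate:

```
GI = tau_double − (φ_pos1 + φ_pos2)
```

Three record families are scored identically and kept separate:
`gene-gene` (different genes), `same-gene` (both positions target one gene;
orientation is not distinguished), and `single-gene-control` (gene × NTC,
with the NTC side's expectation the mean phenotype of all NTC elements in
that orientation — a designed-null family that should never produce hits).

**Weak-phenotype filter.** Per gene and orientation, the cutoff is the mean
of that gene's element phenotypes. The default `signed` mode passes an
element when its phenotype is at least as extreme as the cutoff in the
cutoff's sign direction (ties pass); a `magnitude` mode compares absolute
values. An element's GI contributions are removed only when it fails in
*both* orientations. The signed reading was chosen because "weak" is only
meaningful relative to the direction of the gene's effect; both modes are
exposed because the choice is genuinely open.

**Testing.** GI values are grouped by (gene pair, orientation, condition);
the group mean is the gene-level GI, with one observation per guide-pair
construct × replicate. Each group mean is tested against zero with a
moderated one-sample t-test: sample variances are modelled as
`s² ~ s0²·F(d, d0)`, the prior `(d0, s0²)` is fitted by method of moments on
`log s²` via digamma/trigamma inversion, the posterior variance is
`(d0·s0² + d·s²)/(d0 + d)` and the t statistic has `d0 + d` degrees of
freedom. When the observed log-variances are no more dispersed than
chi-square sampling explains, `d0 = ∞` and the pooled variance is used —
in that limit (e.g. identical sample variances) the moderated t equals the
ordinary t. The implementation agrees with Bioconductor limma's
`squeezeVar` to ~1e−13 on shared inputs (cross-checked in the test suite).
Benjamini–Hochberg step-up correction is applied within each
(condition, record family), so the control families do not dilute the
gene-gene family; the prior is fitted across all of a condition's groups.

Groups with a single observation report their mean with no p-value.

**Hit calling.** A record is a hit when `|GI| > 0.2` and `FDR < 0.5`
(defaults taken verbatim from the screening practice this package
implements; the permissive FDR bound is deliberate, not corrected). A gene
pair enters the reproducible-interaction network only when it is a hit in
both orientations; the edge weight is the mean GI over orientations, its
sign buffering (+) or synergistic (−).

Note on calibration: because the φ terms are themselves estimates shared
across a group's observations, the one-sample test is mildly
anti-conservative when guides per gene are many relative to NTC partners
(shared-error variance grows like `2·G/N_NTC` relative to the nominal
variance). At the panel proportions used here the measured type-I error at
p < 0.05 is ≈ 0.055–0.06.

## Read processing

Reads identify constructs positionally: R1 carries the position-1 core
inside fixed amplicon context (74 nt head, 18 nt tail), R2 reads the bottom
strand with the reverse-complemented position-2 core inside 59/33-nt
context. For array libraries the cores are gRNA-1 of array-1 and gRNA-3 of
array-2. The processing chain:

1. **Recombination filter** — pairs containing `GCTTTAAGGC` in R1 or
   `CCAACAAGGT` in R2 (single-cassette recombination diagnostics) are
   removed. The default `or` logic removes a pair when either mate shows its
   motif, since a recombined product corrupts the pair regardless of which
   mate reveals it; an `and` mode preserves the stricter literal reading.
2. **Fixed-coordinate trimming** — coordinates count removed bases; too-short
   reads are tallied, not errors.
3. **Joining** — R2 core is reverse-complemented; because the two spacer
   slots are disjoint amplicon intervals the default is concatenation in
   construct order. An overlap mode (minimum-mismatch offset search,
   `min_overlap=10`, `max_mismatch_frac=0.25`, ties → unmerged) exists for
   overlapping designs; those two defaults are package choices.
4. **Assignment** — Hamming distance against every reference core; unique
   minimum ≤ 3 → assigned, tie → ambiguous, else unassigned. Substitution-
   only distance is appropriate for fixed-length amplicon interiors; reads
   with indels fall into "unassigned".

The processing report (total = recombined + too_short + unmerged +
unassigned + ambiguous + assigned) is asserted on every run.

## The screen simulator

The simulator exists so every downstream stage is testable against known
truth. Growth is exponential in log2 units relative to NTC: a construct with
fitness `f` (log2/day) multiplies its relative abundance by `2^(f·days)`,
so planted truth maps linearly onto tau. Construct fitness is

```
f = eff1·m·effect(g1) + eff2·effect(g2) + eff1·m·eff2·gi(g1, g2)
```

with NTC contributions zero, array efficiency the max over member guides
(arrays knock down more strongly), and `m` the position-1 interference
factor (below).

Defaults (chosen once as realistic screen conditions; all overridable and
seeded):

| parameter | default | meaning |
|---|---|---|
| `days` | 19 | growth window between t0 and endpoint |
| `coverage` | 1000 | reads per construct per sample |
| `replicates` | 2 | endpoint replicates per arm |
| `treated_effect` | 0.05 log2/day | per-gene effect magnitude under drug (±, half the genes sensitising, half desensitising) |
| `untreated_effect` | 0.01 log2/day | mild same-sign effects without drug |
| `baseline_sigma` | 0.5 | log-normal sd of baseline abundances (library bottleneck) |
| `efficiency_beta` | Beta(5, 2) | per-guide knockdown efficiency |
| `dispersion` | 0.05 | NB overdispersion of endpoint counts |
| `error_rate` | 0.001/base | FASTQ substitution errors |

Counting noise: each sample is a multinomial draw at depth
`coverage × constructs`; endpoint samples additionally receive gamma-Poisson
jitter (`var = μ + μ²·dispersion`) representing clonal growth stochasticity.
The baseline is a pre-growth snapshot and carries sequencing noise only —
growth stochasticity has no analogue at t0. With `dispersion = 0` sample
sums equal the depth exactly.

**Interference model.** Only the concatenated `U6-g1-g2` strategy exhibits
partner interference, and it modulates only the position-1 element's
activity. The log interference factor for (pos1, pos2) is a *shared*
per-partner term `z(pos2) ~ N(0, interference_sd²)` — the same partner
boosts or dampens every position-1 guide, which is what makes profiles of
different guides correlate — plus a pair-specific term
`N(0, (interference_sd/2)²)` that degrades the position-1 vs position-2
phenotype agreement. A purely pair-independent draw would render the
cross-profile correlation diagnostic powerless by construction, so the
shared component is essential to emulate the phenomenon.

What the simulator does *not* model: drug dose escalation (a single
per-condition fitness landscape stands in for IC50→IC80 kinetics),
collateral RNA cleavage, cell-cycle structure, multiple integration at
MOI > 1, selection dynamics, and PCR jackpotting. Passing tests therefore
demonstrate the *analysis* is correct and calibrated under a plausible
generative model, not that real screens meet these assumptions.

## Interference diagnostics

Partner profiles (element × NTC-partner matrices of replicate-mean taus,
shared column ordering) are compared pairwise by Pearson correlation
(pairwise-complete, ≥ 3 shared observations; Spearman behind a flag). The
interference score is the mean |r| over distinct-element pairs; its null is
built by independently permuting each profile's partner labels (≥ 999
permutations, seeded), giving an empirical p in `[1/(B+1), 1]`. The score is
a summary statistic constructed for this package — the phenomenon it detects
is usually shown as a correlation heatmap without a formal test — and is
labelled as such in outputs. Orientation asymmetry (pos1 score − pos2 score,
with both permutation p-values) flags position-1-specific interference.

At the suite's study conditions (6 genes × 3 guides + 10 NTCs, 2
replicates, 1000× coverage, `interference_sd = 0.5`) the score exceeds the
null 95th percentile in ≈ 98–100% of concatenated runs and ≈ 4–8% of
matched dual-promoter runs.

## Problem sizes used by the validation suites

Stochastic checks use the smallest designs that instantiate the stated
study conditions: null calibration on 21 genes × 2 guides + 30 NTCs (20
seeds; ~16,800 gene-pair tests), planted-GI recovery on 2 genes × 27 guides
+ 30 NTCs at 500× coverage (20 seeds), and interference discrimination on
6 genes × 3 guides + 10 NTCs (50 paired seeds). These sizes are package
choices balancing statistical resolution against simulation cost.

## Numerical and degenerate-input choices

* Spacers are upper-cased ACGT-only, exactly 23 nt; ambiguity codes are
  rejected at construction.
* The DR36 direct repeat is a configurable 36-nt constant (default: the
  published RfxCas13d direct repeat), validated for length.
* Element ids are deterministic (`GENE_gNN`, `NTC_NN`, `GENE_aN`) so
  count-matrix joins are stable across runs.
* A gene with a single element trivially passes the weak-phenotype filter
  (it equals its own mean).
* Zero-variance correlation inputs return NaN with a zero-variance flag
  rather than raising.
* All randomness flows through `numpy` `SeedSequence` children keyed per
  stage; identical (config, seed) reproduce byte-identical outputs.

## Known limitations

* The moderated test treats guide-pair × replicate observations as
  exchangeable within a group; shared baseline counts and shared phenotype
  estimates induce mild positive correlation, so p-values are slightly
  anti-conservative at large guides-per-gene to NTC ratios (see above).
* Hamming-only assignment discards reads with indels.
* Same-gene records measure deviation from additivity of two guides against
  one transcript; the simulator's additive truth gives them no planted
  signal, so they exercise plumbing, not biology.
* The untreated/treated arms share one baseline sample, as in the screen
  design being modelled; tau values across arms are therefore not
  independent.
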