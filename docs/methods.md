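# Methods

## Differential expression

Expression is analysed on the log2 scale; raw nonnegative intensities can
be transformed with `log2_normalize` (pseudocount 1 by default, so a zero
intensity maps to 0).  No between-array normalization (quantile, TMM) or
batch correction is performed; inputs are assumed normalized upstream.

Per feature the effect is the mean tumor−normal difference: for paired
designs the mean of within-pair differences (residual df = n_pairs − 1,
standard-error scale c = 1/√n_pairs), for unpaired designs the difference
of group means with a pooled variance (df = n₁ + n₂ − 2,
c = √(1/n₁ + 1/n₂)).  Variances are moderated empirically: assuming the
per-feature variance follows a scaled inverse-chi-square prior with d₀
degrees of freedom and scale s₀², the posterior variance is

    s̃² = (d₀·s₀² + df·s²) / (d₀ + df),

and t = log₂FC / (s̃·c) is referred to a t distribution with df + d₀
degrees of freedom.  The hyperparameters are estimated by moment-matching
the log sample variances z = log s²: solve
trigamma(d₀/2) = var(z) − trigamma(df/2) for d₀ by monotone root-finding
(Brent's method on [1e−8, 1e8]; a plain bisection serves as the test
oracle), then
s₀² = exp(mean(z) − digamma(df/2) + digamma(d₀/2) + log(df/d₀)).  When
var(z) ≤ trigamma(df/2) the log-variances are under-dispersed relative to
pure chi-square sampling noise: d₀ = ∞ and every feature shares
s₀² = exp(mean(z) − digamma(df/2) + log df), with normal rather than t
reference.  d₀ = 0 (or no prior) reduces exactly to the classical t-test,
verified to 1e−10 against an independent implementation.  Features with
zero residual variance are excluded from prior fitting and flagged
(`zero_variance`), never silently dropped — silent drops would corrupt
downstream overlap counts; with a prior they still receive a moderated
statistic, without one their p-value is NaN.

Multiple testing uses the Benjamini–Hochberg step-up rule, implemented
directly from the formula adj₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·m/j capped at 1;
an O(m²) min-scan and `statsmodels.multipletests` are independent test
oracles.  Direction calls are strict: up iff log₂FC > cutoff AND
adjusted p < alpha (down symmetric); boundary values are non-significant.
Defaults: cutoff 1.5, alpha 0.05; cutoff 0 gives the relaxed
|log₂FC| > 0 rule used when intersecting a second, less balanced circRNA
dataset.  The sign-consistent intersection keeps features called the same
direction in both studies and discards conflicts.

The paired/unpaired choice is per study: matched tumor/adjacent-tissue
microarray designs are analysed paired by default, large unmatched cohort
designs unpaired.

## Interaction catalogs and consensus

Catalogs are TSV tables with one row per (source, target, database)
attestation; rows for the same pair merge with database sets unioned,
order-independently.  miRNA labels are canonicalized (case-fold, species
prefix stripped, the common "has-" misspelling treated as the prefix) so
spelling variants match across catalogs.  The consensus filter keeps
miRNA→mRNA pairs attested by ≥ k databases; the default k = 1 (union) is
the conservative reading when the combination rule across prediction
databases is unknown — raising k trades sensitivity for precision and is
monotone by construction.

## Triad assembly

`assemble` is a single pass: for each circRNA–miRNA pair and each mRNA
target of that miRNA, the triad is kept iff all three members carry DE
directions and those directions match a paradigm exactly.  This is
set-algebraically equivalent to the two-pass formulation (join against
all miRNAs, then crosscheck against the DE miRNA list), which the
brute-force triple-loop oracle in the tests confirms.  Duplicate triads
arising from multi-database pairs collapse to one; output ordering is
lexicographic everywhere for stable diffs and reproducible exports.
Networks export to GraphML (node attributes type/direction, edge
attribute type-pair, triads in a graph attribute so round-trips are
lossless) or a triad TSV.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) (inclusive at k; depletion is out of scope), computed via
`scipy.stats.hypergeom.sf` and verified against exhaustive enumeration of
all C(N, n) draws for N ≤ 12.  The universe defaults to all genes in the
annotation collection and is configurable to all measured mRNAs (the
pipeline passes the measured set).  Terms are filtered on **raw**
p < 0.05 — matching the screening convention of the upstream workflow —
while BH-adjusted p-values are computed within each category and reported
alongside; ranking is ascending p with ties broken by larger overlap then
term id, truncated to the top 15 per category.

## PPI hubs

The interaction graph keeps edges with confidence strictly above 0.4
(medium confidence) between whitelisted genes, collapsing duplicates to
the maximum score and dropping self-loops.  Hub genes are nodes with
degree ≥ 2 — the smallest degree in the reference hub table — ranked by
degree descending.  Plain degree is used as the centrality; other hub
metrics (MCC, betweenness) are out of scope.  The hub subnetwork keeps
exactly the triads whose mRNA is a hub.

## qPCR quantification

ΔCt = Ct(target) − Ct(reference) per tissue, ΔΔCt = ΔCt(tumor) −
ΔCt(normal) per patient, relative expression 2^(−ΔΔCt).  Technical
replicates are averaged on the Ct scale before analysis.  The paired
t-test is applied to per-patient ΔCt values (tumor vs normal) — the
standard practice for ΔΔCt designs; testing the fold changes directly is
available via `paired_t`.  The test is two-sided; t = mean(d)/(sd(d)/√n),
df = n − 1.  A cohort whose ΔCt differences are identical in every
patient has an undefined t: the quantification result flags it (NaN
statistics) rather than failing, while the bare `paired_t` operation
raises.  Patients missing either tissue are excluded and reported.
Amplification-efficiency correction (Pfaffl) and standard curves are out
of scope.

## Synthetic data generator

One seeded run emulates a complete study: **two** circRNA expression
datasets (shared truth, independent noise — so the cross-dataset
intersection stage has genuine work), one miRNA and one mRNA dataset, the
two interaction catalogs, a PPI edge table, annotation term sets, and a
qPCR Ct table, plus the planted truth (DE directions, triads, hub
clique).

Expression: log2 value = baseline + condition shift + pair effect +
noise.  Baselines are Normal(8, 2) per feature — a typical log2
microarray/RNA-seq abundance scale.  Planted DE features (a `frac_de`
fraction per class, half up / half down) shift tumor samples by
±`effect_lfc`.  Pair effects are Normal(0, 0.5·noise_sd), shared by the
two samples of a pair, to exercise the paired-vs-unpaired analysis
choice; residual noise is Normal(0, noise_sd) per measurement.

Defaults are chosen as a realistic small paired design: 10 tumor/normal
pairs per dataset, 60/80/400 circRNA/miRNA/mRNA features, frac_de = 0.3.
The effect/noise regime (effect_lfc = 3.0, noise_sd = 0.75, a 4:1 ratio)
was fixed by a-priori power analysis: the planted |log₂FC| must clear the
screening cutoff of 1.5 with a wide margin at n = 10 pairs (standard
error of the paired mean difference ≈ noise_sd·√2/√10 ≈ 0.34, so the
cutoff sits ≈ 4.5 SE below the planted effect), making planted-direction
recovery the expected outcome and any failure informative about the
pipeline rather than about sampling noise.

Triads (20 by default, split between the two paradigms) reuse 2 circRNAs
and up to 4 miRNAs per paradigm and give each planted gene exactly one
triad — mirroring the hub-like topology of real ceRNA subnetworks (few
sponges, many targets).  True miRNA–mRNA pairs are reported by each of
the 5 pseudo-databases independently with probability 0.9 (a pair missed
by all databases is honestly absent); decoy pairs (≈ 2 per feature)
connect random features without direction constraints, so the direction
filter has genuine false positives to reject — decoys test specificity,
not just sensitivity.  The PPI table contains all edges of a planted
6-gene clique (chosen inside the up-paradigm triad genes so it survives
the network whitelist) at confidence 0.9 plus background edges with
probability 0.01 and Uniform(0, 1) confidence.  Annotation sets contain
one planted term per category holding the planted genes plus random
background terms.  The Ct table encodes each validated circRNA's planted
fold change through ΔΔCt (reference gene fixed at 15 cycles, target 10
cycles later in normal tissue) with Normal(0, 0.2) noise per target
reading, for a 52-patient cohort.

What the generator does **not** emulate: count-based mean–variance
relationships, between-sample normalization artefacts, batch effects,
correlated features, annotation-term overlap structure, or sequence-level
target prediction.  Passing recovery tests therefore demonstrates the
pipeline's correctness under its own statistical assumptions, not
robustness to real-data violations of them.

All identifiers are deterministic strings (circ_0001, mir_0001,
gene_0001); the same seed yields byte-identical outputs.

## Packaged worked-example tables

The three packaged TSVs are stored verbatim as printed.  Coordinate
convention: the printed genomic lengths equal end − start (not
end − start + 1); lengths are always re-derived by that rule.  The "—"
strand entries are stored as "-" (the single "+" row indicates the column
is strand, not absence).  The subnetwork table prints 23 rows while the
accompanying prose says 22 pairs; the package reports what it computes
from the table (23) and does not resolve the discrepancy.  The printed
"has-" miRNA prefix is normalized to the canonical form on load.  The
unprinted intermediate lists of the reference workflow (the full pair
catalogs and the 104-gene list) are not reconstructed.

## Pipeline and reproducibility

`run_all` executes simulate (optional) → DE ×4 (two circRNA datasets,
miRNA, mRNA) → intersect → consensus → assemble → enrich → hubs →
subnetwork → qPCR, writing every intermediate TSV, GraphML exports, a
JSON summary of per-stage counts, and a timestamped log with version,
seed and parameters.  A single config seed governs all stochastic stages;
identical config + seed gives an identical summary.  Any stage failure
aborts with the completed stages named.  Default thresholds: lfc 1.5
(relaxed 0 for the second circRNA dataset), alpha 0.05, min_databases 1,
PPI confidence 0.4, min degree 2, enrichment alpha 0.05, top 15.

`scripts/acceptance.py` re-runs the worked examples, an end-to-end
recovery study at the default conditions above, the variance-prior
recovery simulation (10,000 features, planted d₀ = 4, s₀² = 1, df = 4),
and the ddCt cohort (planted ΔΔCt = −2, n = 52), all driven by a single
seed.
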