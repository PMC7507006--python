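# Methods

## Coverage model

The measurand is mean per-base fragment-overlap depth over the promoter
window [TSS − flank, TSS + flank), flank = 1000 bp, normalized per
million fragments in the sample's library. Windows are symmetric in
genome coordinates regardless of strand; strand matters only when
orienting composite profiles (minus-strand windows are reversed so
offsets increase in the transcription direction). Windows clipped at a
chromosome edge exclude the clipped positions from the denominator.
Per-base overlap depth (not fragment-midpoint counting) is the default
statistic; midpoint counting is available on `FragmentSet` for
sensitivity analyses. Coverage queries run on sorted endpoint arrays
with prefix sums, so a window's total overlap is a closed form rather
than a per-base scan.

Coordinates are 0-based half-open everywhere (BED convention). Genes
from GTF are collapsed to one model per `gene_id` with the 5′-most
transcript start (strand-aware); per-transcript mode is available.

## Differential screen

Per promoter, a two-sided Wilcoxon rank-sum test compares normalized
coverage between response groups. For tie-free data with combined
n ≤ 25 the exact null distribution of the Mann–Whitney U is used
(dynamic-programming count over rank arrangements; two-sided p doubles
the smaller tail, capped at 1). Ties, or larger n, switch to the normal
approximation with tie-corrected variance and a 0.5 continuity
correction; a promoter whose pooled values are all identical gets p = 1.
Fold change is (mean_pCR + ε)/(mean_nonpCR + ε) with
ε = 0.01 × the global matrix mean, stabilizing ratios near zero
coverage. FDR is Benjamini–Hochberg over all tested promoters
(statsmodels). The pass rule is two-sided: FC ≥ t or FC ≤ 1/t (default
t = 1.5) and FDR ≤ 0.05 — a volcano plot has two arms, and which group
is in the numerator is a labeling choice, so the rule must be symmetric
(swapping labels maps FC → 1/FC and leaves p, FDR and the pass flag
unchanged; this is a tested invariant).

Cohort-size floor: with n₁ = n₂ = m per group, the smallest achievable
exact p is 2/C(2m, m), and BH multiplies it by roughly
(number of genes)/(number of true positives). At 5 vs 5 and 2000 genes
with ~50 true positives the floor is ≈ 0.0079·40 ≈ 0.3 — nothing can
pass FDR 0.05. Ten samples per group (the scale of the screen this
package targets) is comfortably above the floor.

Passing promoters are z-scored per gene across samples (sample sd,
ddof = 1; constant rows become zeros and are flagged) and clustered
agglomeratively on both axes with distance 1 − Pearson correlation and
average linkage; leaf orders and linkages are returned so callers can
cut the dendrogram.

## Composite (meta-)profiles and the group test

Per sample, per-base normalized depth is averaged over genes at the TSS
or TTS anchor (clipped anchors skipped), then over samples — the
gene-mean-then-sample-mean order keeps samples the exchangeable unit.
The group test is a rank-sum on **per-sample window means** (default).
The alternative unit — ranking the two groups' per-offset mean signals
across all 2·flank offsets — is retained behind a flag for
comparability with composite-profile figures but is *not valid for
inference*: all offsets of a sample share that sample's random
library-level baseline, so the per-offset unit treats ~2000 strongly
dependent values as independent and rejects on null cohorts most of the
time (measured: p ≈ 0 in 8/10 null cohorts at study scale). Published
composite-profile p-values of astronomical magnitude are characteristic
of the per-offset unit; this package does not attempt to reproduce any
particular one.

## Synthetic cohorts

The generator emulates the fragmentation biology the pipeline reads
out. Genome: two autosome-like contigs (20 Mb each by default) plus a
16,569 bp mitochondrial contig; coordinates are arbitrary. Genes (2000
by default) are spread evenly with sub-pitch random jitter (so promoter
windows are not phase-locked to the nucleosome grid), alternating
strands, 10 kb bodies.

Per sample, the fragment count is Poisson(depth); defaults: depth
200,000 — a desk-scale stand-in for low-coverage WGS, sized so a 2 kb
promoter window holds ~10 fragment midpoints. Each fragment is
mitochondrial (probability `mito_fraction`, default 0.01), uniform
background (default 0.10), or nucleosomal: its midpoint is a uniformly
chosen nucleosome center from a grid with 190 bp spacing plus Gaussian
jitter (sd 20 bp), thinned by rejection with probability d inside the
promoter window of every currently-"high" gene (d = `ndr_depletion`;
whole-window depletion is the default idealization, an optional "core"
mode depletes only −200..+50 bp around the TSS). Fragment lengths are
Normal(167, 10) truncated to [100, 400] bp — the literature-standard
mononucleosomal cfDNA size. Expression classes are Bernoulli(0.5) per
gene; the group effect flips the class of `n_differential` randomly
chosen genes in the non-pCR group. Everything is driven by one seed
through spawned `SeedSequence` children: identical config + seed gives
byte-identical output files.

What the generator does **not** model: sequence (no reads, no error
model), GC and mappability bias, copy-number aberrations, tumor
fraction dilution, between-patient covariates, and any *net* expression
shift — class flips are direction-balanced, so the two groups differ
per-promoter but have nearly equal composite mean TSS signal. Passing
tests therefore demonstrate the pipeline's statistical behavior under
idealized fragmentation physics, not performance on real plasma.

A side effect of fixed library depth worth knowing: depleting promoter
bp redistributes fragments genome-wide, so groups with different total
depleted footprints differ microscopically in baseline density
everywhere. On compact test genomes this renormalization ripple is
detectable by the (invalid) per-offset unit at the TTS; at default
genome size it is far below noise.

## Classifier

Linear SVM, C = 1 (configurable), features standardized per fold on the
training samples only; a feature constant within a fold standardizes to
zeros there. LOOCV emits one decision score per sample from a model
that never saw it. AUC is the Mann–Whitney statistic (ties ½); its CI
is a DeLong-variance Wald interval clipped to [0, 1], collapsing to the
point (flagged) when the variance degenerates at AUC ∈ {0, 1}; paired
classifier comparison is DeLong's test for correlated ROC curves.

Panel search ranks candidates by FDR, then |log₂ FC|, then gene id;
restricts to the top `pool_size` (default 20); enumerates all panels up
to `max_panel_size` when the count fits `enumeration_budget` (default
10⁶), else falls back to greedy forward selection with the same
training-LOOCV-AUC objective, logged loudly. Ties prefer smaller
panels, then lexicographic order, making the search deterministic. The
desk-scale acceptance runs use pool 10 with panels up to size 2–3,
which keeps a full enumeration in seconds at n = 20–40.

The operating threshold maximizes Youden's J on training scores (ties
toward higher specificity) and is frozen for the validation and
all-cohort evaluations. The chronological split sorts by collection
date (ties by sample id) and requires at least two samples of each
label per cohort.

Two properties of honest LOOCV worth stating plainly: (i) under a null
(uninformative features) it is *pessimistically* biased — per-fold
refitting anti-correlates held-out scores with labels, so null LOOCV
AUC centers below 0.5 with heavy spread at n ≈ 20; (ii) the training
LOOCV AUC of a panel *selected by maximizing that same quantity* is
optimistically biased (winner's curse) and is not an estimate of
generalization — the validation cohort exists precisely for that.
Tests assert the absence of optimistic leakage and the held-out
performance, not a null LOOCV AUC of exactly 0.5.

## Pipeline

Stages run in order (inputs → coverage → split → screen →
z-score/cluster → comparator features → classifier), writing TSV/JSON
outputs plus a manifest of SHA-256 checksums. Outputs carry no
timestamps; config + seed fully determine every checksum (tested).
Stage caching was deliberately left out: at these problem sizes a full
rerun is cheaper than a correct invalidation scheme, and an always-cold
run keeps the determinism contract trivial. A cohort where no promoter
passes the screen completes gracefully — the classifier stage is
skipped and the CLI exits with the documented empty-result status (4);
config errors exit 2, data errors 3.

## Numerical choices and degenerate inputs

- Exact/approximate rank-sum crossover at combined n = 25; ties always
  force the corrected approximation.
- Zero-variance pooled promoter → p = 1; empty p-vector → empty BH
  output; single p → q = p.
- Sample with zero fragments → all-zero coverage column plus a warning.
- 5-Mb bins are full bins only (an assembly shorter than the bin is an
  error); bins with zero long fragments are imputed to the sample
  median ratio; an all-constant ratio vector standardizes to zeros.
- mtDNA proxy = (mito/16,569) / (nuclear/nuclear bp) × 2; zero nuclear
  fragments is an error, zero mito fragments gives proxy 0.
- Correlation distances that are undefined (zero-variance vectors) are
  replaced with a neutral 1.0 before linkage.
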