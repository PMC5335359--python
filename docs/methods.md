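# Methods

This note documents the models, numerical choices and defaults behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Study design emulated by the generator

The synthetic experiment mirrors a two-compartment sorting design: two cell
types (SC, MAC) × three groups (wt-1mo, mut-1mo, mut-7mo) × three
replicates, hybridized in two batches. Per gene, a baseline log2 intensity
is drawn from a two-component mixture: an "absent" mode N(2.6, 0.4²) with
probability 0.30 and an "expressed" mode N(6.5, 1.5²). These values were
chosen once so that the pooled first quartile of intensities lands near 3.1
— the regime in which a presence cutoff at Q1 meaningfully separates
unexpressed probes from expressed ones. Within-group replicate noise is
N(0, 0.5²) log2 units (microarray-typical; the real arrays' variance is not
derivable from summary statements, so this is a testability choice).

Batch effects are gene-specific: an additive shift N(0, 0.3²) plus a
multiplicative residual scale exp(N(0, 0.1²)) per (gene, batch) — exactly
the location/scale family the batch adjuster estimates. Replicates are
assigned to batches round-robin, so batch composition is identical across
groups and batch is never confounded with biology.

Planted truth: a `de_fraction` of expressed genes (default 5%, i.e. 100 of
2000) receive ±`de_log2fc_magnitude` (default 2.0, i.e. 4-fold) added to
the mut-7mo samples of an alternating cell type, making the expected
tumor-vs-1-month contrast exactly the planted value. Planted
ligand–receptor loops use up-regulated DE genes as ligands and
well-expressed non-DE genes as receptors, cycling through the four
(sender, receiver) directions. Injury-day gene sets are constructed with
*exact* requested overlaps against the tumor DEG set (the pipeline scales
requested overlaps proportionally if fewer DEGs were planted, preserving
the day ordering). Catalog source files are written so that the three
sources have specified sizes and pairwise overlaps with no triple overlap,
giving a closed-form expected union.

What the generator does **not** emulate: probe-level effects (summarization
artifacts, probe GC bias), heavy-tailed or gene-correlated noise,
sorting-induced composition noise, and cross-talk between the planted
effects. Passing tests therefore demonstrate correctness of the algorithms
under the stated model, not robustness to every pathology of real arrays.

## Preprocessing

**Quantile normalization.** Each column acquires the reference distribution
formed by row means of the column-sorted matrix; ties receive the mean of
their destination values. Idempotent and rank-preserving on tie-free data
(with ties, the tie rule can perturb a second pass by design).

**Batch adjustment.** Parametric empirical-Bayes location/scale adjustment:
per-gene OLS with batch indicators plus protected group covariates,
standardization by pooled residual variance, per-batch gene-wise location
(normal prior) and scale (inverse-gamma prior) estimates shrunk by the
iterative conditional solution with method-of-moments hyperpriors
(convergence 1e-6, capped at 1000 sweeps). Two deliberate choices:
biological group is protected by default (`preserve=` to override), and
each gene is finally recentered to its original grand mean so the operation
is pure batch removal — this recentering is the one departure from the
common reference implementation, and the cross-check test against it
compares gene-centered outputs (agreement < 1e-3).

**Ortholog filter.** "Strong ortholog" = support-flagged row whose source
symbol maps unambiguously (exactly one flagged target). Targets may be
shared — paralogs collapsing onto one ortholog are legitimate and are
re-deduplicated downstream. Genes without a strong ortholog are dropped;
row order is preserved.

## Differential expression

Two-group contrasts only (the design the analysis needs): per gene, group
means, log2FC = mean_a − mean_b, pooled variance on df = n_a + n_b − 2. The
variance prior (d0, s0²) is fitted by moments on z = log s²: the excess of
Var(z) over ψ′(df/2) identifies d0 through trigamma inversion (Newton), and
s0² follows from the mean with digamma corrections. When the excess is ≤ 0,
d0 = ∞ and all genes share s0² — note the estimator's chi-square bias
correction means "identical observed s²" maps to s0² = s²·exp(log(df/2) −
ψ(df/2)), not s² itself; this matches the reference implementation exactly
(cross-checked to 1e-6 on t-statistics). Moderated t uses the posterior
variance and d0 + df degrees of freedom (normal in the d0 = ∞ limit). BH
adjustment is the step-up rule, verified against both statsmodels and the
exhaustive definition. Fold calling is strict: `2^|log2FC| > fold_cut`.

## Catalog compilation

The DLRP-style dialect is defined here (the historical flat format has no
durable spec): blank-line-separated blocks of `LIGAND\t...` and
`RECEPTOR\t...` records, all combinations within a block forming pairs.
BioGrid TAB2 rows pass a physical-evidence filter and are oriented by
ligand/receptor role sets (a row orientable both ways emits both
directions). KGML relations are read entry1 → entry2 (ligand → receptor),
multi-gene entries expanded combinatorially; organism prefixes are
stripped. Symbols are uppercased and trimmed everywhere. Merging is a union
on ordered (ligand, receptor) with provenance accumulation; the printed
snapshot sizes of the original public databases are not reproducible from
fixtures and are deliberately not asserted anywhere.

## Interactome calling

Presence cutoff: 25th percentile (linear interpolation between closest
ranks — the convention giving 2.75 for 1..8) of all pooled gene × sample
values; pooling over both cell types is the default, per-cell pooling is an
option. Presence is evaluated on group means of the tumor-state (mut-7mo)
groups, one bin per gene per cell type. Quartile bins use pooled Q1/Q2/Q3
breakpoints of the group-mean distribution with ties assigned downward. A
call requires ligand presence in the sender, receptor presence in the
receiver, and — under the default `require_de="any"` — at least one side
differentially expressed (`both`/`none` available). Catalog genes absent
from the arrays are recorded as skipped, never fatal. Output: deterministic
TSV plus a Graphviz DOT with one cluster per cell type and DE highlighting.

## Bi-cellular network flux

The intra-cell network (SIF input; the original tool's internal network is
proprietary, so synthetic/fixture networks stand in) is duplicated per cell
type; every catalog pair contributes an inter edge for each of the four
ordered cell combinations, including autocrine copies. One walk runs over
the merged graph (the alternative — two coupled walks — is not described
anywhere authoritative; the merged-graph reading is recorded in output
metadata). The walk uses the undirected skeleton: T_ij = w_j / Σ_{k∈N(i)}
w_k, restart vector q = w/Σw, restart probability r = 0.15 (standard
practice; the source analysis does not state one), tolerance 1e-10, cap 1e5
iterations, renormalization every step. Dangling nodes restart with
probability 1. Node weights: the two t-vectors are jointly
quantile-normalized (equal lengths reduce to ordinary two-column QN;
unequal lengths interpolate the two quantile functions) and mapped through
w = 2^t — strictly positive and order-preserving (`shift` alternative
available); genes missing from one cell receive that cell's median weight.
Flux: (1−r)(p_i T_ij + p_j T_ji) for undirected intra edges, the single
ligand→receptor term for inter edges. Power iteration is verified against
the direct linear solve to 1e-8. No degree-bias correction is applied by
default (none is described for the source analysis). Top-k extraction
(default k = 500) breaks ties by edge labels for determinism.

## Factor analysis

Correlation matrices throughout. Velicer's MAP uses the original squared
partial-correlation criterion (4th-power revision available), criterion(0)
evaluated on the correlation itself, argmin with smallest-m tie-break, and
stops early if partialling exhausts a variable's variance; default max_m =
min(8, p−1). The ML fit is EM on the sample correlation with the canonical
eigen start (uniquenesses from squared multiple correlations via the
pseudo-inverse, loadings from excess-above-1 eigenvalues of the rescaled
correlation — a PCA-loading start can park the fit on a degenerate
likelihood plateau), convergence at 1e-8 log-likelihood change, per-sweep
monotonicity asserted, Heywood uniquenesses clamped at 0.005 with a
warning. Varimax rotation (SVD form) with column signs fixed so each
column's largest-magnitude loading is positive; m = 1 is the identity.
Scores are regression (Thomson) scores from column-standardized data;
zero-variance variables are rejected with a clear error. Uniquenesses agree
with the R reference ML routine to ~1e-5 on planted two-factor data.

## Enrichment and overlap

Hypergeometric upper tail P(X ≥ k), exact, with BH across the tested sets;
the universe defaults to the genes present on the (ortholog-filtered)
array and is configurable, since the original background is not stated.
Signature lists (M1/M2, interferon-regulated) are inputs in GMT form. The
injury comparison selects tumor DEGs at fold > 3×, q < 0.05, counts per-day
overlaps, and judges the maximum on raw counts (ties all reported; Jaccard
and the hypergeometric p ride along for context).

## Pipeline and determinism

One YAML-serializable config drives all stages; every run writes the
resolved config back out, per-stage logs (wall time stays in the log, never
in tested outputs), and a SHA-256 manifest of every artifact. All
randomness flows from the single seed through named substreams, so
identical config + seed reproduce every file byte for byte. Stage
dependencies are checked file-wise with errors naming the prerequisite
stage. Degenerate runs (no DEGs planted) complete with empty DEG tables,
empty call lists and empty factor outputs rather than failing.

## Problem sizes used in tests and the acceptance script

Simulated matrices are 1000–2000 genes × 18 samples; null calibration uses
50 replications at 1000 genes, power checks 20 replications at 2000 genes;
network detection uses 200-gene networks (≈400 nodes) over 30–50
simulations; factor recovery uses 30 variables × 200 samples over 50
simulations and n = 500 for loading recovery. These sizes make every
recovery property measurable with comfortable Monte-Carlo margins while
keeping a full suite run around a quarter of a minute of compute per
module.

## Known limitations

Two-group contrasts only (no multi-factor designs, array weights, or
duplicate-correlation modeling); protein-complex receptors are out of
scope; the catalog parsers accept the dialects defined here, not every
historical variant; flux scores carry the degree bias inherent to
stationary flow unless the rewiring option is used; and all quantitative
guarantees are statements about the generator's model of the data, not
about any particular public dataset.
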