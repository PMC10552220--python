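# Methods

## The projection model

A reference atlas is a set of metacells — pooled groups of transcriptionally
homogeneous single cells — each defining a distribution of UMI counts over
genes, together with a type label per metacell, gene masks (feature / noisy
/ lateral), and a short list of *essential* marker genes per type. A query
is another metacell × gene count matrix. The package models every query
metacell as a convex mixture of atlas metacells and quantifies how well
that mixture explains the observed expression.

All computation happens on the common gene set G (atlas ∩ query, in atlas
order). With per-metacell totals N taken over G only, log expression is

    e = log2(ε + u / N),          ε = 1e-5 by default.

The regularization ε sets the floor for unobserved genes (log2 ε ≈ −16.6)
and caps every fold change involving a zero count.

**Seeding.** For query metacell *i*, the anchor is the atlas metacell with
the highest Pearson correlation of log expression over the fitted genes.
The candidate set is the anchor's 10 nearest atlas metacells under the
max-absolute-log-difference distance, plus up to 40 more within distance 2
(at most 50 total). Ties resolve to the lower atlas index, so runs are
deterministic.

**Mixture fit.** Weights solve

    min ‖e_i^Q − Σ_k w_k e_k^A‖₂   s.t.  Σ w_k = 1,  w_k ≥ 0

over the candidate set and the fitted genes. The quadratic program is
solved by non-negative least squares on a system augmented with a heavy
sum-to-one penalty row, followed by an exact equality-constrained
refinement (KKT system) on the active support; the solution is compared
against the anchor-only fallback so the objective can never exceed it.
Weights below 1e-5 are dropped and the rest renormalized. On problems small
enough for exhaustive search, the solver matches a 0.01-step simplex grid
to machine precision.

**Projected expression.** The weights are solved on log expression, as the
objective is written, but the *emitted* projected profile mixes candidate
linear fractions: fractions_P = w · fractions_A, e^P = log2(ε + fractions_P).
A convex mixture of UMI distributions is an arithmetic mixture; averaging
log values instead would be a geometric mean, which systematically
undershoots every variable gene (by half the candidate spread for a 50/50
mix). That bias would masquerade as a per-gene correction factor ≈ 0.8 on
weakly expressed genes and would make true two-type doublets unrepresentable
under the 8× misfit gate. This choice is the one place the implementation
departs from the most literal reading of the mixture formula, and it is
deliberate.

## Multiplicative gene correction

Technology effects that act independently on single molecules (capture,
RT, amplification) multiply each gene's expression by one constant factor.
When enabled, the correction stage computes, per gene, the correlation
fit_g between query and projected log expression across metacells and the
factor cf_g = Σ_i projected fraction / Σ_i query fraction. A gene is
corrected (query fractions multiplied by cf_g, logs recomputed) when

* fit_g > 0.8 (the trend matches),
* |log cf_g| > log 1.15 (the shift is material),
* the gene is neither noisy nor lateral, and
* its pooled query + projected profiles carry ≥ 40 UMIs — the same
  evidence rule applied to all fold factors; below that depth cf_g is
  noise.

Correction and re-projection alternate for at most 3 rounds, stopping
early once no gene is corrected; reported factors are the per-round
products. Corrected fractions are deliberately **not** renormalized:
renormalizing would leak one gene's correction into every other gene.
Every common gene is a correction candidate, not only features — the bias
is a property of the assay, not of the feature selection. Note that the
factor is the multiplier applied to the query, so a gene whose capture is
inflated 2× in the query receives a factor near 0.5; the inferred bias is
its reciprocal.

## Gene filtering

**Range filter** (once, after correction): per gene, the 2%–98% quantile
range of query and projected log expression (linear interpolation between
order statistics). A fitted gene is dropped when the shared range is
strictly shorter than 50% of the query range; zero-range genes are kept.
Noisy and lateral genes are exempt — they are never negative evidence.

**Per-type skew filter** (iterated ≤ 3 rounds): fold deviations
lfold = log2((ε + query fraction)/(ε + projected fraction)) are thresholded
into misfit indicators δ = |lfold| > 3 with ≥ 40 summed profile UMIs. Each
query metacell is assigned the type with maximal summed weight
(lexicographic tie-break, logged). A gene whose δ-fraction within a type
strictly exceeds 0.5 is removed from that type's fitted set (accumulating
across rounds), and the affected metacells are re-projected; the loop stops
when the type assignment is stable. One deliberate exception: a type's own
**essential genes are never skew-filtered**. Essentials are the designated
sentinels of their type — every query metacell assigned the type is
expected to express them compatibly — and removing them would blind the QC
to exactly the mismatch it exists to catch. Without this protection, a
homogeneous query of one novel cell state pushes the assigned type's
essential markers into the skewed set and then sails through the
unassignment and composite gates.

## Unassigned metacells and composites

After zeroing δ for type-skewed genes, a metacell is **unassigned** when it
has more than 3 misfit fitted genes or when ≥ 25% of its assigned type's
essential genes are misfit. For each unassigned metacell a two-region
explanation is attempted: the projection is subtracted from query and atlas
expression, a second candidate set is found on the residual correlations
(excluding the primary candidates), and the query is refit over the union
of the two candidate sets, on the original values. The composite is
accepted when the refit leaves ≤ 3 misfits, ≤ 25% misfit essentials over
the essentials of both types ("up to 25%", inclusive — the rescue boundary
admits what unassignment rejects at the same value), and no more misfits
than the single-region fit. Accepted metacells carry a projected and a
composite type; rejected ones keep their single-region representation.
Composites are typically doublet clusters or mixed cell groups the query's
metacell partition failed to split; the search is attempted once, never
recursively.

## QC outputs

Per metacell: projected type, composite type (empty if none), misfit gene
count, misfit essential fraction, fitted-gene mask (per type; intersection
of the two types' masks for composites), R² between observed (corrected)
and projected log expression over fitted genes, and a **similar** flag —
not unassigned AND at least ⅓ of the query's feature genes fitted. The
numeric gates behind "similar" are pinned to the unassignment thresholds,
since no separate values are published. Per gene: common-gene and feature
masks, correlation-gate mask, correction factor (1 if uncorrected), fitted
mask per type. The result container also stores the fold deviations and
profile depths, so misfit QC can be recomputed at any other fold threshold
without re-running the projection (`recompute`), reproducing the original
QC exactly at the original threshold.

## Synthetic data generator

The generator emulates the data regime the algorithm assumes, with full
ground truth. Its defaults describe the desk-scale study conditions used
throughout the tests: 8 types × 12 metacells × 2,000 genes at 50,000 UMIs
per metacell, 500 feature genes.

* **Baseline**: shared per-gene weights, log-normal (σ = 1.5 on the
  natural-log scale) — a heavy-tailed transcriptome.
* **Types**: genome-wide per-type modulation of 2^N(0, 1.0) — real cell
  types differ moderately in most genes — plus a disjoint block of 120
  marker genes per type boosted by 2^U(4.0, 5.5). Markers are drawn from
  mid-baseline genes so their expression fractions land in the
  ~10⁻³–10⁻² range of real canonical markers; marker-block genes get a
  reduced residual modulation (2^N(0, 0.5)) since their separation is
  carried by the boost itself. More extreme markers (single genes at
  several percent of the transcriptome) would make two-region composites
  unrepresentable under the 8× gate by construction — a property of the
  geometry, not of the implementation.
* **Within-type structure**: metacells interpolate between the base
  profile and a drifted endpoint (markers drifted by up to ±1 log2) and
  carry independent per-gene jitter of 2^N(0, 0.25); a metacell partition
  keeps states separate only when they are quantitatively distinct.
* **Sampling**: multinomial per metacell (totals exact by construction);
  the 50k depth keeps fold estimates stable above the 40-UMI evidence
  gate.
* **Feature genes**: top-variance genes among those with ≥ 25 mean UMIs
  per metacell — below that, log-expression variance is dominated by
  multinomial noise and no curated atlas would select the gene as a
  feature. **Essential genes**: the 4 most type-distinctive markers per
  type (≥ 4-fold over the other types' mean by construction).
* **Queries**: convex combinations of 1–3 atlas metacells of one type,
  contiguous along the type's gradient — a query state sits locally on
  the manifold, as a left-out batch does; doublets mix single metacells
  of two types at fraction α ∈ (0, 1); novel metacells are drawn from
  held-out type profiles that the atlas never sees; an optional
  multiplicative bias vector is applied to all query metacells before
  sampling (renormalized, as real capture biases are). All randomness is
  threaded through named substreams of one seed.

What the generator does **not** emulate: ambient RNA fields, cell-cycle or
other lateral programs, non-multiplicative (cell-type-specific) technology
effects, UMI saturation, and batch structure within the atlas. Passing
tests therefore demonstrate the machinery's correctness and its behavior
under the modeled effects; they do not certify performance on effects
outside the model, which on real data are handled by (or deliberately left
to) the gene masks.

## Numerical and scale notes

Runs are deterministic: no randomness anywhere in the projection path, and
all ties are broken by index or lexicographic order. Solver feasibility
tolerance is at machine precision after the KKT refinement; weights within
−1e-9 of zero are clipped. Degenerate situations — a query metacell with
zero UMIs on G, empty gene intersection, fewer than 2 fitted genes after
filtering, zero-variance correlation vectors, zero residuals in the
composite search — are either hard errors naming the offender or logged
fallbacks, as documented per function.

Validation designs run at desk scale (an 8 × 12 metacell atlas; queries of
~100 metacells), where a full projection takes well under a second on one
CPU. Two desk-scale effects are worth knowing about. First, with only 12
metacells per type, the closest-10 candidate rule occasionally excludes a
true mixture component whose noise-driven max-abs distance exceeds the
d < 2 gate for extras; at atlas scale the manifold is sampled densely
enough that the rule catches the local neighborhood. Second, mixture
weights among near-collinear same-type metacells are only partly
identifiable at 50k UMIs: the least-squares optimum genuinely trades a few
percent of weight between similar candidates to fit sampling noise
(type-level weights are recovered exactly). Both effects bound the
achievable per-metacell weight accuracy, not the type assignment, novelty
detection or bias correction.
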