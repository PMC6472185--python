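# Methods

This note documents the models and numerical conventions behind `nctools`:
what each stage computes, which parameters matter, and what the synthetic
data generator does and does not emulate.

## The measurement and its artifacts

NanoString nCounter counts individual reporter-probe molecules: one
cartridge holds up to 12 flow-cell lanes, each producing one RCC file with
an integer count per probe. The panel emulated here has the composition of
a 770-gene immune-profiling panel: endogenous probes, housekeeping probes
(assumed biologically stable), six synthetic positive controls spiked at a
known serial-dilution ladder (128, 32, 8, 2, 0.5, 0.125 fM), and eight
negative controls that measure non-specific background. Two technical
artifacts dominate: an additive background common to all probes in a lane,
and a multiplicative per-lane efficiency ("lane effect") that scales every
count in the lane.

## QC flags

Three advisory flags per lane; none of them alters counts or excludes a
lane — they surface problems to the user.

* **Binding density** (spots/µm², read from the lane attributes): pass iff
  inside a closed interval, default [0.1, 2.25] — the instrument's
  published operating range. Out-of-range density means the imaging surface
  was under- or over-loaded and counts saturate non-linearly.
* **Positive-control linearity**: squared Pearson correlation between
  `log2(count + 1)` and `log2(concentration)` over the ladder. Log-log is
  the natural scale for a serial dilution; the `+1` guards zero counts and
  costs at most ~1e-7 in r² at realistic count levels (which is why the
  rescaling invariance of r² is exact only up to that offset). Default pass
  threshold r² ≥ 0.95; counts with zero variance make the correlation
  undefined and are reported as r² = 0 with a warning.
* **Limit of detection**: the 0.5 fM positive control (POS_E by default)
  must reach the lane's background threshold (below). A lane failing this
  cannot distinguish low-expressed genes from noise.

## Normalization

1. **Background threshold**, per lane:
   `T_l = geomean(negatives) + 2 · SD(negatives)`, with zeros floored to 1
   inside the geometric mean only and the sample SD (ddof = 1) taken on raw
   counts; hence `T_l ≥ 1`. Counts below `T_l` are floored to `T_l`
   (thresholding, not subtraction), so corrected matrices are strictly
   positive.
2. **Housekeeper selection** (geNorm): for candidate gene *j*,
   `M_j = mean_{k≠j} SD_samples(log2(x_j / x_k))`. Low M = stable *ratios*
   against the other candidates. M is computed from the covariance matrix
   of the log2 values (`Var(L_j − L_k) = Var_j + Var_k − 2 Cov_jk`), which
   is algebraically identical to the double loop but O(g²) instead of
   O(g²·s); the tests verify equality to 1e-9 against a literal double-loop
   oracle. Selection removes the highest-M candidate and recomputes until
   `n_keep` (default 3, the minimum meaningful reference set) survive.
   Exact ties remove the lexicographically last gene name first, so the
   whole path is bit-reproducible without any random seed. Because M
   depends only on within-lane ratios, it is invariant to the very lane
   effects normalization has not yet removed — which is what makes it
   usable at this point in the pipeline.
3. **Scaling factors**: with `g_l` the geometric mean of the selected
   housekeepers in lane *l* and `A = mean_l(g_l)` (arithmetic mean),
   `SF_l = A / g_l`. All counts in lane *l* are multiplied by `SF_l`, which
   equalizes housekeeper geomeans across lanes (`g_l · SF_l = A` exactly)
   and preserves their mean level. With a single lane, stability across
   samples is undefined; all candidates are kept (M reported as NaN) and
   `SF = 1`, so the output equals the background-corrected counts.

Control probes are carried through correction and scaling but excluded
from the analysis matrix (they are not expression measurements); they
remain available in the normalization record.

## Variability filter

Visualizing 770 genes at once is useless, so the heatmap operates on the
*k* most variable genes. The same M statistic is reused in reverse: a
single pass computes M for every gene against all others and the top-k by
descending M (ties lexicographic ascending) are kept. A single pass — not
the iterative elimination used for housekeepers — because this is a
selection, and it buys a useful property for free: the k-gene set is
always a prefix of the (k+1)-gene set. The filter accepts an absolute
count or a percentage (`ceil(p% · genes)`); it runs on normalized values
because M needs positive ratios, not on z-scores.

## Heatmaps

Pipeline: filter → sample ordering → per-gene z-score → clustering.
Z-scores use the sample SD (ddof = 1) across the *selected* samples only,
so the color scale reflects the comparison actually shown; constant genes
become all-zero rows with a warning rather than being dropped silently.
Clustering is agglomerative with average linkage on Euclidean distances
over z-scored rows (the common default for expression heatmaps; both are
configurable), via SciPy. Four comparison layouts fix the sample order —
one patient's time course (I), every patient's first sample (II), second
sample (III), or all first samples then all second samples in the same
patient order (IV) — and in those layouts only genes are clustered, since
clustering the sample axis would destroy the comparison. A `free` mode
clusters both axes. Dendrograms export to Newick with branch lengths
derived from merge heights; rendering to an image is a thin optional layer
and nothing downstream depends on pixels.

## Network inference

Both algorithms decompose inference into one regression per target gene:
the target's profile, standardized to unit variance, is regressed on all
candidate regulators across samples, and the edge weight *j → i* is the
importance of predictor *j* in target *i*'s ensemble — the raw
(unnormalized) impurity decrease summed over split nodes, averaged (GENIE3)
or summed (boosting) over trees. Raw rather than per-tree-normalized
importance keeps weights comparable across targets.

* **genie3**: Random Forest (bootstrapped) or Extra-Trees (default)
  ensembles, default 1000 trees, `sqrt(p)` features per split.
* **grnboost2**: stochastic gradient boosting of depth-3 trees, default
  learning rate 0.01, subsample 0.9, up to 500 rounds, stopping early when
  the mean out-of-bag improvement over the last 25 rounds turns negative.
  A window larger than the round budget disables early stopping exactly.

Base ensembles are scikit-learn regressors; the per-target loop,
standardization, importance extraction, early-stop monitor and edge
assembly are this package's own. Per-target seeds are drawn from one
user-supplied seed, so identical input + seed gives a bit-identical edge
list. Self-edges are never emitted; a constant target yields zero-weight
incoming edges with a warning. `top_n_links` keeps the n highest-weight
edges with weight > 0 (ties by (regulator, target) name), a prefix of the
full sort and hence monotone in n. Samples are treated as exchangeable
observations — these are steady-state regressors, not dynamical models —
and fewer than 10 samples triggers an under-determination warning.

## Synthetic cartridges

The generator draws `count[g,l] = round(base_g · e_l · 2^ε)` with
`ε ~ N(0, sd_class)`: log-normal counts around per-gene base levels
(endogenous bases 2^U(4,11), housekeeping 2^U(6,10)), multiplicative lane
effects (default `2^N(0, 0.25)`, or planted explicitly), housekeeping log2
noise 0.1 (settable per gene, so designated stable sets are recoverable),
endogenous noise 0.5, positive controls proportional to concentration ×
lane effect (200 counts/fM, so linearity is ~1 by construction), negatives
`N(10, 3)` floored at 0. Rounding is round-half-to-even and all randomness
flows from one seed, so cartridges are platform-reproducible. Optional
planted structure: two anti-correlated gene blocks (heatmap recovery
tests) and regulator→target links; a separate generator produces the
20-gene / 30-sample / 5-link / 10%-noise matrices used for network
recovery checks.

What the generator does *not* emulate: real panel gene names, biological
covariance between genes, batch effects across cartridges, or count
overdispersion beyond log-normal noise. Passing tests therefore
demonstrate that the pipeline removes the artifacts it models (additive
background, multiplicative lane effects) and recovers planted structure —
not that it is robust to every failure mode of real cartridges.

## Problem sizes and tolerances

Oracle-equality checks (background threshold, M statistic, selection loop,
agglomeration merges) are asserted to 1e-9 absolute; the housekeeper
geomean equalization identity to 1e-9 relative; lane-effect recovery as
Pearson r > 0.99 at housekeeper noise ≤ 1e-3. The naive O(n³)
agglomeration oracle runs on ≤ 8 items, the double-loop M oracle on up to
20×8 matrices, and network recovery uses 500-tree Extra-Trees over 10
seeds (majority must place ≥ 4 of 5 planted edges in the top 10) — sizes
at which the brute-force references are fast and exact ties have measure
zero.

## Known limitations

* The four-sample clinical scenario the heatmap layouts serve is far below
  what per-target tree ensembles need; the GRN module only warns.
* The filter's M-based ranking inherits geNorm's assumption of positive,
  ratio-scaled values; it is not a variance or MAD filter.
* QC bounds and the linearity cutoff are conventions (vendor range, r² ≥
  0.95), configurable but not estimated from data.
* No cross-cartridge batch correction and no positive-control content
  normalization: scaling is by housekeepers only.
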