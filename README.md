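# nctools

Analytics for NanoString nCounter gene-expression cartridges, built for
panels like the 770-gene immune-profiling panel used in clinical
immuno-oncology studies. An nCounter cartridge yields up to 12 per-lane
RCC files of raw probe counts; before those counts mean anything they
need quality control and normalization, and to be useful to a clinician
they need to be reduced to the genes that actually change and presented
as comparable heatmaps or regulatory networks. `nctools` covers that
whole path as a library plus a CLI:

* **RCC I/O** — parse and write the sectioned per-lane RCC text format,
  assemble multi-lane experiments, attach patient/time-point metadata.
* **QC** — per-lane flags: binding density within the instrument range,
  positive-control linearity (r² of log2 counts vs the known 128…0.125 fM
  ladder), and limit of detection against the negative-control background.
  Flags warn; they never drop data.
* **Normalization** — background thresholding at
  `geomean(negatives) + 2·SD`, selection of the ≥3 most stably expressed
  housekeeping genes by the geNorm stability statistic
  `M_j = mean_{k≠j} SD(log2 x_j/x_k)` (iterative removal of the
  highest-M candidate), and per-lane scaling factors
  `SF_l = mean(g)/g_l` that equalize housekeeper geometric means across
  lanes.
* **Filtering** — keep the *k* (or top *p*%) most *variable* genes, ranked
  by the same M statistic in reverse.
* **Heatmaps** — per-gene z-scores, average-linkage hierarchical
  clustering, and four clinically motivated sample layouts (one patient's
  time course; first samples of all patients; second samples; first-then-
  second), exported as TSV matrices and Newick dendrograms.
* **GRN inference** — directed regulator→target networks from per-target
  tree-ensemble regressions (`genie3` Random-Forest/Extra-Trees,
  `grnboost2` stochastic gradient boosting with out-of-bag early
  stopping), edge weights = impurity-decrease importances, filtered to
  the n strongest links. Seed-deterministic.
* **Simulator** — synthetic 12-lane, 770-probe cartridges with known lane
  effects, housekeeper stability, control ladders and planted
  cluster/regulator structure, so every stage is testable end to end.

See `docs/methods.md` for the statistical details and conventions.

## Worked example

Simulate a full cartridge and run the whole pipeline:

```bash
nctools simulate --lanes 12 --endogenous 730 --housekeeping 40 --seed 7 --out demo/rcc
# wrote 12 RCC files to demo/rcc
nctools run --in demo/rcc --out demo/out --top-k 100 --top-n 20 --trees 200 --seed 7
# pipeline complete -> demo/out
```

`demo/out/normalization_summary.tsv` holds the per-lane numbers:

```
sample_id      background_threshold  lane_geomean        scaling_factor
SIMCART_L01    14.613485169506621    152.48861690543384  1.0708444542416158
SIMCART_L02    15.033642144977675    168.69531835972822  0.9679675247415753
SIMCART_L03    14.755424471122073    148.62319395810118  1.0986951995809764
...
```

Lane 1's negative controls put its detection floor at ~14.6 counts; its
housekeeper geometric mean (152.5) sits below the cartridge average, so
every count in that lane is scaled up by 1.071. After scaling, all lanes
share one housekeeper geomean exactly. `selected_housekeepers.txt` lists
the surviving reference set (here `HK012, HK020, HK033` — the three
candidates with the lowest stability M), and `grn_edges.tsv` ranks the
inferred regulatory links:

```
regulator  target    weight                rank
GENE0710   GENE0668  0.08255854269635417   1
GENE0222   GENE0178  0.0808980131085499    2
...
```

Weights are summed variance reductions, so ranks — not absolute values —
are the interpretable quantity. `heatmap_zmatrix.tsv` plus the `.nwk`
dendrograms contain the clustered z-score heatmap of the 100 most
variable genes; `manifest.json` records every parameter and seed so a
rerun is byte-identical.

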