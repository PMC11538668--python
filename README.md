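# zonatlas

Liver-lobule zonation analysis for Visium-style spatial transcriptomics.

Hepatocytes divide their metabolic labor along the portal–central (PN–CV)
axis of the liver lobule, a roughly hexagonal unit of 9–12 concentric cell
layers. `zonatlas` reconstructs that axis from spot-level expression alone
and classifies how each gene's expression is arranged along it — and how
that arrangement changes between nutritional states (ad-libitum control,
fasted, refed). It is aimed at anyone analyzing Space Ranger-style spatial
count bundles of zonated tissue who wants a tested, scriptable alternative
to ad-hoc notebook pipelines.

## What it computes

1. **Portal–central pseudotime.** Spots are clustered (PCA → k-NN → Leiden);
   erythroid-contaminated clusters (high globin fraction) are set aside; a
   diffusion map with per-spot adaptive bandwidth is built on the remaining
   spots, and pseudotime `t ∈ [0, 1]` is the diffusion-metric distance to a
   root spot in the most portal cluster, oriented with landmark markers
   (Alb/Cyp2f2 portal, Glul/Lgr5 central) so `t = 0` is periportal.
2. **Five-way zonation classification.** For each gene detected with more
   than 10 counts in at least 200 spots, three models are fitted by least
   squares to the 20-bin mean profile along `t`:
   a quadratic `a + bt + ct²`, a Gaussian peak `h·exp(−(t−μ)²/2σ²)`, and an
   inverted Gaussian `C − h·exp(−(t−μ)²/2σ²)`. The best model (AIC) is
   summarized by its **normalized range** `(max − min)/max`; genes below
   0.1 are *non-zonated*, the rest are labeled *periportal*, *pericentral*,
   *midzonal* or *bipolar* from the fitted curve's extrema.
3. **Pattern transitions.** 5×5 transition tables (with per-cell gene
   lists and Sankey-ready JSON) between conditions.
4. **Differential expression.** Two-sided Wilcoxon rank-sum per gene with
   Benjamini–Hochberg FDR; defaults `|log2FC| > 0.25`, `FDR < 0.05`.
5. **Per-spot ssGSEA.** Rank-based single-sample enrichment scores for
   user-supplied GMT gene sets, profiled along the axis.

A synthetic lobule simulator (`zonatlas.synthetic_data`) generates
hexagonal-lobule geometries, draws genes from the same five pattern
families with per-condition effects (including fasting-elevated
mitochondrial fraction, globin-rich erythroid spots, and lipogenic-style
portal→non-zonated switches after refeeding), and emits the ground truth
used throughout the test suite.

## Worked example

```python
from zonatlas import synthetic_data as syn, zonation as zo
from zonatlas.io_visium import merge_conditions
from zonatlas.pipeline import RunConfig, analyze_dataset

samples, truths = syn.simulate_study(seed=1)     # ctrl / fasted / refed
ds = merge_conditions(samples)
res = analyze_dataset(ds, RunConfig(outdir="unused", seed=0))

ctrl = res["labels"].query("condition == 'ctrl'").set_index("gene")
for gene in ["Alb", "Glul", "Scd1", "Fasn"]:
    row = ctrl.loc[gene]
    print(f"{gene:6s} {row['label']:12s} family={row['family']:9s} "
          f"normalized_range={row['normalized_range']:.2f}")
```

prints

```
Alb    periportal   family=poly2     normalized_range=0.41
Glul   pericentral  family=poly2     normalized_range=0.26
Scd1   midzonal     family=poly2     normalized_range=0.76
Fasn   periportal   family=poly2     normalized_range=0.50
```

— the portal albumin gradient, the pericentral glutamine-synthetase
gradient, a midzonal peak, and the lipogenic Fasn profile, each with its
zonation strength. Cross-tabulating control against refed labels:

```python
tt = zo.transition_table(
    zo.labels_as_series(res["labels"], "ctrl"),
    zo.labels_as_series(res["labels"], "refed"),
)
print(tt.matrix)
```

```
             periportal  pericentral  midzonal  bipolar  non_zonated
periportal          114            0         4        0           17
pericentral           0          102         0        0           14
midzonal              2            0        90        0           10
bipolar               0            0         0      105           18
non_zonated           0            0         0        3          113
```

Most genes keep their pattern; the off-diagonal mass into *non-zonated* is
dominated by the simulator's programmed refeeding switches (Fasn-like loss
of zonation).

## Command line

```sh
zonatlas simulate --seed 1 --out out/           # bundles + ground truth
zonatlas run --config full.yaml                 # full pipeline
zonatlas zonation --counts ctrl=out/bundle_ctrl --axis axis.tsv --out labels.tsv
```

`zonatlas run` validates a YAML config against a schema (every parameter
has a default), writes all artifacts as TSV/MTX/JSON, and echoes the fully
resolved configuration into `run_report.json`.

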