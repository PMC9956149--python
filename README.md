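# fusagg

Quantification of fluorescent protein aggregation in cultured cells, built
for experiments that ask how a genetic perturbation (here: wild-type vs
mistranslating serine tRNAs) changes the production, aggregation kinetics
and toxicity of an aggregation-prone reporter protein such as FUS-mCherry
and its ALS-linked R521C variant.

It is aimed at cell-biology labs doing live-cell imaging of aggregation
reporters who want the measurement side of such studies — focus counting,
kinetics, toxicity ratios, densitometry, tRNA-seq pool accounting — as
tested, scriptable code rather than a one-off macro.

## What it computes

**Aggregate detection and median-size-adjusted counting.** A frame's
fluorescent cell area is the set of 8-connected components above
`bg_mean + k_cell·bg_sd` (robust, truncation-corrected background
statistics). Aggregates are pixels inside the cell mask brighter than a
stringent threshold

    T = mean + k_sigma · SD        (k_sigma = 18 by default)

of the cell-mask pixel intensities of that frame. Counts are area ratios:
with median cell area Ã_c and median aggregate area Ã_a pooled over the
*entire experiment*,

    cell_count       = total_cell_area / Ã_c
    aggregate_count  = total_aggregate_area / Ã_a
    aggregates_per_cell = aggregate_count / cell_count

and per-cell fluorescence is the background-corrected integrated density
over the cell mask divided by `cell_count`. Counts are deliberately
fractional; touching cells merge components without corrupting areas.

**Kinetics.** Per-replicate time courses of these quantities, fold changes
between conditions at a query time (replicate means, linear
interpolation), plateau levels over a final window, and saw-tooth rupture
events (consecutive drops exceeding `min_drop`).

**Cytotoxicity.** Dye-exclusion ratio = pre-lysis (dead cells) /
post-lysis (total cells) fluorescence per well, normalized to a control
condition's mean.

**SDD-AGE densitometry.** Rolling-minimum baseline subtraction and the
aggregated fraction = lane area outside the monomer band / total lane
area, with an automatic Gaussian-fit monomer window.

**tRNA-seq accounting.** Pooling of multi-mapped identical gene copies,
total-count normalization, Welch-test differential abundance with 1.5×/2×
fold flags, and pool-fraction statistics (e.g. a mutant tRNA's share of
its isoacceptor pool, transfection-adjusted).

**Synthetic data.** `fusagg.imgsim` + `fusagg.presets` generate images,
time-lapses (with cell-rupture events), count tables, toxicity plates and
lane profiles with known injected effect sizes, so the whole pipeline is
testable without any downloads. See `docs/methods.md` for the model and
its limitations.

## Worked example

Recover the injected per-cell reporter-fluorescence shifts from synthetic
replicate fields (8 fields of 400 cells per condition; `none` = no extra
tRNA, `AGA` = wild-type tRNA, `AAA` = mistranslating variant):

```python
from fusagg import pipeline

res = pipeline.recover_fluorescence_ratios(seed=7, preset="fig1", n_replicates=8)
rec = res["recovered"]
for cond in ("none", "AGA", "AAA"):
    print(f"{cond:5s} recovered {rec[cond]:.3f}  injected {res['injected'][cond]:.2f}")
print(f"increase (AGA vs none): {100*(rec['AGA']-1):.1f}%")
print(f"decrease (AAA vs none): {100*(1-rec['AAA']):.1f}%")
```

prints

```
none  recovered 1.000  injected 1.00
AGA   recovered 1.328  injected 1.33
AAA   recovered 0.781  injected 0.78
increase (AGA vs none): 32.8%
decrease (AAA vs none): 21.9%
```

i.e. the segmentation/quantification pipeline recovers the injected +33% /
−22% per-cell fluorescence effects to within ~1%. The same pattern —
simulate with known truth, measure with the pipeline, compare — is
available for every preset (`fusagg.presets.list_presets()`).

The CLI wraps the same stages:

```
fusagg simulate --preset demo --seed 3 --out imgs/
fusagg quantify --images imgs/ --k-sigma 18 --out quant.csv --masks masks/
fusagg kinetics --quant quant.csv --min-drop 0.25 --out kin
fusagg run --preset fig4 --seed 1 --out out/    # end-to-end with summary.json
```

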