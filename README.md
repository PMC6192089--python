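# octlayers

Retinal layer segmentation and enface metrics from SD-OCT raster volumes,
with the statistics used to relate those metrics to visual acuity in
diabetic eyes — plus synthetic phantoms and cohorts so the whole pipeline
can be validated end to end without patient data.

## Who this is for

Researchers studying diabetic macular edema (DME) quantify how individual
retinal layers — not just total retinal thickness — relate to vision.
That requires (1) tracing the eight interfaces that bound the seven
layers (NFL, GCLIPL, INL, OPL, ONL, OSL, RPE) in every B-scan of a dense
macular raster, (2) turning the traces into enface thickness maps and
RPE-normalized reflectance images, (3) averaging them in the ETDRS
central subfield (the central 1-mm circle) while excluding regions where
an interface is visually indiscernible ("disrupted"), and (4) fitting
covariate-adjusted linear models of logMAR acuity on each metric.
`octlayers` implements each stage as an importable library with a thin
CLI on top.

## The method

**Segmentation.** Each interface in a B-scan is the minimum-weight
horizontal path through a graph whose nodes are pixels and whose edges
connect adjacent columns with a row change of at most one. With
normalized directional-gradient values g, the edge weight is
`2 − (g_a + g_b) + w_min`, so strong vertical edges of the correct
polarity are cheap to traverse. The optimum is found by an exact dynamic
programming sweep (equivalent to Dijkstra on this column-monotone
graph), with free endpoints and deterministic tie-breaking. The eight
interfaces are detected sequentially — strongest contrast first — each
restricted to the band of rows left between already-found neighbours.
Operator corrections re-run the same search in a narrow band around a
drawn line; operator-marked disruptions invalidate the affected A-scans.

**Enface metrics.** Layer thickness at enface position (b, x) is the
bounding-interface separation times the axial pixel size (3.9 µm);
layer reflectance is the mean intensity of the rows the layer occupies.
Metrics are means over the central subfield: six thickness metrics
(NFL_T … OSL_T, µm), six reflectance ratios (layer mean / RPE mean),
the central subfield thickness CST, and four percent-area disruption
metrics (NFL_d, INL_d, ONL_d, RPE_d), each the union of two interfaces'
disrupted areas. Disrupted pixels are never assigned values.

**Statistics.** DME is defined by CST > 320 µm (men) or > 304 µm
(women). Acuity models are OLS fits of logMAR on one metric plus age,
sex, race, diabetes type, diabetes duration and HbA1c, with the metric
coefficient reported per 10 µm (thickness) or per 0.1 (reflectance
ratio) and significance at the Bonferroni threshold 0.05/6 ≈ 0.008.
Acuity across disruption-severity bins (0%, <10%, ≥10%) is compared by
one-way ANOVA and Kruskal–Wallis. The power of a k-variable model to
detect a partial correlation r uses the Fisher-z approximation
Φ(atanh(r)·√(n − (k−1) − 3) − z₁₋α/₂) (plus the opposite tail), with a
simulation cross-check.

**Synthetic data.** `octlayers.synth` generates phantom volumes (flat
inner surface, cumulative layer thicknesses, Gaussian foveal pit
thinning the inner layers, per-layer reflectance levels, additive
Gaussian noise, hypo-reflective cysts that inflate their host layer, and
zero-contrast disruption zones) together with ground-truth interfaces,
and cohorts with realistic covariate distributions and a known linear
acuity structure — so segmentation accuracy, metric exactness and
regression recovery are all checkable against truth.

## Worked example

```bash
python examples/03_cohort_regression.py
```

```
INL_T coefficient: 0.065 logMAR per 10 um (true value 0.048)
95% CI: (0.040, 0.090); covers the truth: True
p = 1.5e-06
Bonferroni threshold 0.008: significant
n = 121 subjects (0 excluded for missing metric)
```

A synthetic no-DME-sized cohort (n = 121) is generated with a true
effect of 0.048 logMAR per 10 µm of INL thickening; the
covariate-adjusted model recovers an estimate whose 95% CI covers the
truth and is significant at the corrected threshold. The other examples
cover phantom segmentation accuracy (`01`), enface maps and subfield
metrics with cysts and disruptions (`02`), and power plus
disruption-severity group comparisons (`04`).

The same stages are scriptable from the shell:

```bash
octlayers simulate-volume --config examples/phantom.yaml --seed 1 --out run/sim
octlayers segment --volume run/sim/volume.tif --geometry run/sim/geometry.json --out run/seg
octlayers metrics --volume run/sim/volume.tif --geometry run/sim/geometry.json \
    --interfaces run/seg/interfaces.csv --out run/metrics
octlayers power --r 0.56 --n 28
```

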