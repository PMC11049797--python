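# beecolor

Objective, continuous-scale quantification of honey bee abdominal
coloration from images — for breeding programs, extension services and
researchers who currently grade yellow tergite marks by eye on coarse
ordinal scales.

Abdominal coloration is among the oldest characters used to tell honey bee
subspecies apart, but visual grading is subjective and categorical.
`beecolor` replaces the grade with a measurement: a photographed abdomen
(long axis along the image x-axis, rectangular ROI over one half of the
abdomen) is collapsed into a *coloration profile* and summarized by a single
*coloration index*, and the package ships the full downstream analysis for a
2 × 2 incubation experiment (colony origin gray/yellow × brood incubation
temperature 30/34 °C).

## Method

1. **Profile extraction.** Average the R, G, B channels into gray on the
   absolute sensor scale `v = mean(R,G,B) / (2^bits − 1)`; mask saturated
   pixels (`v > 0.95`) and desaturated pixels (`v == 0`); take the median of
   each pixel **column** (position along the abdomen); fill fully-masked
   columns by linear interpolation and resample every profile to a common
   length *L* (default 1998) over normalized position.
2. **Coloration index.** The trapezoidal area under the profile with unit
   spacing on the position axis,
   `CI = Σᵢ (vᵢ + vᵢ₊₁)/2 ≈ mean gray × (L − 1)`.
   Higher index = lighter abdomen.
3. **Classification harness.** Per colony of origin, a linear-kernel SVM
   predicts incubation temperature from the raw profiles or from a UMAP
   embedding (default 75 neighbours, 2 components), evaluated over repeated
   stratified 75/25 train/test splits (default 10 replicates) with
   precision, recall, F1 and ROC AUC reported as mean ± SD; a sweep covers
   neighbours {5, 10, 20, 50, 75, 99} × dimensions 2–10.
4. **Inference.** Shapiro–Wilk and variance-homogeneity checks, a Box–Cox
   transform when residual normality fails, two-way ANOVA
   (origin × temperature, Type II sums of squares) and Tukey HSD over all
   six group pairs.

A synthetic abdomen generator (`beecolor.synthetic_abdomen`) renders
gray-on-gray tergite-banded ROI images with configurable group effects and
known ground truth, so every stage is testable without original photographs.

## Worked example

```
beecolor simulate --out demo --n-per-group 4 --width 240 --height 40 --seed 7
beecolor run --images demo/images --roi demo/rois.csv --meta demo/meta.csv \
             --out demo/results --target-length 240 --umap-neighbors 4 \
             --replicates 2 --seed 5
```

`demo/results/summary.csv` then contains (this exact run):

```
group,n,mean,sd,min,max,se
30gray,4,51.70546291738452,0.6098042691635829,51.02184756747887,52.26308146689638,0.30490213458179144
30yellow,4,53.585207974403154,1.0225386673344303,52.301365985724836,54.763352202805805,0.5112693336672152
34gray,4,48.789326441873826,0.7912755117481348,47.9669866272869,49.63829682500615,0.3956377558740674
34yellow,4,51.675851177290994,3.024864706607278,48.003248830913115,54.43494134055296,1.512432353303639
```

— at profile length 240 a mean gray of ~0.21 gives indices near
0.21 × 239 ≈ 51, and the yellow-colony groups score ~1.9–2.9 units lighter
(the simulated origin effect plus sampling noise at n = 4).
`demo/results/report.json` holds the inference chain on these indices; in
this run no Box–Cox transform was needed and the ANOVA gives
p(origin) = 0.0146, p(temperature) = 0.0137, p(interaction) = 0.56.
At the study scale (L = 1998, n = 50/group) the same pipeline produces
indices in the 430–460 range with within-group SDs near 20.

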