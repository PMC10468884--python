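# speckleperf

Quantification of tissue perfusion from laser speckle contrast imaging
(LSCI), in **Relative Perfusion Units (RPU)**, together with a synthetic
dynamic-speckle scene generator that emulates three intraoperative porcine
bowel experiments: a progressively ischemic (partially devascularized)
bowel loop, progressive arterial/venous occlusion coupled to mean arterial
pressure (MAP), and a pair of side-to-side anastomoses.

It is aimed at researchers working on intraoperative perfusion imaging who
need a tested, reproducible reference implementation of relative perfusion
quantification — and a controllable phantom to validate it against, since
intraoperative raw video is rarely shareable.

## The method

LSCI maps blood flow through the blurring of coherent-light speckle: at
exposure time $T$ and speckle correlation time $\tau_c$ (shorter = faster
flow), the single-exposure speckle contrast $K = \sigma/\mu$ obeys

$$K^2(T, \tau_c) = \frac{\tau_c}{2T}\left[2 - \frac{\tau_c}{T}\left(1 - e^{-2T/\tau_c}\right)\right].$$

A raw flow index $F = 1/K^2$ is computed per pixel from a 7×7 sliding
window, temporally smoothed, and sampled over 317-pixel disk regions.
Because raw values vary with equipment and tissue, regions of interest are
normalized by manually chosen maximally ("Hot") and minimally ("Cold")
perfused reference regions:

$$\mathrm{RPU} = 100 \times \frac{\mathrm{ROI}^{raw} - \mathrm{Cold}^{raw}}{\mathrm{Hot}^{raw} - \mathrm{Cold}^{raw}}$$

RPU values are computed on single frames and averaged over 5
representative frames spread across one cardiac cycle. The ratio is
invariant to affine rescaling of the raw flow quantity, and is never
clipped (ROIs brighter than Hot legitimately read slightly above 100 %).

The synthetic generator inverts the contrast model so that the flow index
is affine in the ground-truth perfusion field (0–100 % scale), renders raw
speckle video (a fast gamma-approximation mode and a physically explicit
AR(1) complex-field mode), and the analysis layer reproduces the study
statistics: segment ANOVA, paired arc/anastomosis t-tests, two-piece
breakpoint detection of the perfusion decline onset, and OLS regression of
mean RPU on MAP.

## Worked example

```python
import speckleperf as sp

res = sp.run_gradient_experiment(seed=1, n_frames=64)
for name, (mean, sd, n) in res.summary.per_segment.items():
    print(f"{name:10s} {mean:6.1f} +/- {sd:4.1f} RPU  (n={n})")
print(f"ANOVA across segments: p = {res.summary.anova.p_value:.2e}")
mes, anti = res.arc_comparison.group_means
print(f"mesenteric vs antimesenteric (perfused+watershed): "
      f"{mes:.1f} vs {anti:.1f} RPU, paired p = {res.arc_comparison.p_value:.2e}")
print(f"decline onset: {res.onset_cm:.1f} cm from the stapled edge")
```

prints

```
ischemic      2.3 +/-  1.4 RPU  (n=5)
watershed    81.3 +/- 13.8 RPU  (n=5)
perfused    100.9 +/-  1.5 RPU  (n=5)
ANOVA across segments: p = 4.51e-10
mesenteric vs antimesenteric (perfused+watershed): 92.0 vs 76.8 RPU, paired p = 1.06e-07
decline onset: 5.0 cm from the stapled edge
```

i.e. the full render → contrast → RPU chain recovers the three calibrated
perfusion segments of the devascularized loop (ischemic near 0 %,
watershed intermediate with a large spread across the slope, perfused near
100 %), separates them decisively, measures the mesenteric border as
better perfused than the antimesenteric, and locates the onset of the
sharp perfusion decline at 5 cm from the stapled edge — 1 cm proximal to
the 4 cm devascularization margin.

The same chain is available from the shell:

```sh
speckleperf scene gradient --seed 1 --out out/scene
speckleperf render --scene out/scene --frames 32 --seed 1 --out out/stack.tif
speckleperf contrast --stack out/stack.tif --out out/flow.tif
speckleperf run gradient --seed 1 --out out/report
```

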