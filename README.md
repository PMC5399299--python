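# oscillaquant

Quantitative image analysis for pulsatile actomyosin contractility in
epithelia. The package measures, from fluorescence time-lapse microscopy
of *Drosophila* follicle cells (and cultured cells):

- **basal oscillations** — per-cell intensity traces of MyoII / ROCK /
  F-actin reporters, photobleach correction, oscillation amplitude,
  per-cycle mean intensity, and the cycle **period** by two methods
  (adjacent-peak intervals and autocorrelation), including an explicit
  "period not prominent" verdict for arrhythmic cells;
- **Rho biosensor FRET** — ratiometric CFP/YFP processing (background
  subtraction, channel registration, smoothing, acceptor masking,
  per-pixel ratio maps) and the region statistics built on it:
  junction/medio-basal ratio and DV/AP junctional polarity;
- **optogenetic clusters** — detection of LARIAT-induced puncta by the
  published intensity / size / circularity criteria, clustered area per
  cell, and cluster time courses after whole-image bleaching
  compensation;
- **tissue morphometry** — egg-chamber rotation speed by nuclear
  tracking, AP/DV elongation ratio, linescan intensity profiles, and
  junctional vs medial signal partitions.

Because raw microscopy for these assays is rarely shareable, the package
ships a first-class **synthetic data generator** (`oscillaquant.synth`)
that produces movies, images and traces with recorded ground truth —
every analysis stage has a parameter-recovery test against data whose
true period, ratio field, cluster geometry, drift speed or axis ratio is
known exactly.

## The quantities

For a per-cell intensity trace $I(t)$ sampled every $\Delta t$ (30 s in
the reference protocol), photobleaching is modeled as a mono-exponential
decay $I(t) = I_0(t)\,e^{-t/\tau}$ and divided out after fitting
$\tau$. The oscillation period is estimated from the normalized
autocorrelation

$$\rho(k) = \operatorname{corr}\big(I_{1..n-k},\; I_{k+1..n}\big),$$

as the lag $k^\*\Delta t$ of the first local maximum of $\rho$ after its
first zero crossing (which avoids harmonics at $2\times,3\times$ the
period). The value $\rho(k^\*)$ is the **detectability score**; if it
falls below a threshold (default 0.2) or below a white-noise
significance bound, the period is reported as `NOT_PROMINENT` rather
than as a number — the analogue of the "∞" annotation used for
arrhythmic genotypes.

FRET activity is the per-pixel acceptor/donor ratio (channel II /
channel I) on valid pixels only; each cell is split into a junctional
band (default 1.5 μm from the boundary, via the distance transform) and
a medial interior, and band pixels are labeled DV- or AP-oriented by the
local boundary tangent. Clusters are 8-connected components inside an
intensity window, kept iff area > 0.2 μm² and circularity
$4\pi A/P^2$ (Crofton perimeter) lies in the preset window
(HeLa 0.5–1.0 at 2,500–4,095 AU; follicle 0.35–1.0 at 1,200–4,095 AU,
12-bit data). Rotation speed is the mean per-nucleus path length per
minute from greedy mutual-nearest-neighbour tracking; elongation is the
AP/DV caliper-length ratio of the tissue mask.

## Worked example

```sh
python examples/oscillation_period.py
```

```
true period:            180 s
peak-interval estimate: 165 s (10 intervals, sd 43 s)
autocorrelation:        180 s (detectability 0.58, 9 cycles)
per-cycle mean intensity: 766 AFU
```

A noisy, bleaching cell (true period 180 s, noise 30% of the oscillation
amplitude, bleaching τ = 900 s) is corrected and analysed: the
autocorrelation recovers the period exactly (one-frame resolution),
while raw peak intervals scatter (sd 43 s) — the reason the
autocorrelation method is preferred for irregular, low-amplitude
signals. The per-cycle mean (766 AFU ≈ baseline + half amplitude) is the
"one cycle = one sample" quantity used for between-genotype comparisons.

The other examples cover the remaining capabilities and print the
ground truth next to each estimate:

```sh
python examples/fret_ratios.py            # shift (+3.00,-2.00) px; ratio 1.529 vs truth 1.5
python examples/cluster_quantification.py # preset-by-preset filter verdicts
python examples/rotation_and_elongation.py# 0.500 um/min vs 0.5; AP/DV 2.49 vs 2.49
```

A thin CLI wraps the same functions (`oscillaquant synth|trace|fret|clusters|morph|run`);
run `oscillaquant --help` for the subcommands.

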