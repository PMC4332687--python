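# lascakit

Spatial-domain laser speckle contrast analysis (LASCA) for detecting and
quantifying dental-enamel erosion, with a synthetic coherent-speckle phantom
generator that makes the whole pipeline testable without laboratory images.

## The problem and the method

Dental erosion is acid-driven, bacteria-free loss of tooth mineral.
Demineralization changes the enamel surface microstructure — more scattering
centers, lower backscattering — which changes how coherent light speckles off
the surface. When a tooth sample is photographed under laser illumination,
the granular speckle pattern therefore encodes the state of the surface.

`lascakit` quantifies this with block-wise speckle statistics. The image is
partitioned into non-overlapping n×n windows (default n = 4) and each window
gets the local speckle contrast

    C_ij = σ_ij / ⟨I⟩_ij

the ratio of the sample standard deviation (n−1 denominator) to the mean of
the pixel intensities in the block. For ideal fully developed polarized
speckle, intensities follow the negative-exponential law
P(I) = exp(−I/⟨I⟩)/⟨I⟩ and C is bounded by 1. A 700×700 trimmed photograph
with n = 4 yields a 175×175 contrast map.

Eroded enamel shows a *higher* local contrast and a *lower* mean intensity
than sound enamel. Given a sound region and a lesion region on one sample,
the per-sample biomarker is the contrast ratio

    CR = 1 − ⟨C_sound⟩ / ⟨C_lesion⟩

computed over the centrally illuminated part of the map. CR is 0 for
indistinguishable regions and grows with erosion severity; it is reported
signed, so a reversed contrast shows up as a negative value instead of being
hidden.

Group-level analysis (several samples per acid-etching duration) uses the
parametric battery: a Shapiro–Wilk normality gate, one-sample t-tests of each
group's CRs against the 0% reference, one-way ANOVA with Tukey HSD post-hoc
across groups, and a Pearson correlation of etching duration against group
mean CR.

Because no laboratory images are deposited anywhere, the package ships a
phantom generator: fully developed speckle is synthesized by low-pass
filtering a complex circular-Gaussian random field in the frequency domain;
averaging N independent patterns lowers the contrast to 1/√N, so a
two-region phantom with (N_sound, N_lesion) pattern sums has the analytic
contrast ratio 1 − √(N_lesion/N_sound) — a ground truth the pipeline can be
checked against.

## Worked example

Simulate a 4-group phantom experiment (3 phantoms per group, 320×320 px),
analyze it, and print the statistical report:

```sh
lascakit simulate --out demo/sim --seed 42 --samples-per-group 3 --size 320
lascakit analyze --manifest demo/sim/manifest.csv --out demo/results
lascakit report --results demo/results
```

```
Group-level analysis (alpha = 0.05)

 duration   n   mean CR     sd CR     SW p  p vs ref
       10   3    0.1690    0.0084   0.2177 0.0008301
       20   3    0.2200    0.0086   0.1201 0.0005042
       30   3    0.3854    0.0040   0.9748 3.661e-05
       40   3    0.4388    0.0018   0.8934 5.648e-06

ANOVA: F(3, 8) = 1220.5426, p = 5.554e-11
Tukey HSD adjusted p:
  10 min vs 20 min: p = 4.804e-05
  ...
  30 min vs 40 min: p = 3.365e-05

Pearson duration vs group mean CR: r = 0.9741, p = 0.0259
```

The four groups are built with pattern-sum pairs (N_sound, N_lesion) =
(3,2), (5,3), (8,3), (16,5), whose analytic contrast ratios are 0.183,
0.225, 0.388 and 0.441: the measured group means recover them to ~0.01,
every group differs from the 0% reference, and the group means correlate
with etching duration. `demo/results/` also contains per-sample
measurements (`samples.csv`), exported contrast maps (`maps/*.csv`),
false-color renderings (`maps/*.png`) and a run log of every effective
parameter.

The same analysis runs on real photographs: write a manifest CSV listing
each image with its sound/lesion rectangles and duration group (see
`lascakit.pipeline.write_manifest`), then `lascakit analyze`.

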