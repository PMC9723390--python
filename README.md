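# osteonlo

Quantitative analysis of multimodal nonlinear-optical (NLO) bone
microscopy: co-registered bright-field, two-photon fluorescence (TPEF),
second-harmonic generation (SHG) and stimulated Raman scattering (SRS)
images of vertebra sections.  Intended for researchers comparing bone
phenotypes (e.g. wild-type vs knock-out mouse models of bone loss) from
label-free imaging.

The package computes, per sample:

* **Collagen content** — average raw SHG pixel intensity over
  cortical/trabecular ROIs (SHG scales linearly with collagen density);
* **Collagen fiber directionality** — pixel-wise orientation
  Θ = atan2(G_y, G_x) + 90° from Sobel cross-correlations, binned into a 1°
  percentage histogram over [0°, 180°) and fitted with a
  baseline-plus-Gaussian model

      f(θ) = B + A·exp(−((θ − θ0)/(2σ))²)

  summarized by the alignment ratio AR = 100·A_G/(A_G + A_B), where A_G is
  the area under the Gaussian term and A_B = 180°·B the baseline area
  (AR → 0 for randomly oriented fibers, → 100 for perfect alignment);
* **Bone composition** — bone/marrow mean-intensity ratios of the SRS
  lipid (2850 cm⁻¹) and protein (2920 cm⁻¹) channels;
* **Group statistics** — Mann–Whitney U (exact enumeration for small
  samples, ties mid-ranked) or two-sample t tests, mean ± SEM, significance
  at a configurable α (default 0.1).

Because raw data for this kind of study are typically not deposited, a
synthetic vertebra-scene generator (`osteonlo.synthetic_scene`) renders
multichannel scenes with known ground truth — fibre orientations drawn from
a wrapped-Gaussian/uniform mixture, SHG amplitudes modulated by the cos⁴
polarization response, SRS channels with prescribed bone:marrow ratios —
so the whole chain is testable end to end.  See `docs/methods.md` for the
model details and conventions.

## Worked example

Generate two synthetic genotype groups (3 vertebrae each) that differ in
lipid content and fiber alignment, run the full pipeline, and compare:

```sh
cat > example.yaml << 'EOF'
n: 3
wt:
  srs_bone_marrow_ratio_lipid: 1.3
  aligned_fraction: 0.8
ko:
  srs_bone_marrow_ratio_lipid: 1.8
  aligned_fraction: 0.5
EOF
osteonlo all --config example.yaml --out demo --seed 1
```

prints

```
shg_bone_mean_parallel: WT 61.76 vs KO 60.33, p=0.1
shg_bone_mean_perpendicular: WT 54.69 vs KO 55.52, p=0.1
bone_marrow_ratio_SRS_2850: WT 1.3 vs KO 1.8, p=0.1
bone_marrow_ratio_SRS_2920: WT 1.3 vs KO 1.3, p=0.7
```

The measured lipid bone/marrow ratios reproduce the generating values (1.3
vs 1.8) and the protein channel, generated identically for both groups,
shows no difference.  With n = 3 per group the smallest achievable exact
two-sided Mann–Whitney p is 0.1 (2 of the 20 rank splits), which is why a
fully separated comparison reports p=0.1.  `demo/` receives the CSV report
bundle; the orientation-model summary (`fit_summary_parallel.csv`) for this
run reads

```
genotype  roi_class    A  theta0  sigma    B  alignment_ratio
      KO   cortical 0.40   91.08  20.70 0.40            28.63
      KO trabecular 0.55   91.85  19.89 0.34            38.51
      WT   cortical 0.59   89.52  20.37 0.32            42.25
      WT trabecular 0.72   90.83  17.52 0.31            44.46
```

Both groups peak at θ0 ≈ 90° (fibres run craniocaudally), and the
less-aligned KO group shows the expected lower amplitude/higher baseline in
the cortical compartment, i.e. a smaller alignment ratio.

The same analysis runs on acquired data via
`osteonlo analyze --stack stack.tif --labels labels.tif --out report`
(multipage TIFF stacks plus an 8-bit tissue label map), and the library
API (`make_scene`, `sobel_gradients`, `fibre_angle_map`,
`orientation_histogram`, `fit_orientation_model`, `bone_marrow_ratio`,
`compare_groups`, `run_pipeline`) exposes every stage individually.

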