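# dentmorph

Geometric-morphometric attribution of hominin deciduous molar crowns, with
lateral enamel-thickness indices and radiocarbon calibration.

When an isolated tooth is the only human fossil in a Paleolithic layer, its
taxonomic identity (Neanderthal vs *Homo sapiens*) is usually decided from the
shape of the crown outline seen occlusally, compared against reference samples
of known attribution.  `dentmorph` implements that workflow end to end for
lower second deciduous molars (dm2) and makes every stage testable on
synthetic data with known ground truth:

1. **Orientation** — the best-fit (total least squares) plane of the digitized
   cervical line becomes z = 0, the mesiodistal fissure runs along x, buccal
   faces +y; right-side crowns are mirrored into the left convention.
2. **Outline → landmarks** — the crown silhouette is projected onto the
   cervical plane and reduced to 16 pseudo-landmarks where equiangular rays
   from the area centroid meet the outline (first ray buccal, along +y), then
   scaled to unit centroid size CS = √Σ‖xᵢ − x̄‖².
3. **Shape space** — PCA of the flattened configurations; per-PC Shapiro–Wilk
   and Fligner–Killeen screens; pairwise PERMANOVA (Anderson's pseudo-F,
   permutation p-values, Bonferroni) on all n−1 coordinates, with merging of
   statistically indistinguishable reference groups.
4. **Attribution** — flexible discriminant analysis (FDA: MARS basis + LDA +
   logistic posterior calibration), multivariate adaptive regression splines
   (MARS, implemented in-package with GCV pruning) and a random forest, each
   validated by repeated stratified 10-fold cross-validation and reporting
   per-class posterior probabilities for the target specimens.
5. **Side analyses** — lateral enamel metrics between the cervical plane and
   the cutting plane through the lowest EDJ point of the mid-occlusal basin
   (Ve, LDPV, SEDJ, LAET = Ve/SEDJ, LRET = LAET/LDPV^⅓), and radiocarbon
   calibration against an IntCal-format curve with 68.27 %/95.45 % highest
   posterior density ranges.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Generate a synthetic two-group population (Neanderthal-like bucco-distal
enlargement vs modern-human-like narrowing, 31 outlines per group), landmark
it, and run the full attribution pipeline:

```bash
dentmorph simulate --out demo_pop.csv --n-per-group 31,31 --seed 7
dentmorph landmarks demo_pop.csv demo_landmarks.csv
dentmorph run-all --out demo_out
```

which prints

```
FDA: CV accuracy 0.860
MARS: CV accuracy 0.877
RF: CV accuracy 0.887
target_N: FDA->N, MARS->N, RF->N
target_MH: FDA->MH, MARS->MH, RF->MH
```

The CV accuracies sit just below the generator's Bayes accuracy of
Φ(2.5/2) ≈ 0.894 for this separation — the pipeline loses almost none of the
information the generative model provides — and both noise-free group-mean
target crowns are attributed to their true group by all three classifiers.
`demo_out/report.json` holds the PCA spectrum, PERMANOVA table, screens, CV
reports, posteriors and a provenance block (config hash + seeds); re-running
with the same config reproduces it byte for byte.

The enamel phantom and a synthetic identity calibration curve exercise the
side analyses:

```bash
dentmorph voxel-phantom phantom.tiff --voxel-size 0.1
dentmorph enamel phantom.tiff
# z_cut=4.000 mm
# Ve_mm3=61.9200      (analytic: pi*4*(3^2-2^2) = 62.83)
# SEDJ_mm2=49.7371    (analytic: 2*pi*2*4 = 50.27)
# LAET_mm=1.2449      (analytic: (R^2-r^2)/(2r) = 1.25)
# LRET=0.3367
dentmorph calibrate identity.14c 40000 100
# sample  68.27%  40100–39900 cal BP
# sample  95.45%  40200–39800 cal BP
```

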