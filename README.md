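# nodulesig

Exemplar-based CT characterization of lung adenocarcinoma (ADC) nodules,
with a complete inter-observer agreement toolkit, exercised entirely on
synthetic phantoms.

## The problem

Lung ADC spans a spectrum from indolent lepidic growth (ground-glass
opacity on CT) to frankly invasive, solid tumors. An exemplar-based voxel
classifier can turn a segmented nodule into a *parametric signature* — the
fraction of its voxels falling into each of nine attenuation/texture
classes — and the summed burden of the most solid classes into a
Good/Intermediate/Poor risk characterization. Because the segmentation step
is semi-automatic (seeded region growing plus manual border edits), the
clinically crucial question is how much the characterization changes when
different observers segment the same nodule. This package implements the
full pipeline *and* the statistical battery used to answer that question,
on synthetic data, so every stage is reproducible and testable without any
patient scans. It is aimed at researchers in quantitative imaging who want
a transparent, auditable reference implementation of this class of method.

## The method

1. **Phantoms** — spherical nodules (solid core + ground-glass shell,
   spanning pure GGO to fully solid), optional abutting vessels and chest
   wall, Gaussian noise; plus simulated observers that displace the true
   border with a smooth random field of standard deviation `boundary_sd` mm.
2. **Segmentation** — seeded region growing (dual HU thresholds, VOI box)
   with scripted eraser-sphere / exclusion-plane edits; sessions replay
   exactly.
3. **Exemplar model** — 774 VOIs of 9×9 voxels sampled from a training
   cohort; 16-bin HU histogram + first-order features; similarity
   s(i,k) = −‖f_i − f_k‖² on standardized features; affinity propagation
   (damped responsibility/availability message passing, implemented here)
   with the diagonal *preference* bisected until exactly nine exemplars
   emerge; classes labeled V, I, B, G, Y, O, R, C, P along the attenuation
   spectrum, with VIRO = {V, I, R, O} the invasion-associated group.
4. **Classification** — every mask voxel with its 80 surrounding in-plane
   voxels is assigned the nearest exemplar's class; the class-fraction
   vector is the signature; risk = Poor if VIRO ≥ 0.45, Good if < 0.10,
   else Intermediate (explicit, configurable cut-points).
5. **Agreement statistics** — per-class two-way random-effects variance
   decomposition; ICC(2,1) = σ²_nodule / (σ²_nodule + σ²_observer +
   σ²_residual) with McGraw–Wong 95% CIs; pairwise Dice 2|A∩B|/(|A|+|B|);
   Fleiss kappa on risk categories; tie-corrected Kruskal–Wallis.

See `docs/methods.md` for assumptions, parameter defaults, numerical
conventions and limitations.

## Worked example

```python
import nodulesig as ns

cohort, manifest = ns.generate_cohort(30, seed=1)
model = ns.train_exemplar_model(cohort, n_vois=774, target_k=9, seed=2)

observers = [ns.ObserverJitter(boundary_sd=0.5, vessel_inclusion_prob=0.2,
                               rng_seed=s) for s in (11, 22, 33)]
report = ns.observer_study(cohort, model, observers)

panel = report.icc_panel.set_index("voxel_class")
print(f"class-average ICC : {panel.loc['Avg.','icc']:.3f}")
print(f"VIRO ICC          : {panel.loc['VIRO','icc']:.3f}")
print(f"mean pairwise DSC : {report.dsc_summary.mean:.3f}")
print(f"Fleiss kappa      : {report.kappa.kappa:.3f} -> {report.kappa.interpretation}")
```

Output:

```
class-average ICC : 0.997
VIRO ICC          : 0.999
mean pairwise DSC : 0.972
Fleiss kappa      : 1.000 -> almost perfect agreement
```

Thirty phantoms, segmented by three simulated observers with half-millimetre
boundary jitter, yield class-fraction ICCs near 1 (observer variance is a
tiny share of total variance), strong mask overlap (Dice well above the 0.7
strong-overlap convention) and essentially perfect agreement on the
three-level risk call — the behavior expected of the method when observer
edits are small relative to nodule heterogeneity. The trained model's class
labels order by exemplar mean HU (here G at −698 HU up to R at −20 HU),
so VIRO fractions track solid content.

A command-line interface mirrors the library:

```bash
nodulesig simulate --n 30 --seed 1 --out-dir cohort/
nodulesig segment  --volume cohort/phantom_000.nii.gz --seed 20,28,28 --out seg.nii.gz
nodulesig train    --cohort-dir cohort/ --n-vois 774 --k 9 --seed 2 --out model.json
nodulesig classify --volume cohort/phantom_000.nii.gz --mask cohort/mask_000.nii.gz \
                   --model model.json --out signature.csv
nodulesig agree    --signatures signatures.csv --out report/
```

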