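# gutmorph

Volume-EM morphometrics of secretory-vesicle polarity in epithelial cells.

In serial block-face scanning EM (SBEM) reconstructions of the sea-urchin
larval midgut, acinar-like (exocrine-pancreas-like) cells stand out from
ordinary stomach cells by two quantitative traits: they carry **at least
3× more** small (~300 nm) electron-lucent secretory vesicles than a
typical main-stomach cell, and those vesicles are **apically polarized** —
more than 75% lie between the base of the nucleus and the apical
membrane, whereas putative differentiating cells are vesicle-rich but
weakly polarized (<50% apical). `gutmorph` implements that quantification
as a reusable, tested pipeline over 3D label volumes:

* **per-cell vesicle census** from instance label grids, with physical
  volumes and equivalent spherical diameters under anisotropic voxel
  spacing (default 50 × 15 × 15 nm, axis order slice/row/column);
* **apico-basal polarity scoring**: per-cell axis estimation from
  lumen/background contacts, the nucleus-base boundary, and the apical
  fraction of secretory vesicles;
* **rule-based phenotype calls** (exocrine-like / differentiating /
  indeterminate / stomach) from the count-ratio and apical-fraction
  criteria;
* a **threshold + magic-wand segmentation** stage so the pipeline can run
  from grayscale intensities, not only from curated labels;
* a seeded **synthetic scene generator** (a polarized columnar monolayer
  around a lumen with planted phenotypes and known ground truth) so the
  whole pipeline is testable end-to-end without any data download.

## The statistics

For a cell with secretory-vesicle centroids $p_1,\dots,p_n$, apico-basal
unit axis $\hat u$ (basal → apical, anchored at the basal surface) and
nucleus-base coordinate $b$ (the apical-most extent of the nucleus along
$\hat u$), the apical fraction is

$$f = \frac{1}{n}\,\#\{i : \langle p_i - a_\text{basal}, \hat u\rangle > b\},$$

and an object's equivalent spherical diameter is $d = (6V/\pi)^{1/3}$
with $V$ = voxel count × voxel volume. A cell is called **exocrine-like**
when its count $c \ge 3\,c_\text{baseline}$ and $f > 0.75$,
**differentiating** when $c \ge 3\,c_\text{baseline}$ and $f < 0.50$,
**indeterminate** in the gap, and **stomach** otherwise.

## Worked example

```python
import gutmorph

result = gutmorph.run_pipeline(seed=0)   # default 20-cell scene
print(result.calls["call"].value_counts().to_dict())
print(result.summary.per_phenotype.round(3))
print(round(result.summary.count_ratio_exocrine_vs_stomach, 2))
```

prints

```
{'stomach': 11, 'exocrine': 7, 'differentiating': 2}
                    n  count_mean  count_sd  apical_mean  apical_sd
call
exocrine          7.0     100.857     8.533        0.890      0.023
differentiating   2.0     100.000    11.314        0.416      0.012
indeterminate     NaN         NaN       NaN          NaN        NaN
stomach          11.0      23.545     4.741        0.477      0.112
4.28
```

i.e. the pipeline recovers exactly the planted population — 7
exocrine-like cells averaging 89% apical vesicles, 2 differentiating
cells at 42%, and an exocrine/stomach mean-count ratio of 4.3 (≥ 3) —
from the label grids alone.

The same stages are available from the shell:

```bash
gutmorph simulate --render --seed 0 --out scene/
gutmorph segment  --in scene/render.tif --mask scene/cells.tif \
                  --low 200 --high 255 --min-size 8 --out pred.tif
gutmorph measure  --cells scene/cells.tif --vesicles scene/vesicles.tif --out objects.csv
gutmorph polarity --cells scene/cells.tif --nuclei scene/nuclei.tif \
                  --lumen scene/lumen.tif --objects objects.csv --out polarity.csv
gutmorph classify --polarity polarity.csv --out calls.csv
gutmorph report   --calls calls.csv --truth scene/ground_truth_cells.csv --out report.csv
gutmorph run      --config pipeline.yaml --out run/
```

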