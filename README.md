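# ttcquant

Semi-automated quantification of ischemic infarct size in photographs of
TTC-stained rodent brain sections.

TTC staining colors viable brain tissue deep red while infarcted tissue
stays pale, and sections are photographed on a dark plate. `ttcquant`
segments such a photograph in two supervised stages:

1. **Infarct extraction** — brightness binarization: pixels whose channel
   mean exceeds a brightness threshold (`t_infarct`) are infarct.
2. **Normal-tissue extraction** — pixels whose red channel exceeds a
   red-channel threshold (`t_red`), whose hue lies inside a "digital red
   filter" band `[-60·F, +60·F]` degrees (`f_hue` = F ∈ [0, 0.2]), and that
   were not already assigned to the infarct, are normal tissue. Achromatic
   pixels have no hue and never pass the filter, which rejects gray and
   off-red impurities.

The infarct ratio is reported as `100 · n_infarct / (n_infarct + n_normal)`
— a percentage of the whole section; background pixels never enter the
denominator. Thresholds are user-supervised: pick them by inspecting a
parameter sweep (`ttcquant sweep`), optionally starting from an automatic
Otsu-based suggestion (`--suggest`, a non-canonical convenience).

Because no public image dataset exists for this task, the package ships a
seeded synthetic fixture generator (dark plate, deep-red elliptical section,
pale infarct region, optional impurity blobs) with exact pixel-level ground
truth, plus the method-comparison statistics (paired t, Pearson R, OLS,
Kolmogorov–Smirnov normality check, variance F-test) used to validate the
method against a reference measurement.

## CLI

```sh
# analyze one section (half-open ROI; thresholds in [0,255], F in [0,0.2])
ttcquant analyze photo.png --roi 40 30 520 400 \
    --t-infarct 150 --t-red 90 --f-hue 0.2 --out results/
# -> prints "ratio_percent=..." and writes result.csv, infarct_mask.png,
#    normal_mask.png, overlay.png

# supervise a threshold: one CSV row + overlay PNG per value
ttcquant sweep photo.png --t-infarct 150 --t-red 90 \
    --parameter t_infarct --values 120,140,160,180 --out sweep/

# batch a manifest CSV (columns: section_id,image,x0,y0,x1,y1,
# t_infarct,t_red,f_hue); --average means ratios across rows sharing a
# section_id (two-analyst averaging)
ttcquant batch manifest.csv --out study.csv --average

# generate a seeded synthetic study with ground-truth manifest
ttcquant synth --n-animals 11 --fraction-range 10 50 --noise-sd 5 \
    --seed 1 --out fixtures/

# compare two result tables sharing section labels
ttcquant compare study_a.csv study_b.csv --out report/
```

Library use mirrors the CLI:

```python
from ttcquant import ROI, ThresholdConfig, analyze_section, load_image

image = load_image("photo.png")
result = analyze_section(image, ROI(40, 30, 520, 400),
                         ThresholdConfig(t_infarct=150, t_red=90, f_hue=0.2))
print(result.ratio_percent)
```

## Conventions

- Images are `(height, width, 3)` uint8 arrays; ROIs are 0-based, `(x, y) =
  (column, row)`, half-open.
- Hue is standard HSV hue recentred to signed degrees `(-180, +180]` with
  pure red at 0; `r = g = b` pixels have undefined hue.
- Strict inequality at both thresholds; ties are excluded.
- The variance check labeled "F-test" is Fisher's F-test of variance
  equality (two-tailed). The KS normality p-value uses the asymptotic
  distribution with fitted mean/SD and is approximate.
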