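# vesica

Automatic bladder-volume measurement from biplane ultrasound, built for
point-of-care scanners with tight compute budgets.  The package provides
the complete chain a portable bladder scanner needs:

1. a **lightweight multitask CNN** (< 1 M trainable parameters) that
   classifies each plane as bladder / no-bladder and segments the bladder
   region, built around a truncated single-channel MobileNetV2 encoder and
   a *quantizable squeeze-and-excitation* (QSE) decoder that contains no
   activation×activation products, so it survives 8-bit fixed-point
   deployment;
2. a **staged training procedure** (segmentation path first, then the
   classification head on the frozen backbone, then a weight merge), with
   a Dice + cross-entropy combo loss, augmentation, early stopping,
   quantization-aware training and int8 post-quantization;
3. a **geometric volume estimator**: on the sagittal plane the bladder
   depth is the longer diagonal chord of the minimum-area rotated bounding
   box; on the transverse plane height and width are the maximum vertical
   and horizontal mask extents; the volume is

   ```
   Volume ≈ c · Depth · Height · Width      (axes in cm → volume in mL)
   ```

   with shape coefficient `c` (0.52 sphere, 0.66 triangular prism,
   0.72 unknown, 0.81 cylinder, 0.89 cuboid).  Measurements are gated by
   the classifier: if either plane is judged bladder-free, no volume is
   reported.
4. a **synthetic biplane phantom simulator** — ellipsoidal bladders with
   exact ground truth rendered as log-compressed exponential speckle with
   an anechoic lumen — so the whole pipeline is trainable and testable
   without any data download.

The intended audience is engineers and researchers prototyping
image-based PVR (post-void residual) measurement on embedded hardware;
everything runs on plain numpy/scipy/scikit-image, with the CNN and its
training loop implemented in a small self-contained layer library.

## Worked example

Measure a simulated 50 mL spherical phantom from its ground-truth masks
(the geometry-only oracle route, `model=None`):

```python
from vesica import phantom_sim as ps
from vesica.measure import auto_measure

phantom = ps.sample_phantom(50.0, eccentricity_range=(1.0, 1.0), rng_seed=0, max_tilt=0.0)
sample = ps.render_biplane(phantom, ps.ImagingConfig(seed=7))
est = auto_measure(sample, model=None, shape_label="spherical")
print(phantom.volume_mL, est.axes, est.volume)
```

prints

```
true volume :  50.00 mL (sphere radius 22.85 mm)
axes        : depth 45.7 mm, height 45.8 mm, width 45.5 mm
estimate    :  49.54 mL  (c = 0.52, detected = (True, True))
error       : -0.93 %
```

The three axes recover the sphere's 45.7 mm diameter to within a pixel,
and the 0.52 coefficient's intrinsic −0.69 % bias (0.52 vs π/6 ≈ 0.5236)
accounts for most of the remaining error.

The same flow with a trained network replaces `model=None` with a float
or quantized model.  From the shell, the five pipeline stages are:

```bash
vesica simulate --n-pos 128 --n-neg 128 --seed 0 --out data/
vesica train    --data data/ --out models/ --train-size 96 --deploy-size 192
vesica quantize --model models/model_float.npz --data data/ --out models/model_int8.npz
vesica measure  --sagittal s.png --transverse t.png --spacing-mm 0.35 \
                --shape unknown --model models/model_int8.npz --out report.json
vesica evaluate --data data/ --model models/model_int8.npz --out eval.json
```

`measure` writes a JSON report with `detected_sagittal`,
`detected_transverse`, `depth_mm`, `height_mm`, `width_mm`,
`coefficient`, `shape_label` and `volume_mL` (null when detection fails
on either plane).

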