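# aorpe — speckle-obscured RPE cell recovery for AO-OCT en face imaging

Adaptive-optics OCT can resolve individual retinal pigment epithelium (RPE)
cells, but a single en face acquisition is dominated by coherent speckle:
interference between light scattered from many points inside each cell
multiplies the tissue reflectance by an exponential random field of unit
contrast, hiding the cell mosaic completely.  The classical workaround —
acquire ~120 volumes at ~5 s intervals so the speckle decorrelates, register
them, and average — takes so long per location that wide-field cellular RPE
maps are impractical in the clinic.

`aorpe` implements the alternative: a **parallel-discriminator GAN (P-GAN)**
that learns the mapping from one speckled acquisition to the averaged-image
appearance, together with everything needed to develop and evaluate it without
access to patient data:

* **`aorpe.sim`** — synthetic acquisition physics: quasi-hexagonal cell
  mosaics (dark centers, bright surrounds), fully developed speckle
  (circular complex Gaussian field, PSF-filtered, squared; `n_looks`
  incoherent looks give contrast `1/√M`), and eye motion as a per-row
  random walk with saccadic jumps, applied raster-row by raster-row.
* **`aorpe.acquire`** — ground-truth construction: two-pass NCC registration
  with subpixel quadratic refinement, score-gated averaging, scanner-artifact
  cropping (300×300 → 300×200 at the default 50 px margin), and
  multi-reference + horizontal-flip training-pair augmentation.
* **`aorpe.model`** — the P-GAN family on an in-package NumPy autodiff
  engine: encoder–decoder generator `G`; CNN discriminator `D2` (real/fake on
  image patches); twin discriminator `D1`, a weight-shared Siamese CNN whose
  multi-depth features are pooled and fused by **weighted feature fusion**
  (WFF, intermediate weights 0.2, last layer 1.0) and compared by L1 distance
  to produce a similarity score.  The generator minimises

  `L_G = λ_D2 · BCE(D2(G(x)), real) + λ_D1 · BCE(D1(G(x), y), similar) + λ_c · ‖G(x) − y‖₁`

  with Adam (lr 2·10⁻⁴, β₁ = 0.5, β₂ = 0.9), 100 epochs, batch 8 by default.
  The ablation family — `G_D2` (conventional GAN), `G_D1`, `G_D2_D1_noWFF`
  (last-layer pooling only), `PGAN` — is pure configuration.
* **`aorpe.metrics`** — quantification: circumferentially averaged power
  spectral density of a 200×200 ROI; cell spacing from the mosaic's
  fundamental-frequency ring (`spacing = (2/√3)/f_peak` for a triangular
  lattice); **peak distinctiveness** `PD = log₁₀PSD(f_peak) − log₁₀PSD(left
  minimum)` as the cellular-contrast measure; µm conversion by a paraxial
  chief-ray trace through a three-surface schematic eye with per-eye axial
  length, corneal radius and anterior chamber depth; and Voronoi packing
  statistics from marked cell centers.

## Worked example

The smoke pipeline simulates three retinal patches, trains P-GAN on two of
them, and recovers a *held-out* patch from a single speckled frame:

```bash
aorpe pipeline --smoke --seed 1 --out runs/demo
```

```
INFO aorpe: built 144 training pairs from 2 stacks
INFO aorpe: trained PGAN in 14.6s
{
  "speckled": 0.27027372059904176,
  "recovered": 0.7726051787895463,
  "averaged": 1.2226944596898135
}
```

The printed numbers are the peak distinctiveness of the held-out patch's
speckled input, the P-GAN recovery, and the 16-frame registered average: the
recovery nearly triples the cellular contrast of the raw frame while staying
below the averaged ground truth, and `runs/demo/report.json` shows all three
images agree on the cell spacing (14.26, 14.35 and 14.27 µm against a
simulated truth of 14 µm).  The report also records the pixel error against
the noiseless reflectance: MSE 0.10 for the recovery versus 0.84 for the
speckled input.

Library use follows scikit-learn conventions:

```python
from aorpe.model import PGANRecovery
est = PGANRecovery(variant="PGAN", epochs=10, depth=3, base_channels=8, seed=0)
recovered = est.fit(speckled_patches, averaged_patches).transform(speckled_image)
```

Other subcommands: `aorpe simulate` (stacks + truth + centers + motion trace),
`aorpe pairs`, `aorpe train`, `aorpe recover`, `aorpe quantify`
(spacing/PD report for one image, with `--biometry`/`--fov-deg`/`--n-px` for
the model-eye scale), `aorpe voronoi` (packing statistics from a centers CSV).

## Documentation

`docs/methods.md` describes the simulation model and its assumptions, the
network and loss configuration, the quantification conventions, and the known
limitations of the synthetic study conditions.
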