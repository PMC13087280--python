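# echogen

Quantitative ultrasound (QUS) characterizes tissue microstructure from raw
radiofrequency (RF) echo signals — but clinical scanners rarely expose RF
data. `echogen` implements a full, desk-scale testbed for the workaround:
learn to **synthesize RF frames back from standard B-mode images** with
conditional GANs, and verify that the synthetic RF supports the same
downstream QUS analysis (spectral parametric maps, texture radiomics,
benign/malignant lesion classification) as the original RF.

Because clinical breast RF data are institutional and unavailable, the
package includes a physics-based phantom simulator as a first-class module:
every stage of the pipeline can be validated by parameter recovery against
known ground truth.

## What's inside

| module | role |
| --- | --- |
| `echogen.synthetic` | point-scatterer RF/B-mode simulator with known microstructure (scatterer radius `a_eff`, density `n`, attenuation `α`), paired benign/malignant lesion cohorts |
| `echogen.preprocessing` | B-mode/RF geometry alignment (resize, flip, power-of-two pad/crop) and global min-max normalization |
| `echogen.qus` | reference-phantom spectral analysis: MBF/SS/SI line fits, backscatter-coefficient estimation, spherical Gaussian form-factor fits (ESD/EAC), spectral-difference attenuation estimation, two-layer point compensation |
| `echogen.texture` | mask-aware GLCM textures (contrast, correlation, energy, homogeneity) and the 25-feature per-lesion vector |
| `echogen.generative` | three cGAN translators (Pix2Pix U-Net, shallow ViT, deep ViT) plus a patch discriminator, built on a small numpy autograd (`echogen.nn`) |
| `echogen.evaluation` | NRMSE/NMAE/SSIM/PSNR fidelity metrics, UMAP feature-distribution comparison |
| `echogen.classification` | two-step feature selection (mutual information → elastic net), RBF-SVC with nested CV, bootstrap evaluation, four-condition original/synthetic experiment matrix |
| `echogen.workbench` | configuration, orchestration, run manifests, `echogen` CLI |

## The core models

**Backscatter model.** Each tissue region is a Poisson field of sub-resolution
scatterers; its backscatter coefficient follows the spherical Gaussian form
factor

```
BSC(f) = κ n a_eff⁶ k⁴ exp(−0.827 k² a_eff²),   k = 2πf/c .
```

Sliding 2 × 2 mm Hann-gated windows (94 % overlap) yield line-averaged power
spectra, normalized by a reference phantom (α = 0.786 dB/MHz/cm,
c = 1540 m/s) to cancel the system response. A linear fit of the corrected
spectrum gives the spectral slope (SS), intercept (SI) and mid-band fit
(MBF = SS·f_c + SI); a linearized form-factor fit of `ln BSC − 4 ln k`
against `k²` gives the effective scatterer diameter ESD = 2·a_eff and the
effective acoustic concentration EAC.

**Translators.** Conditional GANs map normalized B-mode rasters to normalized
RF frames: a 7-level U-Net (Pix2Pix), and two ViT generators (2 and 5
transformer blocks over 16 × 16 patches). All variants share a 3-stage patch
discriminator and are trained with BCE adversarial loss (label smoothing on
real labels) plus L1/L2 reconstruction losses weighted 1000/100, Adam
(lr 1e-4 generator / 1e-5 discriminator, β = (0.5, 0.999)), batch size 1.
Geometry is fully parametric: the clinical 2048 × 512 and the desk-scale
256 × 64 instantiations share the same code.

## Worked example

```python
import numpy as np
from echogen.synthetic import DatasetConfig, build_paired_dataset
from echogen.workbench import extract_lesion_features, split_lesions
from echogen import classification as cls

ds = build_paired_dataset(DatasetConfig(n_lesions_per_class=6, n_planes=2), seed=3)
feats, labels = extract_lesion_features(ds)       # 12 lesions x 25 features
ben = feats.loc[[i for i, l in labels.items() if l == "benign"]]
mal = feats.loc[[i for i, l in labels.items() if l == "malignant"]]
print(f"ESD-MEAN benign {ben['ESD-MEAN'].mean():.1f} um, "
      f"malignant {mal['ESD-MEAN'].mean():.1f} um")
print(f"MBF-MEAN benign {ben['MBF-MEAN'].mean():.1f} dB, "
      f"malignant {mal['MBF-MEAN'].mean():.1f} dB")
```

prints

```
ESD-MEAN benign 69.1 um, malignant 65.2 um
MBF-MEAN benign 2.0 dB, malignant 7.3 dB
```

i.e. over the core + 5 mm margin the benign lesions (larger, sparser
scatterers) and malignant lesions (smaller, denser, higher-variance
scatterers) separate cleanly in mid-band fit and concentration-sensitive
features — which is what drives the downstream classifier to high accuracy
on the synthetic cohort.

The end-to-end pipeline (simulate → train a translator → synthesize RF →
QUS maps → textures → classification matrix) runs from the shell:

```bash
echogen run --out run/ --seed 0
```

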