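# edxmix

Unsupervised spectral mixture analysis for large-scale STEM-EDX hyperspectral
imaging of biological tissue.

Energy-dispersive X-ray (EDX) spectrum imaging records a full X-ray energy
histogram at every scanned pixel, so a tiled acquisition of a tissue section
yields a hyperspectral cube whose spectra reflect local elemental composition
(C, N, O, P, S, Os, Fe, ...). `edxmix` turns such cubes into interpretable
maps without training data:

1. **Preprocessing** — drop leading calibration channels, bin spatially and
   spectrally with a count-conserving sum (2048 × 2048 × 4096 →
   1024 × 1024 × 250 with the defaults), and mean-filter each spectral band.
2. **Endmember extraction** — augment each pixel spectrum with
   Gaussian-blurred copies of the cube (radii 1/3/5, σ = 2; 250 → 1000
   features), subsample 20 % of non-overlap pixels, embed to 2-D with a
   manifold method (UMAP backend; exact PCA backend for reproducibility
   tests), histogram the embedding, and average the raw spectra inside
   bounding boxes over local density maxima.  Endmembers can also come from
   sparse hand annotations (per-class mean spectra).
3. **Unmixing** — per-pixel non-negative least squares
   `min ‖E a − s‖₂  s.t.  a ≥ 0` against the endmember matrix `E`, one
   global display scale across the mosaic, dominant-endmember colour maps,
   and per-channel endmember Z-scores.
4. **Frame-accumulation analysis** — relative intra-class spectral distance
   and intra/inter distance ratios versus accumulated frame count, to find
   the minimum number of frames that still separates structures (Poisson
   counting noise shrinks these curves like 1/√k).
5. **Prompted segmentation** — blur and threshold each structure's abundance
   map (σ = 4; threshold 0.4, or 0.5 for nucleic acids), take local maxima
   as point prompts for a pluggable promptable segmenter, close nucleic-acid
   masks with a 70-px disk, and score masks by intersection-over-union.  A
   deterministic flood-fill fallback segmenter ships for CPU-only runs;
   foundation segmentation models plug in through the same adapter.

A synthetic-phantom module generates EDX cubes with known ground truth
(linear mixtures of element-line + bremsstrahlung spectra under Poisson
frame accumulation), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from edxmix import (five_structure_phantom, render_phantom, preprocess_cube,
                    PreprocessConfig, extract_endmembers, match_to_reference,
                    nnls_unmix, finalize_scale, dominant_map)
from edxmix.embedding import EndmemberSet

spec = five_structure_phantom(shape=(128, 128), seed=7)   # 5 structures + background
cube, gt = render_phantom(spec)                            # Poisson counts + ground truth
cube = preprocess_cube(cube, PreprocessConfig(0, 1, 1))    # band-wise 3x3 mean filter

ems, emb, hist = extract_endmembers(cube, seed=7)          # unsupervised
ems, cos = match_to_reference(ems, gt.spectra, gt.class_labels)
print("worst endmember cosine:", round(float(np.nanmin(cos)), 4))

stack = nnls_unmix(cube.with_counts(cube.counts / spec.n_frames),
                   EndmemberSet(gt.spectra, list(gt.class_labels),
                                ["truth"] * 6))
finalize_scale([stack])
print("abundance MAE:", round(float(np.abs(stack.coeffs - gt.abundances).mean()), 4))
print("label accuracy:", round(float((dominant_map(stack).labels == gt.labels).mean()), 3))
```

prints

```
worst endmember cosine: 0.9948
abundance MAE: 0.0071
label accuracy: 0.998
```

i.e. every ground-truth spectrum is recovered essentially exactly by the
embedding workflow, per-pixel abundances are recovered to well under one
percent absolute, and the dominant-endmember map reproduces the scene (the
residual label disagreement sits on structure boundaries, where the mean
filter genuinely mixes classes).

The same pipeline is available from the shell:

```bash
edxmix simulate --out cube.h5 --scene five_structure --seed 7
edxmix preprocess --cube cube.h5 --out pp.h5 --drop-channels 0 --spatial-bin 1 --spectral-bin 1
edxmix endmembers --cube pp.h5 --out endmembers.tsv --seed 7
edxmix unmix --cube pp.h5 --endmembers endmembers.tsv --out maps/
edxmix run --config pipeline.yaml --out run/        # full pipeline + manifest
```

## Layout

| module | contents |
| --- | --- |
| `edxmix.core` | `HyperspectralCube`, energy axis, mosaic layout, HDF5 container + manifest I/O, flatten/unflatten |
| `edxmix.synthetic` | spectral models, phantom scenes, Poisson frame rendering, ground truth |
| `edxmix.preprocess` | trim/bin, band mean filter, percentile normalisation, median equalisation, grid stitching |
| `edxmix.embedding` | feature augmentation, subsampling, 2-D embedding, density maxima, endmember averaging |
| `edxmix.unmixing` | NNLS unmixing, global scaling, dominant maps, Z-scores, display images |
| `edxmix.frames` | intra/inter spectral distances vs frame count, plateau detection |
| `edxmix.segment` | prompt generation, morphology, segmenter adapter + flood-fill fallback, IoU |
| `edxmix.pipeline`, `edxmix.cli` | end-to-end runner, run manifest, command-line interface |

See `docs/methods.md` for the underlying model, conventions and known
limitations.
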