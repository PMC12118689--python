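# Methods

## Model

`edxmix` treats an EDX spectrum image as a linear mixing problem.  Each pixel
spectrum `s ∈ R^C` (C energy channels of X-ray counts) is assumed to be a
nonnegative combination of a small number of characteristic spectra
("endmembers") `e_1 … e_K`, one per biological structure class:

    s(p) ≈ Σ_k a_k(p) · e_k ,   a_k(p) ≥ 0.

The abundances `a` are estimated per pixel by non-negative least squares
(`scipy.optimize.nnls`), with **no** sum-to-one constraint: EDX counts scale
with local mass-thickness, so the intensity freedom is physical, and display
scaling (one global maximum coefficient across the whole mosaic) handles
normalisation.  NNLS is deterministic; a rank-deficient endmember matrix is
accepted with a warning, since tissue scenes can legitimately contain
spectrally identical structures (the abundances are then non-unique but
their sum over the degenerate set is still well determined).

Counting statistics are Poisson.  A pixel accumulated over `k` scan frames
has counts `~ Poisson(k·λ)`, so relative spectral noise shrinks like
`1/√k`; this is what the frame-accumulation analysis measures and what the
synthetic phantoms realise exactly.

## Preprocessing

Raw cubes are extremely sparse.  The pipeline, in order:

* **Channel trim** — the first `drop_first_channels` (default 96) channels
  are treated as calibration artefacts and removed before any binning.
* **Binning** — spatial factor 2, spectral factor 16 by default, mapping a
  2048 × 2048 × 4096 acquisition onto 1024 × 1024 × 250.  The spectral and
  spatial reducer is **sum**, which conserves total counts exactly (a "mean"
  reducer is available for display work).  Non-divisible shapes are a hard
  error — silent truncation of a calibrated axis is worse than asking the
  caller to crop.  The energy axis is updated: new bin width = old × 16, new
  channel-0 center = mean of the merged raw centers.
* **Mean filter** — a normalised box kernel (default 3 × 3, the smallest
  nontrivial denoiser; configurable) applied independently to every spectral
  band, reflect borders.

Display normalisation maps the `q`-quantile to 0 and the `1−q` quantile to 1
(`q` = 1 % by default, 0.5 % for dense single-tile figures), linear
interpolation quantiles, then clips; a constant image maps to 0.5 by
convention.  HAADF tiles are equalised by shifting each tile down so all
medians equal the lowest tile median (only downward shifts, preserving the
darkest tile).  Mosaics are stitched purely from grid metadata
(`tile_px·n − overlap·(n−1)` per axis); overlap pixels default to
first-written-tile-wins, and an overlap mask (coverage ≥ 2) feeds the
subsampling stage.

## Endmember extraction

Pure (least-mixed) pixels concentrate at the extremities of protrusions in a
2-D embedding of pixel spectra.  The stages and their defaults:

* **Feature augmentation** — the flattened cube is concatenated with
  Gaussian-blurred copies (radii 1, 3, 5 at σ = 2), giving
  `C·(1+3)` features; the blur injects spatial context so the embedding
  groups pixels by neighbourhood as well as spectrum.  "Radius" is read as
  the kernel truncation radius of a σ = 2 Gaussian by default; a per-copy-σ
  reading is available via `interpretation="sigma"` since the phrase is
  ambiguous in common usage.
* **Subsampling** — 20 % of the non-overlap pixels, uniform without
  replacement, seeded.  Overlap pixels are excluded because doubly exposed
  regions carry extra spectral variance.
* **Embedding** — any method mapping N × F → N × 2 behind one contract.
  The default backend is UMAP (seeded); a PCA backend provides an exact,
  fully deterministic alternative used for duplicate-consistency tests and
  as a linear baseline.  The package deliberately does not re-implement a
  manifold learner.
* **Density maxima** — a 2-D histogram (default 64 bins per axis at phantom
  scale; 256 is appropriate for million-pixel mosaics) is optionally
  smoothed (σ = 1 bin) and scanned for local maxima: a bin qualifies if it
  attains the maximum of its `(2d+1)²` neighbourhood (d = 3 bins) and holds
  ≥ 2 counts; plateaus collapse to their centroid.  An automated stand-in
  for interactive protrusion picking suppresses maxima inside the connected
  region around the global mode at ≥ 50 % of its height
  (`exclude_central_bulk`).  The orchestrator keeps *all* surviving maxima
  as candidate endmembers rather than pre-trimming to an expected K: weak
  structures produce weak density peaks, and selection is better done
  downstream (by matching, or by a user inspecting the spectra) than by
  rank-ordering peak heights.
* **Averaging** — each endmember is the arithmetic mean of the **raw
  un-augmented** spectra of sampled pixels inside a box of ± 2.5 bins around
  its maximum; the augmentation exists only to stabilise the embedding and
  would bias averaged spectra.  An empty user-supplied box is a hard error
  naming the box; automatically generated boxes promoted by smoothing are
  silently dropped instead.

Annotation-derived endmembers (per-class mean spectra over hand-picked
pixels) share the same `EndmemberSet` type and feed the same unmixing.

When ground truth or reference spectra exist, `match_to_reference` assigns
extracted endmembers to references one-to-one by maximising total cosine
similarity (Hungarian algorithm) — the programmatic equivalent of manually
identifying what each endmember represents.

## Frame-accumulation statistics

"Relative" distances need a normalisation; the package's conventions
(tagged on every output so alternates can be added):

* intra-class: `mean_i ‖s_i − μ‖₂ / ‖μ‖₂` over class members, spectra first
  divided by the frame count;
* inter-class: `‖μ_a − μ_b‖₂ / ‖(μ_a+μ_b)/2‖₂` per pair;
* ratio: per-pair `mean(intra_a, intra_b) / inter_ab`, aggregated as the
  arithmetic mean over pairs.

All three are invariant to global intensity rescaling.  Frames are rendered
once and accumulated cumulatively (frame j always derives from seed
`(seed, j)`), mirroring a real accumulation where the k-frame image contains
the (k−1)-frame image.  The plateau criterion — first frame count after
which every per-step change is below 5 % of the curve's initial value — is a
repo convention for reading convergence off a curve, not a claim about any
particular instrument.

## Prompted segmentation

Per structure: Gaussian-blur the globally scaled abundance map (σ = 4 px),
zero below the threshold (0.4; 0.5 for nucleic acids, whose maps are
noisier because chromatin is fragmented), and emit the local maxima
(neighbourhood scan, plateau centroids, min distance 10 px — unspecified
upstream, chosen as roughly the blur support) as point prompts.  The
blur-then-threshold order is the default; the reverse order is available via
config since both readings occur in practice.  Nucleic-acid masks are closed
(dilate+erode) with a 70-px-radius disk at full tile scale so that chromatin
prompts aggregate into whole-nucleus masks; the phantom pipeline scales this
radius with the linear image size.

The segmenter is an adapter: `(image, points) → [(mask, score), …]`.  The
shipped `FloodFillSegmenter` (tolerance flood fill from each prompt on the
lightly smoothed grayscale image) is a deterministic classical baseline that
makes the whole pipeline runnable on one CPU with no model weights;
promptable foundation models plug into the identical contract.  IoU is exact
set overlap; two empty masks score 1.0 by convention (agreement on absence).

## Synthetic phantoms

The generator realises exactly the assumptions above and nothing more:
per-structure spectra are Gaussian characteristic lines (channel-integrated
via the error function, so line mass is exact) on an exponentially decaying
bremsstrahlung-like continuum; scenes are geometric primitives (disks,
ellipses, annuli, bands) with constant fractional abundance, background an
explicit carbon-rich class taking up the remainder; counts are independent
Poisson draws per frame, summed.  Defaults — 250 expected counts per pixel
per frame, 20 accumulated frames, ~0.1–8.1 keV axis in 80 eV bins, stock
element lines for C/N/O/P/S/Os/Fe at 55 eV detector width — represent a
well-exposed, already-binned acquisition of stained tissue.

What the phantoms do **not** contain: detector response beyond Gaussian line
width, absorption and pile-up, scan drift, stage/beam damage, spatially
textured abundances, or spectrally overlapping structure classes with subtle
contrast.  Passing tests therefore demonstrate that the algorithms are
correct under the linear-mixture + Poisson model, not that real tissue
reaches the same scores; on real data the limiting factors are spectral
similarity between structures and staining variability.  In particular the
phantom mean-IoU bar (> 0.8 with the classical fallback segmenter) is a
regression property of this pipeline, not a reproduction of
foundation-model segmentation quality on tissue.

## Numerical choices and conventions

* Coordinates 0-based `(row, col)`, boxes half-open; energy channel 0-based;
  raw counts unsigned integers, all derived arrays float64.
* Quantiles: linear interpolation (numpy default), documented so
  normalisation is bit-stable.
* Argmax ties in dominant maps break to the lowest endmember index;
  all-zero pixels get a reserved background label (−1) with intensity 0.
* Endmember Z-scores use the population standard deviation across the K
  endmembers per channel; zero-variance channels map to 0.
* The band mean filter clamps ~1e−17 negatives produced by the separable
  sliding-sum implementation back to 0 so cube invariants hold.
* Problem sizes in tests and the acceptance script (128–160 px phantoms,
  ≤ 64 frames, 20 % subsamples of ≤ 26k pixels) are chosen so the full suite
  runs in a couple of minutes on one CPU while keeping ≥ 5×10³ expected
  counts per pixel, the regime where the CLT-based recovery bounds are
  meaningful.

## Known limitations

* Grid stitching is purely metadata-driven; no cross-correlation refinement
  of tile positions is attempted (acquisition software is assumed to have
  drift-corrected frames).
* No vendor file readers; cubes enter through the package's documented HDF5
  container (an adapter layer is the natural extension point).
* UMAP's seeded determinism holds per installed version; bit-identical
  embeddings across library versions are not guaranteed (the PCA backend is
  exactly reproducible everywhere).
* No endmember-count estimation criterion is provided; K emerges from the
  density maxima and is meant to be reviewed by the analyst.
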