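"""Endmember extraction via 2-D manifold embedding of pixel spectra.

The least-mixed (purest) spectra in a spectrum image sit at the extremities
of protrusions from the main cluster when the pixels are embedded in two
dimensions.  The pipeline is:

1. augment each pixel's spectrum with Gaussian-blurred copies of the cube
   (spatial-context features, radii 1/3/5 at sigma 2 by default), turning a
   C-channel table into a C*(1+len(radii))-feature table;
2. subsample a fraction of the non-overlap pixels (20% by default);
3. embed the subsample to 2-D with a manifold backend (umap by default, a
   deterministic PCA backend for exact reproducibility);
4. histogram the embedding, pick local density maxima away from the central
   bulk, and average the *raw* (un-augmented) spectra of the pixels inside a
   bounding box around each maximum — those averages are the endmembers.

Endmembers can alternatively be derived from sparse hand annotations
(per-class mean spectra).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter

from .core import AnnotationSet, FlatPixelTable, HyperspectralCube, flatten

__all__ = [
    "FeatureAugmentConfig",
    "Embedding2D",
    "Histogram2D",
    "EndmemberSet",
    "augment_features",
    "subsample",
    "embed",
    "histogram2d",
    "find_histogram_maxima",
    "boxes_around",
    "endmembers_from_boxes",
    "endmembers_from_annotations",
    "extract_endmembers",
    "cosine_similarity_matrix",
    "match_to_reference",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureAugmentConfig:
    """Spatial-context augmentation parameters.

    ``interpretation='radius'`` reads each entry of ``blur_radii`` as the
    truncation radius (in pixels) of a Gaussian kernel with ``blur_sigma``;
    ``interpretation='sigma'`` reads each entry as that copy's own sigma.
    Both are supported because "radius" is ambiguous in common usage; the
    truncation-radius reading is the default.
    """

    blur_radii: tuple[float, ...] = (1, 3, 5)
    blur_sigma: float = 2.0
    include_base: bool = True
    interpretation: str = "radius"  # or "sigma"

    def __post_init__(self) -> None:
        if len(set(self.blur_radii)) != len(self.blur_radii):
            raise ValueError("blur radii must be distinct")
        if any(r <= 0 for r in self.blur_radii):
            raise ValueError("blur radii must be positive")
        if self.interpretation not in ("radius", "sigma"):
            raise ValueError("interpretation must be 'radius' or 'sigma'")


@dataclass
class Embedding2D:
    """2-D coordinates of sampled pixels plus backend provenance."""

    coords: np.ndarray  # (N, 2)
    sample: FlatPixelTable  # the table the coords correspond to, row-aligned
    backend: str = "umap"
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (N, 2)")
        if self.coords.shape[0] != self.sample.n_pixels:
            raise ValueError("coords rows must match sample rows")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coords must be finite")


@dataclass
class Histogram2D:
    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    def bin_center(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            0.5 * (self.x_edges[ix] + self.x_edges[ix + 1]),
            0.5 * (self.y_edges[iy] + self.y_edges[iy + 1]),
        )


@dataclass
class EndmemberSet:
    """K characteristic spectra plus provenance.

    ``provenance`` is ``'annotation'`` or ``'embedding'`` per endmember;
    ``boxes`` holds the embedding-space selection box for embedding-derived
    endmembers (``(x0, x1, y0, y1)``, half-open in bin terms but inclusive
    as float intervals).
    """

    spectra: np.ndarray  # (K, C)
    labels: list[str]
    provenance: list[str]
    boxes: list[tuple[float, float, float, float] | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        if self.spectra.ndim != 2 or self.spectra.shape[0] < 1:
            raise ValueError("spectra must be (K >= 1, C)")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("endmember spectra must be finite")
        if self.spectra.min() < 0:
            raise ValueError("endmember spectra must be nonnegative")
        if len(self.labels) != self.spectra.shape[0]:
            raise ValueError("one label per endmember required")
        if not self.boxes:
            self.boxes = [None] * self.spectra.shape[0]

    @property
    def k(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_channels(self) -> int:
        return self.spectra.shape[1]

    def save_tsv(self, path) -> None:
        """Spectra table, channels x K, tab-separated with a header row."""
        header = "\t".join(self.labels)
        np.savetxt(path, self.spectra.T, delimiter="\t", header=header, comments="")

    @staticmethod
    def load_tsv(path) -> "EndmemberSet":
        with open(path) as f:
            labels = f.readline().strip().split("\t")
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        if data.ndim == 1:
            data = data[:, None]
        return EndmemberSet(
            spectra=data.T, labels=labels, provenance=["file"] * data.shape[1]
        )


# ---------------------------------------------------------------------------
# Feature augmentation
# ---------------------------------------------------------------------------

def augment_features(
    cube: HyperspectralCube,
    cfg: FeatureAugmentConfig = FeatureAugmentConfig(),
    selection: np.ndarray | None = None,
) -> FlatPixelTable:
    """Concatenate the flattened cube with Gaussian-blurred copies.

    Output feature count is ``n_channels * (1 + len(blur_radii))`` when
    ``include_base`` is set.  Blurs are computed in the spatial domain on the
    full cube before any pixel selection, then re-flattened in the same row
    order as the base table.
    """
    base = flatten(cube, selection)
    blocks = [base.values] if cfg.include_base else []
    rr, cc = base.origin[:, 0], base.origin[:, 1]
    data = cube.counts.astype(np.float64)
    for r in cfg.blur_radii:
        if cfg.interpretation == "radius":
            sigma, truncate = cfg.blur_sigma, float(r) / cfg.blur_sigma
        else:
            sigma, truncate = float(r), 4.0
        blurred = gaussian_filter(
            data, sigma=(sigma, sigma, 0), truncate=truncate, mode="reflect"
        )
        blocks.append(blurred[rr, cc, :])
    if not blocks:
        raise ValueError("no features: empty radii with include_base=False")
    return FlatPixelTable(
        values=np.concatenate(blocks, axis=1), origin=base.origin, tile_ids=base.tile_ids
    )


def subsample(
    table: FlatPixelTable,
    fraction: float,
    overlap: np.ndarray | None = None,
    seed: int = 0,
) -> FlatPixelTable:
    """Uniform random subsample of the non-overlap pixels, without
    replacement; reproducible from ``seed``.

    ``overlap`` is an optional boolean mask over cube/mosaic coordinates;
    rows whose origin falls on a True pixel are excluded from the pool.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    pool = np.arange(table.n_pixels)
    if overlap is not None:
        overlap = np.asarray(overlap, dtype=bool)
        keep = ~overlap[table.origin[:, 0], table.origin[:, 1]]
        pool = pool[keep]
    if pool.size == 0:
        raise ValueError("empty sampling pool: all pixels masked")
    n = max(1, int(round(fraction * pool.size)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pool, size=n, replace=False))
    return table.take(idx)


# ---------------------------------------------------------------------------
# Embedding backends
# ---------------------------------------------------------------------------

_BACKEND_MIN_ROWS = {"umap": 10, "pca": 2}


def embed(
    table: FlatPixelTable,
    backend: str = "umap",
    seed: int = 0,
    **params,
) -> Embedding2D:
    """Map the N x F table to N x 2 with the chosen backend.

    ``'umap'`` is the default manifold backend (seeded; approximate manifold
    projection in the same family as pairwise-controlled methods).  ``'pca'``
    is an exact, fully deterministic linear fallback useful for tests and as
    a sanity baseline.  Any other backend can be registered by passing a
    callable ``table.values -> (N, 2)`` as ``params['transform']`` with
    ``backend='custom'``.
    """
    n = table.n_pixels
    min_rows = _BACKEND_MIN_ROWS.get(backend, 2)
    if n < min_rows:
        raise ValueError(f"backend {backend!r} needs >= {min_rows} rows, got {n}")
    x = np.asarray(table.values, dtype=np.float64)
    if backend == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, svd_solver="full").fit_transform(x)
    elif backend == "umap":
        import umap

        nn = int(params.pop("n_neighbors", min(15, n - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=2,
                n_neighbors=max(2, nn),
                random_state=seed,
                **params,
            )
            coords = reducer.fit_transform(x)
    elif backend == "custom":
        coords = params["transform"](x)
    else:
        raise ValueError(f"unknown embedding backend {backend!r}")
    return Embedding2D(
        coords=np.asarray(coords, dtype=np.float64),
        sample=table,
        backend=backend,
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Density histogram and maxima
# ---------------------------------------------------------------------------

def histogram2d(embedding: Embedding2D, bins: int = 256) -> Histogram2D:
    """2-D histogram of the embedding (half-open bins, last bin closed)."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    counts, x_edges, y_edges = np.histogram2d(
        embedding.coords[:, 0], embedding.coords[:, 1], bins=bins
    )
    return Histogram2D(counts=counts, x_edges=x_edges, y_edges=y_edges)


def find_histogram_maxima(
    hist: Histogram2D,
    min_distance_bins: int = 3,
    min_count: float = 1.0,
    smooth_sigma: float = 0.0,
    exclude_central_bulk: bool = False,
    bulk_frac: float = 0.5,
    max_peaks: int | None = None,
) -> list[tuple[float, float]]:
    """Local maxima of the (optionally smoothed) density histogram.

    A bin is a candidate if it attains the maximum of its
    ``(2*min_distance_bins+1)`` square neighbourhood and holds at least
    ``min_count``; plateau candidates collapse to their centroid bin.  With
    ``exclude_central_bulk`` the connected region around the global mode at
    ``>= bulk_frac * max`` is suppressed — an automated stand-in for the
    interactive choice of protrusion extremities over the primary cluster.
    Returns embedding-space (x, y) points, strongest first.
    """
    h = np.asarray(hist.counts, dtype=np.float64)
    if smooth_sigma > 0:
        h = gaussian_filter(h, smooth_sigma, mode="constant")
    size = 2 * int(min_distance_bins) + 1
    local_max = (h == ndimage.maximum_filter(h, size=size, mode="constant")) & (
        h >= min_count
    )
    if exclude_central_bulk and h.max() > 0:
        bulk = h >= bulk_frac * h.max()
        lab, _ = ndimage.label(bulk)
        mode_lab = lab[np.unravel_index(np.argmax(h), h.shape)]
        local_max &= lab != mode_lab
    # collapse plateaus to one representative bin each
    lab, nlab = ndimage.label(local_max)
    peaks: list[tuple[int, int, float]] = []
    for li in range(1, nlab + 1):
        ys, xs = np.nonzero(lab == li)  # first axis = x-bin by histogram2d layout
        ix = int(round(ys.mean()))
        iy = int(round(xs.mean()))
        peaks.append((ix, iy, float(h[ix, iy])))
    peaks.sort(key=lambda p: (-p[2], p[0], p[1]))
    if max_peaks is not None:
        peaks = peaks[:max_peaks]
    return [hist.bin_center(ix, iy) for ix, iy, _ in peaks]


def boxes_around(
    hist: Histogram2D,
    points: list[tuple[float, float]],
    half_width_bins: int = 2,
) -> list[tuple[float, float, float, float]]:
    """Embedding-space bounding boxes of ``+- half_width_bins`` around each
    point (the default selection box over a density maximum)."""
    dx = float(hist.x_edges[1] - hist.x_edges[0])
    dy = float(hist.y_edges[1] - hist.y_edges[0])
    hw_x = (half_width_bins + 0.5) * dx
    hw_y = (half_width_bins + 0.5) * dy
    return [(x - hw_x, x + hw_x, y - hw_y, y + hw_y) for x, y in points]


# ---------------------------------------------------------------------------
# Endmember averaging
# ---------------------------------------------------------------------------

def endmembers_from_boxes(
    raw_table: FlatPixelTable,
    boxes: list[tuple[float, float, float, float]],
    embedding: Embedding2D,
    labels: list[str] | None = None,
) -> EndmemberSet:
    """Average the raw (un-augmented) spectra of pixels whose embedding
    coordinates fall inside each box.

    ``raw_table`` must be row-aligned with ``embedding.sample`` (same pixels
    in the same order) and carry the preprocessed spectra *without* the
    Gaussian-context augmentation — the augmentation exists only to stabilise
    the embedding.
    """
    if raw_table.n_pixels != embedding.coords.shape[0]:
        raise ValueError("raw table and embedding must cover the same pixels")
    if labels is None:
        labels = [f"endmember_{i}" for i in range(len(boxes))]
    spectra = []
    for i, (x0, x1, y0, y1) in enumerate(boxes):
        inside = (
            (embedding.coords[:, 0] >= x0)
            & (embedding.coords[:, 0] <= x1)
            & (embedding.coords[:, 1] >= y0)
            & (embedding.coords[:, 1] <= y1)
        )
        if not inside.any():
            raise ValueError(f"box {i} ({labels[i]}) contains no sampled pixels")
        spectra.append(raw_table.values[inside].mean(axis=0))
    return EndmemberSet(
        spectra=np.clip(np.stack(spectra), 0.0, None),
        labels=list(labels),
        provenance=["embedding"] * len(boxes),
        boxes=list(boxes),
    )


def endmembers_from_annotations(
    cube: HyperspectralCube, annotations: AnnotationSet
) -> EndmemberSet:
    """One endmember per annotation class: the mean spectrum of its pixels."""
    if not annotations.classes:
        raise ValueError("annotation set has no classes")
    annotations.validate((cube.rows, cube.cols))
    spectra, labels = [], []
    for cls in annotations.classes:
        rc = np.array(cls.pixels)
        spectra.append(cube.counts[rc[:, 0], rc[:, 1], :].mean(axis=0))
        labels.append(cls.label)
    return EndmemberSet(
        spectra=np.stack(spectra).astype(np.float64),
        labels=labels,
        provenance=["annotation"] * len(labels),
    )


# ---------------------------------------------------------------------------
# Orchestrated extraction
# ---------------------------------------------------------------------------

def extract_endmembers(
    cube: HyperspectralCube,
    n_endmembers: int | None = None,
    fraction: float = 0.2,
    overlap: np.ndarray | None = None,
    augment: FeatureAugmentConfig = FeatureAugmentConfig(),
    backend: str = "umap",
    bins: int = 64,
    min_distance_bins: int = 3,
    min_count: float = 2.0,
    smooth_sigma: float = 1.0,
    exclude_central_bulk: bool = False,
    box_half_width_bins: int = 2,
    seed: int = 0,
) -> tuple[EndmemberSet, Embedding2D, Histogram2D]:
    """Run the full unsupervised extraction on one (preprocessed) cube.

    Augment, subsample, embed, histogram, find density maxima, average boxed
    raw spectra.  ``n_endmembers`` caps the peaks at the strongest K; by
    default every surviving maximum becomes an endmember.
    """
    aug = augment_features(cube, augment)
    raw = flatten(cube)
    sampled_aug = subsample(aug, fraction, overlap, seed)
    # align the raw table with the sampled augmented rows
    key = {tuple(rc): i for i, rc in enumerate(raw.origin)}
    ridx = np.array([key[tuple(rc)] for rc in sampled_aug.origin])
    sampled_raw = raw.take(ridx)
    emb = embed(sampled_aug, backend=backend, seed=seed)
    hist = histogram2d(emb, bins=bins)
    points = find_histogram_maxima(
        hist,
        min_distance_bins=min_distance_bins,
        min_count=min_count,
        smooth_sigma=smooth_sigma,
        exclude_central_bulk=exclude_central_bulk,
        max_peaks=n_endmembers,
    )
    if not points:
        raise ValueError("no density maxima found; lower min_count or bins")
    boxes = boxes_around(hist, points, box_half_width_bins)
    # smoothing can promote near-empty bins to maxima; keep populated boxes
    occupied = []
    for b in boxes:
        x0, x1, y0, y1 = b
        inside = (
            (emb.coords[:, 0] >= x0)
            & (emb.coords[:, 0] <= x1)
            & (emb.coords[:, 1] >= y0)
            & (emb.coords[:, 1] <= y1)
        )
        if inside.any():
            occupied.append(b)
    ems = endmembers_from_boxes(sampled_raw, occupied, emb)
    return ems, emb, hist


# ---------------------------------------------------------------------------
# Matching against reference spectra
# ---------------------------------------------------------------------------

def cosine_similarity_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows of ``a`` (K_a, C) and
    ``b`` (K_b, C); zero rows get similarity 0."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (a / na) @ (b / nb).T


def match_to_reference(
    ems: EndmemberSet, reference: np.ndarray, reference_labels: list[str]
) -> tuple[EndmemberSet, np.ndarray]:
    """Relabel extracted endmembers by their best reference spectra.

    One-to-one assignment maximising total cosine similarity (Hungarian
    algorithm); surplus endmembers keep their original labels.  This mirrors
    the manual step of identifying what each extracted endmember represents.
    Returns the relabelled set (reference-matched endmembers first, in
    reference order) and the per-reference assigned cosine similarities
    (NaN for references left unmatched when K < number of references).
    """
    from scipy.optimize import linear_sum_assignment

    sim = cosine_similarity_matrix(np.asarray(reference), ems.spectra)
    ri, ci = linear_sum_assignment(-sim)
    order = list(ci)
    labels = [reference_labels[r] for r in ri]
    sims = np.full(sim.shape[0], np.nan)  # per reference; NaN if unmatched
    sims[ri] = sim[ri, ci]
    rest = [i for i in range(ems.k) if i not in set(order)]
    order += rest
    labels += [ems.labels[i] for i in rest]
    matched = EndmemberSet(
        spectra=ems.spectra[order],
        labels=labels,
        provenance=[ems.provenance[i] for i in order],
        boxes=[ems.boxes[i] for i in order],
    )
    return matched, sims
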