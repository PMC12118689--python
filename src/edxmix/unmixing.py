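"""Linear spectral unmixing by non-negative least squares.

Each pixel spectrum ``s`` is decomposed against the endmember matrix ``E``
(channels x K) by solving ``min ||E a - s||_2  s.t.  a >= 0`` — plain NNLS,
with no sum-to-one constraint; display scaling handles intensity.  For
consistent colour across a mosaic all coefficients are divided by the single
maximum coefficient found anywhere in the mosaic, and the dominant-endmember
visualisation colours each pixel by its argmax endmember with intensity equal
to that scaled abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _nnls

from .core import FlatPixelTable, HyperspectralCube
from .embedding import EndmemberSet

__all__ = [
    "AbundanceStack",
    "DominantMap",
    "BACKGROUND_LABEL",
    "nnls_unmix",
    "finalize_scale",
    "dominant_map",
    "endmember_zscores",
    "abundance_to_images",
    "default_palette",
]

BACKGROUND_LABEL = -1  # reserved label for all-zero pixels in dominant maps


@dataclass
class AbundanceStack:
    """Per-pixel nonnegative endmember coefficients ``(rows, cols, K)``.

    ``global_scale`` is None until :func:`finalize_scale` fixes it to the
    maximum coefficient across all tiles of the mosaic; after that,
    ``scaled()`` lies in [0, 1].
    """

    coeffs: np.ndarray
    endmembers: EndmemberSet
    global_scale: float | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.ndim != 3:
            raise ValueError("coeffs must be (rows, cols, K)")
        if self.coeffs.shape[2] != self.endmembers.k:
            raise ValueError("coeff depth must equal number of endmembers")
        if self.coeffs.size and self.coeffs.min() < -1e-12:
            raise ValueError("abundances must be nonnegative")
        self.coeffs = np.maximum(self.coeffs, 0.0)

    @property
    def k(self) -> int:
        return self.coeffs.shape[2]

    def scaled(self) -> np.ndarray:
        if self.global_scale is None:
            raise ValueError("stack not finalized; call finalize_scale first")
        if self.global_scale == 0:
            return np.zeros_like(self.coeffs)
        return self.coeffs / self.global_scale


@dataclass
class DominantMap:
    """Argmax endmember per pixel plus its scaled abundance as intensity."""

    labels: np.ndarray  # int map; BACKGROUND_LABEL where all coeffs are 0
    intensity: np.ndarray  # in [0, 1]
    tie_rule: str = "lowest-index"


def _unmix_matrix(values: np.ndarray, e: np.ndarray) -> np.ndarray:
    """NNLS row by row; ``values`` (N, C), ``e`` (C, K) -> (N, K)."""
    out = np.empty((values.shape[0], e.shape[1]), dtype=np.float64)
    for i in range(values.shape[0]):
        out[i], _ = _nnls(e, values[i])
    return out


def nnls_unmix(
    data: HyperspectralCube | FlatPixelTable, endmembers: EndmemberSet
) -> AbundanceStack | np.ndarray:
    """Solve per-pixel NNLS against the endmember spectra.

    Accepts a cube (returns an :class:`AbundanceStack`) or a flat table
    (returns the raw ``(N, K)`` coefficient array).  Deterministic; warns if
    the endmember matrix is column-rank-deficient.
    """
    e = endmembers.spectra.T  # (C, K)
    if np.linalg.matrix_rank(e) < endmembers.k:
        warnings.warn(
            "endmember matrix is rank deficient; abundances are not unique",
            stacklevel=2,
        )
    if isinstance(data, FlatPixelTable):
        if data.n_features != endmembers.n_channels:
            raise ValueError(
                f"table has {data.n_features} channels, endmembers have "
                f"{endmembers.n_channels}"
            )
        return _unmix_matrix(data.values, e)
    if data.n_channels != endmembers.n_channels:
        raise ValueError(
            f"cube has {data.n_channels} channels, endmembers have "
            f"{endmembers.n_channels}"
        )
    values = data.counts.reshape(-1, data.n_channels).astype(np.float64)
    coeffs = _unmix_matrix(values, e).reshape(data.rows, data.cols, endmembers.k)
    return AbundanceStack(coeffs=coeffs, endmembers=endmembers)


def finalize_scale(stacks: list[AbundanceStack]) -> list[AbundanceStack]:
    """Fix one shared ``global_scale`` = max coefficient across all tiles."""
    if not stacks:
        raise ValueError("no abundance stacks")
    scale = max(float(s.coeffs.max(initial=0.0)) for s in stacks)
    for s in stacks:
        s.global_scale = scale
    return stacks


def dominant_map(stack: AbundanceStack) -> DominantMap:
    """Per-pixel argmax endmember with deterministic tie-breaking.

    Ties go to the lowest endmember index (numpy argmax convention);
    all-zero pixels get :data:`BACKGROUND_LABEL` and intensity 0.
    """
    scaled = stack.scaled()
    labels = np.argmax(scaled, axis=2).astype(np.int32)
    intensity = np.take_along_axis(scaled, labels[:, :, None], axis=2)[:, :, 0]
    empty = scaled.sum(axis=2) == 0
    labels[empty] = BACKGROUND_LABEL
    intensity[empty] = 0.0
    return DominantMap(labels=labels, intensity=intensity)


def endmember_zscores(endmembers: EndmemberSet) -> np.ndarray:
    """Per-channel Z-score of each endmember across the K endmembers.

    ``z_k(c) = (e_k(c) - mean_k e_k(c)) / std_k e_k(c)`` with the population
    standard deviation; channels where all endmembers agree (zero std) are
    set to 0.  Requires K >= 2.
    """
    if endmembers.k < 2:
        raise ValueError("z-scores need at least 2 endmembers")
    e = endmembers.spectra
    mu = e.mean(axis=0)
    sd = e.std(axis=0)  # population std
    z = np.zeros_like(e)
    ok = sd > 0
    z[:, ok] = (e[:, ok] - mu[ok]) / sd[ok]
    return z


def default_palette(k: int) -> np.ndarray:
    """K distinct RGB colours in [0, 1] (tab10-style cycle)."""
    base = np.array(
        [
            (0.894, 0.102, 0.110),
            (0.216, 0.494, 0.722),
            (0.302, 0.686, 0.290),
            (0.596, 0.306, 0.639),
            (1.000, 0.498, 0.000),
            (1.000, 1.000, 0.200),
            (0.651, 0.337, 0.157),
            (0.969, 0.506, 0.749),
            (0.600, 0.600, 0.600),
            (0.121, 0.471, 0.706),
        ]
    )
    reps = int(np.ceil(k / len(base)))
    return np.tile(base, (reps, 1))[:k]


def abundance_to_images(
    stack: AbundanceStack,
    colors: np.ndarray | None = None,
    invert: bool = False,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-endmember grayscale maps plus a dominant-endmember composite.

    Grayscale maps are the scaled abundances in [0, 1]; with ``invert`` low
    abundance maps to white and high to black.  The composite colours each
    pixel with its dominant endmember's colour at the scaled-abundance
    intensity; background pixels stay black.
    """
    scaled = stack.scaled()
    if colors is None:
        colors = default_palette(stack.k)
    colors = np.asarray(colors, dtype=np.float64)
    grays = [
        (1.0 - scaled[:, :, i]) if invert else scaled[:, :, i].copy()
        for i in range(stack.k)
    ]
    dom = dominant_map(stack)
    comp = np.zeros(scaled.shape[:2] + (3,), dtype=np.float64)
    fg = dom.labels != BACKGROUND_LABEL
    comp[fg] = colors[dom.labels[fg]] * dom.intensity[fg][:, None]
    return grays, comp
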