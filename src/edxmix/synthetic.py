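"""Synthetic EDX phantoms with the statistical structure the workflow assumes.

A phantom is a linear mixture of per-structure spectra observed through
Poisson counting noise accumulated over frames:

    counts[p, c] ~ Poisson( n_frames * sum_k a_k(p) * e_k(c) )

where ``a_k(p)`` is the ground-truth fractional abundance of structure ``k``
at pixel ``p`` and ``e_k`` its expected per-frame spectrum.  Spectra are
characteristic element lines (Gaussians on the energy axis) on top of a
decaying bremsstrahlung-like continuum.  Abundances at a pixel sum to at most
one; the remainder is assigned to an explicit background class (carbon-rich
embedding resin / intracellular space), so every pixel is a convex-ish mixture
of known endmembers.

The default scene mimics a thin tissue section: granule disks of two spectral
classes, an elliptical nucleus with phosphorus-rich chromatin, osmium-rich
membrane bands, and diffuse background.  No attempt is made at
physics-accurate X-ray emission (no ionization cross-sections, detector
response, pile-up or absorption); the phantom's job is to realise the linear
mixing + Poisson assumptions with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .core import EnergyAxis, HyperspectralCube

__all__ = [
    "GaussianLine",
    "Continuum",
    "SpectralModel",
    "Geometry",
    "Structure",
    "PhantomSpec",
    "GroundTruth",
    "expected_spectrum",
    "render_phantom",
    "render_frames",
    "accumulate_frames",
    "make_haadf",
    "default_energy_axis",
    "default_phantom",
    "five_structure_phantom",
    "ELEMENT_LINES_EV",
]

# Characteristic X-ray line energies (eV) used by the stock spectral models.
ELEMENT_LINES_EV = {
    "C_Ka": 277.0,
    "N_Ka": 392.0,
    "O_Ka": 525.0,
    "Fe_La": 705.0,
    "Os_Ma": 1914.0,
    "P_Ka": 2013.0,
    "S_Ka": 2307.0,
    "Cl_Ka": 2621.0,
    "Fe_Ka": 6404.0,
}

# Detector energy resolution: roughly 130 eV FWHM -> sigma ~ 55 eV.
_DETECTOR_SIGMA_EV = 55.0


# ---------------------------------------------------------------------------
# Spectral model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianLine:
    """One characteristic line: Gaussian of total area ``amplitude``."""

    energy_ev: float
    width_ev: float  # Gaussian sigma
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_ev <= 0:
            raise ValueError("line width must be > 0")
        if self.amplitude < 0:
            raise ValueError("line amplitude must be >= 0")


@dataclass(frozen=True)
class Continuum:
    """Bremsstrahlung-like background: ``scale * exp(-E / decay_ev)``."""

    scale: float = 0.0
    decay_ev: float = 3000.0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("continuum scale must be >= 0")
        if self.decay_ev <= 0:
            raise ValueError("continuum decay must be > 0")


@dataclass(frozen=True)
class SpectralModel:
    lines: tuple[GaussianLine, ...] = ()
    continuum: Continuum = Continuum()

    @staticmethod
    def from_elements(
        amplitudes: dict[str, float],
        continuum_scale: float = 0.0,
        decay_ev: float = 3000.0,
        width_ev: float = _DETECTOR_SIGMA_EV,
    ) -> "SpectralModel":
        lines = tuple(
            GaussianLine(ELEMENT_LINES_EV[el], width_ev, amp)
            for el, amp in amplitudes.items()
        )
        return SpectralModel(lines=lines, continuum=Continuum(continuum_scale, decay_ev))


def expected_spectrum(model: SpectralModel, axis: EnergyAxis) -> np.ndarray:
    """Channel-integrated expected spectrum of a model on an energy axis.

    Each line contributes its Gaussian mass integrated over every channel
    (so a line fully inside the axis contributes exactly ``amplitude`` in
    total); the continuum contributes its analytic integral per channel.
    Returns a nonnegative vector of length ``axis.n_channels``.
    """
    edges = axis.edges()
    out = np.zeros(axis.n_channels, dtype=np.float64)
    for line in model.lines:
        z = (edges - line.energy_ev) / line.width_ev
        cdf = ndtr(z)
        out += line.amplitude * np.diff(cdf)
    c = model.continuum
    if c.scale > 0:
        # integral of scale * exp(-E/decay) over each channel
        expo = np.exp(-edges / c.decay_ev)
        out += c.scale * c.decay_ev * (expo[:-1] - expo[1:])
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Scene geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Placement primitive: disk, ellipse, annulus, or axis-aligned band.

    params per kind:
      disk    — center (row, col), radius
      ellipse — center, semi_axes (r, c)
      annulus — center, r_inner, r_outer
      band    — r0, r1, c0, c1  (half-open rectangle)
    """

    kind: str
    params: dict

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        p = self.params
        if self.kind == "disk":
            (r0, c0), rad = p["center"], p["radius"]
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        if self.kind == "ellipse":
            (r0, c0), (ar, ac) = p["center"], p["semi_axes"]
            return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
        if self.kind == "annulus":
            (r0, c0) = p["center"]
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            return (d2 >= p["r_inner"] ** 2) & (d2 <= p["r_outer"] ** 2)
        if self.kind == "band":
            m = np.zeros(shape, dtype=bool)
            m[p["r0"] : p["r1"], p["c0"] : p["c1"]] = True
            return m
        raise ValueError(f"unknown geometry kind {self.kind!r}")


@dataclass(frozen=True)
class Structure:
    """One labelled structure: a geometry, a spectral model, an abundance."""

    label: str
    geometry: Geometry
    model: SpectralModel
    abundance: float = 1.0  # fractional abundance inside the geometry

    def __post_init__(self) -> None:
        if not (0.0 <= self.abundance <= 1.0):
            raise ValueError("structure abundance must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom; ``seed`` determines the render exactly."""

    shape: tuple[int, int]
    structures: tuple[Structure, ...]
    background: SpectralModel
    energy: EnergyAxis
    counts_per_pixel_per_frame: float = 250.0
    n_frames: int = 20
    pixel_size_nm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.counts_per_pixel_per_frame < 0:
            raise ValueError("counts_per_pixel_per_frame must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def class_labels(self) -> list[str]:
        return [s.label for s in self.structures] + ["background"]

    @property
    def n_classes(self) -> int:
        return len(self.structures) + 1


@dataclass
class GroundTruth:
    """Abundance maps, argmax label map and endmember matrix of a phantom."""

    abundances: np.ndarray  # (rows, cols, K) incl. background last
    labels: np.ndarray  # (rows, cols) int argmax
    spectra: np.ndarray  # (K, n_channels) expected per-frame endmembers
    class_labels: list[str]

    def class_mask(self, label: str) -> np.ndarray:
        k = self.class_labels.index(label)
        return self.labels == k


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _abundance_tensor(spec: PhantomSpec) -> np.ndarray:
    """(rows, cols, K) ground-truth abundances, background as remainder."""
    k = len(spec.structures)
    ab = np.zeros(spec.shape + (k + 1,), dtype=np.float64)
    for i, s in enumerate(spec.structures):
        ab[:, :, i] = s.abundance * s.geometry.mask(spec.shape)
    fg = ab[:, :, :k].sum(axis=2)
    if float(fg.max(initial=0.0)) > 1.0 + 1e-9:
        raise ValueError(
            "overlapping structures exceed total abundance 1 at some pixel; "
            "reduce abundances or separate geometries"
        )
    ab[:, :, k] = 1.0 - fg
    return ab


def _endmember_matrix(spec: PhantomSpec) -> np.ndarray:
    """(K, C) expected per-frame spectra, each scaled so a pure pixel's
    expected total per frame equals ``counts_per_pixel_per_frame``."""
    models = [s.model for s in spec.structures] + [spec.background]
    mat = np.stack([expected_spectrum(m, spec.energy) for m in models])
    totals = mat.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return spec.counts_per_pixel_per_frame * mat / safe


def ground_truth(spec: PhantomSpec) -> GroundTruth:
    ab = _abundance_tensor(spec)
    spectra = _endmember_matrix(spec)
    labels = np.argmax(ab, axis=2)
    return GroundTruth(
        abundances=ab, labels=labels, spectra=spectra, class_labels=spec.class_labels
    )


def _frame_counts(spec: PhantomSpec, frame_index: int, lam: np.ndarray) -> np.ndarray:
    rng = np.random.default_rng([int(spec.seed), int(frame_index)])
    return rng.poisson(lam).astype(np.uint32)


def render_phantom(
    spec: PhantomSpec, noiseless: bool = False
) -> tuple[HyperspectralCube, GroundTruth]:
    """Render the phantom cube and its ground truth.

    With ``noiseless=True`` the cube holds the exact expected values
    ``n_frames * lambda`` (float), i.e. the exact linear mixture of the
    ground-truth endmembers.  Otherwise counts are the sum of ``n_frames``
    independent Poisson frames, frame ``j`` drawn from seed ``(seed, j)``,
    so the same spec renders bit-identically and single-frame renders add
    up to the multi-frame render.
    """
    gt = ground_truth(spec)
    lam = np.einsum("ijk,kc->ijc", gt.abundances, gt.spectra)
    if noiseless:
        counts: np.ndarray = lam * spec.n_frames
    else:
        counts = np.zeros(lam.shape, dtype=np.uint64)
        for j in range(spec.n_frames):
            counts += _frame_counts(spec, j, lam)
        counts = counts.astype(np.uint32)
    cube = HyperspectralCube(
        counts=counts,
        energy=spec.energy,
        pixel_size_nm=spec.pixel_size_nm,
        n_frames=spec.n_frames,
    )
    return cube, gt


def render_frames(spec: PhantomSpec, k: int) -> list[HyperspectralCube]:
    """Render ``k`` independent single-frame cubes (frame ``j`` from seed
    ``(seed, j)``); accumulate with :func:`accumulate_frames`."""
    if k < 1:
        raise ValueError(f"frame count must be >= 1, got {k}")
    gt = ground_truth(spec)
    lam = np.einsum("ijk,kc->ijc", gt.abundances, gt.spectra)
    frames = []
    for j in range(k):
        frames.append(
            HyperspectralCube(
                counts=_frame_counts(spec, j, lam),
                energy=spec.energy,
                pixel_size_nm=spec.pixel_size_nm,
                n_frames=1,
            )
        )
    return frames


def accumulate_frames(frames: list[HyperspectralCube]) -> HyperspectralCube:
    """Sum single-frame cubes into one accumulated cube."""
    if not frames:
        raise ValueError("no frames to accumulate")
    total = np.zeros(frames[0].shape, dtype=np.uint64)
    for f in frames:
        total += f.counts.astype(np.uint64)
    out = frames[0].with_counts(total.astype(np.uint32))
    out.n_frames = len(frames)
    return out


def make_haadf(
    gt: GroundTruth, seed: int = 0, noise: float = 0.02, blur_sigma: float = 0.0
) -> np.ndarray:
    """Synthetic co-registered grayscale EM (HAADF-like) image in [0, 1].

    Each class gets a distinct gray level (heavier classes brighter),
    mixed by abundance, with mild Gaussian noise.
    """
    k = gt.abundances.shape[2]
    levels = np.linspace(0.85, 0.25, k)  # background (last) darkest-ish
    img = np.einsum("ijk,k->ij", gt.abundances, levels)
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, blur_sigma, mode="reflect")
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise, img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Stock scenes
# ---------------------------------------------------------------------------

def default_energy_axis(
    n_channels: int = 100, bin_width_ev: float = 80.0, offset_ev: float = 140.0
) -> EnergyAxis:
    """Reduced-resolution axis covering ~0.1-8.1 keV, spanning the stock
    element lines; comparable to a rebinned acquisition axis."""
    return EnergyAxis(offset_ev=offset_ev, bin_width_ev=bin_width_ev, n_channels=n_channels)


# Stock per-structure spectral models.  Amplitudes are relative line areas;
# each model is renormalised at render time, so only ratios matter.
_BACKGROUND = SpectralModel.from_elements(
    {"C_Ka": 6.0, "O_Ka": 1.0}, continuum_scale=1.5e-3, decay_ev=2500.0
)
_INSULIN = SpectralModel.from_elements(
    {"C_Ka": 2.0, "N_Ka": 3.0, "S_Ka": 2.5, "O_Ka": 0.5}, continuum_scale=8e-4
)
_GLUCAGON = SpectralModel.from_elements(
    {"C_Ka": 2.0, "N_Ka": 3.5, "S_Ka": 0.6, "O_Ka": 0.5}, continuum_scale=8e-4
)
_CHROMATIN = SpectralModel.from_elements(
    {"C_Ka": 1.5, "N_Ka": 2.0, "P_Ka": 3.0, "O_Ka": 0.8}, continuum_scale=8e-4
)
_MEMBRANE = SpectralModel.from_elements(
    {"C_Ka": 1.5, "Os_Ma": 3.0, "Fe_La": 1.0, "Fe_Ka": 0.8}, continuum_scale=1e-3
)
_PP_GHRELIN = SpectralModel.from_elements(
    {"C_Ka": 2.0, "N_Ka": 2.5, "S_Ka": 1.2, "P_Ka": 1.2}, continuum_scale=8e-4
)
_EXOCRINE = SpectralModel.from_elements(
    {"C_Ka": 2.5, "N_Ka": 1.5, "S_Ka": 3.5, "Cl_Ka": 0.8}, continuum_scale=8e-4
)


def default_phantom(
    shape: tuple[int, int] = (128, 128),
    counts_per_pixel_per_frame: float = 250.0,
    n_frames: int = 20,
    seed: int = 0,
    energy: EnergyAxis | None = None,
) -> PhantomSpec:
    """Four foreground classes + background, mimicking a tissue scene:
    granule disks of two classes, a nuclear ellipse, membrane bands."""
    if energy is None:
        energy = default_energy_axis()
    r, c = shape

    def sc(v: float) -> int:  # scale scene coordinates to the grid
        return int(round(v * r / 128.0))

    structures = (
        Structure("insulin", Geometry("disk", {"center": (sc(30), sc(30)), "radius": sc(12)}), _INSULIN, 0.95),
        Structure("insulin2", Geometry("disk", {"center": (sc(52), sc(22)), "radius": sc(8)}), _INSULIN, 0.95),
        Structure("glucagon", Geometry("disk", {"center": (sc(30), sc(95)), "radius": sc(11)}), _GLUCAGON, 0.95),
        Structure("glucagon2", Geometry("disk", {"center": (sc(55), sc(105)), "radius": sc(7)}), _GLUCAGON, 0.95),
        Structure("chromatin", Geometry("ellipse", {"center": (sc(92), sc(62)), "semi_axes": (sc(18), sc(26))}), _CHROMATIN, 0.9),
        Structure("membrane", Geometry("band", {"r0": sc(8), "r1": sc(12), "c0": sc(4), "c1": sc(124)}), _MEMBRANE, 0.9),
        Structure("membrane2", Geometry("band", {"r0": sc(60), "r1": sc(63), "c0": sc(30), "c1": sc(95)}), _MEMBRANE, 0.9),
    )
    return PhantomSpec(
        shape=shape,
        structures=structures,
        background=_BACKGROUND,
        energy=energy,
        counts_per_pixel_per_frame=counts_per_pixel_per_frame,
        n_frames=n_frames,
        seed=seed,
    )


def five_structure_phantom(
    shape: tuple[int, int] = (160, 160),
    counts_per_pixel_per_frame: float = 250.0,
    n_frames: int = 20,
    seed: int = 0,
    energy: EnergyAxis | None = None,
) -> PhantomSpec:
    """Five spectrally and spatially distinct structures + background, for
    end-to-end detection/segmentation tests (insulin, glucagon, nucleic
    acids, PP/ghrelin, exocrine granules)."""
    if energy is None:
        energy = default_energy_axis()
    r, _ = shape

    def sc(v: float) -> int:
        return int(round(v * r / 160.0))

    structures = (
        Structure("insulin", Geometry("disk", {"center": (sc(35), sc(35)), "radius": sc(16)}), _INSULIN, 0.95),
        Structure("glucagon", Geometry("disk", {"center": (sc(35), sc(120)), "radius": sc(15)}), _GLUCAGON, 0.95),
        Structure("nucleic", Geometry("ellipse", {"center": (sc(115), sc(40)), "semi_axes": (sc(20), sc(24))}), _CHROMATIN, 0.9),
        Structure("pp_ghrelin", Geometry("disk", {"center": (sc(118), sc(118)), "radius": sc(14)}), _PP_GHRELIN, 0.95),
        Structure("exocrine", Geometry("disk", {"center": (sc(78), sc(78)), "radius": sc(12)}), _EXOCRINE, 0.95),
    )
    return PhantomSpec(
        shape=shape,
        structures=structures,
        background=_BACKGROUND,
        energy=energy,
        counts_per_pixel_per_frame=counts_per_pixel_per_frame,
        n_frames=n_frames,
        seed=seed,
    )
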