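"""Spectral-distance convergence as a function of frame accumulation.

Accumulating more scan frames increases per-pixel counts and shrinks the
Poisson relative noise like 1/sqrt(k).  To decide how many frames are enough,
two statistics are tracked against the accumulated frame count k:

* intra-class distance — the mean Euclidean distance of class members from
  the class mean spectrum, divided by the norm of the class mean ("relative"
  normalisation; spectra are first divided by k so counts are comparable
  across frame counts);
* the intra/inter ratio — intra-class distance over the between-class-means
  distance (itself normalised by the norm of the pair midpoint), averaged
  arithmetically over class pairs.

Both conventions are tagged on the output so alternates can be added.  The
curves plateau once extra frames stop improving spectral separability; the
plateau is detected as the first count where the per-step change drops below
a configurable fraction of the curve's initial value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .synthetic import PhantomSpec, render_frames

__all__ = [
    "DistanceCurves",
    "intra_class_distance",
    "inter_class_distance",
    "distance_vs_frames",
    "plateau_frame_count",
    "loglog_slope",
]


@dataclass
class DistanceCurves:
    frame_counts: np.ndarray  # strictly increasing
    intra: dict[str, np.ndarray]  # per class, one value per frame count
    ratio: dict[tuple[str, str], np.ndarray]  # per class pair
    mean_ratio: np.ndarray  # arithmetic mean over pairs
    normalization: str = "intra: /||class mean||; inter: /||pair midpoint||"

    def __post_init__(self) -> None:
        fc = np.asarray(self.frame_counts)
        if fc.ndim != 1 or np.any(np.diff(fc) <= 0):
            raise ValueError("frame_counts must be strictly increasing")

    def mean_intra(self) -> np.ndarray:
        return np.mean([v for v in self.intra.values()], axis=0)


def intra_class_distance(spectra: np.ndarray, n_frames: int = 1) -> float:
    """Relative intra-class spectral distance.

    ``spectra`` is (N >= 2, C): the member spectra of one class at a given
    accumulated frame count.  Spectra are divided by ``n_frames`` (a no-op
    for the ratio, kept so absolute curves are comparable across counts),
    then the mean member-to-mean distance is normalised by the mean norm:

        mean_i ||s_i - mu|| / ||mu||,  mu = mean_i s_i.

    Scale-invariant: multiplying all spectra by any gamma > 0 leaves it
    unchanged.  Returns 0 for identical members; 0 by convention when the
    class mean is the zero spectrum.
    """
    s = np.asarray(spectra, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("need at least 2 member spectra")
    s = s / float(n_frames)
    mu = s.mean(axis=0)
    denom = float(np.linalg.norm(mu))
    if denom == 0:
        return 0.0
    return float(np.mean(np.linalg.norm(s - mu, axis=1)) / denom)


def inter_class_distance(mu_a: np.ndarray, mu_b: np.ndarray, n_frames: int = 1) -> float:
    """Relative distance between two class means:
    ``||mu_a - mu_b|| / ||(mu_a + mu_b)/2||``; symmetric in (a, b) and
    scale-invariant.  0 by convention when the midpoint is zero."""
    a = np.asarray(mu_a, dtype=np.float64) / float(n_frames)
    b = np.asarray(mu_b, dtype=np.float64) / float(n_frames)
    mid = 0.5 * (a + b)
    denom = float(np.linalg.norm(mid))
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(a - b) / denom)


def distance_vs_frames(
    spec: PhantomSpec,
    class_pixels: dict[str, list[tuple[int, int]]],
    frame_counts: list[int],
) -> DistanceCurves:
    """Render per-frame phantoms, accumulate, and evaluate both curves.

    ``class_pixels`` names the member pixels of each class (e.g. interior
    pixels of each ground-truth structure).  Randomness is fixed by the
    phantom's seed; frame j is always drawn from (seed, j), so curves at
    nested frame counts share their frames, as in a real accumulation.
    """
    frame_counts = sorted(set(int(k) for k in frame_counts))
    if frame_counts[0] < 1:
        raise ValueError("frame counts must be >= 1")
    frames = render_frames(spec, frame_counts[-1])
    cum = np.cumsum([f.counts.astype(np.float64) for f in frames], axis=0)

    names = list(class_pixels)
    idx = {
        name: (np.array([p[0] for p in pts]), np.array([p[1] for p in pts]))
        for name, pts in class_pixels.items()
    }
    intra: dict[str, list[float]] = {n: [] for n in names}
    ratio: dict[tuple[str, str], list[float]] = {
        pair: [] for pair in combinations(names, 2)
    }
    for k in frame_counts:
        cube_k = cum[k - 1]
        means = {}
        for name in names:
            rr, cc = idx[name]
            members = cube_k[rr, cc, :]
            intra[name].append(intra_class_distance(members, n_frames=k))
            means[name] = members.mean(axis=0)
        for (a, b) in ratio:
            inter = inter_class_distance(means[a], means[b], n_frames=k)
            pair_intra = 0.5 * (intra[a][-1] + intra[b][-1])
            ratio[(a, b)].append(pair_intra / inter if inter > 0 else np.inf)
    ratio_arr = {p: np.array(v) for p, v in ratio.items()}
    mean_ratio = (
        np.mean([v for v in ratio_arr.values()], axis=0)
        if ratio_arr
        else np.zeros(len(frame_counts))
    )
    return DistanceCurves(
        frame_counts=np.array(frame_counts),
        intra={n: np.array(v) for n, v in intra.items()},
        ratio=ratio_arr,
        mean_ratio=mean_ratio,
    )


def plateau_frame_count(
    frame_counts: np.ndarray, curve: np.ndarray, rel_change: float = 0.05
) -> int | None:
    """First frame count where the per-step change falls below
    ``rel_change`` of the curve's initial value and stays there.

    Returns None if the curve never stabilises within the range.  This is a
    repo convention for reading a plateau off a convergence curve, not a
    universal criterion.
    """
    fc = np.asarray(frame_counts, dtype=float)
    cv = np.asarray(curve, dtype=float)
    if cv.size < 2:
        return None
    ref = abs(cv[0]) if cv[0] != 0 else 1.0
    steps = np.abs(np.diff(cv)) / ref
    for i in range(len(steps)):
        if np.all(steps[i:] < rel_change):
            return int(fc[i + 1])
    return None


def loglog_slope(frame_counts: np.ndarray, curve: np.ndarray) -> float:
    """Least-squares slope of log(curve) vs log(k); ~ -0.5 under Poisson."""
    x = np.log(np.asarray(frame_counts, dtype=float))
    y = np.log(np.asarray(curve, dtype=float))
    return float(np.polyfit(x, y, 1)[0])
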