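"""Radial distribution functions under periodic boundaries, with peak finding.

g(r) is the probability of finding a pair of particles at separation r
relative to a completely random (ideal-gas) arrangement at the same density.
Two normalizations are supported: full 3D (shell volume 4πr²dr, number
density per Å³) and lateral (in-plane xy distances, shell area 2πr·dr,
density per Å²). The lateral mode is the natural choice for trans-bilayer
molecules that share a z-band, where in-plane clustering is the question;
3D suits terminal-group contact distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from bilayerlab.errors import ValidationError
from bilayerlab.trajectory import GroupSpec, Trajectory


@dataclass(frozen=True)
class RDFResult:
    """Binned pair-correlation function.

    ``bin_centers`` in Å; ``g`` dimensionless; ``counts`` the raw pair
    histogram (useful for conservation checks); ``reference_density`` the
    mean ideal-gas density in Å⁻³ (3d) or Å⁻² (lateral).
    """

    bin_centers: np.ndarray
    g: np.ndarray
    mode: str
    n_frames_used: int
    reference_density: float
    counts: np.ndarray

    @property
    def dr(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class PeakSet:
    """Detected local maxima of a smoothed g(r)."""

    positions: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)


def cor_positions(traj: Trajectory, groups: GroupSpec) -> np.ndarray:
    """Per-frame center of each additive's central ring, shape (n_frames, n_mol, 3).

    The centroid is computed with the minimum-image convention relative to
    the first ring atom, so rings straddling a periodic boundary are handled
    correctly; the result is folded back into the primary cell.
    """
    if not groups.additive_molecules:
        raise ValidationError("no additive molecules define cor_ring_atoms")
    n_mol = len(groups.additive_molecules)
    out = np.empty((traj.n_frames, n_mol, 3))
    box = traj.box[:, None, :]
    for m, mol in enumerate(groups.additive_molecules):
        ring = mol.cor_ring_atoms
        pts = traj.positions[:, ring, :]  # (n_frames, n_ring, 3)
        anchor = pts[:, :1, :]
        rel = pts - anchor
        if traj.wrapped:
            rel = rel - box * np.round(rel / box)
        cen = anchor[:, 0, :] + rel.mean(axis=1)
        if traj.wrapped:
            cen = np.mod(cen, traj.box)
        out[:, m, :] = cen
    return out


def _min_image_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray, lateral: bool
) -> np.ndarray:
    """All-pairs minimum-image distances for one frame; shape (n_a, n_b)."""
    ndim = 2 if lateral else 3
    diff = a[:, None, :ndim] - b[None, :, :ndim]
    L = box[:ndim]
    diff -= L * np.round(diff / L)
    return np.sqrt(np.square(diff).sum(axis=2))


def compute_rdf(
    traj: Trajectory,
    points_a: np.ndarray,
    points_b: np.ndarray | None = None,
    r_max: float = 30.0,
    dr: float = 0.2,
    mode: str = "lateral",
    exclude_self: bool | None = None,
) -> RDFResult:
    """Pair correlation between two per-frame point sets.

    ``points_a``/``points_b`` have shape (n_frames, n_points, 3); passing
    the same array (or omitting ``points_b``) gives the single-species g(r)
    with self-pairs excluded. ``exclude_self=True`` additionally removes
    same-index pairs across two different sets — use it when index i of both
    sets belongs to the same molecule (e.g. a molecule's own CH3 vs its own
    CF3), whose intra-molecular separation would contaminate the
    intermolecular structure.
    """
    if dr <= 0:
        raise ValidationError("dr must be > 0")
    if mode not in ("3d", "lateral"):
        raise ValidationError(f"mode must be '3d' or 'lateral', got {mode!r}")
    lateral = mode == "lateral"
    same = points_b is None or points_b is points_a
    if points_b is None:
        points_b = points_a
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape[0] != traj.n_frames or b.shape[0] != traj.n_frames:
        raise ValidationError("point series must have one entry per frame")
    if exclude_self is None:
        exclude_self = same
    ndim = 2 if lateral else 3
    half_min = traj.box[:, :ndim].min() / 2.0
    if r_max > half_min + 1e-9:
        raise ValidationError(
            f"r_max {r_max} Å exceeds half the smallest "
            f"{'lateral ' if lateral else ''}box length {half_min:.3f} Å"
        )
    n_bins = int(round(r_max / dr))
    edges = np.linspace(0.0, n_bins * dr, n_bins + 1)
    counts = np.zeros(n_bins)
    expected = np.zeros(n_bins)
    density_acc = 0.0
    shell = (
        np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        if lateral
        else 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    )
    for f in range(traj.n_frames):
        dist = _min_image_distances(a[f], b[f], traj.box[f], lateral)
        mask = np.ones_like(dist, dtype=bool)
        if exclude_self:
            k = min(dist.shape)
            mask[np.arange(k), np.arange(k)] = False
        d = dist[mask]
        counts += np.histogram(d, bins=edges)[0]
        measure = (
            traj.box[f, 0] * traj.box[f, 1]
            if lateral
            else traj.box[f].prod()
        )
        n_pairs = int(mask.sum())
        expected += n_pairs * shell / measure
        density_acc += b.shape[1] / measure
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    return RDFResult(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        g=g,
        mode=mode,
        n_frames_used=traj.n_frames,
        reference_density=density_acc / traj.n_frames,
        counts=counts,
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Moving average with edge correction (partial windows at the ends)."""
    if window == 1:
        return y.copy()
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def find_peaks(
    rdf: RDFResult,
    smooth_window: int = 5,
    min_prominence: float = 0.1,
    min_count: float = 0.0,
) -> PeakSet:
    """Locate local maxima of the smoothed g(r) above a prominence floor.

    The curve is moving-average smoothed over ``smooth_window`` bins (odd),
    then scanned with a prominence filter; positions are reported at the
    smoothed maximum's bin center, sorted ascending.

    ``min_count`` discards peaks whose smoothed raw pair count falls below
    the floor. At small r the shell measure is tiny, so the ideal-gas
    normalization turns a single chance pair into a large g spike; requiring
    a minimum number of supporting pair observations suppresses that
    shot noise without touching well-sampled structure.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValidationError("smooth_window must be odd and >= 1")
    s = _smooth(rdf.g, smooth_window)
    idx, props = signal.find_peaks(s, prominence=min_prominence)
    if min_count > 0:
        sc = _smooth(rdf.counts, smooth_window)
        keep = sc[idx] >= min_count
        idx = idx[keep]
        props = {k: v[keep] for k, v in props.items()}
    return PeakSet(
        positions=rdf.bin_centers[idx],
        heights=s[idx],
        prominences=props["prominences"],
    )


def first_minimum(
    rdf: RDFResult,
    after: float | None = None,
    smooth_window: int = 5,
    min_prominence: float = 0.1,
) -> float:
    """Position of the first-shell boundary: the g(r) minimum after the first peak.

    With two or more detected peaks this is the lowest smoothed value
    between the first and second peak; with a single peak, the first local
    minimum after it. ``after`` (Å), when given, requires a detected peak
    before that position.
    """
    peaks = find_peaks(rdf, smooth_window=smooth_window, min_prominence=min_prominence)
    if len(peaks) == 0:
        raise ValidationError("no peaks detected; cannot locate a first minimum")
    if after is not None and peaks.positions[0] >= after:
        raise ValidationError(f"no peak detected before {after} Å")
    s = _smooth(rdf.g, smooth_window)
    i0 = int(np.searchsorted(rdf.bin_centers, peaks.positions[0]))
    if len(peaks) >= 2:
        i1 = int(np.searchsorted(rdf.bin_centers, peaks.positions[1]))
        j = i0 + int(np.argmin(s[i0 : i1 + 1]))
        return float(rdf.bin_centers[j])
    minima, _ = signal.find_peaks(-s[i0:])
    if minima.size == 0:
        raise ValidationError("no local minimum after the single detected peak")
    return float(rdf.bin_centers[i0 + minima[0]])
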