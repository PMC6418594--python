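"""Orientation observables and axial (z) structure.

The bilayer normal is the +z axis throughout. Backbone orientation uses two
half-backbone vectors v1 = end_a − COR and v2 = end_b − COR: alpha1 and
alpha2 are their angles to +z, and beta — the bending angle at the central
ring — is the angle between them, so 180° means an unbent (collinear)
backbone. Side-chain orientation is the angle between the vector from a
terminal group to the central ring and +z; 90° means the terminal sits
directly between the leaflets in the bilayer plane.

Axial structure is measured relative to a reference group's center of mass
(the whole system by default) with z = 0 at the bilayer center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from bilayerlab.errors import ValidationError
from bilayerlab.pair_correlation import cor_positions
from bilayerlab.trajectory import GroupSpec, Trajectory, group_com

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class BackboneAngleSeries:
    """Backbone angles per frame and additive molecule (degrees, shape
    (n_frames, n_additives)): tilt of each half-backbone vs the bilayer
    normal (alpha1, alpha2) and the bending angle at the central ring (beta)."""

    alpha1: np.ndarray
    alpha2: np.ndarray
    beta: np.ndarray


@dataclass(frozen=True)
class AngleDistribution:
    """Normalized angle histogram over [0, 180]°; density is probability per degree."""

    bin_centers: np.ndarray
    density: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class DensityProfile:
    """Normalized 1D density along z (probability per Å), bins symmetric about 0."""

    z_bin_centers: np.ndarray
    density: np.ndarray
    group_label: str = ""

    @property
    def bin_width(self) -> float:
        return float(self.z_bin_centers[1] - self.z_bin_centers[0])


def _minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def _angle_deg(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    nv = np.linalg.norm(v, axis=-1)
    nw = np.linalg.norm(w, axis=-1)
    if np.any(nv == 0) or np.any(nw == 0):
        raise ValidationError("zero-length vector in angle computation")
    cosang = np.clip(np.sum(v * w, axis=-1) / (nv * nw), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def backbone_angles(
    traj: Trajectory,
    groups: GroupSpec,
    normal: Sequence[float] = (0.0, 0.0, 1.0),
) -> BackboneAngleSeries:
    """Backbone tilt and bending angles for every additive and frame.

    Both half-backbone vectors are taken with the minimum-image convention,
    so molecules straddling a periodic boundary are measured correctly.
    """
    if not groups.additive_molecules:
        raise ValidationError("no additive molecules defined")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    cor = cor_positions(traj, groups)
    n_mol = len(groups.additive_molecules)
    a1 = np.empty((traj.n_frames, n_mol))
    a2 = np.empty_like(a1)
    beta = np.empty_like(a1)
    box = traj.box
    for m, mol in enumerate(groups.additive_molecules):
        v1 = traj.positions[:, mol.backbone_end_a, :] - cor[:, m, :]
        v2 = traj.positions[:, mol.backbone_end_b, :] - cor[:, m, :]
        if traj.wrapped:
            v1 = _minimum_image(v1, box)
            v2 = _minimum_image(v2, box)
        a1[:, m] = _angle_deg(v1, n[None, :])
        a2[:, m] = _angle_deg(v2, n[None, :])
        beta[:, m] = _angle_deg(v1, v2)
    return BackboneAngleSeries(alpha1=a1, alpha2=a2, beta=beta)


def side_chain_angle(
    traj: Trajectory,
    groups: GroupSpec,
    terminal: str = "ch3",
    normal: Sequence[float] = (0.0, 0.0, 1.0),
) -> np.ndarray:
    """Angle (degrees) between (COR − terminal position) and the bilayer normal.

    ``terminal`` selects the role: "ch3" or "cf3". Shape (n_frames,
    n_additives). 0° means the terminal hangs straight below its ring along
    −z; 90° means it lies in the bilayer plane.
    """
    role = {"ch3": "ch3_terminal", "cf3": "cf3_terminal"}.get(terminal)
    if role is None:
        raise ValidationError(f"terminal must be 'ch3' or 'cf3', got {terminal!r}")
    if not groups.additive_molecules:
        raise ValidationError("no additive molecules defined")
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    cor = cor_positions(traj, groups)
    out = np.empty((traj.n_frames, len(groups.additive_molecules)))
    for m, mol in enumerate(groups.additive_molecules):
        term = traj.positions[:, getattr(mol, role), :]
        v = cor[:, m, :] - term
        if traj.wrapped:
            v = _minimum_image(v, traj.box)
        out[:, m] = _angle_deg(v, n[None, :])
    return out


def angle_histogram(values: np.ndarray, bin_width: float = 2.0) -> AngleDistribution:
    """Normalized histogram of angles over [0, 180]°."""
    v = np.ravel(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValidationError("angle_histogram: no values")
    if np.any(v < 0) or np.any(v > 180):
        raise ValidationError("angles must lie in [0, 180] degrees")
    n_bins = int(np.ceil(180.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    density = counts / (v.size * bin_width)
    return AngleDistribution(bin_centers=0.5 * (edges[:-1] + edges[1:]), density=density)


def z_profile(
    traj: Trajectory,
    group: Sequence[int] | np.ndarray,
    reference: Sequence[int] | np.ndarray,
    bin_width: float = 1.0,
    z_range: float = 34.0,
    group_label: str = "",
) -> DensityProfile:
    """Axial density of a group relative to the reference-group COM z.

    Per frame, each group particle contributes z − z_COM(reference);
    subtracting the reference COM removes collective drift along the normal.
    Bin centers sit at integer multiples of ``bin_width`` so a plane at an
    exact multiple lands mid-bin. Samples beyond ±``z_range`` are dropped;
    the profile is normalized to unit area over the retained samples.
    """
    group = np.atleast_1d(np.asarray(group, dtype=int))
    if group.size == 0:
        raise ValidationError("z_profile: empty group")
    ref_com = group_com(traj, reference)
    dz = (traj.positions[:, group, 2] - ref_com[:, 2:3]).ravel()
    k = int(np.floor(z_range / bin_width + 0.5))
    edges = (np.arange(-k, k + 1) + 0.5) * bin_width  # centers at multiples of bw
    edges = np.concatenate([[-(k + 0.5) * bin_width], edges])
    counts, _ = np.histogram(dz, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValidationError("no samples inside z_range")
    density = counts / (total * bin_width)
    centers = np.arange(-k, k + 1) * bin_width
    return DensityProfile(z_bin_centers=centers, density=density, group_label=group_label)


def bilayer_thickness(headgroup_profile: DensityProfile) -> float:
    """Peak-to-peak bilayer thickness: distance between the density maxima
    of the upper (z > 0) and lower (z < 0) leaflet."""
    z = headgroup_profile.z_bin_centers
    d = headgroup_profile.density
    upper = z > 0
    lower = z < 0
    if not d[upper].any() or not d[lower].any():
        raise ValidationError("headgroup profile has no density on both sides of z=0")
    z_up = z[upper][np.argmax(d[upper])]
    z_lo = z[lower][np.argmax(d[lower])]
    return float(z_up - z_lo)


def midplane_ratio(profile: DensityProfile, center_halfwidth: float = 2.0) -> float:
    """Mean density within |z| ≤ ``center_halfwidth`` relative to the global maximum.

    Quantifies how often a group visits the bilayer midplane compared with
    its preferred location (1.0 for a flat profile, 0.0 for an empty center).
    """
    z = profile.z_bin_centers
    central = np.abs(z) <= center_halfwidth + 1e-12
    peak = profile.density.max()
    if peak == 0:
        return 0.0
    return float(profile.density[central].mean() / peak)


@dataclass(frozen=True)
class FlipEventList:
    """Trans-leaflet flip events of one terminal group.

    ``times`` (ns) mark the frame at which the series enters the opposite
    leaflet band; ``dwell_durations`` are the times between consecutive flips.
    """

    times: np.ndarray
    dwell_durations: np.ndarray

    @property
    def n_events(self) -> int:
        return len(self.times)


def flip_events(
    z_series: np.ndarray,
    dt: float,
    threshold: float = 10.0,
) -> FlipEventList:
    """Detect passages between the leaflet bands z > +threshold and z < −threshold.

    A flip is recorded only when the series reaches the opposite band;
    excursions into the midplane region that return to the same band do not
    count. Dwell durations are the intervals between consecutive flips.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    z = np.asarray(z_series, dtype=float)
    band = np.zeros(z.size, dtype=int)
    band[z > threshold] = 1
    band[z < -threshold] = -1
    times = []
    current = 0
    for i, b in enumerate(band):
        if b == 0:
            continue
        if current != 0 and b == -current:
            times.append(i * dt)
        current = b
    t = np.asarray(times)
    return FlipEventList(times=t, dwell_durations=np.diff(t))
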