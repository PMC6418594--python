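"""Seeded synthetic trajectories with known ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — 2D Brownian lateral motion for the diffusion estimator, trimer
triangles for the pair-correlation peaks, tilted rods for the angle
observables, bilayer slabs for the z-profiles, and a two-state telegraph
process for the transient-cluster timescale — so the whole pipeline can be
validated by parameter recovery without any MD run.

All generators are bit-reproducible for a fixed seed and spec, and their
outputs pass trajectory validation and round-trip through the XYZ writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from bilayerlab.errors import ValidationError
from bilayerlab.trajectory import AdditiveMolecule, GroupSpec, Trajectory

#: 1 × 10⁻¹² m²/s expressed in Å²/ns. The single authoritative conversion
#: constant; used here and by the diffusion reporter, nowhere else.
D_UNIT_IN_A2_PER_NS = 0.01

#: Default nearest- and second-neighbor center spacings of a trimer (Å):
#: two directly adjacent molecules sit ~7 Å apart, the third closes a
#: triangle with ~12 Å to the far partner.
TRIMER_PAIR_DISTANCE = 7.0
TRIMER_THIRD_DISTANCE = 12.0

#: Default terminal-group contact distances (Å): alkyl CH3 carbons touch at
#: ~3 Å, the bulkier perfluorinated CF3 carbons at ~5 Å.
CH3_CONTACT_DISTANCE = 3.0
CF3_CONTACT_DISTANCE = 5.0


def _degenerate_molecule(i: int) -> AdditiveMolecule:
    """Single-point additive: all five roles map to the same particle."""
    return AdditiveMolecule(
        backbone_end_a=i,
        backbone_end_b=i,
        cor_ring_atoms=np.array([i]),
        ch3_terminal=i,
        cf3_terminal=i,
    )


# ---------------------------------------------------------------------------
# 2D Brownian walkers


@dataclass(frozen=True)
class BrownianSpec:
    """Lateral Brownian motion of lipid-like walkers, optionally with a second
    additive-like population diffusing at its own rate in the same cell.

    ``d_true`` / ``d_additive`` are diffusion coefficients in 10⁻¹² m²/s;
    ``drift`` is a collective lateral velocity in Å/ns applied to everything.
    """

    n_walkers: int = 288
    d_true: float = 13.9
    dt: float = 0.1
    n_steps: int = 9800
    box: float = 98.0
    drift: tuple[float, float] = (0.0, 0.0)
    z_plane: float = 0.0
    seed: int = 0
    n_additives: int = 0
    d_additive: float = 0.0

    def __post_init__(self) -> None:
        if self.d_true < 0 or self.d_additive < 0:
            raise ValidationError("diffusion coefficients must be >= 0")
        if self.n_steps < 2:
            raise ValidationError("n_steps must be >= 2")
        if self.box <= 0:
            raise ValidationError("box must be > 0")
        if self.n_walkers < 1:
            raise ValidationError("n_walkers must be >= 1")
        if not (0 <= self.z_plane < self.box):
            raise ValidationError("z_plane must lie inside [0, box)")


def gen_brownian2d(spec: BrownianSpec) -> tuple[Trajectory, GroupSpec]:
    """Generate wrapped 2D Brownian walkers with known diffusivity.

    Per step each walker's x and y advance by independent Gaussians of
    variance 2·D·dt (D converted to Å²/ns) plus drift·dt; z stays at
    ``z_plane``. The first ``n_walkers`` particles form the "lipids" group;
    any second population forms "additives" with degenerate single-point
    roles, so the same fixture feeds both the lipid and the additive branch
    of the diffusion pipeline.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_walkers + spec.n_additives
    sigmas = np.empty(n)
    sigmas[: spec.n_walkers] = np.sqrt(2.0 * spec.d_true * D_UNIT_IN_A2_PER_NS * spec.dt)
    sigmas[spec.n_walkers :] = np.sqrt(
        2.0 * spec.d_additive * D_UNIT_IN_A2_PER_NS * spec.dt
    )
    start = rng.uniform(0.0, spec.box, size=(n, 2))
    steps = rng.standard_normal(size=(spec.n_steps - 1, n, 2)) * sigmas[None, :, None]
    drift = np.asarray(spec.drift, dtype=float) * spec.dt
    steps += drift[None, None, :]
    xy = np.empty((spec.n_steps, n, 2))
    xy[0] = start
    np.cumsum(steps, axis=0, out=steps)
    xy[1:] = start[None] + steps
    pos = np.empty((spec.n_steps, n, 3))
    pos[:, :, :2] = np.mod(xy, spec.box)
    pos[:, :, 2] = spec.z_plane
    traj = Trajectory(
        positions=pos,
        box=np.array([spec.box, spec.box, spec.box]),
        dt=spec.dt,
        wrapped=True,
    )
    groups = {
        "lipids": np.arange(spec.n_walkers),
        "additives": np.arange(spec.n_walkers, n),
        "water": np.empty(0, dtype=int),
    }
    mols = [_degenerate_molecule(i) for i in range(spec.n_walkers, n)]
    return traj, GroupSpec(groups=groups, additive_molecules=mols)


# ---------------------------------------------------------------------------
# trimer cluster frames


@dataclass(frozen=True)
class ClusterTemplate:
    """Geometry of a three-molecule cluster: an isosceles triangle with two
    nearest-neighbor sides of ``pair_distance`` and one ``third_distance``
    base, plus ``n_molecules_outside`` dispersed molecules."""

    pair_distance: float = TRIMER_PAIR_DISTANCE
    third_distance: float = TRIMER_THIRD_DISTANCE
    jitter_sigma: float = 0.0
    n_molecules_outside: int = 3

    def __post_init__(self) -> None:
        if not (self.third_distance >= self.pair_distance > 0):
            raise ValidationError("need third_distance >= pair_distance > 0")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be >= 0")
        if self.third_distance >= 2.0 * self.pair_distance:
            raise ValidationError(
                "triangle inequality violated: third_distance must be < 2*pair_distance"
            )
        if self.n_molecules_outside < 0:
            raise ValidationError("n_molecules_outside must be >= 0")


def gen_cluster_frames(
    template: ClusterTemplate,
    n_frames: int,
    box: float,
    seed: int = 0,
) -> tuple[Trajectory, GroupSpec]:
    """Frames holding one jittered trimer triangle plus dispersed molecules.

    Each frame places a triangle with side lengths (pair, pair, third) at a
    random position and in-plane orientation, adds isotropic Gaussian jitter
    of ``jitter_sigma`` per coordinate, and scatters the outside molecules
    uniformly. All base placements share one z plane (mid-cell). Each point
    is one additive molecule with degenerate single-point roles.
    """
    rng = np.random.default_rng(seed)
    p, t = template.pair_distance, template.third_distance
    # Apex at origin between the two equal sides; base vertices at +-.
    apex_angle = np.arccos((2.0 * p * p - t * t) / (2.0 * p * p))
    tri = np.array(
        [
            [0.0, 0.0],
            [p, 0.0],
            [p * np.cos(apex_angle), p * np.sin(apex_angle)],
        ]
    )
    n_out = template.n_molecules_outside
    n = 3 + n_out
    z0 = box / 2.0
    pos = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        shift = rng.uniform(0.0, box, size=2)
        pos[f, :3, :2] = tri @ rot.T + shift
        pos[f, 3:, :2] = rng.uniform(0.0, box, size=(n_out, 2))
        pos[f, :, 2] = z0
        if template.jitter_sigma > 0:
            pos[f] += rng.normal(0.0, template.jitter_sigma, size=(n, 3))
    pos = np.mod(pos, box)
    traj = Trajectory(
        positions=pos, box=np.array([box, box, box]), dt=1.0, wrapped=True
    )
    spec = GroupSpec(
        groups={"additives": np.arange(n), "lipids": np.empty(0, int)},
        additive_molecules=[_degenerate_molecule(i) for i in range(n)],
    )
    return traj, spec


# ---------------------------------------------------------------------------
# terminal-group contact pairs


@dataclass(frozen=True)
class ContactPairSpec:
    """Point pairs at a fixed contact distance plus uniform background,
    emulating the single contact peak of terminal-group pair correlations."""

    contact_distance: float = CH3_CONTACT_DISTANCE
    jitter_sigma: float = 0.3
    n_pairs: int = 3
    n_background: int = 6

    def __post_init__(self) -> None:
        if self.contact_distance <= 0:
            raise ValidationError("contact_distance must be > 0")
        if self.jitter_sigma < 0:
            raise ValidationError("jitter_sigma must be >= 0")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")


def gen_contact_pairs(
    spec: ContactPairSpec,
    n_frames: int,
    box: tuple[float, float, float] = (98.0, 98.0, 68.0),
    seed: int = 0,
) -> tuple[Trajectory, GroupSpec]:
    """Frames of randomly oriented point pairs at the contact spacing.

    Each pair's axis is drawn uniformly on the sphere; jitter is isotropic
    Gaussian per coordinate. Background points are uniform in the cell.
    The paired points form the "terminals" group; intra-pair separation is
    the only built-in structure, so a 3D g(r) shows one contact peak.
    """
    rng = np.random.default_rng(seed)
    bx = np.asarray(box, dtype=float)
    n = 2 * spec.n_pairs + spec.n_background
    pos = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        centers = rng.uniform(0.0, 1.0, size=(spec.n_pairs, 3)) * bx
        # uniform random axis
        v = rng.standard_normal(size=(spec.n_pairs, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        half = 0.5 * spec.contact_distance * v
        pos[f, : spec.n_pairs] = centers + half
        pos[f, spec.n_pairs : 2 * spec.n_pairs] = centers - half
        pos[f, 2 * spec.n_pairs :] = (
            rng.uniform(0.0, 1.0, size=(spec.n_background, 3)) * bx
        )
        if spec.jitter_sigma > 0:
            pos[f, : 2 * spec.n_pairs] += rng.normal(
                0.0, spec.jitter_sigma, size=(2 * spec.n_pairs, 3)
            )
    pos = np.mod(pos, bx)
    traj = Trajectory(positions=pos, box=bx, dt=1.0, wrapped=True)
    gspec = GroupSpec(
        groups={
            "terminals": np.arange(2 * spec.n_pairs),
            "background": np.arange(2 * spec.n_pairs, n),
        }
    )
    return traj, gspec


# ---------------------------------------------------------------------------
# tilted/bent backbone rods


@dataclass(frozen=True)
class RodSpec:
    """Three-point backbone rod: arm a tilted ``alpha1`` from +z, arm b
    tilted ``alpha2`` from −z, bending angle ``beta`` at the central ring.

    With coplanar same-side arms (the default, ``relative_azimuth=0``) the
    bend is beta = 180 − (alpha1 + alpha2); 180° means unbent. ``noise_sigma``
    perturbs each polar angle with a Gaussian (degrees).
    """

    alpha1: float = 20.0
    alpha2: float = 20.0
    arm_length: float = 14.0
    noise_sigma: float = 0.0
    relative_azimuth: float = 0.0
    beta: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 180.0):
                raise ValidationError(f"{name} must be in [0, 180], got {v}")
        if self.arm_length <= 0:
            raise ValidationError("arm_length must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        expected = self._beta_from_geometry(self.alpha1, self.alpha2, self.relative_azimuth)
        if self.beta is None:
            object.__setattr__(self, "beta", expected)
        elif self.noise_sigma == 0.0 and abs(self.beta - expected) > 1e-6:
            raise ValidationError(
                f"beta={self.beta} inconsistent with alpha1/alpha2 geometry "
                f"(expected {expected:.6f})"
            )

    @staticmethod
    def _beta_from_geometry(a1: float, a2: float, rel_az: float) -> float:
        r1, r2, dphi = np.radians([a1, a2, rel_az])
        v1 = np.array([np.sin(r1), 0.0, np.cos(r1)])
        v2 = np.array([np.sin(r2) * np.cos(dphi), np.sin(r2) * np.sin(dphi), -np.cos(r2)])
        return float(np.degrees(np.arccos(np.clip(v1 @ v2, -1.0, 1.0))))


def gen_rod_frames(
    spec: RodSpec,
    n_frames: int,
    seed: int = 0,
    box: float | None = None,
) -> tuple[Trajectory, GroupSpec]:
    """Frames of one 3-point backbone (end_a, center, end_b) at set tilts.

    The shared azimuth is uniform per frame; polar angles get Gaussian noise
    of ``noise_sigma`` degrees. Roles are populated so the backbone-angle
    observables can consume the output directly.
    """
    rng = np.random.default_rng(seed)
    L = box if box is not None else 4.0 * spec.arm_length
    center = np.array([L / 2.0, L / 2.0, L / 2.0])
    pos = np.empty((n_frames, 3, 3))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_frames)
    a1 = np.radians(spec.alpha1 + rng.normal(0.0, spec.noise_sigma, size=n_frames))
    a2 = np.radians(spec.alpha2 + rng.normal(0.0, spec.noise_sigma, size=n_frames))
    dphi = np.radians(spec.relative_azimuth)
    ua = np.stack(
        [np.sin(a1) * np.cos(phi), np.sin(a1) * np.sin(phi), np.cos(a1)], axis=1
    )
    ub = np.stack(
        [
            np.sin(a2) * np.cos(phi + dphi),
            np.sin(a2) * np.sin(phi + dphi),
            -np.cos(a2),
        ],
        axis=1,
    )
    pos[:, 0] = center + spec.arm_length * ua  # end_a
    pos[:, 1] = center  # central ring
    pos[:, 2] = center + spec.arm_length * ub  # end_b
    traj = Trajectory(
        positions=pos, box=np.array([L, L, L]), dt=1.0, wrapped=True
    )
    mol = AdditiveMolecule(
        backbone_end_a=0,
        backbone_end_b=2,
        cor_ring_atoms=np.array([1]),
        ch3_terminal=0,
        cf3_terminal=2,
    )
    gspec = GroupSpec(
        groups={"additives": np.arange(3), "lipids": np.empty(0, int)},
        additive_molecules=[mol],
    )
    return traj, gspec


# ---------------------------------------------------------------------------
# bilayer slab


@dataclass(frozen=True)
class ZMixtureComponent:
    """One Gaussian component of a terminal-group z distribution."""

    mean: float
    sigma: float
    weight: float


@dataclass(frozen=True)
class BilayerSlabSpec:
    """Headgroup planes at ±thickness/2 with Gaussian roughness; optional
    terminal-group particles drawn from a Gaussian z-mixture.

    z-mixture means are relative to the bilayer center (z = 0); internally
    the slab is stored mid-cell so coordinates stay inside the box.
    """

    thickness: float = 40.0
    roughness_sigma: float = 0.0
    n_lipids_per_leaflet: int = 144
    lateral_box: float = 98.0
    box_height: float = 68.0
    terminal_groups: dict[str, tuple[Sequence[ZMixtureComponent], int]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValidationError("thickness must be > 0")
        if self.roughness_sigma < 0:
            raise ValidationError("roughness_sigma must be >= 0")
        if self.thickness >= self.box_height:
            raise ValidationError("thickness must be smaller than box_height")
        for name, (components, count) in self.terminal_groups.items():
            w = sum(c.weight for c in components)
            if not components or w <= 0:
                raise ValidationError(f"terminal group {name!r}: empty or zero-weight mixture")
            if count < 1:
                raise ValidationError(f"terminal group {name!r}: count must be >= 1")


def gen_bilayer_slab(
    spec: BilayerSlabSpec,
    n_frames: int,
    seed: int = 0,
) -> tuple[Trajectory, GroupSpec]:
    """Frames of headgroup markers at ±thickness/2 plus optional terminal groups.

    Headgroup z values are thickness/2 above/below the slab center with
    Gaussian roughness; lateral placement is uniform. Terminal particles are
    drawn per frame from their z-mixture (component chosen by weight). Groups:
    "headgroups", "upper_leaflet", "lower_leaflet", and one per terminal name.
    """
    rng = np.random.default_rng(seed)
    n_head = 2 * spec.n_lipids_per_leaflet
    names = sorted(spec.terminal_groups)
    n_term = sum(spec.terminal_groups[k][1] for k in names)
    n = n_head + n_term
    zc = spec.box_height / 2.0
    half = spec.thickness / 2.0
    pos = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        pos[f, :, 0] = rng.uniform(0.0, spec.lateral_box, size=n)
        pos[f, :, 1] = rng.uniform(0.0, spec.lateral_box, size=n)
        z_up = zc + half + rng.normal(0.0, spec.roughness_sigma, size=spec.n_lipids_per_leaflet)
        z_lo = zc - half + rng.normal(0.0, spec.roughness_sigma, size=spec.n_lipids_per_leaflet)
        pos[f, : spec.n_lipids_per_leaflet, 2] = z_up
        pos[f, spec.n_lipids_per_leaflet : n_head, 2] = z_lo
        offset = n_head
        for name in names:
            components, count = spec.terminal_groups[name]
            weights = np.array([c.weight for c in components], dtype=float)
            weights /= weights.sum()
            choice = rng.choice(len(components), size=count, p=weights)
            means = np.array([c.mean for c in components])[choice]
            sigmas = np.array([c.sigma for c in components])[choice]
            pos[f, offset : offset + count, 2] = zc + means + rng.normal(size=count) * sigmas
            offset += count
    box = np.array([spec.lateral_box, spec.lateral_box, spec.box_height])
    pos = np.mod(pos, box)
    traj = Trajectory(positions=pos, box=box, dt=1.0, wrapped=True)
    groups = {
        "headgroups": np.arange(n_head),
        "upper_leaflet": np.arange(spec.n_lipids_per_leaflet),
        "lower_leaflet": np.arange(spec.n_lipids_per_leaflet, n_head),
        "all": np.arange(n),
    }
    offset = n_head
    for name in names:
        count = spec.terminal_groups[name][1]
        groups[name] = np.arange(offset, offset + count)
        offset += count
    gspec = GroupSpec(groups=groups, headgroup_atoms=np.arange(n_head))
    return traj, gspec


# ---------------------------------------------------------------------------
# two-state telegraph process


@dataclass(frozen=True)
class TelegraphSpec:
    """Stationary two-state Markov chain with autocorrelation e-folding time
    ``tau`` (ns) and stationary on-probability ``p_on``, sampled every ``dt``."""

    tau: float = 100.0
    p_on: float = 0.5
    dt: float = 0.1
    n_steps: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")
        if not (0.0 < self.p_on < 1.0):
            raise ValidationError("p_on must be in (0, 1)")
        if self.dt >= self.tau:
            raise ValidationError("dt >= tau: the chain would be undersampled")
        if self.n_steps < 2:
            raise ValidationError("n_steps must be >= 2")


def gen_telegraph(spec: TelegraphSpec) -> np.ndarray:
    """Sample a stationary two-state telegraph indicator series.

    The continuous-time rates are split as k_on = p_on/tau, k_off =
    (1−p_on)/tau, so the lag-t autocorrelation is exp(−t/tau) exactly.
    The discrete chain uses the matching per-step switch probabilities
    p(0→1) = p_on·(1−λ), p(1→0) = (1−p_on)·(1−λ) with λ = exp(−dt/tau),
    starts from the stationary distribution, and is simulated by geometric
    holding times (the discrete chain is memoryless, so the first holding
    time is geometric as well).
    """
    lam = np.exp(-spec.dt / spec.tau)
    p01 = spec.p_on * (1.0 - lam)
    p10 = (1.0 - spec.p_on) * (1.0 - lam)
    rng = np.random.default_rng(spec.seed)
    states = np.empty(spec.n_steps, dtype=np.int8)
    s = int(rng.random() < spec.p_on)
    pos = 0
    while pos < spec.n_steps:
        p_switch = p10 if s == 1 else p01
        if p_switch <= 0.0:
            run = spec.n_steps - pos
        else:
            run = int(rng.geometric(p_switch))
        run = min(run, spec.n_steps - pos)
        states[pos : pos + run] = s
        pos += run
        s = 1 - s
    return states
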