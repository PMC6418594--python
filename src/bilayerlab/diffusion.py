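"""Lateral self-diffusion from mean squared displacement.

The MSD is computed over all (or strided) time origins after subtracting the
collective motion of a reference group (typically the lipid ensemble), and
the diffusion coefficient follows from the Einstein relation

    D = slope(MSD) / (2 d),

with d = 2 for in-plane lateral diffusion. Uncertainties come from splitting
the trajectory into contiguous blocks and quoting three times the standard
error of the block estimates.

D is reported in 10⁻¹² m²/s; MSD curves and slopes stay in Å² and Å²/ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from bilayerlab.errors import ValidationError
from bilayerlab.synthetic import D_UNIT_IN_A2_PER_NS
from bilayerlab.trajectory import Trajectory, subtract_com_motion


@dataclass(frozen=True)
class MSDCurve:
    """Mean squared displacement per lag time.

    ``lags`` in ns (starting at 0), ``msd`` in Å², ``n_pairs`` the number of
    (particle, origin) pairs averaged at each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.msd[0] != 0.0:
            raise ValidationError("msd at zero lag must be 0")
        if np.any(np.diff(self.lags) <= 0):
            raise ValidationError("lags must be strictly increasing")
        if np.any(np.diff(self.n_pairs) > 0):
            raise ValidationError("n_pairs must be non-increasing in lag")


@dataclass(frozen=True)
class DiffusionEstimate:
    """Fitted diffusion coefficient with block-based uncertainty.

    ``d_value`` and ``d_uncertainty`` in 10⁻¹² m²/s; the uncertainty is
    three times the standard error of the mean over trajectory blocks (0 for
    a single fit). ``slope`` (Å²/ns) and ``intercept`` (Å²) describe the
    ordinary least-squares line over ``fit_window`` (ns).
    """

    d_value: float
    d_uncertainty: float
    fit_window: tuple[float, float]
    slope: float
    intercept: float
    r_squared: float
    dimensionality: int
    metadata: dict = field(default_factory=dict)


def _msd_all_origins(x: np.ndarray, m_max: int) -> np.ndarray:
    """MSD over all time origins via the FFT autocorrelation identity.

    ``x`` has shape (n_frames, n_particles, n_dims). Returns the per-lag MSD
    averaged over particles, shape (m_max + 1,).
    """
    n, p, dims = x.shape
    fsize = 2 * n
    f = np.fft.rfft(x, n=fsize, axis=0)
    acf = np.fft.irfft(f * f.conj(), n=fsize, axis=0)[:n]  # (n, p, dims)
    s2 = acf.sum(axis=2)  # sum over dims -> (n, p)
    d = np.square(x).sum(axis=2)  # (n, p)
    # S1[m] = sum_{k=m}^{n-1} D_k + sum_{k=0}^{n-1-m} D_k, per particle
    csum = np.concatenate([np.zeros((1, p)), np.cumsum(d, axis=0)])  # (n+1, p)
    total = csum[-1]
    m = np.arange(n)[:, None]
    tail = total[None, :] - csum[:-1, :]  # sum_{k=m}^{n-1}
    head = csum[n - m[:, 0], :]  # sum_{k=0}^{n-1-m}
    counts = (n - m).astype(float)
    msd_pp = (tail + head - 2.0 * s2) / counts
    return msd_pp[: m_max + 1].mean(axis=1)


def _msd_strided(x: np.ndarray, m_max: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[0]
    msd = np.zeros(m_max + 1)
    n_origins = np.zeros(m_max + 1, dtype=int)
    n_origins[0] = len(range(0, n, stride))
    for m in range(1, m_max + 1):
        origins = np.arange(0, n - m, stride)
        d = x[origins + m] - x[origins]
        msd[m] = np.square(d).sum(axis=2).mean()
        n_origins[m] = origins.size
    return msd, n_origins


def compute_msd(
    traj: Trajectory,
    group: Sequence[int] | np.ndarray,
    reference: Sequence[int] | np.ndarray,
    max_lag: float | None = None,
    origin_stride: int = 1,
    lateral: bool = True,
    group_label: str = "",
) -> MSDCurve:
    """Multiple-time-origin MSD of a group with reference-COM correction.

    The reference group's center-of-mass motion is subtracted first, so any
    collective drift (water layer, whole-system translation) cancels. With
    ``lateral`` only x and y enter the displacement. ``max_lag`` (ns)
    defaults to half the trajectory length.
    """
    if traj.wrapped:
        raise ValidationError("compute_msd requires an unwrapped trajectory; call unwrap() first")
    group = np.atleast_1d(np.asarray(group, dtype=int))
    if group.size == 0:
        raise ValidationError("compute_msd: empty group")
    corrected = subtract_com_motion(traj, reference)
    dims = slice(0, 2) if lateral else slice(0, 3)
    x = corrected.positions[:, group, dims]
    if max_lag is None:
        max_lag = (traj.n_frames - 1) * traj.dt / 2.0
    m_max = int(round(max_lag / traj.dt))
    if m_max > traj.n_frames - 1:
        raise ValidationError(
            f"max_lag {max_lag} ns exceeds trajectory span "
            f"{(traj.n_frames - 1) * traj.dt} ns"
        )
    if origin_stride == 1:
        msd = _msd_all_origins(np.ascontiguousarray(x), m_max)
        msd[0] = 0.0
        n_origins = traj.n_frames - np.arange(m_max + 1)
    else:
        msd, n_origins = _msd_strided(x, m_max, origin_stride)
    lags = np.arange(m_max + 1) * traj.dt
    return MSDCurve(
        lags=lags,
        msd=msd,
        n_pairs=n_origins * group.size,
        group_label=group_label,
    )


def fit_diffusion(
    curve: MSDCurve,
    fit_window: tuple[float, float],
    d: int = 2,
) -> DiffusionEstimate:
    """Einstein-relation fit: OLS line on MSD(t) inside ``fit_window`` (ns).

    d_value = slope / (2 d), converted from Å²/ns to 10⁻¹² m²/s.
    """
    t0, t1 = fit_window
    sel = (curve.lags >= t0) & (curve.lags <= t1)
    if sel.sum() < 5:
        raise ValidationError(
            f"fit window [{t0}, {t1}] ns contains only {int(sel.sum())} lag points (need >= 5)"
        )
    res = stats.linregress(curve.lags[sel], curve.msd[sel])
    d_value = res.slope / (2.0 * d) / D_UNIT_IN_A2_PER_NS
    return DiffusionEstimate(
        d_value=float(d_value),
        d_uncertainty=0.0,
        fit_window=(float(t0), float(t1)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        dimensionality=d,
        metadata={"n_points": int(sel.sum()), "group_label": curve.group_label},
    )


def block_diffusion(
    traj: Trajectory,
    group: Sequence[int] | np.ndarray,
    reference: Sequence[int] | np.ndarray,
    n_blocks: int = 5,
    fit_window: tuple[float, float] | None = None,
    d: int = 2,
    lateral: bool = True,
    max_lag: float | None = None,
    origin_stride: int = 1,
) -> DiffusionEstimate:
    """Block-averaged diffusion coefficient with 3-sigma uncertainty.

    The trajectory is split into ``n_blocks`` contiguous equal spans; MSD and
    Einstein fit run per block. The estimate is the block mean, and the
    uncertainty is quoted as three times the standard error of that mean.
    ``fit_window`` defaults to 10–50% of ``max_lag``; ``max_lag`` defaults
    to half a block span.
    """
    if traj.wrapped:
        raise ValidationError("block_diffusion requires an unwrapped trajectory; call unwrap() first")
    if n_blocks < 3:
        raise ValidationError("n_blocks must be >= 3")
    block_len = traj.n_frames // n_blocks
    if block_len < 2:
        raise ValidationError("trajectory too short for the requested number of blocks")
    span = (block_len - 1) * traj.dt
    if max_lag is None:
        max_lag = span / 2.0
    if fit_window is None:
        fit_window = (0.1 * max_lag, 0.5 * max_lag)
    if fit_window[1] > span:
        raise ValidationError(
            f"block span {span} ns shorter than fit window end {fit_window[1]} ns"
        )
    estimates = []
    for b in range(n_blocks):
        sub = Trajectory(
            positions=traj.positions[b * block_len : (b + 1) * block_len],
            box=traj.box[b * block_len : (b + 1) * block_len],
            dt=traj.dt,
            wrapped=False,
        )
        curve = compute_msd(
            sub, group, reference, max_lag=min(max_lag, span),
            origin_stride=origin_stride, lateral=lateral,
        )
        estimates.append(fit_diffusion(curve, fit_window, d=d))
    values = np.array([e.d_value for e in estimates])
    mean = float(values.mean())
    if n_blocks > 1:
        unc = 3.0 * float(values.std(ddof=1)) / np.sqrt(n_blocks)
    else:
        unc = 0.0
    slopes = np.array([e.slope for e in estimates])
    return DiffusionEstimate(
        d_value=mean,
        d_uncertainty=unc,
        fit_window=estimates[0].fit_window,
        slope=float(slopes.mean()),
        intercept=float(np.mean([e.intercept for e in estimates])),
        r_squared=float(np.mean([e.r_squared for e in estimates])),
        dimensionality=d,
        metadata={
            "n_blocks": n_blocks,
            "block_values": values.tolist(),
            "uncertainty_convention": "3 * std(block estimates) / sqrt(n_blocks)",
        },
    )
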