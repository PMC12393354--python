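"""Local streamline tracking through an orientation volume.

Both propagation rules advance a streamline with fixed-step Euler
integration through the trilinearly interpolated axis field:

* deterministic — each step follows the interpolated fiber axis,
  sign-aligned with the previous direction; same seed, same trajectory.
* probabilistic — each step direction is drawn from a von Mises-Fisher
  distribution with concentration ``kappa`` about that axis, modelling
  orientational uncertainty; draws whose turning angle exceeds
  ``max_angle`` are rejected and redrawn (up to 20 times).

Tracking is bidirectional from each seed, terminates when the interpolated
FA falls below ``fa_stop_threshold`` or the point leaves the grid, and
discards streamlines shorter than ``min_length``.  Seeds are placed
uniformly at random inside every voxel whose FA exceeds
``fa_seed_threshold`` (``seeds_per_voxel`` per voxel); the seed layout
depends only on ``rng_seed``, never on the tracking mode, so deterministic
and probabilistic runs of the same volume consume identical seed sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .phantom import OrientationVolume

__all__ = [
    "TrackingParams",
    "Tractogram",
    "EmptySeedMaskError",
    "interpolate_field",
    "propagate",
    "generate_tractogram",
]


class EmptySeedMaskError(ValueError):
    """No voxel passes the FA seeding threshold."""


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters (lengths in mm, angles in degrees)."""

    mode: str = "deterministic"
    step_size: float = 0.5
    fa_seed_threshold: float = 0.15
    fa_stop_threshold: float = 0.15
    seeds_per_voxel: int = 8
    max_angle: float = 30.0
    kappa: float = 30.0
    min_length: float = 10.0
    max_length: float = 250.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("deterministic", "probabilistic"):
            raise ValueError(f"unknown tracking mode {self.mode!r}")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        for name in ("fa_seed_threshold", "fa_stop_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.max_angle < 90.0):
            raise ValueError("max_angle must lie in (0, 90) degrees")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0.0 <= self.min_length < self.max_length):
            raise ValueError("require 0 <= min_length < max_length")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")


@dataclass
class Tractogram:
    """A collection of streamlines in world-mm RAS space with provenance."""

    streamlines: list[np.ndarray]
    seed_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    space: str = "world-mm-RAS"
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)


_MAX_REJECTION_TRIES = 20
_CORNERS = np.array(list(itertools.product((0, 1), repeat=3)))


class _FieldSampler:
    """Vectorized trilinear sampling of FA and sign-aligned axis blending.

    Axis fields are antipodally symmetric, so each of the 8 neighbouring
    axes is sign-flipped to have a nonnegative dot product with a reference
    direction before blending; naive blending would cancel near sign flips.
    """

    def __init__(self, volume: OrientationVolume):
        self.fa = volume.fa
        self.axes = volume.orientations
        self.shape = np.asarray(volume.fa.shape, dtype=np.float64)
        inv = np.linalg.inv(volume.affine)
        self._inv_rot = inv[:3, :3].T.copy()
        self._inv_off = inv[:3, 3].copy()

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self._inv_rot + self._inv_off

    def sample(
        self, pts: np.ndarray, reference: Optional[np.ndarray]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (direction, fa, in_bounds) at world points ``pts`` (N, 3).

        ``reference`` is an (N, 3) array of directions used for sign
        alignment, or None to align against the stored canonical axis of
        the nearest voxel.  Out-of-bounds points are flagged; their values
        come from edge-clamped coordinates and must be ignored.
        """
        v = self.world_to_voxel(pts)
        in_bounds = np.all((v >= -0.5) & (v <= self.shape - 0.5), axis=1)
        vc = np.clip(v, 0.0, self.shape - 1.0)
        i0 = np.minimum(np.floor(vc), self.shape - 2.0).astype(np.int64)
        f = vc - i0

        if reference is None:
            nearest = np.rint(vc).astype(np.int64)
            reference = self.axes[nearest[:, 0], nearest[:, 1], nearest[:, 2]]

        fa_out = np.zeros(len(pts))
        blend = np.zeros((len(pts), 3))
        for corner in _CORNERS:
            w = np.prod(np.where(corner, f, 1.0 - f), axis=1)
            ii = i0 + corner
            fa_out += w * self.fa[ii[:, 0], ii[:, 1], ii[:, 2]]
            ax = self.axes[ii[:, 0], ii[:, 1], ii[:, 2]]
            dots = np.sum(ax * reference, axis=1)
            blend += (w * np.where(dots < 0, -1.0, 1.0))[:, None] * ax
        norms = np.linalg.norm(blend, axis=1)
        degenerate = norms < 1e-8
        if degenerate.any():
            blend[degenerate] = reference[degenerate]
            norms = np.linalg.norm(blend, axis=1)
        direction = blend / norms[:, None]
        return direction, fa_out, in_bounds


def interpolate_field(
    volume: OrientationVolume,
    point: np.ndarray,
    reference_dir: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Sample the interpolated (direction, fa) at one world-mm point."""
    sampler = _FieldSampler(volume)
    pt = np.asarray(point, dtype=np.float64)[None, :]
    ref = None if reference_dir is None else np.asarray(reference_dir, dtype=np.float64)[None, :]
    direction, fa, in_bounds = sampler.sample(pt, ref)
    if not in_bounds[0]:
        raise _OutOfBounds(point)
    return direction[0], float(fa[0])


class _OutOfBounds(Exception):
    """Internal signal: a sample point left the grid (caught by the propagator)."""


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw unit vectors from a von Mises-Fisher distribution on S^2.

    Uses the exact inverse-CDF for the cosine w of the polar angle in three
    dimensions (density proportional to exp(kappa * w)).
    """
    m = len(mu)
    u = rng.random(m)
    # w = 1 + log(u + (1-u) e^{-2 kappa}) / kappa, numerically safe for large kappa
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    v = rng.standard_normal((m, 3))
    v -= np.sum(v * mu, axis=1, keepdims=True) * mu
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    v /= norms
    return w[:, None] * mu + np.sqrt(np.maximum(1.0 - w * w, 0.0))[:, None] * v


def _draw_step_dirs(
    mu: np.ndarray,
    prev: np.ndarray,
    kappa: float,
    cos_max: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """vMF draws about ``mu`` constrained to within max_angle of ``prev``.

    Rejected draws are redrawn up to the try cap; unresolved entries are
    reported as failures (the propagator terminates those streamlines).
    """
    out = mu.copy()
    ok = np.zeros(len(mu), dtype=bool)
    pending = np.arange(len(mu))
    for _ in range(_MAX_REJECTION_TRIES):
        draw = _sample_vmf(mu[pending], kappa, rng)
        acc = np.sum(draw * prev[pending], axis=1) >= cos_max
        hit = pending[acc]
        out[hit] = draw[acc]
        ok[hit] = True
        pending = pending[~acc]
        if len(pending) == 0:
            break
    return out, ok


def _track_half(
    sampler: _FieldSampler,
    seeds: np.ndarray,
    init_dirs: np.ndarray,
    active0: np.ndarray,
    params: TrackingParams,
    rng: Optional[np.random.Generator],
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate one half of every streamline in lockstep.

    Returns ``(points, counts)`` with ``points`` of shape
    ``(N, max_steps, 3)`` and ``counts[i]`` the number of valid points for
    seed ``i``.
    """
    n = len(seeds)
    max_steps = int(np.floor((params.max_length / 2.0) / params.step_size))
    out = np.zeros((n, max_steps, 3))
    counts = np.zeros(n, dtype=np.int64)

    pos = seeds.copy()
    d_prev = init_dirs.copy()
    axis_cur = init_dirs.copy()  # interpolated axis at pos, aligned with d_prev
    active = active0.copy()
    cos_max = np.cos(np.deg2rad(params.max_angle))
    deterministic = params.mode == "deterministic"

    for _ in range(max_steps):
        ia = np.flatnonzero(active)
        if len(ia) == 0:
            break
        if deterministic:
            d_new = axis_cur[ia]
            ok = np.sum(d_new * d_prev[ia], axis=1) >= cos_max
        else:
            d_new, ok = _draw_step_dirs(axis_cur[ia], d_prev[ia], params.kappa, cos_max, rng)
        active[ia[~ok]] = False
        ia = ia[ok]
        if len(ia) == 0:
            break
        d_new = d_new[ok]

        p_new = pos[ia] + params.step_size * d_new
        axis_next, fa_new, in_bounds = sampler.sample(p_new, d_new)
        alive = in_bounds & (fa_new >= params.fa_stop_threshold)
        active[ia[~alive]] = False
        ia = ia[alive]
        if len(ia) == 0:
            break
        out[ia, counts[ia]] = p_new[alive]
        counts[ia] += 1
        pos[ia] = p_new[alive]
        d_prev[ia] = d_new[alive]
        axis_cur[ia] = axis_next[alive]
    return out, counts


def _assemble(
    seeds: np.ndarray,
    half_fwd: tuple[np.ndarray, np.ndarray],
    half_bwd: tuple[np.ndarray, np.ndarray],
    params: TrackingParams,
) -> tuple[list[np.ndarray], np.ndarray]:
    pts_f, n_f = half_fwd
    pts_b, n_b = half_bwd
    keep_min = params.min_length / params.step_size
    streamlines: list[np.ndarray] = []
    kept = []
    for k in range(len(seeds)):
        if n_f[k] + n_b[k] < keep_min:
            continue
        parts = [pts_b[k, : n_b[k]][::-1], seeds[k][None, :], pts_f[k, : n_f[k]]]
        streamlines.append(np.vstack(parts))
        kept.append(k)
    return streamlines, np.asarray(kept, dtype=np.int64)


def propagate(
    volume: OrientationVolume,
    seed: np.ndarray,
    params: TrackingParams,
    rng: Optional[np.random.Generator] = None,
) -> Optional[np.ndarray]:
    """Track one streamline bidirectionally from a world-mm seed point.

    Returns the ``(n_points, 3)`` point array, or None when the result is
    shorter than ``min_length``.  Deterministic mode never touches ``rng``.
    """
    params.validate()
    if params.mode == "probabilistic" and rng is None:
        rng = np.random.default_rng(params.rng_seed)
    sampler = _FieldSampler(volume)
    seed = np.asarray(seed, dtype=np.float64)[None, :]
    axis0, fa0, in_bounds = sampler.sample(seed, None)
    if not in_bounds[0] or fa0[0] <= params.fa_seed_threshold:
        raise ValueError(
            f"seed FA {fa0[0]:.3f} does not exceed the seeding threshold "
            f"{params.fa_seed_threshold}"
        )
    active0 = np.ones(1, dtype=bool)
    fwd = _track_half(sampler, seed, axis0, active0, params, rng)
    bwd = _track_half(sampler, seed, -axis0, active0, params, rng)
    streamlines, _ = _assemble(seed, fwd, bwd, params)
    return streamlines[0] if streamlines else None


def generate_tractogram(volume: OrientationVolume, params: TrackingParams) -> Tractogram:
    """Whole-volume tracking: seed every supra-threshold voxel and propagate.

    ``seeds_per_voxel`` points are drawn uniformly inside each voxel with
    FA above ``fa_seed_threshold``.  The seed layout and (in probabilistic
    mode) the directional draws are fully determined by ``rng_seed``.
    """
    params.validate()
    mask = volume.fa > params.fa_seed_threshold
    voxels = np.argwhere(mask)
    if len(voxels) == 0:
        raise EmptySeedMaskError(
            f"no voxel has FA > {params.fa_seed_threshold}; nothing to seed"
        )

    seed_ss, track_ss = np.random.SeedSequence(params.rng_seed).spawn(2)
    seed_rng = np.random.default_rng(seed_ss)
    track_rng = np.random.default_rng(track_ss)

    offsets = seed_rng.uniform(-0.5, 0.5, size=(len(voxels), params.seeds_per_voxel, 3))
    seeds_vox = (voxels[:, None, :] + offsets).reshape(-1, 3)
    seeds = seeds_vox @ volume.affine[:3, :3].T + volume.affine[:3, 3]

    sampler = _FieldSampler(volume)
    axis0, fa0, in_bounds = sampler.sample(seeds, None)
    active0 = in_bounds & (fa0 > params.fa_seed_threshold)

    rng = track_rng if params.mode == "probabilistic" else None
    fwd = _track_half(sampler, seeds, axis0, active0, params, rng)
    bwd = _track_half(sampler, seeds, -axis0, active0, params, rng)
    streamlines, kept = _assemble(seeds, fwd, bwd, params)

    return Tractogram(
        streamlines=streamlines,
        seed_indices=kept,
        provenance={
            "params": params,
            "n_seed_voxels": int(len(voxels)),
            "n_seeds": int(len(seeds)),
        },
    )
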