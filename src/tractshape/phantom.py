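"""Synthetic single-bundle fiber phantoms and subject cohorts.

The tracking substrate is an :class:`OrientationVolume`: a voxel grid that
stores, per voxel, one fiber *axis* (a sign-ambiguous unit vector) and an
FA-like scalar in [0, 1].  A curved, arcuate-like bundle is modelled as a
circular arc of radius ``arc_radius`` lying in the x-y plane, thickened into
a tube of radius ``tube_radius``.  Voxels inside the tube carry the local
arc tangent (optionally perturbed by voxelwise angular noise) and a high FA;
all other voxels carry a constant axis and an FA below the usual 0.15
tracking threshold, so streamlines never leave the tube.

A *cohort* is a set of per-subject phantoms obtained by seeded geometric
perturbation of a base phantom (arc radius, arc center, tube thickness,
angular-noise level), emulating inter-subject anatomical variability.  A
noise-free *model bundle* laid deterministically along the base arc plays
the role of a standard-space atlas bundle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "PhantomSpec",
    "CohortSpec",
    "OrientationVolume",
    "arc_centerline",
    "build_phantom",
    "sample_cohort",
    "model_bundle",
]

#: Conventional FA cutoff separating "trackable" from background tissue.
FA_TRACKING_THRESHOLD = 0.15

#: Axis assigned to voxels outside the tube.  Tracking never follows it
#: because the out-of-tube FA sits below the stopping threshold.
_BACKGROUND_AXIS = np.array([1.0, 0.0, 0.0])


class GeometryError(ValueError):
    """The requested arc/tube does not fit inside the voxel grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic single-bundle phantom.

    Lengths are in millimetres, ``arc_span`` in radians, ``angular_noise_sd``
    in degrees.  The voxel-to-world affine is ``diag(voxel_size)`` with voxel
    centers at integer indices (RAS world convention).
    """

    grid_shape: tuple[int, int, int] = (52, 34, 12)
    voxel_size: float = 1.0
    arc_radius: float = 15.0
    arc_center: tuple[float, float, float] = (26.0, 5.0, 6.0)
    arc_span: tuple[float, float] = (0.0, float(np.pi))
    tube_radius: float = 2.5
    fa_inside: float = 0.8
    fa_outside: float = 0.05
    angular_noise_sd: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if any(int(n) < 4 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape components must be >= 4, got {self.grid_shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.arc_radius <= 0:
            raise ValueError("arc_radius must be positive")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if not (0.0 <= self.fa_outside < FA_TRACKING_THRESHOLD):
            raise ValueError(
                f"fa_outside must lie in [0, {FA_TRACKING_THRESHOLD}), got {self.fa_outside}"
            )
        if not (FA_TRACKING_THRESHOLD <= self.fa_inside <= 1.0):
            raise ValueError(
                f"fa_inside must lie in [{FA_TRACKING_THRESHOLD}, 1], got {self.fa_inside}"
            )
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be >= 0")
        if self.arc_span[0] == self.arc_span[1]:
            raise ValueError("arc_span must cover a nonzero angle")
        lo, hi = _tube_bbox(self)
        avail_lo, avail_hi = _grid_bounds(self)
        tol = 1e-6  # mm; sub-nanometre excursions are float noise, not geometry
        for ax, name in enumerate("xyz"):
            if lo[ax] < avail_lo[ax] - tol or hi[ax] > avail_hi[ax] + tol:
                raise GeometryError(
                    f"arc tube extends to [{lo[ax]:.2f}, {hi[ax]:.2f}] mm on the "
                    f"{name}-axis but the grid covers [{avail_lo[ax]:.2f}, "
                    f"{avail_hi[ax]:.2f}] mm"
                )

    @property
    def affine(self) -> np.ndarray:
        A = np.diag([self.voxel_size] * 3 + [1.0])
        return A


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of subjects derived from a base phantom by seeded jitter.

    Subject ``i`` uses the child seed ``master_seed * 10**6 + i``; jitters
    are additive Gaussian draws from that child seed, clamped back to a
    valid geometry where necessary.
    """

    n_subjects: int
    base: PhantomSpec
    radius_jitter_sd: float = 0.0
    center_jitter_sd: float = 0.0
    tube_jitter_sd: float = 0.0
    noise_jitter_sd: float = 0.0
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("radius_jitter_sd", "center_jitter_sd", "tube_jitter_sd", "noise_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.base.validate()


@dataclass
class OrientationVolume:
    """Voxel grid of fiber axes plus an FA-like scalar map.

    ``orientations`` has shape ``(X, Y, Z, 3)`` with unit-norm rows stored
    under a canonical sign (nonnegative x-component; ties broken by
    nonnegative y, then z).  ``affine`` maps voxel indices to world mm.
    """

    orientations: np.ndarray
    fa: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=np.float64)
        self.fa = np.asarray(self.fa, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.orientations.ndim != 4 or self.orientations.shape[-1] != 3:
            raise ValueError("orientations must have shape (X, Y, Z, 3)")
        if self.fa.shape != self.orientations.shape[:3]:
            raise ValueError("fa and orientations grids disagree")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fa.shape

    def save(self, fa_path, orientations_path) -> None:
        """Write FA (3D) and orientations (4D, last axis 3) as NIfTI-1."""
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.fa.astype(np.float32), self.affine), str(fa_path))
        nib.save(
            nib.Nifti1Image(self.orientations.astype(np.float32), self.affine),
            str(orientations_path),
        )

    @classmethod
    def load(cls, fa_path, orientations_path) -> "OrientationVolume":
        import nibabel as nib

        fa_img = nib.load(str(fa_path))
        ori_img = nib.load(str(orientations_path))
        vol = cls(
            orientations=np.asarray(ori_img.dataobj, dtype=np.float64),
            fa=np.asarray(fa_img.dataobj, dtype=np.float64),
            affine=fa_img.affine,
        )
        # float32 storage denormalizes the axes slightly; restore unit norm
        norms = np.linalg.norm(vol.orientations, axis=-1, keepdims=True)
        vol.orientations = vol.orientations / np.where(norms == 0, 1.0, norms)
        return vol


def _grid_bounds(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """World-mm extent of the full voxel grid (voxel edges, not centers)."""
    n = np.asarray(spec.grid_shape, dtype=float)
    half = 0.5 * spec.voxel_size
    return np.full(3, -half), (n - 1) * spec.voxel_size + half


def _tube_bbox(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    pts = arc_centerline(spec.arc_radius, spec.arc_center, spec.arc_span, 512)
    lo = pts.min(axis=0) - spec.tube_radius
    hi = pts.max(axis=0) + spec.tube_radius
    return lo, hi


def arc_centerline(
    radius: float,
    center: Sequence[float],
    span: tuple[float, float],
    n_points: int,
) -> np.ndarray:
    """Points on a circular arc in the x-y plane, equally spaced in angle.

    Returns an ``(n_points, 3)`` array in increasing-angle order.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if span[0] == span[1]:
        raise ValueError("span must cover a nonzero angle")
    a, b = sorted(span)
    phi = np.linspace(a, b, int(n_points))
    center = np.asarray(center, dtype=np.float64)
    pts = np.empty((len(phi), 3))
    pts[:, 0] = center[0] + radius * np.cos(phi)
    pts[:, 1] = center[1] + radius * np.sin(phi)
    pts[:, 2] = center[2]
    return pts


def canonical_axes(v: np.ndarray) -> np.ndarray:
    """Flip axes to the canonical sign: x >= 0, ties broken by y then z."""
    v = np.asarray(v, dtype=np.float64)
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    flip = (x < 0) | ((x == 0) & ((y < 0) | ((y == 0) & (z < 0))))
    return np.where(flip[..., None], -v, v)


def _arc_tangents_and_distance(
    spec: PhantomSpec, pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from ``pts`` to the arc and the tangent of the nearest arc point.

    The nearest point on a finite planar arc is either the radial projection
    (when the point's azimuth falls inside the span) or one of the two arc
    endpoints; both cases are handled analytically.
    """
    center = np.asarray(spec.arc_center)
    d = pts - center
    rho = np.hypot(d[:, 0], d[:, 1])
    a, b = sorted(spec.arc_span)
    phi = np.arctan2(d[:, 1], d[:, 0])
    # wrap azimuth into [a, a + 2*pi)
    phi = a + np.mod(phi - a, 2.0 * np.pi)
    in_span = phi <= b

    dist = np.empty(len(pts))
    tangent = np.empty((len(pts), 3))

    dist[in_span] = np.hypot(rho[in_span] - spec.arc_radius, d[in_span, 2])
    tangent[in_span] = np.stack(
        [-np.sin(phi[in_span]), np.cos(phi[in_span]), np.zeros(in_span.sum())], axis=1
    )

    out = ~in_span
    if out.any():
        ends = np.stack(
            [
                center + spec.arc_radius * np.array([np.cos(t), np.sin(t), 0.0])
                for t in (a, b)
            ]
        )
        d_ends = np.linalg.norm(pts[out, None, :] - ends[None, :, :], axis=2)
        nearest = np.argmin(d_ends, axis=1)
        dist[out] = d_ends[np.arange(out.sum()), nearest]
        end_tangents = np.stack(
            [np.array([-np.sin(t), np.cos(t), 0.0]) for t in (a, b)]
        )
        tangent[out] = end_tangents[nearest]
    return dist, tangent


def build_phantom(spec: PhantomSpec) -> OrientationVolume:
    """Rasterize a phantom spec into an :class:`OrientationVolume`.

    In-tube voxels receive ``fa_inside`` and the arc tangent at the nearest
    centerline point, perturbed by a rotation whose angle is drawn from
    ``N(0, angular_noise_sd)`` about a random axis perpendicular to the
    tangent (seeded by ``rng_seed``).  Identical spec + seed produces a
    bit-identical volume.
    """
    spec.validate()
    nx, ny, nz = (int(n) for n in spec.grid_shape)
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    centers = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3) * spec.voxel_size

    dist, tangent = _arc_tangents_and_distance(spec, centers)
    in_tube = dist <= spec.tube_radius

    axes = np.tile(_BACKGROUND_AXIS, (len(centers), 1))
    fa = np.full(len(centers), float(spec.fa_outside))
    fa[in_tube] = spec.fa_inside

    t = tangent[in_tube]
    if spec.angular_noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        m = len(t)
        alpha = np.deg2rad(rng.normal(0.0, spec.angular_noise_sd, size=m))
        # random unit vector perpendicular to each tangent
        u = rng.standard_normal((m, 3))
        u -= np.sum(u * t, axis=1, keepdims=True) * t
        norms = np.linalg.norm(u, axis=1, keepdims=True)
        # a degenerate draw (u parallel to t) is measure-zero; guard anyway
        bad = norms[:, 0] < 1e-12
        if bad.any():
            u[bad] = np.cross(t[bad], _BACKGROUND_AXIS)
            u[bad] += 1e-9  # avoid exact zero when t is the background axis
            norms = np.linalg.norm(u, axis=1, keepdims=True)
        u /= norms
        t = t * np.cos(alpha)[:, None] + u * np.sin(alpha)[:, None]
        t /= np.linalg.norm(t, axis=1, keepdims=True)
    axes[in_tube] = t
    axes = canonical_axes(axes)

    return OrientationVolume(
        orientations=axes.reshape(nx, ny, nz, 3),
        fa=fa.reshape(nx, ny, nz),
        affine=spec.affine,
    )


def _clamp_to_grid(spec: PhantomSpec) -> PhantomSpec:
    """Shift/shrink a jittered spec so that its tube stays inside the grid."""
    tol = 1e-9
    for _ in range(16):
        lo, hi = _tube_bbox(spec)
        avail_lo, avail_hi = _grid_bounds(spec)
        viol = (avail_lo - lo > tol) | (hi - avail_hi > tol)
        if not viol.any():
            return spec
        # a tube (nearly) as wide as the grid cannot be fixed by shifting:
        # shrink the arc until every violating axis has real slack
        width_excess = ((hi - lo) - (avail_hi - avail_lo))[viol].max()
        if width_excess > -1e-6:
            new_r = spec.arc_radius - 0.5 * float(width_excess) - 1e-6
            if new_r <= 0:
                raise GeometryError("arc cannot be shrunk to fit the grid")
            spec = dataclasses.replace(spec, arc_radius=new_r)
        else:
            # center the bbox inside the grid on violating axes only; with
            # slack available this resolves each axis in one step
            shift = np.where(viol, 0.5 * ((avail_lo + avail_hi) - (lo + hi)), 0.0)
            center = np.asarray(spec.arc_center) + shift
            spec = dataclasses.replace(spec, arc_center=tuple(center))
    raise GeometryError("failed to clamp jittered arc into the grid")


def sample_cohort(cohort: CohortSpec) -> list[PhantomSpec]:
    """Draw per-subject phantom specs from a cohort description.

    Reproducible from ``master_seed`` alone: subject ``i``'s jitters come
    from the child seed ``master_seed * 10**6 + i``, which is also installed
    as the subject's ``rng_seed``.
    """
    cohort.validate()
    specs = []
    for i in range(cohort.n_subjects):
        child_seed = cohort.master_seed * 1_000_000 + i
        rng = np.random.default_rng(child_seed)
        d_radius = rng.normal(0.0, cohort.radius_jitter_sd) if cohort.radius_jitter_sd else 0.0
        d_center = (
            rng.normal(0.0, cohort.center_jitter_sd, size=3)
            if cohort.center_jitter_sd
            else np.zeros(3)
        )
        d_tube = rng.normal(0.0, cohort.tube_jitter_sd) if cohort.tube_jitter_sd else 0.0
        d_noise = rng.normal(0.0, cohort.noise_jitter_sd) if cohort.noise_jitter_sd else 0.0

        base = cohort.base
        tube = base.tube_radius + d_tube
        if tube <= 0:
            raise ValueError(
                f"subject {i}: tube_radius jittered to {tube:.3f} mm (must stay > 0); "
                "reduce tube_jitter_sd"
            )
        spec = dataclasses.replace(
            base,
            arc_radius=max(base.arc_radius + d_radius, 2.0 * tube),
            arc_center=tuple(np.asarray(base.arc_center) + d_center),
            tube_radius=tube,
            angular_noise_sd=max(base.angular_noise_sd + d_noise, 0.0),
            rng_seed=child_seed,
        )
        spec = _clamp_to_grid(spec)
        spec.validate()
        specs.append(spec)
    return specs


def model_bundle(spec: PhantomSpec, n_streamlines: int, n_points: int = 100) -> list[np.ndarray]:
    """Noise-free reference bundle laid deterministically along the arc.

    Streamlines are copies of the centerline offset on a deterministic
    lattice (concentric rings) within the tube cross-section; the first
    streamline is the centerline itself.  The result is independent of
    ``angular_noise_sd`` and ``rng_seed``, playing the role of a
    standard-space atlas bundle.
    """
    spec.validate()
    if n_streamlines < 1:
        raise ValueError("n_streamlines must be >= 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    offsets = [(0.0, 0.0)]
    ring = 0
    while len(offsets) < n_streamlines:
        ring += 1
        for j in range(6 * ring):
            offsets.append((ring, 2.0 * np.pi * j / (6 * ring)))
            if len(offsets) == n_streamlines:
                break
    n_rings = max(ring, 1)
    radial_step = 0.9 * spec.tube_radius / n_rings

    a, b = sorted(spec.arc_span)
    phi = np.linspace(a, b, int(n_points))
    center = np.asarray(spec.arc_center)
    cos_phi, sin_phi = np.cos(phi), np.sin(phi)

    bundle = []
    for k, off in zip(range(n_streamlines), offsets):
        if k == 0:
            dr, dz = 0.0, 0.0
        else:
            ring_idx, ang = off
            dr = ring_idx * radial_step * np.cos(ang)
            dz = ring_idx * radial_step * np.sin(ang)
        pts = np.empty((len(phi), 3))
        pts[:, 0] = center[0] + (spec.arc_radius + dr) * cos_phi
        pts[:, 1] = center[1] + (spec.arc_radius + dr) * sin_phi
        pts[:, 2] = center[2] + dz
        bundle.append(pts)
    return bundle
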