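"""Simplified streamline-based linear registration.

Aligns a moving bundle to a static bundle by minimizing a symmetric
streamline-distance cost (mean minimum MDF in both directions) over a
rigid (6 dof), similarity (7 dof, isotropic scale) or full affine (12 dof)
parameterization, with a derivative-free optimizer.  The cost is
piecewise-smooth because of the min/flip operations in MDF, so Powell's
method is used rather than a gradient scheme.

This is an instrumental stand-in for full streamline-based registration
(progressive, cluster-centroid based); it is sufficient to place synthetic
subject bundles in the model-bundle space before shape comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .metrics import Bundle, _bundle_array, mdf_matrix

__all__ = [
    "AffineTransform",
    "RegistrationResult",
    "apply_affine",
    "registration_cost",
    "register",
]

_DOF = {"rigid": 6, "similarity": 7, "affine": 12}


@dataclass
class AffineTransform:
    """A 4x4 homogeneous world-mm transform."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-9):
            raise ValueError("bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self o other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def save(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.17g")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(path))


@dataclass
class RegistrationResult:
    transform: AffineTransform
    cost: float
    cost_identity: float
    improved: bool
    dof: str
    n_evaluations: int


def apply_affine(B: Bundle, T: AffineTransform) -> list[np.ndarray]:
    """Map every point of every streamline through ``T``."""
    return [T.transform_points(s) for s in B]


def registration_cost(static: Bundle, moving: Bundle, K: int = 20) -> float:
    """Symmetric bundle distance (mm) used as the registration objective.

    0.5 * [ mean over static of the min MDF to moving
          + mean over moving of the min MDF to static ], on K-point
    resamples.  Zero iff every streamline has an exact (possibly flipped)
    counterpart.
    """
    if len(static) == 0 or len(moving) == 0:
        raise ValueError("registration_cost requires nonempty bundles")
    a = _bundle_array(static, K)
    b = _bundle_array(moving, K)
    D = mdf_matrix(a, b)
    return 0.5 * (float(D.min(axis=1).mean()) + float(D.min(axis=0).mean()))


def _euler_rotation(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation from Euler angles in degrees, applied in x, then y, then z order."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_matrix(x: np.ndarray, dof: str, origin: np.ndarray) -> np.ndarray:
    """Build a 4x4 transform rotating/scaling about ``origin`` then translating."""
    t = x[:3]
    R = _euler_rotation(x[3], x[4], x[5])
    if dof == "rigid":
        A = R
    elif dof == "similarity":
        A = np.exp(x[6]) * R
    else:  # full affine: anisotropic log-scales + upper-triangular shears
        S = np.diag(np.exp(x[6:9]))
        Sh = np.array([[1.0, x[9], x[10]], [0.0, 1.0, x[11]], [0.0, 0.0, 1.0]])
        A = R @ Sh @ S
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = t + origin - A @ origin
    return M


def register(
    static: Bundle,
    moving: Bundle,
    dof: str = "similarity",
    K: int = 20,
    centroid_align: bool = True,
    maxiter: int = 400,
    xtol: float = 1e-4,
    ftol: float = 1e-6,
) -> RegistrationResult:
    """Find the transform mapping ``moving`` onto ``static``.

    Derivative-free (Powell) local minimization of
    :func:`registration_cost`, initialized at identity, optionally with the
    moving centroid pre-aligned to the static centroid (this enlarges the
    basin of attraction and is on by default).  The returned transform is
    never worse than identity; if the optimizer fails to improve, identity
    is returned with ``improved=False``.
    """
    if dof not in _DOF:
        raise ValueError(f"dof must be one of {sorted(_DOF)}, got {dof!r}")
    if len(static) == 0 or len(moving) == 0:
        raise ValueError("register requires nonempty bundles")

    a = _bundle_array(static, K)
    b = _bundle_array(moving, K)
    b_flat = b.reshape(-1, 3)
    origin = b_flat.mean(axis=0)

    def cost_of(M: np.ndarray) -> float:
        moved = (b_flat @ M[:3, :3].T + M[:3, 3]).reshape(b.shape)
        D = mdf_matrix(a, moved)
        return 0.5 * (float(D.min(axis=1).mean()) + float(D.min(axis=0).mean()))

    n_params = {"rigid": 6, "similarity": 7, "affine": 12}[dof]
    x0 = np.zeros(n_params)
    if centroid_align:
        x0[:3] = a.reshape(-1, 3).mean(axis=0) - origin

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return cost_of(_params_to_matrix(x, dof, origin))

    # initial step sizes per parameter class: mm for translations, degrees
    # for rotations, ~5% for log-scales and shears
    steps = [2.0] * 3 + [4.0] * 3
    if dof == "similarity":
        steps += [0.05]
    elif dof == "affine":
        steps += [0.05] * 6
    direc = np.diag(steps)

    res = minimize(
        objective,
        x0,
        method="Powell",
        options={"maxiter": maxiter, "xtol": xtol, "ftol": ftol, "direc": direc},
    )

    cost_identity = cost_of(np.eye(4))
    candidates = [(cost_identity, np.eye(4))]
    candidates.append((objective(x0), _params_to_matrix(x0, dof, origin)))
    candidates.append((float(res.fun), _params_to_matrix(res.x, dof, origin)))
    best_cost, best_M = min(candidates, key=lambda c: c[0])
    improved = best_cost < cost_identity - 1e-12
    if not improved:
        best_cost, best_M = cost_identity, np.eye(4)
    return RegistrationResult(
        transform=AffineTransform(best_M),
        cost=best_cost,
        cost_identity=cost_identity,
        improved=improved,
        dof=dof,
        n_evaluations=n_eval,
    )
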