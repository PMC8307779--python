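"""Low-level vector geometry shared across modules.

All routines are vectorised over a leading frame axis where noted;
coordinates are in Å throughout the package.
"""

from __future__ import annotations

import numpy as np


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Both inputs are (n_atoms, 3) arrays of the atoms used for fitting.
    Returns ``(R, t, rmsd)`` with the proper rotation ``R`` (det = +1,
    reflections corrected via the SVD determinant sign) and translation
    ``t`` such that ``mobile @ R.T + t`` minimises the RMSD to
    ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    P = mobile - mu_m
    Q = reference - mu_r
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    moved = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def is_collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    """True if the point set is degenerate (rank < 2 after centering)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s.size < 2 or s[1] <= tol * max(s[0], 1.0))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle, dihedral) -> np.ndarray:
    """NeRF internal-coordinate placement, vectorised over frames.

    Given positions ``a, b, c`` of shape (..., 3), returns the position
    ``d`` with |c-d| = ``bond``, angle b-c-d = ``angle`` and dihedral
    a-b-c-d = ``dihedral`` (radians; scalars or per-frame arrays).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    angle = np.asarray(angle, float)
    dihedral = np.asarray(dihedral, float)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    angle, dihedral = np.broadcast_arrays(angle, dihedral)
    d_local = np.stack(
        [
            -bond * np.cos(angle),
            bond * np.cos(dihedral) * np.sin(angle),
            bond * np.sin(dihedral) * np.sin(angle),
        ],
        axis=-1,
    )
    return c + (d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n)


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral p0-p1-p2-p3 in radians, vectorised over frames."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.arctan2(y, x)


def angle_at(b, a, c) -> np.ndarray:
    """Angle (radians) at vertex ``a`` formed by points ``b`` and ``c``."""
    b, a, c = (np.asarray(p, float) for p in (b, a, c))
    u = b - a
    v = c - a
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))
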