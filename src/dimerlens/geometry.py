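"""Low-level vector geometry on Calpha traces."""

from __future__ import annotations

import numpy as np

__all__ = ["bond_angles", "pseudo_dihedrals", "kabsch", "rigid_transform"]

_COLLINEAR_EPS = 1e-8


def bond_angles(coords: np.ndarray) -> np.ndarray:
    """Pseudo bond angle (degrees) at every residue of a trace.

    The angle at residue ``i`` is formed by the triplet ``(i-1, i, i+1)``.
    Terminal residues and near-collinear triplets are NaN.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    theta = np.full(n, np.nan)
    if n < 3:
        return theta
    u = coords[:-2] - coords[1:-1]
    v = coords[2:] - coords[1:-1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > _COLLINEAR_EPS) & (nv > _COLLINEAR_EPS)
    cosang = np.full(n - 2, np.nan)
    cosang[ok] = np.einsum("ij,ij->i", u[ok], v[ok]) / (nu[ok] * nv[ok])
    theta[1:-1] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return theta


def pseudo_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Signed pseudo dihedral (degrees) at every residue of a trace.

    The dihedral at residue ``i`` is formed by the quadruplet
    ``(i-1, i, i+1, i+2)``; undefined positions (the first residue and the
    last two) and degenerate quadruplets are NaN.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    tau = np.full(n, np.nan)
    if n < 4:
        return tau
    b0 = coords[1:-2] - coords[0:-3]
    b1 = coords[2:-1] - coords[1:-2]
    b2 = coords[3:] - coords[2:-1]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1_hat = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b1_hat)
    bad = (np.linalg.norm(n1, axis=1) < _COLLINEAR_EPS) | \
          (np.linalg.norm(n2, axis=1) < _COLLINEAR_EPS)
    val = np.degrees(np.arctan2(y, x))
    val[bad] = np.nan
    tau[1:-2] = val
    return tau


def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (proper rotation only).

    Returns ``(R, t)`` with ``mobile @ R.T + t`` closest to ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ct - rot @ cm
    return rot, t


def rigid_transform(coords: np.ndarray, rot: np.ndarray, t: np.ndarray
                    ) -> np.ndarray:
    return coords @ rot.T + t
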