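"""Least-squares rigid superposition (Kabsch), shared by loop closure and
helical-parameter fitting."""

from __future__ import annotations

import numpy as np

from .errors import DegeneracyError


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation R and translation t minimizing ||R x + t - y||.

    Returns ``(R, t, rmsd)``.  Raises :class:`DegeneracyError` for fewer than
    3 points or (near-)collinear point sets, where the rotation is not unique.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise DegeneracyError(f"need >= 3 points for a unique superposition, got {n}")
    xm = X.mean(axis=0)
    ym = Y.mean(axis=0)
    Xc = X - xm
    Yc = Y - ym
    # collinearity: second singular value of the centered cloud ~ 0
    sv = np.linalg.svd(Xc, compute_uv=False)
    if sv[0] > 0 and sv[1] / sv[0] < 1e-9:
        raise DegeneracyError("mobile points are collinear; rotation not unique")
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ym - R @ xm
    resid = Xc @ R.T - Yc
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return R, t, rmsd
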