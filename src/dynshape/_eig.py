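"""Eigendecomposition of sample covariances given as factor matrices.

A sample covariance here always has the form K = B.T @ B for some real
factor B of shape (r, L) (rows are weighted, centered observations). When
r >= L (or L is small) K is formed densely and handed to a symmetric
solver; when r < L the snapshot (Gram / inner-product) trick diagonalizes
the r x r matrix B @ B.T instead, which has the same nonzero spectrum, and
maps its eigenvectors back through B.T.
"""

from __future__ import annotations

import numpy as np

#: relative tolerance defining a "nonzero" eigenvalue
ZERO_TOL = 1e-8


def fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each column's largest-|entry| is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def eig_from_factor(B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-pairs of K = B.T @ B, descending, sign-fixed.

    Returns ``(eigenvalues, vectors)`` with vectors as columns of an
    (L, k) array where k = min(r, L); eigenvalues are clamped at zero.
    """
    B = np.asarray(B, dtype=float)
    r, L = B.shape
    # The snapshot route only pays off with fewer observations than features.
    dense = r >= L

    if dense:
        K = B.T @ B
        vals, vecs = np.linalg.eigh(K)
        vals, vecs = vals[::-1], vecs[:, ::-1]
    else:
        G = B @ B.T
        gvals, gvecs = np.linalg.eigh(G)
        gvals, gvecs = gvals[::-1], gvecs[:, ::-1]
        vals = gvals
        vecs = np.zeros((L, r))
        top = gvals[0] if r else 0.0
        nz = np.where(gvals > max(top, 1.0) * 1e-14)[0]
        # map Gram eigenvectors u back to covariance eigenvectors B.T u / sqrt(lam)
        if nz.size:
            vecs[:, nz] = (B.T @ gvecs[:, nz]) / np.sqrt(gvals[nz])
        # zero-eigenvalue columns carry no direction information; leave as 0
    vals = np.clip(vals, 0.0, None)
    return vals, fix_signs(vecs)


def nonzero_count(eigenvalues: np.ndarray, zero_tol: float = ZERO_TOL) -> int:
    """Number of eigenvalues above the relative tolerance.

    An eigenvalue counts as nonzero iff it exceeds
    ``zero_tol * max(leading eigenvalue, 1)``.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        return 0
    return int(np.sum(ev > zero_tol * max(ev[0], 1.0)))
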