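"""Exact coefficient fitting by Cramer's rule.

This is the white-box core: given M term values sampled at M timepoints, the
coefficients that make the model agree exactly with the targets at those
timepoints are ratios of determinants,

    f_m = det(S_m) / det(Z),

where Z[j, k] is the value of term j at timepoint k (rows = terms, columns =
timepoints) and S_m is Z with row m replaced by the target vector. Every
coefficient is therefore a differentiable, analytically explicit function of
each datum that enters it — no matrix inverse, no iterative solver.

Determinant ratios are formed in log-magnitude + sign space to defer the
under/overflow that plain floating products invite when terms are very small
or numerous.
"""

from __future__ import annotations

import numpy as np

from .errors import SingularDesignError

__all__ = ["determinant", "log_determinant", "cramer_solve", "design_scale"]


def log_determinant(matrix) -> tuple[float, float]:
    """Sign and log-magnitude of the determinant of a square real matrix.

    Returns ``(sign, logabs)`` with ``sign`` in {-1, 0, 1}; ``logabs`` is
    ``-inf`` for a singular matrix. 1x1 and 2x2 matrices use closed forms;
    larger matrices use pivoted row reduction (LU).
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"matrix must be square, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix entries must be finite")
    n = a.shape[0]
    if n == 1:
        d = a[0, 0]
    elif n == 2:
        d = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    else:
        sign, logabs = np.linalg.slogdet(a)
        return float(sign), float(logabs)
    if d == 0.0:
        return 0.0, -np.inf
    return float(np.sign(d)), float(np.log(abs(d)))


def determinant(matrix) -> float:
    """Determinant of a square real matrix (closed form for M <= 2)."""
    sign, logabs = log_determinant(matrix)
    return sign * np.exp(logabs)


def design_scale(Z: np.ndarray) -> float:
    """Hadamard-style magnitude scale: product of row maximum magnitudes.

    Used to make the singularity threshold relative, so rescaling volumes does
    not change whether a draw is classified singular.
    """
    return float(np.prod(np.max(np.abs(Z), axis=1)))


def cramer_solve(Z, Y, rtol: float = 1e-12) -> np.ndarray:
    """Solve Z^T f = Y for the coefficient vector f by Cramer's rule.

    Parameters
    ----------
    Z : (M, M) array
        Design matrix; row j holds term j evaluated at the M timepoints.
    Y : (M,) array
        Target values at the same timepoints.
    rtol : float
        Relative singularity threshold: the solve is rejected when
        ``|det(Z)| <= rtol * prod(row max magnitudes)``.

    Returns
    -------
    (M,) ndarray of coefficients that interpolate the targets exactly at the
    sampled timepoints.

    Raises
    ------
    SingularDesignError
        If the design is singular or nearly so; the caller should resample
        timepoints.
    """
    Z = np.asarray(Z, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise ValueError(f"design must be square, got shape {Z.shape}")
    if Y.shape != (Z.shape[0],):
        raise ValueError(
            f"target length {Y.shape} does not match design dimension {Z.shape[0]}"
        )
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(Y))):
        raise ValueError("design and targets must be finite")

    sign_z, log_z = log_determinant(Z)
    scale = design_scale(Z)
    if sign_z == 0.0 or scale == 0.0 or log_z <= np.log(rtol * scale):
        raise SingularDesignError(
            f"|det Z| = {sign_z * np.exp(log_z):.3e} at or below threshold "
            f"{rtol:.1e} * scale {scale:.3e}; resample timepoints"
        )

    m = Z.shape[0]
    coeffs = np.empty(m)
    for row in range(m):
        S = Z.copy()
        S[row, :] = Y
        sign_s, log_s = log_determinant(S)
        coeffs[row] = sign_s * sign_z * np.exp(log_s - log_z)
    return coeffs
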