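"""Collapse vertex-level source time courses to one ROI time course.

Plain averaging of source dipole time courses within an anatomical label can
cancel signal when dipole orientations differ across the cortical folding
("180-degree phase flips"). The "PCA flip" collapse avoids this: SVD of the
vertex × time matrix, take the first right singular vector, fix its sign
from the first left singular vector, and rescale so the output's mean power
matches the average per-vertex power.
"""

from __future__ import annotations

import warnings

import numpy as np


def pca_flip(data: np.ndarray) -> np.ndarray:
    """Signed, power-matched first principal time course of a vertex bundle.

    Parameters
    ----------
    data : ndarray, shape (n_vertices, n_times)
        Vertex source time courses for one label. Must be finite, with at
        least one vertex and two time samples.

    Returns
    -------
    ndarray, shape (n_times,)
        ``sign * scale * v1`` where ``v1`` is the first right singular
        vector, ``scale = ||s|| / sqrt(n_vertices)`` matches the output's
        mean power to the mean per-vertex power, and ``sign`` is the sign of
        the largest-magnitude element of the first left singular vector
        (a deterministic resolution of the SVD sign ambiguity).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 2:
        raise ValueError("data must be (n_vertices >= 1, n_times >= 2)")
    if not np.all(np.isfinite(data)):
        raise ValueError("vertex time courses must be finite")
    if not data.any():
        warnings.warn("all-zero vertex bundle; returning zeros", stacklevel=2)
        return np.zeros(data.shape[1])
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    scale = np.linalg.norm(s) / np.sqrt(data.shape[0])
    sign = np.sign(u[np.argmax(np.abs(u[:, 0])), 0])
    if sign == 0:
        sign = 1.0
    return sign * scale * vt[0]
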