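"""Simplex geometry for angle-based multicategory learning.

With ``k`` treatments, decision functions live in ``R^{k-1}`` and each
treatment ``j`` is represented by a unit vector ``W_j``, the ``j``-th vertex
of a regular simplex centred at the origin.  The *angle margin* of treatment
``j`` at a point with decision value ``f`` is the inner product
``<W_j, f>``: the larger the margin, the closer ``f`` points toward that
treatment's vertex.  Because the vertices sum to zero, the k margins of any
``f`` sum to zero, so the smallest margin is never positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimplexGeometry", "simplex_vertices", "angle_margins", "order_margins"]


@dataclass(frozen=True)
class SimplexGeometry:
    """Vertices of the regular (k-1)-simplex used to encode k treatments.

    Attributes
    ----------
    k : int
        Number of treatments (>= 2).
    vertices : ndarray of shape (k, k-1)
        Row ``j`` is the unit vector ``W_{j+1}``.  Rows satisfy
        ``<W_i, W_j> = -1/(k-1)`` for ``i != j`` and sum to the zero vector.
    """

    k: int
    vertices: np.ndarray


def simplex_vertices(k: int) -> SimplexGeometry:
    """Construct the k vertices of a regular simplex in ``R^{k-1}``.

    ``W_1 = (k-1)^{-1/2} 1`` and, for ``j >= 2``,
    ``W_j = -(1 + sqrt(k)) (k-1)^{-3/2} 1 + sqrt(k/(k-1)) e_{j-1}``.

    Parameters
    ----------
    k : int
        Number of treatments, at least 2.

    Returns
    -------
    SimplexGeometry
    """
    k = int(k)
    if k < 2:
        raise ValueError(f"need at least 2 treatments, got k={k}")
    d = k - 1
    vertices = np.empty((k, d), dtype=float)
    vertices[0] = d ** -0.5
    base = -(1.0 + np.sqrt(k)) * d ** -1.5
    scale = np.sqrt(k / d)
    for j in range(1, k):
        vertices[j] = base
        vertices[j, j - 1] += scale
    return SimplexGeometry(k=k, vertices=vertices)


def angle_margins(geom: SimplexGeometry, fvals: np.ndarray) -> np.ndarray:
    """Angle margins ``m_j = <W_j, f>`` for one or many decision values.

    Parameters
    ----------
    geom : SimplexGeometry
    fvals : ndarray of shape (k-1,) or (n, k-1)

    Returns
    -------
    ndarray of shape (k,) or (n, k)
        Margins; each row sums to zero up to float error.
    """
    fvals = np.asarray(fvals, dtype=float)
    if fvals.shape[-1] != geom.k - 1:
        raise ValueError(
            f"decision values must have dimension k-1={geom.k - 1}, "
            f"got {fvals.shape[-1]}"
        )
    return fvals @ geom.vertices.T


def order_margins(margins: np.ndarray) -> np.ndarray:
    """Treatment indices (1-based) sorted by margin, largest first.

    Ties are broken by the lower treatment index, so the result is
    deterministic.  Position 0 holds the treatment attaining the largest
    margin ``<W_(1), f>``.
    """
    margins = np.asarray(margins, dtype=float)
    # stable sort on -margins keeps lower indices first among ties
    return np.argsort(-margins, kind="stable") + 1
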