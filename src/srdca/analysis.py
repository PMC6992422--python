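"""Sequence-space PCA and barycentric coordinates for triangle plots."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import LabeledMSA
from .plmdca import one_hot


class DegenerateVarianceError(ValueError):
    pass


@dataclass
class ProjectionResult:
    """2-D principal-component projection of an alignment.

    ``coordinates`` is (B, 2); ``components`` holds the two orthonormal
    loading vectors (2, L·q); ``explained_variance`` the fraction of total
    variance captured by each component; ``labels`` the per-row subfamily
    labels carried over from the alignment.
    """

    coordinates: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    labels: np.ndarray


def pca_projection(msa: LabeledMSA) -> ProjectionResult:
    """Project sequences onto their first two principal components.

    Sequences are one-hot encoded over all q states (gap included),
    mean-centered, and projected onto the top-2 right singular vectors.
    The component sign is fixed by making each component's
    largest-magnitude loading positive, so the projection is fully
    deterministic.
    """
    if msa.B < 3:
        raise ValueError("need at least 3 sequences for a PCA projection")
    X = one_hot(msa.sequences, msa.q).reshape(msa.B, msa.L * msa.q)
    X = X - X.mean(axis=0)
    _, svals, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((svals**2).sum())
    if total <= 0.0 or svals[1] == 0.0:
        raise DegenerateVarianceError("alignment has (near-)constant columns only")
    components = Vt[:2].copy()
    for c in range(2):
        lead = np.argmax(np.abs(components[c]))
        if components[c, lead] < 0:
            components[c] = -components[c]
    coords = X @ components.T
    explained = (svals[:2] ** 2) / total
    return ProjectionResult(
        coordinates=coords,
        components=components,
        explained_variance=explained,
        labels=msa.labels.copy(),
    )


#: equilateral triangle with unit side: vertex for each of the 3 subfamilies
_TRIANGLE_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


def barycentric_coords(omega: np.ndarray) -> np.ndarray:
    """Embed a 3-simplex weight vector into the plane for triangle plots.

    The k-th vertex of a unit-side equilateral triangle corresponds to
    all weight on subfamily k; interior points interpolate affinely.
    """
    omega = np.asarray(omega, dtype=np.float64)
    if omega.shape != (3,):
        raise ValueError("barycentric embedding is defined for K=3 only")
    if omega.min() < -1e-9 or abs(omega.sum() - 1.0) > 1e-9:
        raise ValueError("omega must lie on the unit 3-simplex")
    return omega @ _TRIANGLE_VERTICES
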