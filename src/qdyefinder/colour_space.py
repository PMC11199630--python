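"""Colour-vector algebra.

An N-channel fluorescence intensity profile, after background subtraction
and per-channel scaling, is unit-normalized into a *colour vector*: a point
on the nonnegative orthant of the unit hypersphere.  Hue similarity between
two such profiles is their Euclidean distance ``d``; the clustering
threshold ``Th(d)`` lives on the same scale (maximum possible distance
between two nonnegative unit vectors is sqrt(2)).

Centroids are magnitude-weighted means of member vectors and are *not*
re-projected onto the sphere; distances to centroids use the raw mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColourVector",
    "vector_normalize",
    "colour_distance",
    "weighted_centroid",
]


@dataclass(frozen=True)
class ColourVector:
    """A unit-normalized N-channel colour plus its pre-normalization magnitude.

    ``values`` has unit L2 norm unless the source intensities were all zero,
    in which case both values and magnitude are zero (kept representable so
    quality control can drop such fragments explicitly).
    """

    values: np.ndarray
    magnitude: float
    fragment_id: object = field(default=None, compare=False)
    norm: str = field(default="l2", compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("colour vector must be a 1-D array with >=1 channel")
        if not np.all(np.isfinite(v)):
            raise ValueError("colour vector contains non-finite values")
        if np.any(v < 0):
            raise ValueError("colour vector contains negative values")
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")
        size = np.linalg.norm(v) if self.norm == "l2" else v.sum()
        if self.magnitude > 0 and abs(size - 1.0) > 1e-9:
            raise ValueError(
                f"values must have unit {self.norm} norm when magnitude > 0"
            )

    @property
    def n_channels(self) -> int:
        return self.values.size


def vector_normalize(raw, norm: str = "l2", fragment_id=None) -> ColourVector:
    """Unit-normalize raw channel intensities into a :class:`ColourVector`.

    Parameters
    ----------
    raw : array-like of nonnegative finite reals
        Per-channel intensities (already background-subtracted / scaled).
    norm : {"l2", "l1"}
        Normalization mode.  Default L2 puts vectors on the unit
        hypersphere, the convention used throughout; L1 (simplex) is
        provided as an alternative reading of "vector-normalized".

    An all-zero input is returned as an all-zero vector with magnitude 0
    rather than raising, so downstream QC can flag it.
    """
    v = np.asarray(raw, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("raw intensities must be a 1-D sequence with >=1 element")
    if not np.all(np.isfinite(v)):
        raise ValueError("raw intensities contain non-finite values")
    if np.any(v < 0):
        raise ValueError("raw intensities contain negative values")
    if norm == "l2":
        mag = float(np.linalg.norm(v))
    elif norm == "l1":
        mag = float(v.sum())
    else:
        raise ValueError(f"unknown norm {norm!r}; expected 'l2' or 'l1'")
    if mag == 0.0:
        return ColourVector(np.zeros_like(v), 0.0, fragment_id=fragment_id,
                            norm=norm)
    return ColourVector(v / mag, mag, fragment_id=fragment_id, norm=norm)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, ColourVector) else np.asarray(x, dtype=float)


def colour_distance(a, b) -> float:
    """Euclidean distance ``d`` between two colour vectors (or raw N-tuples)."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    return float(np.linalg.norm(va - vb))


def weighted_centroid(points) -> np.ndarray:
    """Magnitude-weighted mean of colour vectors.

    Weights are the pre-normalization magnitudes, so brighter fragments pull
    the centroid harder.  The result is a plain mean position (norm <= 1);
    it is deliberately not re-normalized.
    """
    pts = list(points)
    if not pts:
        raise ValueError("cannot compute centroid of empty point set")
    vals = np.stack([_values(p) for p in pts])
    w = np.array(
        [p.magnitude if isinstance(p, ColourVector) else 1.0 for p in pts],
        dtype=float,
    )
    total = w.sum()
    if total <= 0:
        raise ValueError("total centroid weight is zero")
    return (w[:, None] * vals).sum(axis=0) / total
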