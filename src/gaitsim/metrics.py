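"""Lp (Minkowski) distances between data vectors and pairwise similarity matrices."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import distance as _sdist

from .errors import DegenerateInputError, DimensionMismatchError, EmptyInputError

__all__ = [
    "DataVector",
    "SimilarityMatrix",
    "lp_distance",
    "pairwise_similarity",
]


@dataclass(frozen=True)
class DataVector:
    """An ``m``-dimensional numeric record with an identifier."""

    id: str
    components: np.ndarray

    def __post_init__(self) -> None:
        comps = np.array(self.components, dtype=float, copy=True)
        if comps.ndim != 1 or comps.size < 1:
            raise ValueError("components must be a 1-d vector of dimension >= 1")
        if not np.all(np.isfinite(comps)):
            raise ValueError("components must be finite")
        comps.flags.writeable = False
        object.__setattr__(self, "components", comps)

    @property
    def dim(self) -> int:
        return self.components.size


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric unit-diagonal matrix of pairwise similarity scores in [0, 1]."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        vals = np.array(self.values, dtype=float, copy=True)
        n = len(ids)
        if vals.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got shape {vals.shape}")
        if len(set(ids)) != n:
            raise ValueError("ids must be unique")
        self._validate(vals)
        vals.flags.writeable = False
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", vals)

    @staticmethod
    def _validate(vals: np.ndarray, atol: float = 1e-9) -> None:
        if not np.allclose(vals, vals.T, atol=atol):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=atol):
            raise ValueError("similarity matrix diagonal must be 1")
        if vals.min() < -atol or vals.max() > 1.0 + atol:
            raise ValueError("similarity values must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def lp_distance(a: DataVector, b: DataVector, p: float = 2.0) -> float:
    """Minkowski distance ``(Σ |a_k − b_k|^p)^(1/p)``; ``p = inf`` is the max-norm.

    ``p`` must satisfy ``p ≥ 1`` (the triangle inequality fails below that).
    The max-norm is the ``p → ∞`` limit, supported as a documented extension.
    """
    if not (p >= 1.0):  # also rejects NaN
        raise ValueError(f"p must be >= 1 (or inf), got {p!r}")
    if a.dim != b.dim:
        raise DimensionMismatchError(
            f"dimension mismatch: {a.id!r} has {a.dim}, {b.id!r} has {b.dim}"
        )
    diff = np.abs(a.components - b.components)
    if math.isinf(p):
        return float(diff.max())
    return float(np.linalg.norm(diff, ord=p))


def pairwise_similarity(
    vectors: Sequence[DataVector],
    p: float = 2.0,
    metric: Callable[[DataVector, DataVector], float] | None = None,
    on_degenerate: str = "raise",
) -> SimilarityMatrix:
    """All-pairs similarity matrix ``s_ij = 1 − d_ij / max_kl d_kl``.

    The normalization is global min-max over the off-diagonal distances (the
    diagonal is forced to 1): the farthest pair scores 0, identical vectors
    score 1. Pass a *metric* callable to override the default Minkowski
    distance of order *p*.

    When every pairwise distance is zero the normalization is undefined;
    ``on_degenerate`` selects between ``"raise"`` (default,
    :class:`~gaitsim.errors.DegenerateInputError`) and ``"ones"`` (return the
    all-ones matrix, defensible since all vectors are identical).
    """
    if len(vectors) < 2:
        raise EmptyInputError("need at least two vectors")
    if on_degenerate not in ("raise", "ones"):
        raise ValueError("on_degenerate must be 'raise' or 'ones'")
    ids = tuple(v.id for v in vectors)
    dims = {v.dim for v in vectors}
    if len(dims) != 1:
        raise DimensionMismatchError(f"vectors have mixed dimensions: {sorted(dims)}")

    if metric is None:
        if not (p >= 1.0):  # also rejects NaN
            raise ValueError(f"p must be >= 1 (or inf), got {p!r}")
        x = np.stack([v.components for v in vectors])
        if math.isinf(p):
            condensed = _sdist.pdist(x, metric="chebyshev")
        else:
            condensed = _sdist.pdist(x, metric="minkowski", p=p)
        dmat = _sdist.squareform(condensed)
    else:
        n = len(vectors)
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dmat[i, j] = dmat[j, i] = float(metric(vectors[i], vectors[j]))

    dmax = dmat.max()
    if dmax == 0.0:
        if on_degenerate == "raise":
            raise DegenerateInputError(
                "all pairwise distances are zero; pass on_degenerate='ones' "
                "to accept the all-ones matrix"
            )
        sims = np.ones_like(dmat)
    else:
        sims = 1.0 - dmat / dmax
    # symmetrize exactly and pin the diagonal before invariant validation
    sims = (sims + sims.T) / 2.0
    np.fill_diagonal(sims, 1.0)
    return SimilarityMatrix(ids, np.clip(sims, 0.0, 1.0))
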