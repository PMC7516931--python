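"""Mutual-information structure inference across variables and layers.

Given samples of tensor-indexed variables X_ih (variable i, layer h), the
dependency structure is estimated by computing the plug-in mutual information
for every unordered vertex pair, masking self-pairs with the bi-delta
(zero exactly when i == j AND h == k — a variable paired with itself in a
*different* layer is a real cross-layer pair and is kept), and thresholding:

    A[i,j,h,k] = 1  iff  I_offdiag[i,j,h,k] > I0        (adjacency)
    W[i,j,h,k] = A[i,j,h,k] * I_offdiag[i,j,h,k]        (strength)

MI is reported in bits.  Continuous columns are discretized by
equal-frequency binning first.  The threshold I0 may be fixed or calibrated
from a permutation null of independence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

DEFAULT_BINS = 10


@dataclass
class SampleTensor:
    """Samples of a tensor-valued variable set: array (samples, vars, layers).

    Discrete data are integer codes; continuous data are reals (discretized
    on demand).  All layers share the sample indexing.
    """

    values: np.ndarray
    var_names: Optional[Tuple[str, ...]] = None
    layer_names: Optional[Tuple[str, ...]] = None
    sample_ids: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("SampleTensor values must be (samples, vars, layers)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]

    def column(self, var: int, layer: int) -> np.ndarray:
        return self.values[:, var, layer]


def _check_hyper(values: np.ndarray) -> None:
    if values.ndim != 4 or values.shape[0] != values.shape[1] or values.shape[2] != values.shape[3]:
        raise ValueError("expected a 4-index array of shape (N, N, L, L)")
    if not np.array_equal(values, values.transpose(1, 0, 3, 2)):
        raise ValueError("hypermatrix must satisfy M[i,j,h,k] == M[j,i,k,h]")
    n, _, l, _ = values.shape
    if np.any(values[np.arange(n), np.arange(n)][:, np.arange(l), np.arange(l)] != 0):
        raise ValueError("hypermatrix bi-diagonal entries M[i,i,h,h] must be zero")


@dataclass
class MIMatrix:
    """Off-diagonal mutual information hypermatrix I[i,j,h,k] in bits."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_hyper(self.values)
        if np.any(self.values < 0):
            raise ValueError("mutual information entries must be non-negative")

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]


@dataclass
class Hypermatrix:
    """4-index neighborhood law: binary adjacency or non-negative strengths."""

    values: np.ndarray
    weighted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_hyper(self.values)
        if not self.weighted and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("unweighted hypermatrix must be binary")
        if np.any(self.values < 0):
            raise ValueError("hypermatrix entries must be non-negative")

    @property
    def n_vars(self) -> int:
        return self.values.shape[0]

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]


def mutual_information(x, y) -> float:
    """Plug-in mutual information of two discrete sample vectors, in bits.

    Marginals are the row/column sums of the empirical joint, so an exactly
    factorizing contingency table yields exactly 0.0.  Summation runs over the
    sorted term values, which makes the estimate bit-for-bit symmetric in its
    arguments.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sample vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    _, cx = np.unique(x, return_inverse=True)
    _, cy = np.unique(y, return_inverse=True)
    kx = int(cx.max()) + 1
    ky = int(cy.max()) + 1
    joint = np.bincount(cx * ky + cy, minlength=kx * ky).reshape(kx, ky) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    terms = joint[mask] * np.log2(joint[mask] / np.outer(px, py)[mask])
    return max(float(np.sort(terms).sum()), 0.0)


def discretize(x, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equal-frequency (quantile) binning of a real sample vector.

    Inputs with at most ``n_bins`` distinct values are relabeled to dense codes
    preserving value order (so already-discrete data pass through).  Otherwise
    samples are ranked (ties broken by stable sample order) and split into
    ``n_bins`` near-equal groups, making the codes invariant under any
    strictly increasing transform.  A constant vector yields a single bin and
    a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x)
    distinct = np.unique(x)
    if distinct.size == 1:
        warnings.warn("constant column: single-bin discretization", stacklevel=2)
        return np.zeros(x.size, dtype=np.int64)
    if distinct.size <= n_bins:
        return np.searchsorted(distinct, x).astype(np.int64)
    order = np.argsort(x, kind="stable")
    codes = np.empty(x.size, dtype=np.int64)
    codes[order] = (np.arange(x.size) * n_bins) // x.size
    return codes


def _column_codes(data: SampleTensor, n_bins: int) -> np.ndarray:
    """Discretized codes for every column, shaped like the sample tensor."""
    values = data.values
    out = np.empty(values.shape, dtype=np.int64)
    continuous = np.issubdtype(values.dtype, np.floating)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(data.n_vars):
            for h in range(data.n_layers):
                col = values[:, i, h]
                if continuous:
                    out[:, i, h] = discretize(col, n_bins)
                else:
                    _, inv = np.unique(col, return_inverse=True)
                    out[:, i, h] = inv
    return out


def mi_matrix(data: SampleTensor, n_bins: int = DEFAULT_BINS) -> MIMatrix:
    """All-pairs off-diagonal MI: I[i,j,h,k] with the bi-diagonal forced to 0.

    Each unordered pair is computed once and mirrored through the symmetry
    I[i,j,h,k] = I[j,i,k,h].  The bi-delta zeroes only exact self-pairs
    (same variable, same layer); a variable duplicated across layers keeps its
    full self-information as a cross-layer entry.
    """
    codes = _column_codes(data, n_bins)
    nv, nl = data.n_vars, data.n_layers
    out = np.zeros((nv, nv, nl, nl))
    pairs = itertools.combinations(
        ((i, h) for h in range(nl) for i in range(nv)), 2
    )
    for (i, h), (j, k) in pairs:
        val = mutual_information(codes[:, i, h], codes[:, j, k])
        out[i, j, h, k] = val
        out[j, i, k, h] = val
    return MIMatrix(out)


def adjacency_hypermatrix(mi: MIMatrix, i0: float) -> Hypermatrix:
    """Heaviside threshold: A[i,j,h,k] = 1 iff I[i,j,h,k] > i0 (strictly)."""
    if i0 < 0:
        raise ValueError("threshold i0 must be non-negative")
    return Hypermatrix((mi.values > i0).astype(float), weighted=False)


def strength_hypermatrix(a: Hypermatrix, mi: MIMatrix) -> Hypermatrix:
    """W = A (elementwise) I: MI weights on the surviving adjacencies."""
    if a.values.shape != mi.values.shape:
        raise ValueError("adjacency and MI hypermatrices have different shapes")
    return Hypermatrix(a.values * mi.values, weighted=True)


def permutation_threshold(
    data: SampleTensor,
    n_perm: int = 100,
    alpha: float = 0.05,
    n_bins: int = DEFAULT_BINS,
    seed=0,
) -> float:
    """MI significance threshold from a permutation null of independence.

    Every column is independently permuted in sample order; the MI of every
    column pair under each permutation forms the null pool, and the
    (1 - alpha) quantile is returned.  Reproducible given ``seed``.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable null")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    codes = _column_codes(data, n_bins)
    rng = np.random.default_rng(seed)
    nv, nl = data.n_vars, data.n_layers
    cols = [(i, h) for h in range(nl) for i in range(nv)]
    null = []
    n = data.n_samples
    for _ in range(n_perm):
        permuted = {c: codes[:, c[0], c[1]][rng.permutation(n)] for c in cols}
        for a, b in itertools.combinations(cols, 2):
            null.append(mutual_information(permuted[a], permuted[b]))
    return float(np.quantile(null, 1.0 - alpha))
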