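"""Eigenspectrum analysis of the processed expression matrix.

The cells x genes log-normalized matrix is decomposed by singular value
decomposition after per-gene mean centering (making the components principal
components).  Left singular vectors order cells along modes of coordinated
transcriptional variation; right singular vectors carry the gene loadings of
each mode; squared singular values divided by the total (squared Frobenius
norm of the centered matrix) give the fraction of transcriptional variance
each component explains.

Variance fractions are always taken against the exact total variance of the
full centered matrix, so they remain correct when only K << rank components
are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import NormalizedMatrix

# below this size the dense LAPACK path is used; above it, seeded randomized
# SVD (verified against the dense path on test sizes)
_DENSE_LIMIT = 600


@dataclass
class SpectralDecomposition:
    """Truncated SVD of the (optionally centered) expression matrix."""

    U: np.ndarray              # cells x K, orthonormal columns
    s: np.ndarray              # K singular values, non-increasing
    V: np.ndarray              # genes x K, orthonormal columns
    total_variance: float      # squared Frobenius norm of the centered matrix
    centered: bool
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    @property
    def K(self) -> int:
        return len(self.s)

    def scores(self, weighted: bool = True) -> np.ndarray:
        """Per-cell component scores: ``U @ diag(s)`` (or plain ``U``)."""
        return self.U * self.s if weighted else self.U.copy()


@dataclass
class VarianceSpectrum:
    """Per-component variance-explained fractions and their running sum."""

    fractions: np.ndarray
    cumulative: np.ndarray


@dataclass
class LinearityFit:
    """OLS fit of variance fraction against component rank."""

    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: the largest-|loading| gene of each
    component is positive; ties resolve to the first such gene."""
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] *= -1.0
            U[:, k] *= -1.0
    return U, V


def decompose(
    X: NormalizedMatrix | np.ndarray,
    K: int,
    center: bool = True,
    seed: int = 0,
    gene_ids=None,
    cell_ids=None,
) -> SpectralDecomposition:
    """Best rank-K decomposition of the expression matrix.

    Genes are mean-centered by default.  Dense LAPACK SVD is used for small
    matrices; larger ones go through seeded randomized SVD.  ``K`` larger
    than the matrix rank is truncated with a warning.
    """
    if isinstance(X, NormalizedMatrix):
        A = X.values
        gene_ids = X.gene_ids
        cell_ids = X.cell_ids
    else:
        A = np.asarray(X, dtype=float)
        if gene_ids is None:
            gene_ids = np.array([f"g{j}" for j in range(A.shape[1])], dtype=object)
        if cell_ids is None:
            cell_ids = np.array([f"c{i}" for i in range(A.shape[0])], dtype=object)
    if not np.isfinite(A).all():
        raise ValueError("non-finite entries in expression matrix")
    n, p = A.shape
    if K > min(n, p):
        raise ValueError(f"K={K} exceeds min(cells, genes)={min(n, p)}")
    if center:
        A = A - A.mean(axis=0, keepdims=True)
    total_variance = float(np.sum(A * A))

    if min(n, p) <= _DENSE_LIMIT:
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        U, s, Vt = U[:, :K], s[:K], Vt[:K]
    else:
        from sklearn.utils.extmath import randomized_svd

        U, s, Vt = randomized_svd(
            A, n_components=K, n_oversamples=15, n_iter=7, random_state=seed
        )
    # drop numerically-zero components beyond the rank
    tol = max(n, p) * np.finfo(float).eps * (s[0] if len(s) and s[0] > 0 else 1.0)
    rank = int(np.sum(s > tol))
    if rank < K:
        warnings.warn(
            f"requested K={K} exceeds matrix rank {rank}; truncating",
            stacklevel=2,
        )
        # keep K components (trailing ones ~0) so shapes match the request,
        # but zero them exactly for reproducibility
        s = s.copy()
        s[rank:] = 0.0
    U, V = _fix_signs(U.copy(), Vt.T.copy())
    return SpectralDecomposition(
        U=U, s=s, V=V, total_variance=total_variance, centered=center,
        cell_ids=np.asarray(cell_ids, dtype=object),
        gene_ids=np.asarray(gene_ids, dtype=object),
    )


def variance_spectrum(d: SpectralDecomposition) -> VarianceSpectrum:
    if d.total_variance <= 0:
        fractions = np.zeros_like(d.s)
    else:
        fractions = d.s**2 / d.total_variance
    return VarianceSpectrum(fractions=fractions, cumulative=np.cumsum(fractions))


def variance_explained(d: SpectralDecomposition, upto: int) -> float:
    """Cumulative variance fraction of the first ``upto`` components."""
    if upto < 1:
        raise ValueError("upto must be >= 1")
    if upto > d.K:
        raise ValueError(f"upto={upto} exceeds retained K={d.K}")
    return float(variance_spectrum(d).cumulative[upto - 1])


def top_loadings(
    d: SpectralDecomposition, component: int, n: int
) -> list[tuple[str, float]]:
    """Genes ranked by |loading| on a component (1-based), signed values.

    Ties in |loading| break lexicographically by gene id.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (1 <= component <= d.K):
        raise ValueError(f"component must be in 1..{d.K}")
    v = d.V[:, component - 1]
    order = sorted(
        range(len(v)), key=lambda j: (-abs(v[j]), str(d.gene_ids[j]))
    )
    return [(str(d.gene_ids[j]), float(v[j])) for j in order[:n]]


def spectrum_linearity(
    v: VarianceSpectrum, start: int = 1, stop: int | None = None
) -> LinearityFit:
    """OLS fit of variance fraction against rank over components
    ``start..stop`` (1-based, inclusive); a decaying spectrum gives a
    negative slope."""
    stop = stop if stop is not None else len(v.fractions)
    if not (1 <= start <= stop <= len(v.fractions)) or stop - start + 1 < 3:
        raise ValueError("window must lie within the spectrum, length >= 3")
    ks = np.arange(start, stop + 1, dtype=float)
    fs = v.fractions[start - 1 : stop]
    if np.allclose(fs, fs[0]):
        return LinearityFit(slope=0.0, intercept=float(fs[0]), r_squared=0.0,
                            degenerate=True)
    res = stats.linregress(ks, fs)
    return LinearityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
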