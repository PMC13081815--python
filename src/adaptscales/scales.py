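"""SCALES: spectral-correlation mutual-information profiling of metadata.

The procedure asks *where in the eigenspectrum* a categorical environmental
variable is encoded.  Left singular vectors are divided into sliding windows
of ``width`` consecutive components (3 by default, stride 1).  For every
sampled pair of cells the spectral correlation within a window is the inner
product of the two cells' projections onto that window's components
(singular-value weighted by default).  Mutual information, in bits, is then
estimated between the correlation values and a binary indicator of whether
the two cells share the same value of the variable, using equal-frequency
binning and the plug-in estimator.  Accumulating per-window MI along the
spectrum gives the MI(CDF) curve; the window at which the normalized curve
first reaches one half defines the variable's *spectral depth*, and sorting
variables by depth yields the adaptive hierarchy.

Significance is judged against a permutation null.  The default
``per_condition`` shuffle permutes the variable's value assignment across
whole sample blocks, preserving within-sample transcriptional structure; a
``per_cell`` mode permutes labels across individual cells.

One pair sample is drawn once per analysis and reused across all windows,
variables and permutations, so curves are directly comparable within a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import SpectralDecomposition

DEFAULT_PAIR_BUDGET = 2_000_000


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """A window of ``width`` consecutive components starting at ``start``
    (1-based)."""

    start: int
    width: int = 3

    def __post_init__(self):
        if self.start < 1 or self.width < 1:
            raise ValueError("start and width must be >= 1")

    @property
    def stop(self) -> int:
        """Last component covered (1-based, inclusive)."""
        return self.start + self.width - 1


def make_windows(
    K: int, width: int = 3, stride: int = 1, max_pc: int = 30
) -> list[WindowSpec]:
    """Sliding windows over components 1..min(K, max_pc)."""
    if width > K:
        raise ValueError(f"width={width} exceeds K={K}")
    last = min(K, max_pc)
    out = []
    start = 1
    while start + width - 1 <= last:
        out.append(WindowSpec(start, width))
        start += stride
    return out


# ---------------------------------------------------------------------------
# Pair sampling
# ---------------------------------------------------------------------------


@dataclass
class PairSample:
    """Unordered distinct cell-index pairs (i < j), at most ``budget``."""

    i: np.ndarray
    j: np.ndarray
    n_cells: int
    budget: int
    seed: int
    exhaustive: bool

    def __post_init__(self):
        if np.any(self.i >= self.j):
            raise ValueError("pairs must satisfy i < j")

    @property
    def n_pairs(self) -> int:
        return len(self.i)


def _linear_to_pair(m: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices over the strict upper triangle (row-major) to
    (i, j) with i < j."""
    m = m.astype(np.float64)
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8 * m)) / 2).astype(np.int64)
    # guard against float rounding at row boundaries
    cum = i * (2 * n - i - 1) // 2
    too_big = cum > m.astype(np.int64)
    i[too_big] -= 1
    cum = i * (2 * n - i - 1) // 2
    j = (m.astype(np.int64) - cum) + i + 1
    return i, j


def sample_pairs(
    n_cells: int, budget: int = DEFAULT_PAIR_BUDGET, seed: int = 0
) -> PairSample:
    """Uniform sample of distinct unordered pairs without replacement;
    exhaustive when the total number of pairs fits the budget."""
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    total = n_cells * (n_cells - 1) // 2
    if total <= budget:
        i, j = np.triu_indices(n_cells, k=1)
        return PairSample(i.astype(np.int64), j.astype(np.int64),
                          n_cells, budget, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    chosen = np.empty(0, dtype=np.int64)
    while len(chosen) < budget:
        need = budget - len(chosen)
        draw = rng.integers(0, total, size=int(need * 1.3) + 16)
        chosen = np.unique(np.concatenate([chosen, draw]))
    # deterministic subset: shuffle the unique pool, take the first `budget`
    rng.shuffle(chosen)
    chosen = np.sort(chosen[:budget])
    i, j = _linear_to_pair(chosen, n_cells)
    return PairSample(i, j, n_cells, budget, seed, exhaustive=False)


# ---------------------------------------------------------------------------
# Spectral correlations
# ---------------------------------------------------------------------------


@dataclass
class SpectralCorrelations:
    """Per-pair inner products of window projections."""

    window: WindowSpec
    values: np.ndarray
    weighting: str      # "scores" (U * s) or "unit" (U alone)
    normalization: str  # "raw" or "cosine"
    n_degenerate: int = 0


def _projections(
    d: SpectralDecomposition, w: WindowSpec, weighting: str
) -> np.ndarray:
    if w.stop > d.K:
        raise ValueError(f"window {w.start}..{w.stop} exceeds K={d.K}")
    if weighting not in ("scores", "unit"):
        raise ValueError("weighting must be 'scores' or 'unit'")
    sl = slice(w.start - 1, w.stop)
    proj = d.U[:, sl]
    if weighting == "scores":
        proj = proj * d.s[sl]
    return proj


def window_correlations(
    d: SpectralDecomposition,
    w: WindowSpec,
    pairs: PairSample,
    weighting: str = "scores",
    normalization: str = "raw",
) -> SpectralCorrelations:
    """Inner product of each sampled cell pair's window projections.

    ``cosine`` divides by the product of projection norms; zero-norm
    (degenerate) cells yield 0 and are counted.
    """
    if normalization not in ("raw", "cosine"):
        raise ValueError("normalization must be 'raw' or 'cosine'")
    proj = _projections(d, w, weighting)
    vals = np.einsum("ij,ij->i", proj[pairs.i], proj[pairs.j])
    n_deg = 0
    if normalization == "cosine":
        norms = np.linalg.norm(proj, axis=1)
        ni, nj = norms[pairs.i], norms[pairs.j]
        denom = ni * nj
        bad = denom == 0
        n_deg = int(bad.sum())
        denom[bad] = 1.0
        vals = vals / denom
        vals[bad] = 0.0
    return SpectralCorrelations(w, vals, weighting, normalization, n_deg)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def mi_from_joint(joint: np.ndarray) -> np.ndarray | float:
    """Plug-in mutual information, in bits, of joint count table(s).

    ``joint`` has shape ``(..., B, C)``; empty cells contribute zero.
    """
    joint = np.asarray(joint, dtype=float)
    n = joint.sum(axis=(-2, -1), keepdims=True)
    scalar = joint.ndim == 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = joint / n
        pb = p.sum(axis=-1, keepdims=True)
        pc = p.sum(axis=-2, keepdims=True)
        ratio = p / (pb * pc)
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, ratio, 1.0)), 0.0)
    mi = terms.sum(axis=(-2, -1))
    mi = np.maximum(mi, 0.0)  # clip float negatives of order eps
    return float(mi) if scalar else mi


def quantile_bins(values: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """Equal-frequency bin assignment; tied values share a bin, so fewer
    than ``n_bins`` distinct bins can result."""
    edges = np.unique(np.quantile(values, np.arange(1, n_bins) / n_bins))
    return np.searchsorted(edges, values, side="right")


def mutual_information(
    values: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 16,
) -> float:
    """Plug-in MI in bits between discretized values and binary labels.

    Values are discretized into at most ``n_bins`` equal-frequency bins.
    Single-class labels or constant values give exactly 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels) or len(values) < 2:
        raise ValueError("values and labels must have equal length >= 2")
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) > 2:
        raise ValueError("labels must contain at most 2 classes")
    if len(classes) < 2:
        return 0.0
    if np.all(values == values[0]):
        return 0.0
    b = quantile_bins(values, n_bins)
    nb = int(b.max()) + 1
    joint = np.bincount(b * 2 + y, minlength=nb * 2).reshape(nb, 2)
    return mi_from_joint(joint)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


@dataclass
class MIProfile:
    """Per-window MI for one variable, with the cumulative MI(CDF) curve."""

    variable: str
    windows: list[WindowSpec]
    mi: np.ndarray
    cumulative: np.ndarray = field(init=False)
    n_bins: int = 16
    weighting: str = "scores"
    normalization: str = "raw"
    null_mean: np.ndarray | None = None
    null_q95: np.ndarray | None = None
    n_perm: int = 0

    def __post_init__(self):
        self.mi = np.asarray(self.mi, dtype=float)
        if np.any(self.mi < 0):
            raise ValueError("negative MI")
        self.cumulative = np.cumsum(self.mi)

    @property
    def cumulative_normalized(self) -> np.ndarray | None:
        total = self.cumulative[-1]
        return self.cumulative / total if total > 0 else None


@dataclass
class NullProfile:
    """Permutation-null MI envelope for one variable."""

    variable: str
    mode: str
    n_perm: int
    null_mi: np.ndarray         # (n_perm, n_windows)
    null_mean: np.ndarray
    null_q95: np.ndarray
    null_max: np.ndarray        # upper edge of the envelope spanned by nulls
    null_cumulative: np.ndarray  # (n_perm, n_windows)


class _WindowBins:
    """Per-window quantile-bin assignment of pair correlation values,
    pre-sorted for fast segmented counting across many label permutations."""

    def __init__(self, values: np.ndarray, n_bins: int):
        b = quantile_bins(values, n_bins)
        self.n_bins = int(b.max()) + 1
        self.bins = b
        self.order = np.argsort(b, kind="stable")
        sorted_b = b[self.order]
        self.seg_starts = np.searchsorted(
            sorted_b, np.arange(self.n_bins), side="left"
        )
        self.counts = np.bincount(b, minlength=self.n_bins)

    def mi_for_labels(self, Y: np.ndarray) -> np.ndarray:
        """MI against each row of binary label matrix ``Y``
        (n_sets, n_pairs) -> (n_sets,)."""
        Ys = Y[:, self.order].astype(np.int64, copy=False)
        n1 = np.add.reduceat(Ys, self.seg_starts, axis=1)
        joint = np.stack([self.counts[None, :] - n1, n1], axis=-1)
        return mi_from_joint(joint)


def _align_labels(
    d: SpectralDecomposition, meta: pd.DataFrame, column: str
) -> np.ndarray:
    if column not in meta.columns:
        raise KeyError(f"metadata has no column {column!r}")
    if meta.index.is_unique and set(d.cell_ids).issubset(set(meta.index)):
        lab = meta.loc[d.cell_ids, column]
    else:
        if len(meta) != len(d.cell_ids):
            raise ValueError("metadata cannot be aligned to decomposition")
        lab = meta[column]
    return lab.to_numpy()


def _window_binsets(d, windows, pairs, weighting, normalization, n_bins):
    return [
        _WindowBins(
            window_correlations(d, w, pairs, weighting, normalization).values,
            n_bins,
        )
        for w in windows
    ]


def mi_profile(
    d: SpectralDecomposition,
    meta: pd.DataFrame,
    variable: str,
    windows: list[WindowSpec] | None = None,
    pairs: PairSample | None = None,
    n_bins: int = 16,
    weighting: str = "scores",
    normalization: str = "raw",
    pair_budget: int = DEFAULT_PAIR_BUDGET,
    seed: int = 0,
) -> MIProfile:
    """Per-window MI between spectral correlations and the same-label
    indicator of ``variable``, with cumulative curve."""
    if pair_budget < 100:
        raise ValueError("pair budget must be at least 100")
    lab = _align_labels(d, meta, variable)
    if len(np.unique(lab)) < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 levels")
    windows = windows or make_windows(d.K)
    pairs = pairs or sample_pairs(d.U.shape[0], pair_budget, seed)
    codes = pd.factorize(lab)[0]
    y = (codes[pairs.i] == codes[pairs.j]).astype(np.int8)
    binsets = _window_binsets(d, windows, pairs, weighting, normalization, n_bins)
    mi = np.array([wb.mi_for_labels(y[None, :])[0] for wb in binsets])
    return MIProfile(variable, list(windows), mi, n_bins, weighting, normalization)


def _sample_blocks(d, meta, variable):
    """Sample index per cell and the per-sample variable value; per-condition
    shuffling requires the variable constant within each sample."""
    samples = _align_labels(d, meta, "sample_id")
    lab = _align_labels(d, meta, variable)
    sample_ids, s_codes = np.unique(samples, return_inverse=True)
    slab = np.empty(len(sample_ids), dtype=object)
    for k in range(len(sample_ids)):
        vals = np.unique(lab[s_codes == k])
        if len(vals) > 1:
            raise ValueError(
                f"variable {variable!r} varies within sample "
                f"{sample_ids[k]!r}; per_condition shuffle is undefined"
            )
        slab[k] = vals[0]
    return s_codes, slab


def null_profile(
    d: SpectralDecomposition,
    meta: pd.DataFrame,
    variable: str,
    windows: list[WindowSpec] | None = None,
    pairs: PairSample | None = None,
    mode: str = "per_condition",
    n_perm: int = 100,
    seed: int = 0,
    n_bins: int = 16,
    weighting: str = "scores",
    normalization: str = "raw",
    permutations: np.ndarray | None = None,
    _binsets: list[_WindowBins] | None = None,
) -> NullProfile:
    """Permutation-null MI envelope.

    ``per_condition`` permutes the per-sample assignment of the variable's
    values across sample blocks; ``per_cell`` permutes labels across
    individual cells.  Explicit ``permutations`` (n_perm x n_units index
    arrays) override the seeded draw, which tests use to force e.g. the
    identity permutation.
    """
    if mode not in ("per_condition", "per_cell"):
        raise ValueError("mode must be 'per_condition' or 'per_cell'")
    if n_perm < 1 and permutations is None:
        raise ValueError("n_perm must be >= 1")
    windows = windows or make_windows(d.K)
    pairs = pairs or sample_pairs(d.U.shape[0], DEFAULT_PAIR_BUDGET, seed)
    binsets = _binsets if _binsets is not None else _window_binsets(
        d, windows, pairs, weighting, normalization, n_bins
    )
    rng = np.random.default_rng(seed)
    if mode == "per_condition":
        s_codes, slab = _sample_blocks(d, meta, variable)
        n_units = len(slab)
        levels, slab_codes = np.unique(slab.astype(str), return_inverse=True)
        counts = np.bincount(slab_codes)
        if np.all(counts == 1):
            warnings.warn(
                "one sample per label level: per-condition permutation "
                "support is trivial", stacklevel=2,
            )
        if permutations is None:
            permutations = np.array(
                [rng.permutation(n_units) for _ in range(n_perm)]
            )
        plab = slab_codes[permutations]            # (n_perm, n_samples)
        si, sj = s_codes[pairs.i], s_codes[pairs.j]
        Y = (plab[:, si] == plab[:, sj]).astype(np.int8)
    else:
        lab = _align_labels(d, meta, variable)
        codes = pd.factorize(lab)[0]
        n_units = len(codes)
        if permutations is None:
            permutations = np.array(
                [rng.permutation(n_units) for _ in range(n_perm)]
            )
        plab = codes[permutations]                 # (n_perm, n_cells)
        Y = (plab[:, pairs.i] == plab[:, pairs.j]).astype(np.int8)
    n_perm = Y.shape[0]
    null_mi = np.column_stack([wb.mi_for_labels(Y) for wb in binsets])
    return NullProfile(
        variable=variable,
        mode=mode,
        n_perm=n_perm,
        null_mi=null_mi,
        null_mean=null_mi.mean(axis=0),
        null_q95=np.quantile(null_mi, 0.95, axis=0),
        null_max=null_mi.max(axis=0),
        null_cumulative=np.cumsum(null_mi, axis=1),
    )


# ---------------------------------------------------------------------------
# Depth and hierarchy
# ---------------------------------------------------------------------------


def spectral_depth(p: MIProfile, threshold: float = 0.5) -> int | None:
    """First window index (1-based) where the normalized cumulative MI
    reaches ``threshold``; ``None`` when the profile carries no MI."""
    cn = p.cumulative_normalized
    if cn is None:
        return None
    return int(np.argmax(cn >= threshold)) + 1


@dataclass
class HierarchyRanking:
    """Variables ordered by spectral depth (shallower = higher priority)."""

    depths: dict
    ordering: list
    ties: list
    undefined: list


def rank_hierarchy(
    profiles: list[MIProfile] | dict[str, MIProfile],
    threshold: float = 0.5,
) -> HierarchyRanking:
    """Order variables by spectral depth ascending; ties break by larger
    total cumulative MI, then by name.  Variables with undefined depth go
    last and are flagged."""
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to rank")
    depths, totals = {}, {}
    for p in profiles:
        depths[p.variable] = spectral_depth(p, threshold)
        totals[p.variable] = float(p.cumulative[-1])
    undefined = [v for v, dep in depths.items() if dep is None]

    def key(v):
        dep = depths[v]
        return (dep if dep is not None else np.inf, -totals[v], v)

    ordering = sorted(depths, key=key)
    ties = []
    by_key = {}
    for v in depths:
        k = (depths[v], totals[v])
        by_key.setdefault(k, []).append(v)
    for k, vs in by_key.items():
        if len(vs) > 1:
            ties.append(sorted(vs))
    return HierarchyRanking(depths, ordering, ties, undefined)


# ---------------------------------------------------------------------------
# One-call analysis
# ---------------------------------------------------------------------------


@dataclass
class ScalesResult:
    profiles: dict
    nulls: dict
    ranking: HierarchyRanking
    pairs: PairSample
    windows: list[WindowSpec]


def run_scales(
    d: SpectralDecomposition,
    meta: pd.DataFrame,
    variables: list[str],
    width: int = 3,
    stride: int = 1,
    max_pc: int = 30,
    n_bins: int = 16,
    pair_budget: int = DEFAULT_PAIR_BUDGET,
    weighting: str = "scores",
    normalization: str = "raw",
    null_mode: str = "per_condition",
    n_perm: int = 100,
    seed: int = 0,
) -> ScalesResult:
    """Full SCALES analysis: one shared pair sample, per-variable MI(CDF)
    profiles with permutation-null envelopes, and the hierarchy ranking."""
    windows = make_windows(d.K, width, stride, max_pc)
    pairs = sample_pairs(d.U.shape[0], pair_budget, seed)
    binsets = _window_binsets(d, windows, pairs, weighting, normalization, n_bins)
    profiles, nulls = {}, {}
    for v in variables:
        lab = _align_labels(d, meta, v)
        codes = pd.factorize(lab)[0]
        y = (codes[pairs.i] == codes[pairs.j]).astype(np.int8)
        mi = np.array([wb.mi_for_labels(y[None, :])[0] for wb in binsets])
        prof = MIProfile(v, windows, mi, n_bins, weighting, normalization)
        null = null_profile(
            d, meta, v, windows, pairs, null_mode,
            n_perm=n_perm, seed=seed + 1, n_bins=n_bins,
            weighting=weighting, normalization=normalization,
            _binsets=binsets,
        )
        prof.null_mean = null.null_mean
        prof.null_q95 = null.null_q95
        prof.n_perm = null.n_perm
        profiles[v] = prof
        nulls[v] = null
    ranking = rank_hierarchy(profiles)
    return ScalesResult(profiles, nulls, ranking, pairs, windows)
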