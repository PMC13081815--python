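"""Synthetic data generators with full ground truth.

Every analysis stage in this package has a matching simulator here, so each
recovery claim can be tested against known truth at desk scale:

* :func:`simulate_scrna` — a multi-condition single-cell ensemble in which
  each environmental cue is planted at a chosen component ("spectral depth")
  of the condition-level expression structure, on top of a smoothly decaying
  ladder of background condition programs, a shared stress shift on the
  leading program, and negative-binomial UMI sampling noise.
* :func:`simulate_bulk` — a 2x2 dual-stress bulk design with log-additive
  single-stress effects and an optional planted interaction (epistasis)
  term on designated gene sets.
* :func:`simulate_trace` — sucrose-gradient A260 traces as sums of Gaussian
  peaks with known areas plus linear drift and noise.
* :func:`simulate_growth` — exponential, logistic or diauxic (two-phase)
  OD600 curves sampled every 20 minutes for 48 hours.
* :func:`simulate_competition` — two-strain flow-cytometry count series
  whose log ratio drifts at a known selection coefficient.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import BulkCounts, CountMatrix
from .physiology import AbsorbanceTrace, CompetitionSeries, GrowthCurve

# ---------------------------------------------------------------------------
# Single-cell ensemble
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CueSpec:
    """One environmental cue: its factor levels, the component index it is
    planted at, and its relative effect size.  The per-gene natural-log fold
    shift per unit of the centered level code is
    ``effect * SyntheticSpec.effect_gene_scale`` (RMS over genes)."""

    name: str
    levels: tuple
    depth: int
    effect: float

    def __post_init__(self):
        if len(self.levels) not in (2, 3):
            raise ValueError("cues must have 2 or 3 levels")
        if self.depth < 2:
            raise ValueError("cue depth must be >= 2 (component 1 carries the "
                             "shared stress/background mode)")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")


DEFAULT_CUES = (
    CueSpec("carbon", ("glucose", "ethanol"), depth=2, effect=1.0),
    CueSpec("media", ("rich", "minimal"), depth=6, effect=0.8),
    CueSpec("osmolarity", ("0M", "0.5M", "1M"), depth=10, effect=0.6),
    CueSpec("temperature", ("30C", "39C"), depth=16, effect=0.45),
    CueSpec("ros", ("-ROS", "+ROS"), depth=24, effect=0.35),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameterization of the planted single-cell ensemble.

    Conditions form the full factorial over cue levels (48 for the default
    cue structure).  Effect sizes are relative amplitudes; multiplied by
    ``effect_gene_scale`` they give RMS per-gene natural-log fold shifts
    (the default scale makes the strongest cue a ~1.4-fold RMS shift, a
    realistic transcriptome-wide perturbation).  ``shared_stress_effect``
    is the amplitude (same units) applied along the leading background
    program to every condition whose cues are not all at their first
    (benign) level.  ``dispersion`` is the negative-binomial
    inverse-dispersion (gamma shape); ``library_*`` set the log-normal UMI
    totals per cell.
    """

    n_genes: int = 1000
    cells_per_condition: int = 100
    cues: tuple = DEFAULT_CUES
    shared_stress_effect: float = 2.0
    effect_gene_scale: float = 0.35
    baseline_log_sd: float = 1.2
    dispersion: float = 10.0
    library_log_mean: float = float(np.log(2000.0))
    library_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        depths = [c.depth for c in self.cues]
        if len(set(depths)) != len(depths):
            raise ValueError("planted components must be distinct across cues")

    @property
    def n_components(self) -> int:
        return max(c.depth for c in self.cues) + 4

    @property
    def condition_grid(self) -> pd.DataFrame:
        grids = np.meshgrid(*[range(len(c.levels)) for c in self.cues],
                            indexing="ij")
        codes = np.stack([g.ravel() for g in grids], axis=1)
        df = pd.DataFrame(
            {c.name: [c.levels[k] for k in codes[:, i]]
             for i, c in enumerate(self.cues)}
        )
        df.index = [
            "|".join(str(df.iloc[r, i]) for i in range(len(self.cues)))
            for r in range(len(df))
        ]
        df.index.name = "sample_id"
        return df

    def with_effects_scaled(self, factor: float) -> "SyntheticSpec":
        cues = tuple(replace(c, effect=c.effect * factor) for c in self.cues)
        return replace(self, cues=cues,
                       shared_stress_effect=self.shared_stress_effect * factor)


@dataclass
class ScrnaGroundTruth:
    """Everything needed to recompute expected outcomes of recovery tests."""

    spec: SyntheticSpec
    loadings: np.ndarray            # genes x n_components, orthonormal
    amplitudes: np.ndarray          # per-component RMS log-shift ladder
    condition_coeffs: np.ndarray    # conditions x n_components
    condition_log_means: np.ndarray  # conditions x genes (ln scale)
    condition_grid: pd.DataFrame
    baseline: np.ndarray

    @property
    def planted_depths(self) -> dict:
        return {c.name: c.depth for c in self.spec.cues}

    @property
    def planted_ordering(self) -> list:
        return [c.name for c in sorted(self.spec.cues, key=lambda c: c.depth)]


def _centered_code(levels_idx: np.ndarray, n_levels: int) -> np.ndarray:
    """Centered, unit-variance level code on a balanced grid: +-1 for two
    levels, (-1, 0, +1)*sqrt(3/2) for three."""
    if n_levels == 2:
        return np.where(levels_idx == 0, -1.0, 1.0)
    vals = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)
    return vals[levels_idx]


def _amplitude_ladder(spec: SyntheticSpec) -> np.ndarray:
    """Strictly decreasing per-component amplitude profile anchored at the
    planted (depth, effect) pairs; component 1 sits just above the
    shallowest cue, and the tail extrapolates the last planted slope."""
    anchors = sorted((c.depth, c.effect) for c in spec.cues)
    ks = np.array([k for k, _ in anchors], dtype=float)
    vs = np.array([v for _, v in anchors], dtype=float)
    amax = vs.max() if len(vs) else 0.0
    ks = np.concatenate([[1.0], ks])
    vs = np.concatenate([[1.2 * amax], vs])
    out = np.empty(spec.n_components)
    for k in range(1, spec.n_components + 1):
        if k <= ks[-1]:
            out[k - 1] = np.interp(k, ks, vs)
        else:  # extrapolate the final slope, floored at half the last anchor
            if len(ks) >= 2 and ks[-1] > ks[-2]:
                slope = (vs[-1] - vs[-2]) / (ks[-1] - ks[-2])
            else:
                slope = 0.0
            out[k - 1] = max(vs[-1] + slope * (k - ks[-1]), 0.5 * vs[-1])
    return out


def simulate_scrna(
    spec: SyntheticSpec | None = None, seed: int | None = None
) -> tuple[CountMatrix, ScrnaGroundTruth]:
    """Generate a planted multi-condition single-cell UMI ensemble.

    Gene programs are orthonormal vectors from a seeded Gaussian QR.  The
    per-condition natural-log mean is

    ``mu = baseline + sqrt(n_genes) * sum_k coeff_k(condition) * q_k``

    where the coefficient of the component planted for cue ``c`` is its
    centered level code times the cue's effect size, non-planted components
    carry standardized condition-level background coefficients scaled by a
    decaying amplitude ladder, and the leading component additionally takes
    the shared stress shift for all non-reference conditions.  UMI counts
    are negative-binomial around library-size-scaled softmax means.
    """
    spec = spec or SyntheticSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    if spec.n_components > spec.n_genes:
        raise ValueError("planted depth exceeds available components")
    grid = spec.condition_grid
    n_cond = len(grid)
    if spec.n_components > n_cond - 1:
        raise ValueError(
            f"planted depth {spec.n_components - 4} needs more than "
            f"{n_cond} conditions"
        )
    Q, _ = np.linalg.qr(rng.normal(size=(spec.n_genes, spec.n_components)))
    # deterministic sign: largest-|entry| coordinate positive
    for k in range(Q.shape[1]):
        j = int(np.argmax(np.abs(Q[:, k])))
        if Q[j, k] < 0:
            Q[:, k] *= -1.0
    amps = _amplitude_ladder(spec)
    depth_of = {c.depth: i for i, c in enumerate(spec.cues)}

    coeff = np.zeros((n_cond, spec.n_components))
    level_idx = {
        c.name: np.array([c.levels.index(v) for v in grid[c.name]])
        for c in spec.cues
    }
    cue_codes = [
        _centered_code(level_idx[c.name], len(c.levels)) for c in spec.cues
    ]
    # background condition-level programs: random balanced +-1 codes,
    # orthogonalized against the constant, every cue's code and each other,
    # then restandardized.  Orthogonality keeps background components free
    # of cue information; the near-two-valued distribution matches the cue
    # codes', so downstream count compression attenuates planted and
    # background components alike.
    basis = [np.ones(n_cond) / np.sqrt(n_cond)]
    for z in cue_codes:
        q = z.copy()
        for b in basis:
            q = q - (q @ b) * b
        basis.append(q / np.linalg.norm(q))
    fillers = []
    n_filler_needed = spec.n_components - len(spec.cues)
    while len(fillers) < n_filler_needed:
        u = np.ones(n_cond)
        u[: n_cond // 2] = -1.0
        rng.shuffle(u)
        for b in basis:
            u = u - (u @ b) * b
        norm_u = np.linalg.norm(u)
        if norm_u < 1e-8:
            continue
        basis.append(u / norm_u)
        fillers.append(u / u.std())
    filler_iter = iter(range(len(fillers)))
    for k in range(1, spec.n_components + 1):
        if k in depth_of:
            cue = spec.cues[depth_of[k]]
            coeff[:, k - 1] = cue.effect * cue_codes[depth_of[k]]
        else:
            coeff[:, k - 1] = amps[k - 1] * fillers[next(filler_iter)]
    # shared stress shift on the leading background program: applied to
    # every condition not at the all-benign reference corner.  The centered
    # indicator is orthogonalized against the cue codes so the shared mode
    # carries no single cue's information (keeping planted depths clean).
    ref_mask = np.all(
        [level_idx[c.name] == 0 for c in spec.cues], axis=0
    )
    ind = (~ref_mask).astype(float)
    ind -= ind.mean()
    for z in cue_codes:
        ind -= (ind @ z) / (z @ z) * z
    coeff[:, 0] += spec.shared_stress_effect * ind

    baseline = rng.normal(0.0, spec.baseline_log_sd, size=spec.n_genes)
    log_means = baseline[None, :] + (
        np.sqrt(spec.n_genes) * spec.effect_gene_scale * (coeff @ Q.T)
    )
    # per-condition relative expression (softmax)
    rel = np.exp(log_means - log_means.max(axis=1, keepdims=True))
    rel /= rel.sum(axis=1, keepdims=True)

    n_cells = n_cond * spec.cells_per_condition
    cond_idx = np.repeat(np.arange(n_cond), spec.cells_per_condition)
    libs = np.exp(
        rng.normal(spec.library_log_mean, spec.library_log_sd, size=n_cells)
    )
    means = rel[cond_idx] * libs[:, None]
    lam = rng.gamma(spec.dispersion, means / spec.dispersion)
    counts = rng.poisson(lam)

    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)
    meta = grid.iloc[cond_idx].copy()
    meta.insert(0, "sample_id", grid.index.to_numpy()[cond_idx])
    meta.index = cell_ids
    m = CountMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=np.array([f"g{j:04d}" for j in range(spec.n_genes)],
                          dtype=object),
        cell_meta=meta,
    )
    gt = ScrnaGroundTruth(
        spec=spec,
        loadings=Q,
        amplitudes=amps,
        condition_coeffs=coeff,
        condition_log_means=log_means,
        condition_grid=grid,
        baseline=baseline,
    )
    return m, gt


# ---------------------------------------------------------------------------
# Bulk dual-stress design
# ---------------------------------------------------------------------------


@dataclass
class BulkGroundTruth:
    base_log2: np.ndarray
    beta_heat: np.ndarray
    beta_osmo: np.ndarray
    gamma: np.ndarray
    gene_sets: dict
    dispersion: float | None
    seed: int


def _balance(base: np.ndarray, beta: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Shift a responsive set's effects so the set's total linear-scale mass
    is unchanged by the stress (induced and repressed genes balance)."""
    mass0 = base[members].sum()
    mass1 = (base[members] * 2.0 ** beta[members]).sum()
    beta = beta.copy()
    beta[members] += np.log2(mass0 / mass1)
    return beta


def simulate_bulk(
    n_genes: int = 2000,
    n_reps: int = 3,
    epistasis: dict | None = None,
    n_responsive: int = 200,
    epistasis_set_size: int = 100,
    effect_sd: float = 1.5,
    dispersion: float | None = 0.005,
    base_log2_mean: float = float(np.log2(200.0)),
    base_log2_sd: float = 1.5,
    library_log_sd: float = 0.1,
    seed: int = 0,
) -> tuple[BulkCounts, BulkGroundTruth]:
    """Generate a 2x2 dual-stress bulk RNA-seq dataset.

    Per-gene log2 means follow ``base + beta_h*heat + beta_o*salt +
    gamma*heat*salt``.  Heat- and salt-responsive gene sets are disjoint and
    mass-balanced (total expression of each set is conserved under its
    stress), so under independence (``gamma = 0``) library composition does
    not distort fold changes.  ``epistasis`` maps set names
    ("HSR_like", "HOG_like") to a planted interaction gamma; by default all
    gamma are zero (independence).  ``dispersion=None`` gives the noiseless
    limit: counts equal their expected values exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if 2 * n_responsive > n_genes:
        raise ValueError(
            "n_genes must accommodate two disjoint responsive sets "
            f"(need >= {2 * n_responsive})"
        )
    rng = np.random.default_rng(seed)
    base = 2.0 ** rng.normal(base_log2_mean, base_log2_sd, size=n_genes)
    genes = np.array([f"g{j:04d}" for j in range(n_genes)], dtype=object)
    heat_set = np.arange(0, n_responsive)
    osmo_set = np.arange(n_responsive, 2 * n_responsive)
    beta_h = np.zeros(n_genes)
    beta_o = np.zeros(n_genes)
    beta_h[heat_set] = rng.normal(0.0, effect_sd, size=len(heat_set))
    beta_o[osmo_set] = rng.normal(0.0, effect_sd, size=len(osmo_set))
    beta_h = _balance(base, beta_h, heat_set)
    beta_o = _balance(base, beta_o, osmo_set)
    gamma = np.zeros(n_genes)
    gene_sets = {
        "heat_responsive": list(genes[heat_set]),
        "osmo_responsive": list(genes[osmo_set]),
        "HSR_like": list(genes[heat_set[:epistasis_set_size]]),
        "HOG_like": list(genes[osmo_set[:epistasis_set_size]]),
    }
    for set_name, g in (epistasis or {}).items():
        idx = np.array([np.where(genes == gid)[0][0]
                        for gid in gene_sets[set_name]])
        gamma[idx] = g

    conditions = [("-", "-"), ("+", "-"), ("-", "+"), ("+", "+")]
    cols, rows = [], {}
    design_rows = []
    for heat, salt in conditions:
        h = 1.0 if heat == "+" else 0.0
        s = 1.0 if salt == "+" else 0.0
        mean = base * 2.0 ** (beta_h * h + beta_o * s + gamma * h * s)
        for rep in range(1, n_reps + 1):
            name = f"{heat}HS_{salt}NaCl_r{rep}"
            if dispersion is None:
                counts = mean
            else:
                lib = np.exp(rng.normal(0.0, library_log_sd))
                mu = mean * lib
                lam = rng.gamma(1.0 / dispersion, mu * dispersion)
                counts = rng.poisson(lam).astype(float)
            rows[name] = counts
            cols.append(name)
            design_rows.append(
                {"sample": name, "heat": heat, "salt": salt,
                 "strain": "ancestral", "replicate": str(rep)}
            )
    counts_df = pd.DataFrame(rows, index=genes)[cols]
    design = pd.DataFrame(design_rows).set_index("sample")
    gt = BulkGroundTruth(
        base_log2=np.log2(base), beta_heat=beta_h, beta_osmo=beta_o,
        gamma=gamma, gene_sets=gene_sets, dispersion=dispersion, seed=seed,
    )
    return BulkCounts(counts_df, design), gt


# ---------------------------------------------------------------------------
# Polysome traces
# ---------------------------------------------------------------------------


@dataclass
class TraceGroundTruth:
    peaks: list            # dicts with center, sd, area
    drift: tuple
    noise_sd: float
    seed: int

    @property
    def area(self) -> dict:
        return {i: p["area"] for i, p in enumerate(self.peaks)}


def simulate_trace(
    peaks: list[dict] | None = None,
    drift: tuple[float, float] = (0.02, 0.01),
    noise_sd: float = 0.002,
    grid: tuple[float, float, int] = (0.0, 1.0, 1200),
    seed: int = 0,
) -> tuple[AbsorbanceTrace, TraceGroundTruth]:
    """Sum-of-Gaussians A260 trace with known peak areas, linear baseline
    drift and Gaussian noise.  The default layout mimics a gradient with
    40S/60S shoulders, a dominant 80S monosome peak and a polysome train.
    """
    if peaks is None:
        peaks = [
            {"center": 0.10, "sd": 0.015, "area": 0.2},   # 40S
            {"center": 0.16, "sd": 0.015, "area": 0.3},   # 60S
            {"center": 0.25, "sd": 0.020, "area": 1.5},   # 80S monosome
            {"center": 0.45, "sd": 0.020, "area": 0.5},
            {"center": 0.55, "sd": 0.020, "area": 0.4},
            {"center": 0.65, "sd": 0.020, "area": 0.3},
            {"center": 0.75, "sd": 0.022, "area": 0.2},
        ]
    centers = [p["center"] for p in peaks]
    if list(centers) != sorted(centers):
        raise ValueError("peaks must be ordered by center")
    import warnings as _w

    for a, b in zip(peaks[:-1], peaks[1:]):
        if b["center"] - a["center"] < (a["sd"] + b["sd"]):
            _w.warn(
                f"peaks at {a['center']} and {b['center']} overlap heavily; "
                "their areas are not separately identifiable", stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    x = np.linspace(grid[0], grid[1], grid[2])
    y = drift[0] + drift[1] * x
    for p in peaks:
        y = y + p["area"] / (p["sd"] * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - p["center"]) / p["sd"]) ** 2
        )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(x))
    y = np.clip(y, 0.0, None)
    return AbsorbanceTrace(x, y), TraceGroundTruth(peaks, drift, noise_sd, seed)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


@dataclass
class GrowthGroundTruth:
    model: str
    params: dict
    noise_sd: float
    seed: int

    @property
    def observable_rates(self) -> tuple[float, ...]:
        """Specific (log-slope) growth rate per phase."""
        p = self.params
        if self.model == "exponential":
            return (p["rate"],)
        if self.model == "logistic":
            return (p["rate"] * (1.0 - p["od0"] / p["capacity"]),)
        return (p["rate1"], p["rate2"])


def simulate_growth(
    model: str = "logistic",
    params: dict | None = None,
    interval_min: float = 20.0,
    horizon_h: float = 48.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[GrowthCurve, GrowthGroundTruth]:
    """OD600 time course sampled every ``interval_min`` minutes.

    Models: ``exponential`` (od0, rate), ``logistic`` (od0, rate, capacity)
    and ``diauxic`` (two logistic phases: od0, rate1, capacity1, rate2,
    capacity2, lag_h between them).
    """
    defaults = {
        "exponential": {"od0": 0.05, "rate": 0.4},
        "logistic": {"od0": 0.02, "rate": 0.4, "capacity": 1.0},
        "diauxic": {"od0": 0.02, "rate1": 0.45, "capacity1": 0.4,
                    "rate2": 0.25, "capacity2": 2.4, "lag_h": 4.0},
    }
    if model not in defaults:
        raise ValueError(f"unknown growth model {model!r}")
    p = {**defaults[model], **(params or {})}
    for key, val in p.items():
        if key.startswith("rate") and val < 0:
            raise ValueError("negative growth rates are not allowed")
    t = np.arange(0.0, horizon_h + 1e-9, interval_min / 60.0)
    if model == "exponential":
        od = p["od0"] * np.exp(p["rate"] * t)
    elif model == "logistic":
        K, r, x0 = p["capacity"], p["rate"], p["od0"]
        od = K / (1.0 + (K / x0 - 1.0) * np.exp(-r * t))
    else:
        # two exponential phases separated by an idle plateau (lag), each
        # capped at its capacity, so the specific rate of each phase is a
        # directly observable log-slope
        K1, r1, x0 = p["capacity1"], p["rate1"], p["od0"]
        K2, r2 = p["capacity2"], p["rate2"]
        t1 = np.log(K1 / x0) / r1            # first phase reaches K1
        t2 = t1 + p["lag_h"]                 # second phase starts
        od = np.where(
            t <= t1,
            x0 * np.exp(r1 * t),
            np.where(
                t <= t2,
                K1,
                np.minimum(K1 * np.exp(r2 * (t - t2)), K2),
            ),
        )
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=len(t))
    od = np.clip(od, 1e-4, None)
    return GrowthCurve(t, od), GrowthGroundTruth(model, p, noise_sd, seed)


# ---------------------------------------------------------------------------
# Competition series
# ---------------------------------------------------------------------------


@dataclass
class CompetitionGroundTruth:
    s: float
    f0: float
    n_events: int
    sampling: bool
    seed: int


def simulate_competition(
    s: float = 0.1,
    n_events: int = 10_000,
    days: tuple = (0, 1, 2, 3),
    f0: float = 0.5,
    sampling: bool = True,
    seed: int = 0,
) -> tuple[CompetitionSeries, CompetitionGroundTruth]:
    """Two-strain competition counts at the given days.

    The expected test-strain fraction follows the logistic of ``s * day``;
    with ``sampling`` the per-day counts are binomial draws of ``n_events``
    cytometry events, otherwise exact expected counts are returned.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    days_arr = np.asarray(days, dtype=float)
    odds = f0 / (1.0 - f0) * np.exp(s * days_arr)
    frac = odds / (1.0 + odds)
    if np.min(n_events * frac) < 1.0 or np.min(n_events * (1 - frac)) < 1.0:
        raise ValueError(
            "selection coefficient too extreme: a strain's expected count "
            "falls below one event"
        )
    rng = np.random.default_rng(seed)
    if sampling:
        test = rng.binomial(n_events, frac).astype(float)
    else:
        test = n_events * frac
    ref = n_events - test
    series = CompetitionSeries(days_arr, test, ref)
    return series, CompetitionGroundTruth(s, f0, n_events, sampling, seed)
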