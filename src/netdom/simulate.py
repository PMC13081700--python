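"""Synthetic spatially autocorrelated imaging data and rejection-rate studies.

The generator emulates the structure of the enrichment-testing benchmark:
per-subject Gaussian random fields with controllable spatial autocorrelation
(white noise smoothed on a toroidal grid or a sampled sphere, rescaled so that
every location's marginal variance is exactly sigma^2), a partition of the
locations into networks of differing size and contiguity, and subject-level
imaging values

    Y_iv = beta0 + 0.05 * x1_i - 0.05 * x2_i + beta3_v * x3_i + noise_iv

with x1 ~ Bernoulli(0.5), x2 ~ N(0,1) and the predictor of interest
x3 ~ N(0,1).  Two noise regimes are built in: "low" spatial autocorrelation
(sigma^2 = 0.09, cortical-thickness-like, baseline beta0 = 3) and "high"
(sigma^2 = 0.36, task-activation-like, beta0 = 0).  Four canonical beta3
configurations cover two null and two alternative enrichment regimes; the
gamma-distributed configuration uses the shape--rate parameterisation, so
Gamma(2, 40) and Gamma(20, 400) share mean 0.05 while the in-network field is
ten times more variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .comparators import (
    VariogramConfig,
    rigea_test,
    spin_surrogates,
    surrogate_test,
    variogram_surrogates,
    weighted_ks_enrichment,
)
from .core import GammaGrid, NetworkPartition, netdom_test
from .glm import (
    ImagingMatrix,
    PermutationPlan,
    PhenotypeDesign,
    fit_association_map,
    freedman_lane_null_maps,
)

__all__ = [
    "BETA3_CONFIGS",
    "SyntheticGeometry",
    "SimulationSetting",
    "SyntheticDataset",
    "StudyResult",
    "make_geometry",
    "default_geometry",
    "sample_autocorrelated_noise",
    "sample_beta3",
    "simulate_dataset",
    "run_rejection_study",
]

#: the four canonical beta3 configurations (in-network value, out-of-network value)
BETA3_CONFIGS = ("null_directional", "null_equal", "shifted", "gamma_variance")

#: smoothing kernel widths (grid units / chord length) backing the two
#: autocorrelation regimes.  Width 1.5 gives a correlation FWHM of ~3.5 grid
#: cells, roughly a quarter of the diameter of the default network patches
#: (12-20 cells) -- matching the proportion between the smoothness of task
#: activation maps (FWHM ~15 mm) and the spatial extent of a cortical
#: functional network (~50-80 mm).  The low-SA regime scales the width down
#: threefold, emulating the much weaker autocorrelation of unsmoothed
#: morphometry relative to the same networks.
LOW_SA_WIDTH = 0.5
HIGH_SA_WIDTH = 1.5

SIM_METHODS = ("netdom", "rigea", "meandiff", "weighted_ks", "variogram", "spin")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGeometry:
    """A location layout with an integer network partition.

    ``labels`` uses 0 for background (out-of-network for every test) and
    1..n_networks for the grown patches.  ``coords`` are grid coordinates for
    the toroidal layout (rows, cols) or unit-sphere xyz for the sphere layout.
    """

    layout: str
    coords: np.ndarray
    labels: np.ndarray
    shape: tuple | None = None  # (H, W) for the grid layout
    neighbors: list = field(repr=False, default_factory=list)

    @property
    def n_locations(self) -> int:
        return len(self.labels)

    @property
    def network_ids(self):
        ids = np.unique(self.labels)
        return ids[ids != 0]

    def partition(self, network_id) -> NetworkPartition:
        return NetworkPartition(self.labels, network_id)


def _grid_neighbors(shape):
    """4-neighbour adjacency with toroidal wraparound; list of index arrays."""
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    nbrs = np.stack(
        [
            np.roll(idx, 1, axis=0),
            np.roll(idx, -1, axis=0),
            np.roll(idx, 1, axis=1),
            np.roll(idx, -1, axis=1),
        ],
        axis=-1,
    ).reshape(h * w, 4)
    return [row for row in nbrs]


def _sphere_points(v):
    """Fibonacci lattice of v points on the unit sphere."""
    i = np.arange(v) + 0.5
    phi = np.arccos(1 - 2 * i / v)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _grow_patch(free, start, size, neighbors, rng):
    """Randomised BFS growth of one connected patch over free locations."""
    patch = [start]
    free[start] = False
    frontier = [n for n in neighbors[start] if free[n]]
    while len(patch) < size:
        if not frontier:
            return None
        j = rng.integers(len(frontier))
        nxt = frontier.pop(j)
        if not free[nxt]:
            continue
        free[nxt] = False
        patch.append(nxt)
        frontier.extend(n for n in neighbors[nxt] if free[n])
    return patch


def make_geometry(layout="grid", size=(50, 50), network_sizes=(400, 250, 150),
                  n_patches=None, seed=0) -> SyntheticGeometry:
    """Grow contiguous network patches on a toroidal grid or a sampled sphere.

    ``network_sizes[j]`` locations receive label j+1, grown as ``n_patches[j]``
    connected patches (default: one patch each); remaining locations are
    labelled 0 (background).
    """
    rng = np.random.default_rng(seed)
    if layout == "grid":
        h, w = size
        V = h * w
        rows, cols = np.divmod(np.arange(V), w)
        coords = np.column_stack([rows, cols]).astype(float)
        neighbors = _grid_neighbors((h, w))
        shape = (h, w)
    elif layout == "sphere":
        V = int(size) if np.isscalar(size) else int(np.prod(size))
        coords = _sphere_points(V)
        _, nn = cKDTree(coords).query(coords, k=7)
        neighbors = [row[1:] for row in nn]
        shape = None
    else:
        raise ValueError(f"unknown layout {layout!r}")

    network_sizes = tuple(int(s) for s in network_sizes)
    if n_patches is None:
        n_patches = (1,) * len(network_sizes)
    if sum(network_sizes) >= V:
        raise ValueError("requested network sizes must sum to less than V")

    for attempt in range(50):
        grow_rng = np.random.default_rng(rng.integers(2**31))
        labels = np.zeros(V, dtype=int)
        free = np.ones(V, dtype=bool)
        ok = True
        for j, (nsize, npatch) in enumerate(zip(network_sizes, n_patches), start=1):
            quota = [nsize // npatch] * npatch
            quota[0] += nsize - sum(quota)
            for qsize in quota:
                starts = np.flatnonzero(free)
                patch = _grow_patch(
                    free, starts[grow_rng.integers(len(starts))], qsize,
                    neighbors, grow_rng,
                )
                if patch is None:
                    ok = False
                    break
                labels[patch] = j
            if not ok:
                break
        if ok:
            return SyntheticGeometry(layout, coords, labels, shape, neighbors)
    raise ValueError("could not grow the requested network patches; sizes infeasible")


def default_geometry(seed=0) -> SyntheticGeometry:
    """The benchmark partition: 50x50 torus with three networks.

    Network 1 is large and split into two patches (default-mode-like, 400
    locations), network 2 is a single mid-size patch (motor-like, 250), and
    network 3 a smaller contiguous patch (visual-like, 150).
    """
    return make_geometry(
        "grid", (50, 50), network_sizes=(400, 250, 150), n_patches=(2, 1, 1),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# noise and effect fields
# ---------------------------------------------------------------------------


def sample_autocorrelated_noise(geometry, N, sigma2, kernel_width, rng=None,
                                seed=None) -> np.ndarray:
    """N x V Gaussian noise with exact marginal variance sigma2 per location.

    White noise is smoothed with a Gaussian kernel of the given width
    (``kernel_width = 0`` gives i.i.d. noise) and rescaled so that the
    marginal variance at every location equals sigma2 exactly; smoothing only
    redistributes variance into spatial covariance.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if kernel_width < 0:
        raise ValueError("kernel_width must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    V = geometry.n_locations
    white = rng.standard_normal((N, V))
    if kernel_width == 0:
        return white * np.sqrt(sigma2)
    if geometry.layout == "grid":
        h, w = geometry.shape
        smoothed = gaussian_filter(
            white.reshape(N, h, w), sigma=(0, kernel_width, kernel_width),
            mode="wrap",
        ).reshape(N, V)
        # exact variance of the filter output: sum of squared kernel weights
        impulse = np.zeros((h, w))
        impulse[0, 0] = 1.0
        k2 = float(
            (gaussian_filter(impulse, kernel_width, mode="wrap") ** 2).sum()
        )
        return smoothed * np.sqrt(sigma2 / k2)
    # sphere: Gaussian kernel over chord distances, per-location exact rescale
    d = np.linalg.norm(
        geometry.coords[:, None, :] - geometry.coords[None, :, :], axis=-1
    )
    W = np.exp(-0.5 * (d / kernel_width) ** 2)
    scale = np.sqrt(sigma2 / (W**2).sum(axis=1))
    return (white @ W.T) * scale[None, :]


@dataclass
class SimulationSetting:
    """One simulation condition: sample size, noise regime, and beta3 field.

    ``sa_level`` 'low' -> sigma2 = 0.09, beta0 = 3, kernel width 1.0 (in grid
    units); 'high' -> sigma2 = 0.36, beta0 = 0, width 3.0; 'custom' requires
    sigma2 and kernel_width to be given explicitly.
    """

    N: int
    beta3_config: str = "null_equal"
    sa_level: str = "low"
    sigma2: float | None = None
    kernel_width: float | None = None
    beta0: float | None = None

    def __post_init__(self):
        if self.N < 10:
            raise ValueError("need N >= 10 subjects")
        if self.beta3_config not in BETA3_CONFIGS:
            raise ValueError(
                f"unknown beta3 config {self.beta3_config!r}; one of {BETA3_CONFIGS}"
            )
        defaults = {
            "low": (0.09, LOW_SA_WIDTH, 3.0),
            "high": (0.36, HIGH_SA_WIDTH, 0.0),
        }
        if self.sa_level in defaults:
            s2, kw, b0 = defaults[self.sa_level]
            self.sigma2 = s2 if self.sigma2 is None else self.sigma2
            self.kernel_width = kw if self.kernel_width is None else self.kernel_width
            self.beta0 = b0 if self.beta0 is None else self.beta0
        elif self.sa_level == "custom":
            if self.sigma2 is None or self.kernel_width is None:
                raise ValueError("custom sa_level requires sigma2 and kernel_width")
            self.beta0 = 0.0 if self.beta0 is None else self.beta0
        else:
            raise ValueError(f"unknown sa_level {self.sa_level!r}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def sample_beta3(config, geometry, network_id=None, rng=None, seed=None) -> np.ndarray:
    """Per-location true effect field for one of the canonical configurations.

    Deterministic configurations return constants per region; the
    gamma-variance configuration draws one value per location (shape--rate
    parameterisation), independently per location and per call.
    """
    if config not in BETA3_CONFIGS:
        raise ValueError(f"unknown beta3 config {config!r}; one of {BETA3_CONFIGS}")
    if network_id is None:
        network_id = int(geometry.network_ids[0])
    in_mask = geometry.labels == network_id
    V = geometry.n_locations
    if config == "null_directional":
        return np.where(in_mask, 0.0, -0.03)
    if config == "null_equal":
        return np.full(V, 0.04)
    if config == "shifted":
        return np.where(in_mask, 0.06, 0.04)
    if rng is None:
        rng = np.random.default_rng(seed)
    beta3 = rng.gamma(shape=20.0, scale=1.0 / 400.0, size=V)
    beta3[in_mask] = rng.gamma(shape=2.0, scale=1.0 / 40.0, size=int(in_mask.sum()))
    return beta3


@dataclass
class SyntheticDataset:
    """A simulated study: imaging matrix, matched design, and the true effect field."""

    imaging: ImagingMatrix
    design: PhenotypeDesign
    true_beta3: np.ndarray


def simulate_dataset(setting: SimulationSetting, geometry, network_id=None,
                     rng=None, seed=None) -> SyntheticDataset:
    """Draw covariates, the beta3 field, and autocorrelated noise; assemble Y.

    The matched analysis model is Y_v ~ 1 + x1 + x2 + x3 with x3 the target.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    N = setting.N
    x1 = rng.binomial(1, 0.5, size=N).astype(float)
    x2 = rng.standard_normal(N)
    x3 = rng.standard_normal(N)
    beta3 = sample_beta3(setting.beta3_config, geometry, network_id, rng=rng)
    noise = sample_autocorrelated_noise(
        geometry, N, setting.sigma2, setting.kernel_width, rng=rng
    )
    Y = (
        setting.beta0
        + 0.05 * x1[:, None]
        - 0.05 * x2[:, None]
        + x3[:, None] * beta3[None, :]
        + noise
    )
    design = PhenotypeDesign(
        pd.DataFrame({"x1": x1, "x2": x2, "x3": x3}),
        target="x3",
        nuisance=("x1", "x2"),
    )
    return SyntheticDataset(ImagingMatrix(Y), design, beta3)


# ---------------------------------------------------------------------------
# rejection-rate studies
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    """Empirical rejection rate with its binomial Monte-Carlo standard error."""

    method: str
    rate: float
    se: float
    n_reject: int
    reps: int
    p_values: np.ndarray


def _run_one(method, dataset, partition, geometry, K, side, perm_seed, grid):
    """One enrichment p-value for the chosen method on one simulated dataset."""
    if method == "netdom":
        plan = PermutationPlan.generate(
            dataset.imaging.n_subjects, K, "freedman_lane", perm_seed
        )
        return netdom_test(
            dataset.imaging, dataset.design, partition, plan, grid, side
        ).p
    if method == "rigea":
        obs = fit_association_map(dataset.imaging, dataset.design)
        return rigea_test(obs, partition, side)
    obs = fit_association_map(dataset.imaging, dataset.design)
    if method in ("meandiff", "weighted_ks"):
        plan = PermutationPlan.generate(
            dataset.imaging.n_subjects, K, "freedman_lane", perm_seed
        )
        nulls = freedman_lane_null_maps(dataset.imaging, dataset.design, plan)
        if method == "meandiff":
            return surrogate_test(obs, partition, nulls, side)
        return weighted_ks_enrichment(obs, partition, nulls, side)
    if method == "variogram":
        coords = geometry.coords[obs.location_index]
        surr = variogram_surrogates(
            obs, coords, K, perm_seed, VariogramConfig(pair_cap=20_000)
        )
        return surrogate_test(obs, partition, surr, side)
    if method == "spin":
        if geometry.layout != "sphere":
            raise ValueError("spin surrogates require a sphere geometry")
        from .comparators import SphereGeometry

        hemi = np.where(geometry.coords[:, 0] < 0, "L", "R")
        sphere = SphereGeometry(geometry.coords, hemi)
        surr = spin_surrogates(obs, sphere, K, perm_seed)
        return surrogate_test(obs, partition, surr, side)
    raise ValueError(f"unknown method {method!r}; one of {SIM_METHODS}")


def run_rejection_study(method, setting, geometry, network_id=None, reps=200,
                        K=200, alpha=0.05, side="right", seed=0,
                        grid: GammaGrid | None = None) -> StudyResult:
    """Monte-Carlo rejection rate of one enrichment test under one condition.

    Per replicate a fresh dataset is simulated and the chosen test run; the
    result is the proportion of replicates with p < alpha together with its
    binomial standard error.  Per-replicate seeds derive deterministically
    from the master seed.
    """
    if method not in SIM_METHODS:
        raise ValueError(f"unknown method {method!r}; one of {SIM_METHODS}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if network_id is None:
        network_id = int(geometry.network_ids[0])
    partition = geometry.partition(network_id)
    children = np.random.SeedSequence(seed).spawn(reps)
    pvals = np.empty(reps)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm_seed = int(child.generate_state(1, np.uint32)[0]) % (2**31)
        dataset = simulate_dataset(setting, geometry, network_id, rng=rng)
        pvals[r] = _run_one(
            method, dataset, partition, geometry, K, side, perm_seed, grid
        )
    n_reject = int((pvals < alpha).sum())
    rate = n_reject / reps
    se = float(np.sqrt(rate * (1 - rate) / reps))
    return StudyResult(method, rate, se, n_reject, reps, pvals)
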