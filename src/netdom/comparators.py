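"""Competing network-enrichment tests used as benchmarks.

Four established approaches, all reduced to the same interface (an observed
association map, a network partition, and some null-generating mechanism):

* RIGEA -- Fisher's exact test on the 2x2 table of thresholded associations.
* Spin test -- difference-in-means enrichment score against spherically
  rotated surrogate maps (contralaterally symmetric rotations; medial-wall
  values rotated into the cortex are discarded).
* Variogram-matched surrogates -- difference-in-means score against surrogate
  maps built by permuting, smoothing, and variogram-matching the observed map.
* Weighted-KS -- a GSEA-style running-sum enrichment score computed on maps
  from phenotype permutation.

None of these is bit-compatible with the released BrainSpace / BrainSmash /
NEST packages; they implement the same procedures at the level needed for
methodological comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .glm import AssociationMap, SurrogateMapSet

__all__ = [
    "ContingencyTable",
    "SphereGeometry",
    "VariogramConfig",
    "rigea_test",
    "enrichment_score",
    "surrogate_test",
    "spin_surrogates",
    "variogram_surrogates",
    "weighted_ks_enrichment",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _map_values(assoc) -> np.ndarray:
    return assoc.values if isinstance(assoc, AssociationMap) else np.asarray(assoc, float)


def _aligned_partition(assoc, partition):
    if isinstance(assoc, AssociationMap):
        return partition.align_to(assoc.location_index)
    return partition


# ---------------------------------------------------------------------------
# RIGEA
# ---------------------------------------------------------------------------


@dataclass
class ContingencyTable:
    """Counts of thresholded ("significant") associations by network membership."""

    s: int  # significant in-network
    S: int  # significant total
    m: int
    n: int

    def __post_init__(self):
        if not (0 <= self.s <= min(self.S, self.m)):
            raise ValueError("inconsistent contingency counts")
        if self.S > self.V:
            raise ValueError("S cannot exceed V")

    @property
    def V(self) -> int:
        return self.m + self.n

    def upper_tail(self) -> float:
        """Exact hypergeometric upper-tail probability P(X >= s).

        Computed with exact integer arithmetic: sum over s <= x <= S of
        C(S,x) C(V-S, m-x) / C(V,m); terms with infeasible x (m - x > V - S)
        vanish because the binomial coefficient is zero.
        """
        total = 0
        for x in range(self.s, min(self.S, self.m) + 1):
            total += comb(self.S, x) * comb(self.V - self.S, self.m - x)
        return float(Fraction(total, comb(self.V, self.m)))


def rigea_test(assoc, partition, side="right", threshold=1.96):
    """Fisher's-exact enrichment test on thresholded association statistics.

    Right side counts T_v >= threshold as significant, left side
    T_v <= -threshold.  Returns the exact hypergeometric upper-tail p-value
    for the in-network significant count.
    """
    values = _map_values(assoc)
    part = _aligned_partition(assoc, partition)
    if side == "right":
        sig = values >= threshold
    elif side == "left":
        sig = values <= -threshold
    else:
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    in_mask = part.in_mask
    table = ContingencyTable(
        s=int(sig[in_mask].sum()),
        S=int(sig.sum()),
        m=int(in_mask.sum()),
        n=int((~in_mask).sum()),
    )
    if table.S == 0:
        warnings.warn(
            "no associations exceed the threshold; the contingency table is "
            "vacuous and p = 1",
            stacklevel=2,
        )
        return 1.0
    return table.upper_tail()


# ---------------------------------------------------------------------------
# difference-in-means score and surrogate comparison
# ---------------------------------------------------------------------------


def enrichment_score(assoc, partition) -> float:
    """Difference in sample means: mean(in-network) - mean(out-of-network)."""
    values = _map_values(assoc)
    part = _aligned_partition(assoc, partition)
    in_mask = part.in_mask
    if in_mask.sum() == 0 or (~in_mask).sum() == 0:
        raise ValueError("in- and out-of-network sets must both be non-empty")
    return float(values[in_mask].mean() - values[~in_mask].mean())


def surrogate_test(assoc, partition, surrogates: SurrogateMapSet, side="right"):
    """Permutation p-value of the mean-difference score against surrogate maps.

    p = (1 + #{ES^(k) >= ES_obs}) / (K + 1) for a right-sided test; the
    inequality is reversed on the left.  Per-surrogate validity masks are
    honoured; a surrogate whose valid locations leave either side of the
    partition empty is dropped (with a warning) and K decremented.
    """
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    values = _map_values(assoc)
    part = _aligned_partition(assoc, partition)
    in_mask = part.in_mask
    es_obs = float(values[in_mask].mean() - values[~in_mask].mean())

    es_null = []
    dropped = 0
    for k in range(surrogates.K):
        ok = surrogates.valid[k]
        vin = ok & in_mask
        vout = ok & ~in_mask
        if vin.sum() == 0 or vout.sum() == 0:
            dropped += 1
            continue
        row = surrogates.maps[k]
        es_null.append(row[vin].mean() - row[vout].mean())
    if dropped:
        warnings.warn(
            f"excluded {dropped} surrogate map(s) with no valid in- or "
            "out-of-network locations",
            stacklevel=2,
        )
    es_null = np.asarray(es_null)
    K = es_null.size
    if K == 0:
        raise ValueError("no usable surrogate maps")
    if side == "right":
        count = int((es_null >= es_obs).sum())
    else:
        count = int((es_null <= es_obs).sum())
    return (1.0 + count) / (K + 1.0)


# ---------------------------------------------------------------------------
# spin surrogates
# ---------------------------------------------------------------------------


@dataclass
class SphereGeometry:
    """Unit-sphere vertex coordinates with hemisphere labels and medial-wall mask."""

    coords: np.ndarray
    hemisphere: np.ndarray  # 'L' or 'R' per vertex
    medial_wall: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coordinates must be V x 3")
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length vertex coordinate")
        self.coords = self.coords / norms[:, None]
        self.hemisphere = np.asarray(self.hemisphere)
        if len(self.hemisphere) != len(self.coords):
            raise ValueError("hemisphere labels do not match coordinates")
        labels = set(np.unique(self.hemisphere))
        if not labels <= {"L", "R"}:
            raise ValueError(f"hemisphere labels must be 'L'/'R', got {labels}")
        if labels != {"L", "R"}:
            raise ValueError("both hemispheres must be present for mirrored spins")
        if self.medial_wall is None:
            self.medial_wall = np.zeros(len(self.coords), dtype=bool)
        self.medial_wall = np.asarray(self.medial_wall, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return len(self.coords)


def _spin_rotations(angles):
    """Left- and mirrored right-hemisphere rotation matrices for one spin."""
    ax, ay, az = angles
    left = Rotation.from_euler("xyz", [ax, ay, az]).as_matrix()
    right = Rotation.from_euler("xyz", [ax, -ay, -az]).as_matrix()
    return left, right


def spin_surrogates(assoc: AssociationMap, geometry: SphereGeometry, K, seed=0,
                    angles=None) -> SurrogateMapSet:
    """Spherically rotated surrogate maps with contralateral symmetry.

    Per spin, rotation angles about x, y, z are sampled uniformly on
    [0, 360) degrees; the same x-rotation but negated y- and z-rotations are
    applied to the right hemisphere.  Each vertex is reassigned the value of
    the nearest rotated vertex within its hemisphere; vertices that receive a
    rotated-in medial-wall (or otherwise non-analyzable) value are marked
    invalid.  ``angles`` (K x 3, radians) may be supplied to fix the spins.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    if angles is None:
        angles = rng.uniform(0.0, 2.0 * np.pi, size=(K, 3))
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (K, 3):
        raise ValueError("angles must have shape (K, 3)")

    V = geometry.n_vertices
    loc = np.asarray(assoc.location_index)
    if loc.max(initial=-1) >= V:
        raise ValueError("geometry does not cover every analyzable location")
    full = np.full(V, np.nan)
    full[loc] = assoc.values
    analyzable = np.zeros(V, dtype=bool)
    analyzable[loc] = True

    hemi_idx = {h: np.flatnonzero(geometry.hemisphere == h) for h in ("L", "R")}
    maps = np.empty((K, len(loc)))
    valid = np.empty((K, len(loc)), dtype=bool)
    source = np.empty(V, dtype=int)
    for k in range(K):
        rot = dict(zip(("L", "R"), _spin_rotations(angles[k])))
        for h, idx in hemi_idx.items():
            rotated = geometry.coords[idx] @ rot[h].T
            tree = cKDTree(rotated)
            _, nearest = tree.query(geometry.coords[idx], k=1)
            source[idx] = idx[nearest]
        maps[k] = full[source[loc]]
        valid[k] = analyzable[source[loc]]
        maps[k, ~valid[k]] = np.nan
    return SurrogateMapSet(
        maps, assoc.location_index, mechanism="spin",
        stat_kind=assoc.stat_kind, valid=valid,
    )


# ---------------------------------------------------------------------------
# variogram-matched surrogates
# ---------------------------------------------------------------------------


@dataclass
class VariogramConfig:
    """Knobs for variogram-matched surrogate generation.

    ``kernel_widths`` default to a geometric grid spanning the 10th--70th
    percentile of pairwise distances; ``n_bins`` equal-count distance bins are
    used for the empirical variograms; at most ``pair_cap`` randomly
    subsampled location pairs enter the variogram estimate.
    """

    n_bins: int = 25
    kernel_widths: np.ndarray | None = None
    n_widths: int = 5
    pair_cap: int = 50_000
    identity_transform: bool = False

    def __post_init__(self):
        if self.n_bins < 3:
            raise ValueError("need at least 3 distance bins")
        if self.kernel_widths is not None:
            self.kernel_widths = np.asarray(self.kernel_widths, dtype=float)


def _binned_variogram(sq_diffs, bin_ids, n_bins):
    gamma = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bin_ids == b
        if sel.any():
            gamma[b] = 0.5 * sq_diffs[sel].mean()
    return gamma


def variogram_surrogates(assoc, coordinates, K, seed=0,
                         config: VariogramConfig | None = None) -> SurrogateMapSet:
    """Surrogate maps that preserve the spatial variogram of the observed map.

    Per surrogate: the map values are permuted across locations (destroying
    the autocorrelation), smoothed with a Gaussian distance kernel for each
    candidate width, and the empirical variogram of each smoothed map is
    regressed onto the variogram of the original map; the width minimising the
    regression sum of squared errors wins, and the fitted linear transform is
    applied (values scaled by sqrt(slope), the intercept realised as added
    white noise of matching variance).
    """
    config = config or VariogramConfig()
    values = _map_values(assoc)
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    L = len(values)
    if coords.shape[0] != L:
        raise ValueError("coordinates do not match the association map")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)

    dist = squareform(pdist(coords))
    iu = np.triu_indices(L, k=1)
    n_pairs = len(iu[0])
    if n_pairs > config.pair_cap:
        keep = rng.choice(n_pairs, size=config.pair_cap, replace=False)
        pairs = (iu[0][keep], iu[1][keep])
    else:
        pairs = iu
    pd_ = dist[pairs]
    if len(np.unique(pd_)) < config.n_bins:
        raise ValueError("too few distinct pair distances for the requested bins")
    # equal-count bins over pair distances
    qs = np.quantile(pd_, np.linspace(0, 1, config.n_bins + 1))
    bin_ids = np.clip(np.searchsorted(qs, pd_, side="right") - 1, 0, config.n_bins - 1)

    widths = config.kernel_widths
    if widths is None:
        lo, hi = np.quantile(pd_, [0.10, 0.70])
        widths = np.geomspace(max(lo, 1e-8), hi, config.n_widths)

    target_v = _binned_variogram((values[pairs[0]] - values[pairs[1]]) ** 2,
                                 bin_ids, config.n_bins)
    # precompute row-normalised smoothing operators per width
    smoothers = []
    for w in widths:
        if w == 0:
            smoothers.append(None)  # identity
        else:
            W = np.exp(-0.5 * (dist / w) ** 2)
            W /= W.sum(axis=1, keepdims=True)
            smoothers.append(W)

    mu = float(values.mean())
    maps = np.empty((K, L))
    for k in range(K):
        perm = rng.permutation(L)
        x = values[perm]
        best = None
        for W in smoothers:
            sm = x if W is None else W @ x
            v = _binned_variogram((sm[pairs[0]] - sm[pairs[1]]) ** 2,
                                  bin_ids, config.n_bins)
            ok = np.isfinite(v) & np.isfinite(target_v)
            if ok.sum() < 3:
                raise ValueError("fewer than 3 populated distance bins")
            vv, tt = v[ok], target_v[ok]
            # OLS: target ~ a + b * v
            vb, tb = vv.mean(), tt.mean()
            den = float(((vv - vb) ** 2).sum())
            b = float(((vv - vb) * (tt - tb)).sum() / den) if den > 0 else 0.0
            a = tb - b * vb
            sse = float(((tt - (a + b * vv)) ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, a, b, sm)
        _, a, b, sm = best
        if config.identity_transform:
            maps[k] = x
        else:
            srg = np.sqrt(max(b, 0.0)) * sm
            if a > 0:
                srg = srg + np.sqrt(a) * rng.standard_normal(L)
            maps[k] = srg - srg.mean() + mu
    loc = assoc.location_index if isinstance(assoc, AssociationMap) else np.arange(L)
    kind = assoc.stat_kind if isinstance(assoc, AssociationMap) else "t"
    return SurrogateMapSet(maps, loc, mechanism="variogram", stat_kind=kind)


# ---------------------------------------------------------------------------
# weighted-KS (GSEA-style) enrichment
# ---------------------------------------------------------------------------


def _wks_score(values, in_mask, side):
    """Signed maximum deviation of the GSEA-style running sum.

    Locations are ranked by statistic (descending for a right-sided test,
    ascending for left); in-network locations step the sum up by
    |T_v| / sum_N |T|, out-of-network locations step it down by 1/n.
    """
    order = np.argsort(-values if side == "right" else values, kind="stable")
    in_ord = in_mask[order]
    w = np.abs(values[order])
    denom = w[in_ord].sum()
    if denom == 0:
        raise ValueError("all in-network statistics are zero; weights undefined")
    n_out = int((~in_mask).sum())
    steps = np.where(in_ord, w / denom, -1.0 / n_out)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def weighted_ks_enrichment(assoc, partition, surrogates: SurrogateMapSet,
                           side="right"):
    """Weighted Kolmogorov--Smirnov enrichment test on permutation null maps.

    The enrichment score is the signed maximum deviation of a running sum over
    locations ranked by statistic (weight exponent 1 on |T|, the GSEA
    default); the p-value compares the observed score against the scores of
    phenotype-permutation surrogate maps.
    """
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    values = _map_values(assoc)
    part = _aligned_partition(assoc, partition)
    in_mask = part.in_mask
    es_obs = _wks_score(values, in_mask, side)
    es_null = np.array(
        [_wks_score(surrogates.maps[k], in_mask, side) for k in range(surrogates.K)]
    )
    count = int((es_null >= es_obs).sum())
    return (1.0 + count) / (surrogates.K + 1.0)
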