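"""Mass-univariate association maps and permutation null maps.

At every brain location v a linear model

    Y_v = b0 + (nuisance coefficients) + b_target * x_target + error

is fit across subjects and the brain--phenotype association is summarised by
the t-statistic of the target coefficient (optionally the partial Pearson r,
or the unsigned F of the target).  Null association maps are produced by a
Freedman--Lane procedure: residuals from the reduced model (intercept +
nuisance) are permuted with a *single* subject reordering shared by every
location, the reduced-model fits are added back, and the full model is refit.
Sharing one permutation across locations preserves the spatial correlation of
the map under the null, which is what makes the downstream enrichment
permutation test valid in the presence of spatial autocorrelation.

Implementation note: the target t-statistic of the full model is computed via
the Frisch--Waugh--Lovell identity (project out the reduced model, then simple
regression on the residualised target).  This is algebraically exact and lets
one permutation's whole map be computed with a single small matrix product.
The observed map is computed by the same kernel with the identity permutation,
so Freedman--Lane with the identity permutation reproduces the observed
statistics bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeDesign",
    "ImagingMatrix",
    "AssociationMap",
    "PermutationPlan",
    "SurrogateMapSet",
    "fit_association_map",
    "freedman_lane_null_maps",
    "permute_phenotype",
]

STAT_KINDS = ("t", "pearson_r", "F")
PERMUTATION_SCHEMES = ("freedman_lane", "simple", "stratified")


class DesignRankError(ValueError):
    """Raised when the design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeDesign:
    """Subject-level phenotype and covariate table.

    Parameters
    ----------
    values
        Numeric table, one row per subject (index = subject identifiers).
    target
        Column name of the predictor of interest.
    nuisance
        Ordered nuisance covariate names; an intercept is always implicit.
    strata
        Optional grouping labels (one per subject) for stratified permutation.
    """

    values: pd.DataFrame
    target: str
    nuisance: tuple = ()
    strata: np.ndarray | None = None

    def __post_init__(self):
        self.nuisance = tuple(self.nuisance)
        if self.target in self.nuisance:
            raise ValueError(f"target {self.target!r} also listed as nuisance")
        cols = (self.target, *self.nuisance)
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise KeyError(f"columns not in phenotype table: {missing}")
        sub = self.values[list(cols)]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"missing values in phenotype columns: {bad}")
        if self.strata is not None:
            self.strata = np.asarray(self.strata)
            if len(self.strata) != len(self.values):
                raise ValueError("strata length does not match subjects")

    @property
    def subjects(self):
        return self.values.index.to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def matrix(self):
        """Full design matrix [1 | nuisance | target] and its column names."""
        n = self.n_subjects
        cols = ["(intercept)", *self.nuisance, self.target]
        X = np.empty((n, len(cols)))
        X[:, 0] = 1.0
        for j, c in enumerate(self.nuisance, start=1):
            X[:, j] = self.values[c].to_numpy(dtype=float)
        X[:, -1] = self.values[self.target].to_numpy(dtype=float)
        return X, cols

    def with_target(self, new_target: np.ndarray) -> "PhenotypeDesign":
        vals = self.values.copy()
        vals[self.target] = new_target
        return PhenotypeDesign(vals, self.target, self.nuisance, self.strata)


@dataclass
class ImagingMatrix:
    """Subjects x locations imaging matrix with a per-location validity mask."""

    data: np.ndarray
    location_ids: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("imaging data must be subjects x locations")
        n, v = self.data.shape
        if self.location_ids is None:
            self.location_ids = np.arange(v)
        self.location_ids = np.asarray(self.location_ids)
        if len(self.location_ids) != v:
            raise ValueError("location_ids length mismatch")
        if self.mask is None:
            self.mask = np.ones(v, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != v:
            raise ValueError("mask length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_locations(self) -> int:
        return self.data.shape[1]


@dataclass
class AssociationMap:
    """Per-location association statistics over the analyzable locations.

    ``location_index`` holds indices into the full location axis of the
    originating :class:`ImagingMatrix`, so maps stay aligned after masked or
    degenerate locations are dropped.
    """

    values: np.ndarray
    location_index: np.ndarray
    stat_kind: str = "t"
    origin: str | int = "observed"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.location_index = np.asarray(self.location_index)
        if self.values.shape != self.location_index.shape:
            raise ValueError("values and location_index must align")
        if self.stat_kind not in STAT_KINDS:
            raise ValueError(f"unknown stat_kind {self.stat_kind!r}")
        if not self.signed and np.any(self.values < 0):
            raise ValueError("unsigned statistic map contains negative values")

    @property
    def signed(self) -> bool:
        return self.stat_kind != "F"


@dataclass
class SurrogateMapSet:
    """K null association maps aligned to an observed map.

    ``maps`` is a (K, L) array over the same analyzable locations as the
    observed map; ``valid`` marks, per surrogate, the locations whose value is
    usable (spin surrogates can rotate medial-wall values into the cortex,
    which are then discarded).
    """

    maps: np.ndarray
    location_index: np.ndarray
    mechanism: str
    stat_kind: str = "t"
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.location_index = np.asarray(self.location_index)
        if self.maps.shape[1] != len(self.location_index):
            raise ValueError("surrogate maps misaligned with location_index")
        if self.valid is None:
            self.valid = np.ones_like(self.maps, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.maps.shape:
            raise ValueError("valid mask shape mismatch")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    def __len__(self) -> int:
        return self.K

    def __getitem__(self, k: int) -> AssociationMap:
        return AssociationMap(
            self.maps[k], self.location_index, self.stat_kind, origin=k
        )


@dataclass
class PermutationPlan:
    """K subject reorderings plus the scheme they realise.

    The same reordering is applied at every location within one permutation,
    which preserves the spatial autocorrelation of the association map.
    """

    K: int
    scheme: str
    seed: int
    permutations: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.scheme not in PERMUTATION_SCHEMES:
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")
        self.permutations = np.asarray(self.permutations)
        if self.permutations.ndim != 2 or self.permutations.shape[0] != self.K:
            raise ValueError("permutations must be a K x N integer array")
        n = self.permutations.shape[1]
        ref = np.arange(n)
        for row in self.permutations:
            if not np.array_equal(np.sort(row), ref):
                raise ValueError("each permutation must be a bijection of subjects")

    @property
    def n_subjects(self) -> int:
        return self.permutations.shape[1]

    @classmethod
    def generate(cls, n_subjects, K, scheme="freedman_lane", seed=0, strata=None):
        """Draw K uniformly random permutations (within strata if stratified)."""
        if K < 1:
            raise ValueError("K must be >= 1")
        rng = np.random.default_rng(seed)
        if scheme == "stratified":
            if strata is None:
                raise ValueError("stratified scheme requires strata labels")
            strata = np.asarray(strata)
            if len(strata) != n_subjects:
                raise ValueError("strata length mismatch")
            groups = [np.flatnonzero(strata == g) for g in np.unique(strata)]
            singletons = sum(1 for g in groups if len(g) == 1)
            if singletons:
                warnings.warn(
                    f"{singletons} stratum/strata of size 1: those subjects are "
                    "fixed under stratified permutation",
                    stacklevel=2,
                )
            perms = np.tile(np.arange(n_subjects), (K, 1))
            for g in groups:
                for k in range(K):
                    perms[k, g] = g[rng.permutation(len(g))]
        else:
            perms = np.stack([rng.permutation(n_subjects) for _ in range(K)])
        return cls(K=K, scheme=scheme, seed=seed, permutations=perms)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

# relative floors distinguishing "no residual signal" from true degeneracy
_REDUCED_RSS_FLOOR = 1e-16
_FULL_RSS_FLOOR = 1e-12


def _check_rank(X, cols):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via the QR diagonal
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [cols[j] for j in np.flatnonzero(diag <= tol)]
        raise DesignRankError(f"design matrix rank deficient; collinear columns: {bad}")


@dataclass
class _ModelParts:
    """Shared pieces of the location-wise OLS problem (analyzable columns only)."""

    Q: np.ndarray            # orthonormal basis of [1 | nuisance]
    xt: np.ndarray           # target residualised against Q
    xnorm: float
    df: int
    F: np.ndarray            # reduced-model fitted values, N x L
    e: np.ndarray            # reduced-model residuals,     N x L
    e2: np.ndarray           # column sums of squares of e
    cF: np.ndarray           # xt @ F (numerically ~0, kept for exactness)
    location_index: np.ndarray
    reduced_flat: np.ndarray  # columns where the reduced model is an exact fit
    y_scale: np.ndarray


def _prepare(imaging: ImagingMatrix, design: PhenotypeDesign) -> _ModelParts:
    X, cols = design.matrix()
    n, p = X.shape
    if imaging.n_subjects != n:
        raise ValueError("imaging rows do not match phenotype subjects")
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} subjects for {p} coefficients")
    _check_rank(X, cols)

    Q, _ = np.linalg.qr(X[:, :-1])
    x = X[:, -1]
    xt = x - Q @ (Q.T @ x)
    xnorm2 = float(xt @ xt)
    if xnorm2 <= n * np.finfo(float).eps * max(1.0, float(x @ x)):
        raise DesignRankError(
            f"target column {design.target!r} is collinear with the nuisance set"
        )
    df = n - p

    keep = np.flatnonzero(imaging.mask)
    Y = imaging.data[:, keep]
    if Y.shape[1] == 0:
        raise ValueError("no analyzable locations (mask is empty)")
    y_scale = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)

    F = Q @ (Q.T @ Y)
    e = Y - F
    e2 = np.einsum("nv,nv->v", e, e)
    cF = xt @ F
    reduced_flat = e2 <= np.maximum(y_scale, 1.0) * _REDUCED_RSS_FLOOR

    # degeneracy: constant columns, or target perfectly absorbing the residual
    B = np.vstack([Q.T @ e, (xt @ e) / np.sqrt(xnorm2)])
    rss = np.clip(e2 - np.einsum("rv,rv->v", B, B), 0.0, None)
    degenerate = (y_scale == 0.0) | (
        ~reduced_flat & (rss <= e2 * _FULL_RSS_FLOOR)
    )
    if degenerate.all():
        raise ValueError("all locations are degenerate (zero residual variance)")
    good = ~degenerate
    return _ModelParts(
        Q=Q,
        xt=xt,
        xnorm=float(np.sqrt(xnorm2)),
        df=df,
        F=F[:, good],
        e=e[:, good],
        e2=e2[good],
        cF=cF[good],
        location_index=keep[good],
        reduced_flat=reduced_flat[good],
        y_scale=y_scale[good],
    )


def _t_maps(parts: _ModelParts, perms: np.ndarray) -> np.ndarray:
    """Target t-statistics for the maps F + P_k e, one row per permutation."""
    R = np.column_stack([parts.Q, parts.xt / parts.xnorm])
    out = np.empty((len(perms), parts.e.shape[1]))
    for k, p in enumerate(perms):
        inv = np.argsort(p)
        B = R[inv].T @ parts.e                       # (q+2) x L
        dot = parts.cF + parts.xnorm * B[-1]
        rss = parts.e2 - np.einsum("rv,rv->v", B, B)
        np.clip(rss, 0.0, None, out=rss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = dot / (parts.xnorm * np.sqrt(rss / parts.df))
        t[parts.reduced_flat] = 0.0                  # no residual signal: t = 0
        out[k] = t
    return out


def _convert_stat(t: np.ndarray, df: int, stat_kind: str) -> np.ndarray:
    if stat_kind == "t":
        return t
    if stat_kind == "pearson_r":
        return t / np.sqrt(t * t + df)
    if stat_kind == "F":
        return t * t
    raise ValueError(f"unknown stat_kind {stat_kind!r}")


_IDENTITY = None  # sentinel for the identity permutation


def fit_association_map(imaging, design, stat_kind="t") -> AssociationMap:
    """Fit Y_v on [1 | nuisance | target] at every location.

    Returns the target statistic per analyzable location; locations with zero
    residual variance are dropped (flagged degenerate) rather than assigned a
    value.
    """
    parts = _prepare(imaging, design)
    identity = np.arange(imaging.n_subjects)[None, :]
    t = _t_maps(parts, identity)[0]
    return AssociationMap(
        _convert_stat(t, parts.df, stat_kind),
        parts.location_index,
        stat_kind,
        origin="observed",
    )


def freedman_lane_null_maps(imaging, design, plan, stat_kind="t") -> SurrogateMapSet:
    """K Freedman--Lane null association maps.

    For each permutation k: regress every Y_v on the reduced model (intercept
    + nuisance), permute the residual rows by the shared reordering, add back
    the reduced-model fits, refit the full model and extract the target
    statistic.  With an empty nuisance set this reduces to simple permutation
    of the phenotype-free residuals about the intercept.
    """
    if plan.scheme != "freedman_lane":
        raise ValueError(f"plan scheme is {plan.scheme!r}, expected 'freedman_lane'")
    if plan.K < 1:
        raise ValueError("K must be >= 1")
    if plan.n_subjects != imaging.n_subjects:
        raise ValueError("permutation plan does not match subject count")
    parts = _prepare(imaging, design)
    t = _t_maps(parts, plan.permutations)
    return SurrogateMapSet(
        _convert_stat(t, parts.df, stat_kind),
        parts.location_index,
        mechanism="phenotype_permutation",
        stat_kind=stat_kind,
    )


def permute_phenotype(design, plan):
    """K designs in which only the target column is reordered."""
    target = design.values[design.target].to_numpy()
    return [design.with_target(target[p]) for p in plan.permutations]
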