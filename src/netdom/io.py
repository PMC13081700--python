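"""File readers/writers, run configuration, and the multi-network pipeline.

Conventions: locations are 0-based internally; label and mask files are one
integer per line in vertex order; GIFTI inputs are concatenated left hemisphere
first, then right.  Floating-point output is printed at 6 significant digits
and permutation p-values can never render as 0 (they are bounded below by
1/(K+1)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparators import SphereGeometry, VariogramConfig, rigea_test, \
    spin_surrogates, surrogate_test, variogram_surrogates, weighted_ks_enrichment
from .core import (
    DEFAULT_GAMMA_GRID,
    GammaGrid,
    NetworkPartition,
    bh_fdr,
    netdom_from_maps,
)
from .glm import (
    ImagingMatrix,
    PermutationPlan,
    PhenotypeDesign,
    fit_association_map,
    freedman_lane_null_maps,
)

logger = logging.getLogger("netdom")

__all__ = ["AnalysisConfig", "load_inputs", "run_analysis", "write_results"]

RESULT_COLUMNS = [
    "network_id", "side", "method", "m", "n", "mean_in", "mean_out",
    "gamma_selected", "p_diff", "p_zero", "p", "p_fdr", "K", "seed",
]


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one enrichment analysis run."""

    imaging: str
    phenotype: str
    labels: str
    target: str
    nuisance: tuple = ()
    mask: str | None = None
    coordinates: str | None = None
    subject_column: str | None = None  # default: first phenotype column
    side: str = "right"
    stat_kind: str = "t"
    method: str = "netdom"
    K: int = 1000
    seed: int = 0
    gamma_grid: tuple = tuple(DEFAULT_GAMMA_GRID)
    networks: tuple | None = None  # None = every non-zero label
    output_dir: str = "netdom_results"

    def __post_init__(self):
        self.nuisance = tuple(self.nuisance)
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        if self.side == "left" and self.stat_kind == "F":
            raise ValueError("left-sided test is undefined for the unsigned F statistic")
        if self.networks is not None:
            self.networks = tuple(int(n) for n in self.networks)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_gifti_data(path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    arrays = [np.asarray(d.data) for d in img.darrays]
    return arrays[0] if len(arrays) == 1 else np.stack(arrays)


def _load_imaging(path) -> tuple:
    """Imaging matrix from CSV (subjects x locations), .npy, or GIFTI pair."""
    paths = [Path(p) for p in (path if isinstance(path, (list, tuple)) else [path])]
    suffix = paths[0].suffix.lower()
    if suffix == ".npy":
        return np.load(paths[0]), None, None
    if suffix == ".gii" or paths[0].name.endswith(".gii.gz"):
        # one metric file per hemisphere, concatenated in file order (L then R)
        parts = [np.atleast_2d(_read_gifti_data(p)) for p in paths]
        return np.concatenate(parts, axis=1), None, None
    df = pd.read_csv(paths[0], index_col=0)
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"non-numeric imaging values in columns: {list(bad)}")
    return df.to_numpy(dtype=float), df.index.to_numpy(), df.columns.to_numpy()


def _load_int_vector(path) -> np.ndarray:
    p = Path(path)
    if p.suffix.lower() == ".gii" or p.name.endswith(".gii.gz"):
        return _read_gifti_data(p).astype(int).ravel()
    return np.loadtxt(p, dtype=int).ravel()


def _load_coordinates(path):
    p = Path(path)
    if p.suffix.lower() == ".gii" or p.name.endswith(".gii.gz"):
        import nibabel as nib

        img = nib.load(str(p))
        return np.asarray(img.darrays[0].data, dtype=float)
    df = pd.read_csv(p)
    return df.to_numpy(dtype=float)


def load_inputs(config: AnalysisConfig):
    """Read and align imaging, phenotype, labels, mask, and coordinates.

    Phenotype rows are reordered to the imaging subject order by ID join when
    both carry subject identifiers; mismatched subjects are reported by ID.
    """
    data, subj_ids, loc_ids = _load_imaging(config.imaging)

    pheno = pd.read_csv(config.phenotype)
    id_col = config.subject_column or pheno.columns[0]
    if id_col not in pheno.columns:
        raise KeyError(f"subject-ID column {id_col!r} not in phenotype table")
    pheno = pheno.set_index(id_col)

    if subj_ids is not None:
        subj_ids = pd.Index(subj_ids).astype(str)
        pheno.index = pheno.index.astype(str)
        missing = subj_ids.difference(pheno.index)
        extra = pheno.index.difference(subj_ids)
        if len(missing):
            raise ValueError(f"subjects missing from phenotype table: {list(missing)}")
        if len(extra):
            logger.warning("phenotype rows without imaging dropped: %s", list(extra))
        pheno = pheno.loc[subj_ids]
    elif len(pheno) != data.shape[0]:
        raise ValueError(
            f"phenotype rows ({len(pheno)}) do not match imaging rows ({data.shape[0]})"
        )

    labels = _load_int_vector(config.labels)
    if len(labels) != data.shape[1]:
        raise ValueError("label vector length does not match imaging locations")
    mask = None
    if config.mask is not None:
        mask = _load_int_vector(config.mask).astype(bool)

    imaging = ImagingMatrix(data, location_ids=loc_ids, mask=mask)
    design = PhenotypeDesign(pheno, target=config.target, nuisance=config.nuisance)

    geometry = None
    if config.coordinates is not None:
        coords = _load_coordinates(config.coordinates)
        if coords.shape[1] >= 4:  # x, y, z, hemisphere flag (0 = L, 1 = R)
            hemi = np.where(coords[:, 3] < 0.5, "L", "R")
            coords = coords[:, :3]
        else:
            hemi = np.where(coords[:, 0] < 0, "L", "R")
        medial = ~imaging.mask if mask is not None else None
        geometry = SphereGeometry(coords, hemi, medial_wall=medial)
    return imaging, design, labels, geometry


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _format_float(x):
    return float(f"{x:.6g}") if isinstance(x, (float, np.floating)) else x


def run_analysis(config: AnalysisConfig) -> pd.DataFrame:
    """One enrichment test per requested network, with BH-FDR across networks.

    Permutation null maps are computed once and reused for every network, so
    the FDR correction operates on p-values sharing a common null ensemble.
    Writes ``results.tsv`` and per-network diagnostics to ``diagnostics.json``
    in the configured output directory and returns the results table.
    """
    imaging, design, labels, geometry = load_inputs(config)
    logger.info(
        "netdom %s | method=%s side=%s stat=%s K=%d seed=%d grid=%s",
        __version__, config.method, config.side, config.stat_kind,
        config.K, config.seed, list(config.gamma_grid),
    )

    observed = fit_association_map(imaging, design, config.stat_kind)
    networks = config.networks
    if networks is None:
        present = np.unique(labels[observed.location_index])
        networks = tuple(int(x) for x in present if x != 0) or tuple(
            int(x) for x in present
        )

    needs_perms = config.method in ("netdom", "meandiff", "weighted_ks")
    nulls = None
    if needs_perms:
        plan = PermutationPlan.generate(
            imaging.n_subjects, config.K, "freedman_lane", config.seed
        )
        nulls = freedman_lane_null_maps(imaging, design, plan, config.stat_kind)
    elif config.method == "variogram":
        if config.coordinates is None:
            raise ValueError("variogram surrogates require coordinates")
        coords = _load_coordinates(config.coordinates)[observed.location_index]
        nulls = variogram_surrogates(observed, coords, config.K, config.seed,
                                     VariogramConfig())
    elif config.method == "spin":
        if geometry is None:
            raise ValueError("spin surrogates require coordinates")
        nulls = spin_surrogates(observed, geometry, config.K, config.seed)

    grid = GammaGrid(np.asarray(config.gamma_grid))
    rows, diagnostics = [], {}
    for net in networks:
        net_labels = labels[observed.location_index]
        if (net_labels == net).sum() < 2:
            logger.warning("network %s has m < 2 analyzable locations; skipped", net)
            continue
        partition = NetworkPartition(labels, net)
        base = {
            "network_id": net, "side": config.side, "method": config.method,
            "K": config.K, "seed": config.seed,
        }
        vals = observed.values
        in_mask = net_labels == net
        if config.method == "netdom":
            res = netdom_from_maps(observed, nulls, partition, grid, config.side)
            rows.append({**base, **res.to_row()})
            diagnostics[str(net)] = {
                "gammas": list(res.gammas),
                "D_obs": list(res.D_obs),
                "p_gamma": list(res.p_gamma),
                "q_obs": res.q_obs,
                "gamma_selected": res.gamma_selected,
                "p_diff": res.p_diff,
                "p_zero": res.p_zero,
                "p": res.p,
            }
        else:
            if config.method == "rigea":
                p = rigea_test(observed, partition, config.side)
            elif config.method in ("meandiff", "variogram", "spin"):
                p = surrogate_test(observed, partition, nulls, config.side)
            elif config.method == "weighted_ks":
                p = weighted_ks_enrichment(observed, partition, nulls, config.side)
            else:
                raise ValueError(f"unknown method {config.method!r}")
            rows.append({
                **base,
                "m": int(in_mask.sum()), "n": int((~in_mask).sum()),
                "mean_in": float(vals[in_mask].mean()),
                "mean_out": float(vals[~in_mask].mean()),
                "gamma_selected": np.nan, "p_diff": np.nan, "p_zero": np.nan,
                "p": p,
            })

    if not rows:
        raise ValueError("no testable networks (all have m < 2)")
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_fdr(table["p"].to_numpy())
    table = table[RESULT_COLUMNS]

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(table, out / "results.tsv")
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(
            {
                "version": __version__, "seed": config.seed, "K": config.K,
                "side": config.side, "stat_kind": config.stat_kind,
                "gamma_grid": list(map(float, config.gamma_grid)),
                "networks": diagnostics,
            },
            fh, indent=2, default=float,
        )
    logger.info("wrote %s", out / "results.tsv")
    return table


def write_results(table: pd.DataFrame, path):
    """TSV writer with 6-significant-digit floats."""
    formatted = table.copy()
    for col in formatted.columns:
        if pd.api.types.is_float_dtype(formatted[col]):
            formatted[col] = formatted[col].map(
                lambda x: f"{x:.6g}" if pd.notna(x) else ""
            )
    formatted.to_csv(path, sep="\t", index=False)
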