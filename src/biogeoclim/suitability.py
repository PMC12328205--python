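"""DOMAIN habitat-suitability mapping with Gower similarity.

Each map cell is scored by its similarity to the environmentally nearest
training observation: similarity = 1 - Gower distance, where the Gower
distance is the mean over variables of |x - y| / range, with each
per-variable term clipped at 1. Ranges are the max - min over the training
points united with the training-slice land cells. Presence-only, no
background sampling, no thresholding — maps are read as continuous fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .climate import ClimateGrid, nearest_land_cell
from .niche import extract_climate
from .occurrences import DEFAULT_STAGES, OccurrenceRecord, StageTable

__all__ = [
    "GowerConfig",
    "SuitabilityMap",
    "gower_similarity",
    "DomainSuitability",
    "build_suitability_map",
    "calibrate_and_project",
    "TRAINING_STAGES",
]

SUITABILITY_VARIABLES = ("MAT", "MAP")


@dataclass(frozen=True)
class GowerConfig:
    """Variables and per-variable normalization ranges (max - min)."""

    variables: tuple[str, ...] = SUITABILITY_VARIABLES
    ranges: tuple[float, ...] = ()

    def __post_init__(self):
        if self.ranges and len(self.ranges) != len(self.variables):
            raise ValueError("one range per variable required")
        if any(r <= 0 for r in self.ranges):
            raise ValueError("ranges must be positive")


def gower_similarity(x, y, config: GowerConfig) -> float:
    """Similarity in [0, 1] between two climate vectors."""
    if not config.ranges:
        raise ValueError("GowerConfig.ranges must be set")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    terms = np.clip(np.abs(x - y) / np.asarray(config.ranges), 0.0, 1.0)
    return float(1.0 - np.clip(terms.mean(), 0.0, 1.0))


@dataclass
class SuitabilityMap:
    """Per-cell DOMAIN suitability on one stage-slice grid."""

    lats: np.ndarray
    lons: np.ndarray
    suitability: np.ndarray     # (nlat, nlon), NaN over sea
    land: np.ndarray
    clade: str = ""
    training_slice: str = ""
    target_slice: str = ""
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        vals = self.suitability[self.land]
        return {
            "clade": self.clade,
            "target_slice": self.target_slice,
            "n_land_cells": int(self.land.sum()),
            "mean_suitability": float(np.mean(vals)) if len(vals) else np.nan,
            "frac_above_0.5": float(np.mean(vals > 0.5)) if len(vals) else np.nan,
            "frac_above_0.8": float(np.mean(vals > 0.8)) if len(vals) else np.nan,
        }


class DomainSuitability(BaseEstimator):
    """Scikit-learn-style DOMAIN model over climate vectors.

    Parameters
    ----------
    variables : tuple of str
        Climate variables used (default MAT, MAP).
    ranges : tuple of float or None
        Gower normalization ranges; computed in :meth:`fit` from the
        training points (united with ``domain`` cells, if given) when None.

    After :meth:`fit`: ``training_points_`` (n x p) and ``config_``.
    :meth:`predict` returns the max Gower similarity of each input vector
    to the training points.
    """

    def __init__(self, variables: tuple = SUITABILITY_VARIABLES, ranges=None):
        self.variables = variables
        self.ranges = ranges

    def fit(self, X, y=None, domain=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            raise ValueError("empty training set")
        if X.shape[1] != len(self.variables):
            raise ValueError(f"expected {len(self.variables)} variables")
        self.training_points_ = X
        if self.ranges is not None:
            ranges = tuple(self.ranges)
        else:
            pool = X if domain is None else np.vstack([X, np.atleast_2d(domain)])
            ranges = tuple(np.ptp(pool, axis=0))
            if any(r <= 0 for r in ranges):
                raise ValueError(
                    "a variable is constant over training + domain; supply ranges"
                )
        self.config_ = GowerConfig(variables=tuple(self.variables), ranges=ranges)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ranges = np.asarray(self.config_.ranges)
        # (n_cells, n_train, p) term tensor, chunked to bound memory
        out = np.empty(len(X))
        train = self.training_points_
        step = max(1, int(2e6 // max(train.size, 1)))
        for i0 in range(0, len(X), step):
            chunk = X[i0 : i0 + step]
            diffs = np.abs(chunk[:, None, :] - train[None, :, :]) / ranges
            np.clip(diffs, 0.0, 1.0, out=diffs)
            dist = np.clip(diffs.mean(axis=2), 0.0, 1.0)
            out[i0 : i0 + step] = 1.0 - dist.min(axis=1)
        return out


def _grid_vectors(per_var: dict, variables) -> tuple[np.ndarray, np.ndarray, ClimateGrid]:
    """Stack co-registered grids into (nlat*nlon, p) with a land mask."""
    ref: ClimateGrid = per_var[variables[0]]
    mats = []
    for v in variables:
        g = per_var[v]
        if g.values.shape != ref.values.shape:
            raise ValueError("target grids are not co-registered")
        mats.append(g.values.ravel())
    return np.column_stack(mats), ref.land.ravel(), ref


def build_suitability_map(
    training_points,
    per_var_grids: dict,
    config: GowerConfig | None = None,
    clade: str = "",
    training_slice: str = "",
) -> SuitabilityMap:
    """Score every land cell of a target slice against training vectors.

    ``per_var_grids`` maps variable -> ClimateGrid for one slice. The
    nearest observation is nearest in environmental, not geographic, space.
    """
    variables = config.variables if config else SUITABILITY_VARIABLES
    model = DomainSuitability(variables=variables,
                             ranges=config.ranges if config else None)
    X, land, ref = _grid_vectors(per_var_grids, variables)
    model.fit(np.asarray(training_points, dtype=float),
              domain=X[land] if config is None else None)
    suit = np.full(len(X), np.nan)
    suit[land] = model.predict(X[land])
    return SuitabilityMap(
        lats=ref.lats,
        lons=ref.lons,
        suitability=suit.reshape(ref.values.shape),
        land=ref.land.copy(),
        clade=clade,
        training_slice=training_slice,
        target_slice=ref.slice_name,
        metadata={"ranges": list(model.config_.ranges), "variables": list(variables)},
    )


# Compound calibration sets: the best-sampled middle-late Norian core plus
# the clade-specific outliers (Carnian lagerpetids; full-Norian pterosaurs).
TRAINING_STAGES = {
    "lagerpetid": ("early Carnian", "late Carnian", "middle Norian", "late Norian"),
    "pterosaur": ("early Norian", "middle Norian", "late Norian"),
}
TRAINING_SLICE = "late Norian"  # the 217.8 Ma slice anchors normalization


def calibrate_and_project(
    records: list[OccurrenceRecord],
    grids: dict,
    clade: str,
    stages: StageTable = DEFAULT_STAGES,
    training_slice: str = TRAINING_SLICE,
    training_stages: tuple | None = None,
    project_slices: tuple | None = None,
) -> dict[str, SuitabilityMap]:
    """Calibrate DOMAIN on a compound occurrence set and project per slice.

    Training vectors are extracted at each compound-set occurrence from its
    own stage slice(s); normalization ranges pool the training vectors with
    the ``training_slice`` land cells. Returns slice name -> SuitabilityMap.
    """
    if training_stages is None:
        if clade not in TRAINING_STAGES:
            raise ValueError(f"no default training stages for clade {clade!r}")
        training_stages = TRAINING_STAGES[clade]
    pool = [
        r for r in records
        if r.clade == clade
        and stages.span_resolves(r.stage_early, r.stage_late)
        and any(s in training_stages for s in stages.span(r.stage_early, r.stage_late))
    ]
    if not pool:
        raise ValueError(f"no occurrences for clade {clade!r} in the training stages")
    climate = extract_climate(pool, grids, stages)
    train = climate[list(SUITABILITY_VARIABLES)].to_numpy()
    dom, land, _ = _grid_vectors(grids[training_slice], SUITABILITY_VARIABLES)
    model = DomainSuitability().fit(train, domain=dom[land])
    config = model.config_
    if project_slices is None:
        project_slices = stages.names
    out = {}
    for sl in project_slices:
        out[sl] = build_suitability_map(
            train, grids[sl], config=config, clade=clade, training_slice=training_slice
        )
        out[sl].metadata["n_training"] = len(train)
    return out


def maps_summary(maps: dict[str, SuitabilityMap]) -> pd.DataFrame:
    return pd.DataFrame([m.summary() for m in maps.values()])
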