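"""Correlation features: molecules x propagation settings.

For every molecule and every propagation setting (edge-score threshold,
disease-side restart probability c_d, molecule-side restart probability
c_m) the feature is the Pearson correlation between the disease
perturbation profile computed at (threshold, c_d) and the molecule
perturbation profile computed at (threshold, c_m), taken over the full
node universe.  The default grid enumerates 3 thresholds x 24 disease-c
x 30 molecule-c = 2,160 settings, with the restart probabilities
log-spaced on [0.0001, 1.0] inclusive of both endpoints.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .interactome import Interactome, apply_threshold, build_transition
from .propagation import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    PropagationSettings,
    SeedSet,
    make_rwr_solver,
    restart_vector,
    rwr,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (400, 600, 800)
DEFAULT_N_C_DISEASE = 24
DEFAULT_N_C_MOLECULE = 30


def log_spaced_restarts(n: int, lo: float = 0.0001, hi: float = 1.0) -> tuple[float, ...]:
    """n log-spaced restart probabilities on [lo, hi], endpoints included."""
    if n < 2:
        raise ValueError("need at least 2 grid points to include both endpoints")
    return tuple(float(c) for c in np.logspace(np.log10(lo), np.log10(hi), n))


@dataclass(frozen=True)
class SettingsGrid:
    """The cartesian grid of propagation settings.

    Enumeration order is thresholds outer, c_disease middle, c_molecule
    inner; feature-matrix columns follow this order.
    """

    thresholds: tuple[int, ...]
    c_disease_grid: tuple[float, ...]
    c_molecule_grid: tuple[float, ...]

    def enumerate(self) -> list[PropagationSettings]:
        return [
            PropagationSettings(threshold=t, c_disease=cd, c_molecule=cm)
            for t in self.thresholds
            for cd in self.c_disease_grid
            for cm in self.c_molecule_grid
        ]

    def __len__(self) -> int:
        return (
            len(self.thresholds)
            * len(self.c_disease_grid)
            * len(self.c_molecule_grid)
        )

    def to_dict(self) -> dict:
        return {
            "thresholds": list(self.thresholds),
            "c_disease_grid": list(self.c_disease_grid),
            "c_molecule_grid": list(self.c_molecule_grid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SettingsGrid":
        return cls(
            thresholds=tuple(int(t) for t in d["thresholds"]),
            c_disease_grid=tuple(float(c) for c in d["c_disease_grid"]),
            c_molecule_grid=tuple(float(c) for c in d["c_molecule_grid"]),
        )


def default_grid() -> SettingsGrid:
    """Thresholds (400, 600, 800) x 24 disease-c x 30 molecule-c = 2,160."""
    return SettingsGrid(
        thresholds=DEFAULT_THRESHOLDS,
        c_disease_grid=log_spaced_restarts(DEFAULT_N_C_DISEASE),
        c_molecule_grid=log_spaced_restarts(DEFAULT_N_C_MOLECULE),
    )


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two profile vectors.

    Zero-variance input is an error: a constant perturbation profile
    signals a degenerate propagation rather than a meaningful feature.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("pearson needs two equal-length vectors of size >= 2")
    da = a - a.mean()
    db = b - b.mean()
    na = float(np.sqrt(da @ da))
    nb = float(np.sqrt(db @ db))
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-variance input to pearson (constant profile)")
    r = float((da @ db) / (na * nb))
    return min(1.0, max(-1.0, r))


@dataclass(frozen=True)
class FeatureMatrix:
    """Molecules x settings table of Pearson correlations."""

    molecules: tuple[str, ...]
    settings: tuple[PropagationSettings, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.molecules), len(self.settings)):
            raise ValueError("feature matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=list(self.molecules),
            columns=[s.label() for s in self.settings],
        )

    def row(self, molecule_id: str) -> np.ndarray:
        return self.values[self.molecules.index(molecule_id)]

    def subset(self, molecule_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.molecules.index(m) for m in molecule_ids]
        return FeatureMatrix(
            molecules=tuple(molecule_ids),
            settings=self.settings,
            values=self.values[idx],
        )


def write_feature_matrix(fm: FeatureMatrix, path: str | Path, grid: SettingsGrid | None = None) -> None:
    """Persist as TSV; the grid definition goes to a JSON sidecar."""
    path = Path(path)
    fm.to_frame().to_csv(path, sep="\t", index_label="molecule", float_format="%.17g")
    sidecar = {"settings": [[s.threshold, s.c_disease, s.c_molecule] for s in fm.settings]}
    if grid is not None:
        sidecar["grid"] = grid.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col="molecule")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    settings = tuple(
        PropagationSettings(threshold=int(t), c_disease=cd, c_molecule=cm)
        for t, cd, cm in sidecar["settings"]
    )
    return FeatureMatrix(
        molecules=tuple(str(m) for m in frame.index),
        settings=settings,
        values=frame.to_numpy(dtype=float),
    )


class PerturbationFeaturizer(BaseEstimator, TransformerMixin):
    """Transform molecule seed sets into profile-correlation features.

    Fitting precomputes, per edge-score threshold, the transition
    operator and the disease perturbation profiles for every
    disease-side restart probability.  ``transform`` then propagates
    each molecule's targets at every (threshold, c_molecule) pair and
    correlates against the cached disease profiles, yielding one row
    per molecule with columns in grid-enumeration order.

    Parameters
    ----------
    network : Interactome
        The full (unthresholded) interaction network.
    disease_seeds : SeedSet
        Disease-associated proteins.
    grid : SettingsGrid, optional
        Defaults to :func:`default_grid`.
    weighting : {'raw', 'binary'}
        Whether confidence scores weight the walk or are binarised.
    solver : {'direct', 'power'}
        'direct' (default) computes each fixed point exactly through a
        cached sparse LU factorisation per (threshold, restart) pair;
        'power' runs the power iteration with ``tol``/``max_iter``.
    tol, max_iter : float, int
        Convergence control for the power iteration.
    """

    def __init__(
        self,
        network: Interactome,
        disease_seeds: SeedSet,
        grid: SettingsGrid | None = None,
        weighting: str = "raw",
        solver: str = "direct",
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ):
        self.network = network
        self.disease_seeds = disease_seeds
        self.grid = grid
        self.weighting = weighting
        self.solver = solver
        self.tol = tol
        self.max_iter = max_iter

    def _solver(self, threshold: int, c: float):
        op = self.operators_[threshold]
        if self.solver == "power":
            return lambda p0, seed_label="": rwr(
                op, p0, c, tol=self.tol, max_iter=self.max_iter, seed_label=seed_label
            )
        if self.solver != "direct":
            raise ValueError(f"solver must be 'direct' or 'power', got {self.solver!r}")
        key = (threshold, c)
        if key not in self._solvers_:
            self._solvers_[key] = make_rwr_solver(op, c)
        return self._solvers_[key]

    def fit(self, X=None, y=None) -> "PerturbationFeaturizer":
        grid = self.grid if self.grid is not None else default_grid()
        self.grid_ = grid
        self.settings_ = tuple(grid.enumerate())
        self.operators_ = {}
        self._solvers_ = {}
        self.disease_profiles_ = {}
        for t in grid.thresholds:
            op = build_transition(
                apply_threshold(self.network, t), weighting=self.weighting, threshold=t
            )
            self.operators_[t] = op
            p0 = restart_vector(self.disease_seeds, op.index)
            for cd in grid.c_disease_grid:
                self.disease_profiles_[(t, cd)] = self._solver(t, cd)(
                    p0, seed_label=self.disease_seeds.source_label
                ).values
        return self

    def transform(self, X: Sequence[SeedSet]) -> np.ndarray:
        if not hasattr(self, "operators_"):
            raise RuntimeError("PerturbationFeaturizer is not fitted")
        grid = self.grid_
        n_cols = len(self.settings_)
        out = np.empty((len(X), n_cols))
        for i, seeds in enumerate(X):
            col = 0
            for t in grid.thresholds:
                op = self.operators_[t]
                p0 = restart_vector(seeds, op.index)
                mol_profiles = {
                    cm: self._solver(t, cm)(p0, seed_label=seeds.source_label).values
                    for cm in grid.c_molecule_grid
                }
                for cd in grid.c_disease_grid:
                    dis = self.disease_profiles_[(t, cd)]
                    for cm in grid.c_molecule_grid:
                        out[i, col] = pearson(dis, mol_profiles[cm])
                        col += 1
        return out

    def feature_matrix(self, molecules: Sequence[SeedSet]) -> FeatureMatrix:
        """Transform and wrap with molecule and settings labels."""
        values = self.transform(molecules)
        return FeatureMatrix(
            molecules=tuple(m.source_label for m in molecules),
            settings=self.settings_,
            values=values,
        )


def build_feature_matrix(
    net: Interactome,
    disease_seeds: SeedSet,
    molecules: Sequence[SeedSet],
    grid: SettingsGrid | None = None,
    weighting: str = "raw",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FeatureMatrix:
    """One-call wrapper around :class:`PerturbationFeaturizer`."""
    if not molecules:
        raise ValueError("no molecules to featurize")
    feat = PerturbationFeaturizer(
        net, disease_seeds, grid=grid, weighting=weighting, tol=tol, max_iter=max_iter
    ).fit()
    return feat.feature_matrix(molecules)
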