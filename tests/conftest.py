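"""Shared fixtures: toy networks and the (expensive) synthetic study runs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import olivenet as ov
from olivenet.associations import filter_targets, targets_to_seeds
from olivenet.features import SettingsGrid, build_feature_matrix, log_spaced_restarts


@pytest.fixture
def triangle_net():
    """Weighted triangle A-B 200, A-C 400, B-C 800."""
    return ov.Interactome.from_edges(
        [("A", "B", 200), ("A", "C", 400), ("B", "C", 800)]
    )


@pytest.fixture
def path_net():
    """Unweighted path A-B-C (all scores 500)."""
    return ov.Interactome.from_edges([("A", "B", 500), ("B", "C", 500)])


@pytest.fixture(scope="session")
def scaled_grid():
    """The default threshold triple with 6x6 restart grids (desk scale)."""
    return SettingsGrid(
        thresholds=(400, 600, 800),
        c_disease_grid=log_spaced_restarts(6),
        c_molecule_grid=log_spaced_restarts(6),
    )


def _run_study(scenario, grid, n_repeats=25, rng_seed=1):
    """Generate a synthetic study, featurize, and fit the ensemble."""
    net = ov.generate_interactome(scenario)
    disease = ov.plant_disease_module(net, scenario)
    table, labels, queries, truth = ov.generate_molecules(net, disease, scenario)
    table = filter_targets(table)
    seeds = []
    for mol in table.molecules:
        s = targets_to_seeds(table, mol, net.index)
        if s is not None:
            seeds.append(s)
    fm = build_feature_matrix(net, disease, seeds, grid)
    labeled = [m for m in fm.molecules if m in labels.labels]
    X = np.array([fm.row(m) for m in labeled])
    y = np.array([1 if labels.labels[m] == "positive" else 0 for m in labeled])
    clf = ov.EnsembleCorrelationClassifier(
        n_repeats=n_repeats, random_state=rng_seed
    ).fit(X, y)
    return {
        "net": net,
        "disease": disease,
        "labels": labels,
        "queries": queries,
        "truth": truth,
        "features": fm,
        "X": X,
        "y": y,
        "clf": clf,
    }


@pytest.fixture(scope="session")
def planted_study(scaled_grid):
    """Default synthetic scenario (seed 1) run end-to-end, 25 CV repeats."""
    return _run_study(ov.SyntheticScenario(), scaled_grid)


@pytest.fixture(scope="session")
def null_study(scaled_grid):
    """Same scenario with overlap_prob = 0: positives carry no signal."""
    scenario = dataclasses.replace(ov.SyntheticScenario(), overlap_prob=0.0)
    return _run_study(scenario, scaled_grid)
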