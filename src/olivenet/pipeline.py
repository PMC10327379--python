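"""End-to-end orchestration: simulate/load -> propagate -> features ->
train -> score -> enrich -> report.

A run is driven by a :class:`RunConfig` (YAML on disk) and is a pure
function of the config and its seed: rerunning with the same config
produces bit-identical artifacts.  Each stage persists its intermediate
(feature matrix, model JSON, ranked table, per-molecule enrichment
tables) under the output directory, and the final report carries the
provenance (config hash, seed, package version) together with an
attrition log of everything that was dropped along the way.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .associations import (
    DEFAULT_TARGET_CUTOFF,
    filter_targets,
    read_labels,
    read_targets,
    targets_to_seeds,
)
from .classifier import EnsembleModel, predict_consensus, train_ensemble
from .enrichment import (
    DEFAULT_ALPHA,
    DEFAULT_MAX_SIZE,
    DEFAULT_MIN_SIZE,
    DEFAULT_N_PERM,
    DEFAULT_WEIGHT,
    enrich_collection,
    interaction_ranking,
    pathway_frequency,
    read_gmt,
    significant_pathways,
)
from .features import (
    PerturbationFeaturizer,
    SettingsGrid,
    log_spaced_restarts,
    write_feature_matrix,
)
from .interactome import read_edge_list
from .propagation import (
    PerturbationProfile,
    SeedSet,
    make_rwr_solver,
    read_seed_list,
    restart_vector,
)
from .synthetic_data import SyntheticScenario, simulate_to_dir

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs.

    Either ``scenario`` (synthetic inputs are generated into the output
    directory) or ``inputs`` (paths to network/seeds/targets/labels/
    gene-set files) must be given.
    """

    outdir: str
    seed: int = 1
    scenario: dict | None = None
    inputs: dict | None = None
    thresholds: tuple[int, ...] = (400, 600, 800)
    n_c_disease: int = 24
    n_c_molecule: int = 30
    weighting: str = "raw"
    target_cutoff: int = DEFAULT_TARGET_CUTOFF
    n_repeats: int = 25
    n_outer: int = 5
    n_inner: int = 5
    gsea_weight: float = DEFAULT_WEIGHT
    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    min_size: int = DEFAULT_MIN_SIZE
    max_size: int = DEFAULT_MAX_SIZE
    top_k: int = 10

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError("exactly one of 'scenario' or 'inputs' must be set")

    def grid(self) -> SettingsGrid:
        return SettingsGrid(
            thresholds=tuple(self.thresholds),
            c_disease_grid=log_spaced_restarts(self.n_c_disease),
            c_molecule_grid=log_spaced_restarts(self.n_c_molecule),
        )

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "scenario": self.scenario,
            "inputs": self.inputs,
            "thresholds": list(self.thresholds),
            "n_c_disease": self.n_c_disease,
            "n_c_molecule": self.n_c_molecule,
            "weighting": self.weighting,
            "target_cutoff": self.target_cutoff,
            "n_repeats": self.n_repeats,
            "n_outer": self.n_outer,
            "n_inner": self.n_inner,
            "gsea_weight": self.gsea_weight,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "min_size": self.min_size,
            "max_size": self.max_size,
            "top_k": self.top_k,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = tuple(int(t) for t in d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunReport:
    """Ranked molecule table with CV summary and provenance."""

    rows: tuple[dict, ...]  # rank, molecule_id, correlation_probability, pathways
    top_k_mean: float
    top_k: int
    cv: dict
    ensemble_size: int
    attrition: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "rows": list(self.rows),
            "top_k": self.top_k,
            "top_k_mean_correlation_probability": self.top_k_mean,
            "cv": self.cv,
            "ensemble_size": self.ensemble_size,
            "attrition": self.attrition,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("rank\tmolecule_id\tcorrelation_probability_percent\tpathways\n")
            for row in self.rows:
                fh.write(
                    f"{row['rank']}\t{row['molecule_id']}\t"
                    f"{row['correlation_probability']:.1f}\t"
                    f"{'; '.join(row['pathways'])}\n"
                )


def make_report(
    probabilities: Mapping[str, float],
    pathways: Mapping[str, Sequence[str]],
    meta: Mapping[str, Any] | None = None,
    top_k: int = 10,
) -> RunReport:
    """Rank molecules by consensus probability (descending, ties by id).

    The summary row is the mean probability of the top-k molecules,
    reported at full precision (the TSV rounds to one decimal).
    """
    if not probabilities:
        raise ValueError("no probabilities to report")
    order = sorted(probabilities, key=lambda m: (-probabilities[m], m))
    rows = tuple(
        {
            "rank": i + 1,
            "molecule_id": m,
            "correlation_probability": float(probabilities[m]),
            "pathways": list(pathways.get(m, [])),
        }
        for i, m in enumerate(order)
    )
    k = min(top_k, len(order))
    top_mean = float(np.mean([probabilities[m] for m in order[:k]]))
    meta = dict(meta or {})
    return RunReport(
        rows=rows,
        top_k_mean=top_mean,
        top_k=k,
        cv=meta.get("cv", {}),
        ensemble_size=meta.get("ensemble_size", 0),
        attrition=meta.get("attrition", {}),
        provenance=meta.get("provenance", {}),
    )


def _reference_setting(ensemble: EnsembleModel):
    """Member setting used for enrichment: highest member CV accuracy."""
    best = max(
        range(len(ensemble.members)),
        key=lambda i: (ensemble.members[i].cv_balanced_accuracy, -i),
    )
    return ensemble.members[best].setting


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and persist every intermediate artifact."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    attrition: dict[str, Any] = {}

    # -- stage 1: obtain inputs -----------------------------------------
    if config.scenario is not None:
        scenario = SyntheticScenario.from_dict(
            {**config.scenario, "rng_seed": config.scenario.get("rng_seed", config.seed)}
        )
        paths = {k: str(v) for k, v in simulate_to_dir(scenario, outdir / "sim").items()}
    else:
        paths = dict(config.inputs)
    for key in ("network", "disease_genes", "targets", "labels", "gene_sets"):
        if key not in paths or not Path(paths[key]).exists():
            raise FileNotFoundError(f"stage inputs: missing {key!r} file")

    net = read_edge_list(paths["network"])
    disease_genes = read_seed_list(paths["disease_genes"])
    disease = SeedSet(
        role="disease",
        members=frozenset(g for g in disease_genes if g in net.index),
        source_label="disease",
    )
    attrition["disease_genes_total"] = len(disease_genes)
    attrition["disease_genes_mapped"] = len(disease.members)

    targets = read_targets(paths["targets"])
    labels = read_labels(paths["labels"])
    gene_sets = read_gmt(paths["gene_sets"])

    # -- stage 2: target filtering and seed mapping ---------------------
    filtered = filter_targets(targets, config.target_cutoff)
    all_molecules = targets.molecules
    seeds: dict[str, SeedSet] = {}
    dropped: list[str] = []
    for mol in filtered.molecules:
        s = targets_to_seeds(filtered, mol, net.index)
        if s is None:
            dropped.append(mol)
        else:
            seeds[mol] = s
    dropped.extend(sorted(set(all_molecules) - set(filtered.molecules)))
    attrition["molecules_total"] = len(all_molecules)
    attrition["molecules_scorable"] = len(seeds)
    attrition["molecules_dropped"] = sorted(dropped)

    labeled_ids = [m for m in sorted(labels.labels) if m in seeds]
    query_ids = [m for m in sorted(seeds) if m not in labels.labels]

    # -- stage 3: correlation features ----------------------------------
    grid = config.grid()
    featurizer = PerturbationFeaturizer(
        net, disease, grid=grid, weighting=config.weighting
    ).fit()
    train_features = featurizer.feature_matrix([seeds[m] for m in labeled_ids])
    query_features = featurizer.feature_matrix([seeds[m] for m in query_ids])
    write_feature_matrix(train_features, outdir / "train_features.tsv", grid)
    write_feature_matrix(query_features, outdir / "query_features.tsv", grid)

    # -- stage 4: training ----------------------------------------------
    ensemble, _clf = train_ensemble(
        train_features, labels,
        n_repeats=config.n_repeats, n_outer=config.n_outer,
        n_inner=config.n_inner, rng_seed=config.seed,
    )
    ensemble.to_json(
        outdir / "model.json",
        extra={"grid": grid.to_dict(), "seed": config.seed, "version": __version__},
    )

    # -- stage 5: scoring -----------------------------------------------
    probabilities = predict_consensus(ensemble, query_features)

    # -- stage 6: enrichment of the top-k queries -----------------------
    ref = _reference_setting(ensemble)
    op = featurizer.operators_[ref.threshold]
    disease_profile = PerturbationProfile(
        values=featurizer.disease_profiles_[(ref.threshold, ref.c_disease)],
        seed_label="disease", settings=ref,
    )
    ranked_ids = sorted(probabilities, key=lambda m: (-probabilities[m], m))
    top_ids = ranked_ids[: config.top_k]
    per_molecule_pathways: dict[str, list[str]] = {}
    enrich_dir = outdir / "enrichment"
    enrich_dir.mkdir(exist_ok=True)
    solve = make_rwr_solver(op, ref.c_molecule)
    for i, mol in enumerate(top_ids):
        p0 = restart_vector(seeds[mol], op.index)
        mol_profile = solve(p0, seed_label=mol)
        mol_profile = PerturbationProfile(
            values=mol_profile.values, seed_label=mol, settings=ref
        )
        ranking = interaction_ranking(
            disease_profile, mol_profile, net.node_ids, molecule_label=mol
        )
        mol_seed = int(
            np.random.SeedSequence([config.seed, 5, i]).generate_state(1)[0]
        )
        results = enrich_collection(
            ranking, gene_sets, weight=config.gsea_weight,
            n_perm=config.n_perm, rng_seed=mol_seed,
            min_size=config.min_size, max_size=config.max_size,
        )
        with (enrich_dir / f"{mol}.tsv").open("w") as fh:
            fh.write("set_name\tes\tnominal_p\toverlap_size\ttested\n")
            for r in sorted(results, key=lambda r: r.set_name):
                fh.write(
                    f"{r.set_name}\t{r.es:.6g}\t{r.nominal_p:.6g}\t"
                    f"{r.overlap_size}\t{int(r.tested)}\n"
                )
        per_molecule_pathways[mol] = significant_pathways(results, config.alpha)
    freq = pathway_frequency(per_molecule_pathways)
    with (outdir / "pathway_frequency.tsv").open("w") as fh:
        fh.write("set_name\tcount\n")
        for name in sorted(freq, key=lambda s: (-freq[s], s)):
            fh.write(f"{name}\t{freq[name]}\n")

    # -- stage 7: report ------------------------------------------------
    report = make_report(
        probabilities,
        per_molecule_pathways,
        meta={
            "cv": {
                "mean_balanced_accuracy": ensemble.cv.mean_balanced_accuracy,
                "sd_balanced_accuracy": ensemble.cv.sd_balanced_accuracy,
                "n_repeats": ensemble.cv.n_repeats,
            },
            "ensemble_size": len(ensemble.members),
            "attrition": attrition,
            "provenance": {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "version": __version__,
            },
        },
        top_k=config.top_k,
    )
    report.to_json(outdir / "report.json")
    report.to_tsv(outdir / "ranked.tsv")
    return report
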