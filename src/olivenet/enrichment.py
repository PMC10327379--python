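"""Gene-set enrichment on the disease x molecule interaction vector.

The per-gene interaction score is the elementwise product of the
disease and molecule perturbation profiles; genes are ranked by it in
descending order and fed to a preranked GSEA: a weighted running-sum
(Kolmogorov-Smirnov-like) statistic whose significance is assessed by
permuting gene labels.  Hits increment the running sum by
|score|^weight normalised by the total in-set weight; misses decrement
by 1 / (N - N_hit); the enrichment score (ES) is the signed extremum.
The nominal p-value is the fraction of permutations whose |ES| reaches
the observed one, with the +1 pseudocount that keeps it positive.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .propagation import PerturbationProfile

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT = 1.0
DEFAULT_N_PERM = 1000
DEFAULT_MIN_SIZE = 3
DEFAULT_MAX_SIZE = 500
DEFAULT_ALPHA = 0.001


@dataclass(frozen=True)
class RankedGeneList:
    """Genes sorted by interaction score, descending; ties by gene id."""

    genes: tuple[str, ...]
    scores: np.ndarray = field(repr=False)
    molecule_label: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranking")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite scores in ranking")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nominal_p: float
    n_perm: int
    overlap_size: int
    tested: bool = True


def interaction_ranking(
    disease_profile: PerturbationProfile,
    molecule_profile: PerturbationProfile,
    node_ids: Sequence[str],
    molecule_label: str = "",
) -> RankedGeneList:
    """Rank genes by the product of disease and molecule perturbations.

    Both profiles must live on the same node universe (and, when their
    settings are recorded, the same edge-score threshold).
    """
    d = disease_profile.values
    m = molecule_profile.values
    if len(d) != len(m) or len(d) != len(node_ids):
        raise ValueError("profiles and node universe have mismatched lengths")
    if (
        disease_profile.settings is not None
        and molecule_profile.settings is not None
        and disease_profile.settings.threshold != molecule_profile.settings.threshold
    ):
        raise ValueError("profiles computed at different network thresholds")
    product = d * m
    # sort by score descending, ties broken lexicographically by gene id
    order = sorted(range(len(node_ids)), key=lambda i: (-product[i], node_ids[i]))
    return RankedGeneList(
        genes=tuple(node_ids[i] for i in order),
        scores=product[np.array(order)],
        molecule_label=molecule_label or molecule_profile.seed_label,
    )


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set file (name, description, members...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = frozenset(parts[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


#: tie window for the signed extremum: when the maximal positive and
#: negative running-sum deviations agree to this tolerance, the positive
#: one is reported (the deviations can tie exactly, e.g. at weight 0)
ES_TIE_TOL = 1e-12


def _signed_extremum(max_dev: float, min_dev: float) -> float:
    return max_dev if max_dev + ES_TIE_TOL >= -min_dev else min_dev


def _es_from_hits(abs_w: np.ndarray, hit_mask: np.ndarray) -> float:
    """Signed extremum of the weighted running sum for one hit pattern."""
    n = len(abs_w)
    n_hit = int(hit_mask.sum())
    hit_total = float(abs_w[hit_mask].sum())
    if hit_total > 0.0:
        inc = np.where(hit_mask, abs_w / hit_total, 0.0)
    else:  # all in-set scores are zero: fall back to uniform hit steps
        inc = np.where(hit_mask, 1.0 / n_hit, 0.0)
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hit)) if n > n_hit else 0.0
    running = np.cumsum(inc - dec)
    return _signed_extremum(float(running.max()), float(running.min()))


def gsea_prerank(
    ranking: RankedGeneList,
    gene_set: Iterable[str],
    set_name: str = "",
    weight: float = DEFAULT_WEIGHT,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> EnrichmentResult:
    """Preranked GSEA for one gene set.

    The null distribution permutes gene labels: each permutation places
    the overlap-many hits uniformly at random along the ranking and
    recomputes the running-sum extremum.  A set whose overlap with the
    ranking is below ``min_size`` (or above ``max_size``) is flagged
    untested rather than raising.
    """
    gene_set = frozenset(gene_set)
    hit_mask = np.array([g in gene_set for g in ranking.genes])
    n_hit = int(hit_mask.sum())
    n = len(ranking)
    if n_hit < min_size or n_hit > max_size or n_hit == n:
        return EnrichmentResult(
            set_name=set_name, es=float("nan"), nominal_p=float("nan"),
            n_perm=0, overlap_size=n_hit, tested=False,
        )
    abs_w = np.abs(ranking.scores) ** weight
    es = _es_from_hits(abs_w, hit_mask)

    rng = np.random.default_rng(rng_seed)
    # each permutation = a uniformly random placement of n_hit hits
    positions = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hit]
    perm_hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(perm_hits, positions, True, axis=1)
    hit_totals = (perm_hits * abs_w[None, :]).sum(axis=1)
    safe_tot = np.where(hit_totals > 0.0, hit_totals, 1.0)
    inc = np.where(
        perm_hits,
        np.where(hit_totals[:, None] > 0.0, abs_w[None, :] / safe_tot[:, None],
                 1.0 / n_hit),
        -1.0 / (n - n_hit),
    )
    running = np.cumsum(inc, axis=1)
    max_dev = running.max(axis=1)
    min_dev = running.min(axis=1)
    es_null = np.where(max_dev + ES_TIE_TOL >= -min_dev, max_dev, min_dev)
    p = (1.0 + float((np.abs(es_null) >= abs(es) - 1e-12).sum())) / (n_perm + 1.0)
    return EnrichmentResult(
        set_name=set_name, es=es, nominal_p=p, n_perm=n_perm,
        overlap_size=n_hit, tested=True,
    )


def enrich_collection(
    ranking: RankedGeneList,
    collection: Mapping[str, Iterable[str]],
    weight: float = DEFAULT_WEIGHT,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[EnrichmentResult]:
    """Run gsea_prerank over every set of a collection (sorted by name)."""
    return [
        gsea_prerank(
            ranking, collection[name], set_name=name, weight=weight,
            n_perm=n_perm, rng_seed=rng_seed, min_size=min_size, max_size=max_size,
        )
        for name in sorted(collection)
    ]


def significant_pathways(
    results: Sequence[EnrichmentResult], alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Set names with nominal p strictly below alpha, most significant first.

    Ties on p are broken by |ES| descending, then by name.
    """
    kept = [r for r in results if r.tested and r.nominal_p < alpha]
    kept.sort(key=lambda r: (r.nominal_p, -abs(r.es), r.set_name))
    return [r.set_name for r in kept]


def pathway_frequency(
    per_molecule_pathways: Mapping[str, Sequence[str]]
) -> dict[str, int]:
    """How many molecules' significant-pathway lists contain each set."""
    counts: Counter[str] = Counter()
    for pathways in per_molecule_pathways.values():
        counts.update(set(pathways))
    return dict(counts)
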