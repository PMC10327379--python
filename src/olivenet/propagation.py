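"""Random walk with restarts (RWR) over the interactome.

A seed set (disease genes or a molecule's protein targets) defines a
restart vector p0 with uniform mass on the mapped seeds.  The walk

    p <- c * p0 + (1 - c) * (W @ p + dangling_mass * p0)

is iterated to its fixed point, where ``c`` is the restart probability,
``W`` the column-stochastic transition operator and ``dangling_mass``
the probability currently sitting on nodes without outgoing edges
(redirected to the restart vector so that the profile stays a
probability distribution).  The fixed point is the perturbation profile:
how strongly each protein in the network is affected by perturbing the
seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .interactome import Interactome, TransitionOperator, apply_threshold, build_transition

logger = logging.getLogger(__name__)

C_MIN = 0.0001
C_MAX = 1.0

#: default L1 convergence tolerance of the power iteration
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance within max_iter."""


@dataclass(frozen=True)
class SeedSet:
    """A named set of seed proteins, either disease genes or drug targets."""

    role: str  # "disease" or "molecule"
    members: frozenset[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("disease", "molecule"):
            raise ValueError(f"role must be 'disease' or 'molecule', got {self.role!r}")
        if not self.members:
            raise ValueError(f"seed set {self.source_label!r} is empty")


@dataclass(frozen=True, order=True)
class PropagationSettings:
    """One point of the propagation grid.

    ``c_disease`` and ``c_molecule`` are the restart probabilities used
    for the disease-side and molecule-side walks respectively; the two
    sides are propagated independently.
    """

    threshold: int
    c_disease: float
    c_molecule: float

    def __post_init__(self) -> None:
        for c in (self.c_disease, self.c_molecule):
            if not C_MIN <= c <= C_MAX:
                raise ValueError(f"restart probability {c} outside [{C_MIN}, {C_MAX}]")

    def label(self) -> str:
        return f"t{self.threshold}_cd{self.c_disease:.6g}_cm{self.c_molecule:.6g}"


@dataclass(frozen=True)
class PerturbationProfile:
    """RWR stationary distribution over the node universe for one seed set."""

    values: np.ndarray = field(repr=False)
    seed_label: str = ""
    settings: PropagationSettings | None = None

    def __post_init__(self) -> None:
        total = float(self.values.sum())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile {self.seed_label!r} sums to {total}, not 1")


def read_seed_list(path: str | Path) -> list[str]:
    """Read a plain-text seed list, one identifier per line, '#' comments."""
    out: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def restart_vector(seeds: SeedSet, index: Mapping[str, int]) -> np.ndarray:
    """Uniform restart distribution over the seeds mapped into the universe.

    Seeds absent from the network are dropped with a warning; if no seed
    maps, a ValueError names the offending seed set.
    """
    mapped = [index[s] for s in sorted(seeds.members) if s in index]
    dropped = len(seeds.members) - len(mapped)
    if dropped:
        logger.warning(
            "seed set %r: %d of %d seeds not in the network universe",
            seeds.source_label, dropped, len(seeds.members),
        )
    if not mapped:
        raise ValueError(
            f"no seed of {seeds.source_label!r} maps into the network universe"
        )
    p0 = np.zeros(len(index))
    p0[mapped] = 1.0 / len(mapped)
    return p0


def rwr(
    operator: TransitionOperator,
    p0: np.ndarray,
    c: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed_label: str = "",
) -> PerturbationProfile:
    """Iterate the restart walk to its fixed point.

    Mass on dangling nodes is redirected to the restart vector each
    step, so the iterate remains on the probability simplex exactly.
    """
    if not C_MIN <= c <= C_MAX:
        raise ValueError(f"restart probability {c} outside [{C_MIN}, {C_MAX}]")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must sum to 1")
    if c == 1.0:
        return PerturbationProfile(values=p0.copy(), seed_label=seed_label)
    W = operator.matrix
    dangling = operator.dangling
    p = p0.copy()
    for _ in range(max_iter):
        dangling_mass = float(p[dangling].sum()) if dangling.any() else 0.0
        p_next = c * p0 + (1.0 - c) * (W @ p + dangling_mass * p0)
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return PerturbationProfile(values=p, seed_label=seed_label)
    raise ConvergenceError(
        f"RWR for {seed_label!r} did not converge in {max_iter} iterations "
        f"(final L1 residual {residual:.3e}, tol {tol:.3e})"
    )


def make_rwr_solver(operator: TransitionOperator, c: float):
    """Exact fixed-point solver, reusable across seed sets.

    The fixed point satisfies (I - (1-c)(W + p0 d^T)) p = c p0 with d
    the dangling-column indicator.  Factorising B = I - (1-c) W once
    (sparse LU) and applying the Sherman-Morrison identity for the
    rank-one dangling term reduces every seed set to a single
    triangular solve: p = c B^-1 p0 / (1 - (1-c) d^T B^-1 p0).  B is
    nonsingular because its off-diagonal column mass is at most 1 - c.

    Power iteration (:func:`rwr`) needs O(1/c) iterations, which is
    prohibitive at the small end of the restart grid (c = 1e-4); this
    solver is exact at any c and is what the featurizer uses.  The two
    paths are cross-checked in the tests.
    """
    if not C_MIN <= c <= C_MAX:
        raise ValueError(f"restart probability {c} outside [{C_MIN}, {C_MAX}]")
    n = operator.n_nodes
    if c == 1.0:
        def solve_restart(p0: np.ndarray, seed_label: str = "") -> PerturbationProfile:
            return PerturbationProfile(values=p0.copy(), seed_label=seed_label)
        return solve_restart
    B = (sp.identity(n, format="csc") - (1.0 - c) * operator.matrix).tocsc()
    lu = splu(B)
    dangling = operator.dangling

    def solve(p0: np.ndarray, seed_label: str = "") -> PerturbationProfile:
        if abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("p0 must sum to 1")
        x0 = lu.solve(p0)
        kappa = c / (1.0 - (1.0 - c) * float(x0[dangling].sum()))
        values = np.maximum(kappa * x0, 0.0)  # clip roundoff negatives
        values /= values.sum()
        return PerturbationProfile(values=values, seed_label=seed_label)

    return solve


def rwr_closed_form(
    operator: TransitionOperator, p0: np.ndarray, c: float
) -> np.ndarray:
    """Dense linear-solve fixed point (small networks only).

    Solves p = c p0 + (1-c)(W + p0 d^T) p directly, where d indicates
    dangling columns.  Used as an exact reference for the iterative walk.
    """
    n = len(p0)
    M = operator.matrix.toarray() + np.outer(p0, operator.dangling.astype(float))
    A = np.eye(n) - (1.0 - c) * M
    return c * np.linalg.solve(A, p0)


def profile_grid(
    net: Interactome,
    seeds: SeedSet,
    grid: Sequence[PropagationSettings],
    weighting: str = "raw",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> dict[PropagationSettings, PerturbationProfile]:
    """Propagate one seed set at every grid point.

    The transition operator per threshold is built once and cached, as
    is the profile per (threshold, restart probability): the restart
    probability relevant to this seed set's role (``c_disease`` for
    disease seeds, ``c_molecule`` for molecule seeds) is the only one
    that matters.
    """
    if not grid:
        raise ValueError("settings grid is empty")
    operators: dict[int, TransitionOperator] = {}
    profiles: dict[tuple[int, float], PerturbationProfile] = {}
    out: dict[PropagationSettings, PerturbationProfile] = {}
    for settings in grid:
        t = settings.threshold
        if t not in operators:
            operators[t] = build_transition(
                apply_threshold(net, t), weighting=weighting, threshold=t
            )
        c = settings.c_disease if seeds.role == "disease" else settings.c_molecule
        key = (t, c)
        if key not in profiles:
            p0 = restart_vector(seeds, operators[t].index)
            profiles[key] = rwr(
                operators[t], p0, c, tol=tol, max_iter=max_iter,
                seed_label=seeds.source_label,
            )
        prof = profiles[key]
        out[settings] = PerturbationProfile(
            values=prof.values, seed_label=prof.seed_label, settings=settings
        )
    return out


def write_profile(
    profile: PerturbationProfile, node_ids: Iterable[str], path: str | Path
) -> None:
    """Write a profile as a two-column TSV (node, value)."""
    with Path(path).open("w") as fh:
        fh.write("node\tvalue\n")
        for node, v in zip(node_ids, profile.values):
            fh.write(f"{node}\t{v:.17g}\n")
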