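"""Molecule-protein target tables and labeled drug sets.

Targets come as a STITCH-dialect TSV (chemical, protein, combined_score
in [0, 999]); labels as a two-column TSV mapping molecule ids to the
binary positive/negative training classes (positives: drugs in advanced
clinical trials against the disease; negatives: other approved drugs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .interactome import MAX_SCORE, EdgeListParseError
from .propagation import SeedSet

logger = logging.getLogger(__name__)

DEFAULT_TARGET_CUTOFF = 200


@dataclass(frozen=True)
class TargetTable:
    """Molecule -> protein interactions with integer confidence scores.

    One row per (molecule, protein) pair; duplicates are merged keeping
    the maximum score.
    """

    frame: pd.DataFrame = field(repr=False)  # columns: molecule, protein, score

    def __post_init__(self) -> None:
        expected = ["molecule", "protein", "score"]
        if list(self.frame.columns) != expected:
            raise ValueError(f"target table columns must be {expected}")

    @classmethod
    def from_rows(cls, rows: list[tuple[str, str, int]]) -> "TargetTable":
        frame = pd.DataFrame(rows, columns=["molecule", "protein", "score"])
        if len(frame):
            bad = frame[(frame["score"] < 0) | (frame["score"] > MAX_SCORE)]
            if len(bad):
                raise ValueError(
                    f"target scores outside [0, {MAX_SCORE}]: {bad.iloc[0].tolist()}"
                )
            frame = (
                frame.groupby(["molecule", "protein"], as_index=False)["score"]
                .max()
                .sort_values(["molecule", "protein"], ignore_index=True)
            )
        return cls(frame=frame)

    @property
    def molecules(self) -> list[str]:
        return sorted(self.frame["molecule"].unique())

    def targets_of(self, molecule_id: str) -> dict[str, int]:
        sub = self.frame[self.frame["molecule"] == molecule_id]
        return dict(zip(sub["protein"], sub["score"]))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class LabeledDrugSet:
    """Binary training labels: molecule id -> 'positive' | 'negative'."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"positive", "negative"}
        if bad:
            raise ValueError(f"labels must be positive/negative, got {sorted(bad)}")

    @property
    def positives(self) -> list[str]:
        return sorted(m for m, l in self.labels.items() if l == "positive")

    @property
    def negatives(self) -> list[str]:
        return sorted(m for m, l in self.labels.items() if l == "negative")

    def require_both_classes(self) -> None:
        if not self.positives or not self.negatives:
            raise ValueError("both classes must be nonempty for training")


def read_targets(path: str | Path, dialect: str = "stitch_tsv") -> TargetTable:
    """Read a STITCH-dialect TSV (chemical, protein, combined_score)."""
    if dialect != "stitch_tsv":
        raise ValueError(f"unknown target-table dialect {dialect!r}")
    path = Path(path)
    rows: list[tuple[str, str, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith(("chemical", "molecule")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(parts)}"
                )
            try:
                score = int(parts[2])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}:{lineno}: score {parts[2]!r} is not an integer"
                ) from exc
            rows.append((parts[0], parts[1], score))
    if not rows:
        logger.warning("target table %s is empty", path)
    return TargetTable.from_rows(rows)


def write_targets(table: TargetTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("chemical\tprotein\tcombined_score\n")
        for row in table.frame.itertuples(index=False):
            fh.write(f"{row.molecule}\t{row.protein}\t{row.score}\n")


def filter_targets(
    table: TargetTable, min_score: int = DEFAULT_TARGET_CUTOFF
) -> TargetTable:
    """Keep interactions with score >= ``min_score`` (boundary inclusive).

    Molecules left without any target are reported in the log; they are
    unscorable downstream.
    """
    if not 0 <= min_score <= MAX_SCORE:
        raise ValueError(f"min_score {min_score} outside [0, {MAX_SCORE}]")
    kept = table.frame[table.frame["score"] >= min_score].reset_index(drop=True)
    lost = sorted(set(table.frame["molecule"]) - set(kept["molecule"]))
    if lost:
        logger.warning(
            "%d molecules lost all targets at cutoff %d: %s",
            len(lost), min_score, ", ".join(lost[:10]),
        )
    return TargetTable(frame=kept)


def targets_to_seeds(
    table: TargetTable, molecule_id: str, universe: Mapping[str, int]
) -> SeedSet | None:
    """Turn one molecule's targets into a seed set over the network universe.

    Returns None (flagging the molecule unscorable) when no target maps
    into the universe; this is attrition, not a pipeline failure.
    """
    targets = table.targets_of(molecule_id)
    if not targets:
        raise KeyError(f"molecule {molecule_id!r} not present in the target table")
    mapped = frozenset(t for t in targets if t in universe)
    if len(mapped) < len(targets):
        logger.warning(
            "molecule %r: %d of %d targets not in the network universe",
            molecule_id, len(targets) - len(mapped), len(targets),
        )
    if not mapped:
        logger.warning("molecule %r has no mapped targets; unscorable", molecule_id)
        return None
    return SeedSet(role="molecule", members=mapped, source_label=molecule_id)


def read_labels(path: str | Path) -> LabeledDrugSet:
    """Read the two-column (molecule_id, positive|negative) label file."""
    labels: dict[str, str] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("molecule"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("positive", "negative"):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 'molecule_id positive|negative'"
                )
            if parts[0] in labels and labels[parts[0]] != parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: molecule {parts[0]!r} appears in both classes"
                )
            labels[parts[0]] = parts[1]
    return LabeledDrugSet(labels=labels)


def write_labels(labels: LabeledDrugSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("molecule_id\tlabel\n")
        for m in sorted(labels.labels):
            fh.write(f"{m}\t{labels.labels[m]}\n")
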