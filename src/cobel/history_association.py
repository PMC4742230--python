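"""Association of top enrichments with medical histories.

Each person contributes an ordered list of medical-history entries and one
top enriched term.  An association matrix (curated externally) marks which
history entries an enriched term is thought to relate to.  The test
shuffles histories across persons under matching constraints and asks how
often a random set of histories would still be associated with the
observed enrichments.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .null_models import EmpiricalResult

logger = logging.getLogger(__name__)

HistorySet = dict[str, list[str]]  # person -> ordered medical-history entries


def read_histories_tsv(path: str | Path) -> HistorySet:
    """Read a 2-column (person, entry) TSV, preserving entry order."""
    histories: HistorySet = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        person, entry = line.split("\t")[:2]
        if not entry:
            raise ValueError(f"empty history entry for {person!r}")
        histories.setdefault(person, []).append(entry)
    return histories


def write_histories_tsv(histories: HistorySet, path: str | Path) -> None:
    with open(path, "w") as out:
        for person in histories:
            for entry in histories[person]:
                out.write(f"{person}\t{entry}\n")


class AssociationMatrix:
    """Boolean links between history entries (rows) and enriched terms
    (columns)."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.astype(bool)

    @classmethod
    def from_dict(
        cls, links: Mapping[str, Mapping[str, bool]]
    ) -> "AssociationMatrix":
        """Build from {entry: {term: linked}} with full coverage."""
        return cls(pd.DataFrame(links).T)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssociationMatrix":
        """Read a TSV grid: header row of terms, first column of entries,
        cells 0/1."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int).astype(bool))

    def to_tsv(self, path: str | Path) -> None:
        self.table.astype(int).to_csv(path, sep="\t")

    def linked(self, entry: str, term: str) -> bool:
        if entry not in self.table.index or term not in self.table.columns:
            raise KeyError(f"association matrix has no cell for ({entry!r}, {term!r})")
        return bool(self.table.at[entry, term])


def _pairing_difference(original: HistorySet, shuffled: HistorySet) -> float:
    """Fraction of (person, entry) pairings that changed, as multisets."""
    total = sum(len(v) for v in original.values())
    same = 0
    for person in original:
        orig_counts: dict[str, int] = {}
        for e in original[person]:
            orig_counts[e] = orig_counts.get(e, 0) + 1
        for e in shuffled.get(person, []):
            if orig_counts.get(e, 0) > 0:
                orig_counts[e] -= 1
                same += 1
    return 1.0 - same / total


def shuffle_histories(
    histories: HistorySet,
    seed: int,
    min_diff_frac: float = 0.8,
    max_attempts: int = 10_000,
) -> HistorySet:
    """Random reassignment of history entries to persons under constraints.

    Per-person entry counts and the global entry multiset are preserved
    exactly; at least ``min_diff_frac`` of (person, entry) pairings must
    differ from the original.  Resamples until the difference constraint
    holds; raises if it cannot be met within ``max_attempts``.
    """
    persons = list(histories)
    if len(persons) < 2:
        raise ValueError("history shuffling requires at least two persons")
    entries = [e for p in persons for e in histories[p]]
    if any(not e for e in entries):
        raise ValueError("history entries must be non-empty")
    counts = [len(histories[p]) for p in persons]
    rng = np.random.default_rng(seed)
    order = np.arange(len(entries))
    for _ in range(max_attempts):
        rng.shuffle(order)
        shuffled: HistorySet = {}
        offset = 0
        for person, count in zip(persons, counts):
            shuffled[person] = [entries[i] for i in order[offset : offset + count]]
            offset += count
        if _pairing_difference(histories, shuffled) >= min_diff_frac:
            return shuffled
    raise RuntimeError(
        f"could not satisfy the {min_diff_frac:.0%} pairing-difference "
        f"constraint in {max_attempts} attempts"
    )


def set_is_associated(
    tops: Mapping[str, str],
    histories: HistorySet,
    matrix: AssociationMatrix,
    min_persons: int | None = None,
) -> bool:
    """Whether the assignment of top terms to persons is associated.

    By default every person's top term must be linked to at least one of
    that person's history entries; ``min_persons`` relaxes this to an
    "at least k of n" criterion.
    """
    matched = 0
    for person, term in tops.items():
        entries = histories.get(person, [])
        if any(matrix.linked(entry, term) for entry in entries):
            matched += 1
    required = len(tops) if min_persons is None else min_persons
    return matched >= required


def association_empirical_p(
    histories: HistorySet,
    tops: Mapping[str, str],
    matrix: AssociationMatrix,
    n_shuffles: int = 1000,
    seed: int = 0,
    min_diff_frac: float = 0.8,
    min_persons: int | None = None,
) -> EmpiricalResult:
    """Empirical chance that constrained random histories remain associated
    with the observed enrichments.

    p = (# shuffles for which the association holds) / n_shuffles.
    """
    if not set_is_associated(tops, histories, matrix, min_persons):
        logger.warning(
            "observed histories are not associated with the observed top terms; "
            "the permutation test is moot"
        )
    n_hits = 0
    for i in range(n_shuffles):
        shuffled = shuffle_histories(histories, seed + i, min_diff_frac)
        if set_is_associated(tops, shuffled, matrix, min_persons):
            n_hits += 1
    return EmpiricalResult(n_shuffles=n_shuffles, n_hits=n_hits)
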