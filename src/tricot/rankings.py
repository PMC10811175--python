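"""Data model and I/O for tricot farmer responses.

A tricot participant grows three masked entries (package slots A, B, C) and
names the best- and worst-performing one per trait.  Because a triad has only
three members, best + worst determine a complete strict ranking: the
unmentioned entry is second.  Rankings can be expanded ("rank-breaking") into
the pairwise comparisons they imply, which is how they reach Bradley-Terry
style models.

File formats
------------
``responses.csv``
    participant_id, block_index, item_A, item_B, item_C, trait, best, worst
    with best/worst in {A, B, C}; an empty best or worst marks the trait as
    not answered for that participant.
``rankings.csv``
    participant_id, trait, rank1, rank2, rank3[, weight].

All files are UTF-8 with "." as the decimal point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .exceptions import (
    DuplicateRecordError,
    InvalidResponseError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "TriadAssignment",
    "TricotResponse",
    "Ranking",
    "PairwiseComparison",
    "response_to_ranking",
    "break_ranking_to_pairs",
    "responses_to_rankings",
    "read_responses",
    "read_rankings",
    "write_rankings",
    "connectivity_check",
]

POSITION_LABELS = ("A", "B", "C")


@dataclass(frozen=True)
class TriadAssignment:
    """Three distinct items handed to one participant, keyed by package slot.

    ``block_index`` is the 1-based position of this package in the ordinal
    distribution sequence of the design.
    """

    participant_id: str
    block_index: int
    items: tuple[str, str, str]  # slots A, B, C in order

    def __post_init__(self):
        if len(self.items) != 3 or len(set(self.items)) != 3:
            raise ValidationError(
                f"assignment for {self.participant_id!r} must hold 3 distinct items, "
                f"got {self.items!r}"
            )
        if self.block_index < 1:
            raise ValidationError("block_index must be >= 1")

    def item_at(self, label: str) -> str:
        if label not in POSITION_LABELS:
            raise SchemaError(f"unknown position label {label!r}; expected one of A, B, C")
        return self.items[POSITION_LABELS.index(label)]


@dataclass(frozen=True)
class TricotResponse:
    """One participant's best/worst answer for one trait.

    ``best`` and ``worst`` are package-slot labels; both ``None`` marks the
    trait as not answered (a partially answered trait is treated as missing,
    never imputed).
    """

    participant_id: str
    trait: str
    best: str | None
    worst: str | None

    def __post_init__(self):
        if not self.trait:
            raise ValidationError("trait must be non-empty")
        for lab in (self.best, self.worst):
            if lab is not None and lab not in POSITION_LABELS:
                raise SchemaError(
                    f"unknown position label {lab!r}; expected one of A, B, C"
                )
        if self.best is not None and self.worst is not None and self.best == self.worst:
            raise InvalidResponseError(
                f"participant {self.participant_id!r}, trait {self.trait!r}: "
                f"best and worst are both {self.best!r}"
            )

    @property
    def is_missing(self) -> bool:
        return self.best is None or self.worst is None


@dataclass(frozen=True)
class Ranking:
    """A strict ordering of >= 2 distinct items, most preferred first."""

    ordered_items: tuple[str, ...]
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "ordered_items", tuple(self.ordered_items))
        if len(self.ordered_items) < 2:
            raise ValidationError("a ranking needs at least 2 items")
        if len(set(self.ordered_items)) != len(self.ordered_items):
            raise ValidationError(f"duplicate items in ranking {self.ordered_items!r}")
        if not self.weight > 0:
            raise ValidationError("ranking weight must be > 0")

    def __len__(self) -> int:
        return len(self.ordered_items)


@dataclass(frozen=True)
class PairwiseComparison:
    winner: str
    loser: str
    weight: float = 1.0

    def __post_init__(self):
        if self.winner == self.loser:
            raise ValidationError("winner and loser must differ")


def response_to_ranking(response: TricotResponse, assignment: TriadAssignment) -> Ranking:
    """Turn a best/worst answer into the complete 3-item ranking it implies.

    The item named best is first, the item named worst is last, and the
    remaining item of the triad takes second place.  Returns ``None`` for a
    missing (unanswered) response.
    """
    if response.participant_id != assignment.participant_id:
        raise ValidationError(
            f"response participant {response.participant_id!r} does not match "
            f"assignment participant {assignment.participant_id!r}"
        )
    if response.is_missing:
        return None
    best_item = assignment.item_at(response.best)
    worst_item = assignment.item_at(response.worst)
    (middle_item,) = [i for i in assignment.items if i not in (best_item, worst_item)]
    return Ranking((best_item, middle_item, worst_item))


def break_ranking_to_pairs(ranking: Ranking) -> list[PairwiseComparison]:
    """Rank-breaking: all m(m-1)/2 pairwise outcomes a ranking implies."""
    return [
        PairwiseComparison(w, l, ranking.weight)
        for w, l in itertools.combinations(ranking.ordered_items, 2)
    ]


_RESPONSE_COLUMNS = [
    "participant_id",
    "block_index",
    "item_A",
    "item_B",
    "item_C",
    "trait",
    "best",
    "worst",
]


def read_responses(path) -> tuple[list[TriadAssignment], list[TricotResponse]]:
    """Read a responses.csv file.

    Returns one assignment per distinct participant (the slot->item map) and
    one response per row.  A row with best == worst raises
    :class:`InvalidResponseError` naming the row; a duplicate
    (participant, trait) pair raises :class:`DuplicateRecordError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    assignments: dict[str, TriadAssignment] = {}
    responses: list[TricotResponse] = []
    seen: set[tuple[str, str]] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        pid = row.participant_id
        triad = (row.item_A, row.item_B, row.item_C)
        if pid in assignments:
            if assignments[pid].items != triad:
                raise SchemaError(
                    f"{path} row {row_number}: participant {pid!r} has conflicting triads"
                )
        else:
            assignments[pid] = TriadAssignment(pid, int(row.block_index), triad)
        key = (pid, row.trait)
        if key in seen:
            raise DuplicateRecordError(
                f"{path} row {row_number}: duplicate record for participant "
                f"{pid!r}, trait {row.trait!r}"
            )
        seen.add(key)
        try:
            responses.append(
                TricotResponse(pid, row.trait, row.best or None, row.worst or None)
            )
        except InvalidResponseError as err:
            raise InvalidResponseError(f"{path} row {row_number}: {err}") from None
    return list(assignments.values()), responses


def responses_to_rankings(
    assignments: list[TriadAssignment],
    responses: list[TricotResponse],
    trait: str | None = None,
) -> list[Ranking]:
    """Convert responses to rankings, dropping unanswered ones.

    ``trait`` restricts to one trait; ``None`` keeps all.
    """
    by_pid = {a.participant_id: a for a in assignments}
    out = []
    for resp in responses:
        if trait is not None and resp.trait != trait:
            continue
        if resp.is_missing:
            continue
        out.append(response_to_ranking(resp, by_pid[resp.participant_id]))
    return out


def write_rankings(rankings, path, participant_ids=None, trait: str = "overall") -> None:
    """Write rankings.csv; row order preserved, lossless round trip."""
    rows = []
    for i, r in enumerate(rankings):
        pid = participant_ids[i] if participant_ids is not None else str(i + 1)
        row = {"participant_id": pid, "trait": trait}
        for j, item in enumerate(r.ordered_items, start=1):
            row[f"rank{j}"] = item
        row["weight"] = r.weight
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rankings(path) -> list[Ranking]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rank_cols = sorted(
        (c for c in df.columns if c.startswith("rank") and c[4:].isdigit()),
        key=lambda c: int(c[4:]),
    )
    if not rank_cols:
        raise SchemaError(f"{path}: no rank1..rankN columns found")
    out = []
    for row in df.itertuples(index=False):
        items = [getattr(row, c) for c in rank_cols if getattr(row, c)]
        weight = float(getattr(row, "weight", 1.0) or 1.0)
        out.append(Ranking(tuple(items), weight))
    return out


def comparison_graph(rankings) -> nx.Graph:
    """Undirected co-occurrence graph: items are nodes, an edge joins two
    items whenever some ranking compares them."""
    g = nx.Graph()
    for r in rankings:
        g.add_nodes_from(r.ordered_items)
        g.add_edges_from(itertools.combinations(r.ordered_items, 2))
    return g


def connectivity_check(rankings) -> list[set[str]]:
    """Partition items into weakly connected components of the comparison
    graph.  One component means the Plackett-Luce worths are identifiable;
    model fitting refuses disconnected input.
    """
    if not rankings:
        raise ValidationError("need at least one ranking")
    g = comparison_graph(rankings)
    return [set(c) for c in nx.connected_components(g)]
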