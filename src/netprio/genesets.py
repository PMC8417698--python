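"""Gene-set collections (GMT-style) used by the enrichment machinery."""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from typing import NamedTuple

from .exceptions import MalformedInputError


class GeneSet(NamedTuple):
    set_id: str
    description: str
    members: frozenset[str]


class GeneSetCollection(Mapping[str, GeneSet]):
    """Ordered, id-unique collection of named gene sets.

    Members are deduplicated frozensets; empty sets and duplicate ids are
    rejected at construction.
    """

    def __init__(self, sets: Iterable[tuple[str, str, Iterable[str]]]):
        self._sets: dict[str, GeneSet] = {}
        for set_id, description, members in sets:
            members = frozenset(members)
            if not members:
                raise MalformedInputError(f"gene set {set_id!r} is empty")
            if set_id in self._sets:
                raise MalformedInputError(f"duplicate set id {set_id!r}")
            self._sets[set_id] = GeneSet(set_id, str(description), members)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneSetCollection({len(self)} sets)"

    @property
    def ids(self) -> list[str]:
        return list(self._sets)

    def universe(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for gs in self._sets.values():
            out |= gs.members
        return frozenset(out)

    def restrict(self, genes: Iterable[str], min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``genes``, dropping sets below ``min_size``."""
        genes = frozenset(genes)
        kept = [
            (gs.set_id, gs.description, gs.members & genes)
            for gs in self._sets.values()
            if len(gs.members & genes) >= min_size
        ]
        return GeneSetCollection(kept)
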