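"""Named ID-set containers used for pathways, perturbation signatures and
protein complexes.

A :class:`GeneSet` is a named, unordered collection of uppercase identifiers
(gene symbols or protein IDs).  A :class:`GeneSetCollection` groups sets under
a collection name (e.g. a pathway database, a chemical/genetic-perturbation
compendium, or a complex catalogue) and enforces name uniqueness.  GMT
serialisation lives in :mod:`persig.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError


def normalize_id(identifier: str) -> str:
    """Uppercase, whitespace-stripped canonical form of an ID."""
    return str(identifier).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "members",
                           frozenset(normalize_id(m) for m in self.members))

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, universe) -> frozenset[str]:
        """Members restricted to a universe of IDs."""
        return self.members & frozenset(normalize_id(u) for u in universe)


@dataclass
class GeneSetCollection:
    name: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate set names in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_name: str) -> GeneSet:
        for s in self.sets:
            if s.name == set_name:
                return s
        raise KeyError(set_name)

    @property
    def set_names(self) -> list[str]:
        return [s.name for s in self.sets]

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.set_names:
            raise InputError(f"set {gene_set.name!r} already in collection")
        self.sets.append(gene_set)
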