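"""Canonical gene-pair containers shared by every pipeline stage.

Synthetic-lethal (SL) interactions are unordered pairs of gene symbols.
Throughout the package a pair is stored in *canonical* form: endpoints
sorted lexicographically, no self-pairs, set membership insensitive to the
order the pair was observed in.  :class:`SLInteractionSet` additionally
tracks per-pair provenance (``yeast_derived`` for pairs transferred from
yeast screens via orthology, ``predicted`` for pairs emitted by the
classifier); a pair supported by both routes keeps both tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

YEAST_DERIVED = "yeast_derived"
PREDICTED = "predicted"

#: Valid provenance tags for SL pairs.
PROVENANCE_TAGS = frozenset({YEAST_DERIVED, PREDICTED})


@dataclass(frozen=True, order=True)
class GenePair:
    """An unordered pair of gene symbols in canonical (sorted) form.

    Equality and hashing ignore ``provenance`` so that the same biological
    pair observed through different routes deduplicates in sets.
    """

    gene_a: str
    gene_b: str
    species: str = "human"
    provenance: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("gene symbols must be non-empty")
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair not allowed: {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            raise ValueError(
                "endpoints out of canonical order; use GenePair.make()"
            )

    @classmethod
    def make(
        cls,
        a: str,
        b: str,
        species: str = "human",
        provenance: str | None = None,
    ) -> "GenePair":
        """Build a canonical pair from endpoints in either order."""
        if a > b:
            a, b = b, a
        return cls(a, b, species=species, provenance=provenance)

    def as_tuple(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


PairLike = GenePair | tuple[str, str]


def _as_key(pair: PairLike) -> tuple[str, str]:
    """Canonical (sorted) endpoint tuple for a pair given in any order."""
    if isinstance(pair, GenePair):
        return pair.as_tuple()
    a, b = pair
    return (a, b) if a <= b else (b, a)


def canonicalize_pairs(
    pairs: Iterable[PairLike],
    species: str = "human",
    provenance: str | None = None,
) -> set[GenePair]:
    """Order-normalize, deduplicate, and drop self-pairs.

    Accepts :class:`GenePair` objects or raw 2-tuples in arbitrary endpoint
    order; self-pairs are silently removed (they cannot encode a synthetic
    lethal relation).  ``len(result) <= len(input)`` always holds.
    """
    out: set[GenePair] = set()
    for p in pairs:
        if isinstance(p, GenePair):
            out.add(p)
            continue
        a, b = p
        if a == b:
            continue
        out.add(GenePair.make(a, b, species=species, provenance=provenance))
    return out


class SLInteractionSet:
    """A canonical, deduplicated set of SL gene pairs with provenance.

    Membership tests accept :class:`GenePair` objects or plain 2-tuples in
    either endpoint order.
    """

    def __init__(
        self,
        pairs: Iterable[PairLike] = (),
        species: str = "human",
        provenance: str | None = None,
    ) -> None:
        self.species = species
        self._prov: dict[tuple[str, str], frozenset[str]] = {}
        for p in pairs:
            self.add(p, provenance=provenance)

    def add(self, pair: PairLike, provenance: str | None = None) -> None:
        tags: frozenset[str] = frozenset()
        if isinstance(pair, GenePair) and pair.provenance:
            tags = tags | {pair.provenance}
        if provenance:
            tags = tags | {provenance}
        key = _as_key(pair)
        if key[0] == key[1]:
            raise ValueError(f"self-pair not allowed: {key[0]!r}")
        self._prov[key] = self._prov.get(key, frozenset()) | tags

    def provenance_of(self, pair: PairLike) -> frozenset[str]:
        return self._prov[_as_key(pair)]

    @property
    def pairs(self) -> set[GenePair]:
        return {
            GenePair(
                a,
                b,
                species=self.species,
                provenance="|".join(sorted(tags)) or None,
            )
            for (a, b), tags in self._prov.items()
        }

    @property
    def gene_universe(self) -> set[str]:
        """All genes appearing as an endpoint of at least one pair."""
        out: set[str] = set()
        for a, b in self._prov:
            out.add(a)
            out.add(b)
        return out

    def __contains__(self, pair: object) -> bool:
        try:
            return _as_key(pair) in self._prov  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return False

    def __len__(self) -> int:
        return len(self._prov)

    def __iter__(self) -> Iterator[GenePair]:
        for (a, b) in sorted(self._prov):
            tags = self._prov[(a, b)]
            yield GenePair(
                a,
                b,
                species=self.species,
                provenance="|".join(sorted(tags)) or None,
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SLInteractionSet):
            return NotImplemented
        return self.species == other.species and self._prov == other._prov

    def __repr__(self) -> str:
        return (
            f"SLInteractionSet({len(self)} pairs, "
            f"{len(self.gene_universe)} genes, species={self.species!r})"
        )

    def keys(self) -> Iterable[tuple[str, str]]:
        return self._prov.keys()

    def items(self) -> Mapping[tuple[str, str], frozenset[str]]:
        return dict(self._prov)


def merge_sl_sets(a: SLInteractionSet, b: SLInteractionSet) -> SLInteractionSet:
    """Set union of two SL sets; shared pairs keep both provenance tags.

    ``len(out) == len(a) + len(b) - len(a ∩ b)`` by construction.
    """
    if a.species != b.species:
        raise ValueError(
            f"cannot merge SL sets of different species: "
            f"{a.species!r} vs {b.species!r}"
        )
    out = SLInteractionSet(species=a.species)
    for src in (a, b):
        for key, tags in src.items().items():
            out._prov[key] = out._prov.get(key, frozenset()) | tags
    return out
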