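"""Gene-set collections and GMT (Gene Matrix Transposed) I/O.

GMT is the canonical tab-separated format: one set per line,
``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt"]


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets with optional per-set descriptions."""

    sets: Dict[str, List[str]]
    descriptions: Dict[str, str] = field(default_factory=dict)
    source: Optional[str] = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                # dedupe but keep first-seen order
                seen: Dict[str, None] = {}
                for g in genes:
                    seen.setdefault(g)
                self.sets[name] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> List[str]:
        return list(self.sets)

    def restrict(self, universe, min_size: int = 2) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets smaller than
        ``min_size`` after intersection."""
        uni = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            sub = [g for g in genes if g in uni]
            if len(sub) >= min_size:
                kept[name] = sub
        return GeneSetCollection(
            kept,
            {n: self.descriptions.get(n, "") for n in kept},
            source=self.source,
        )


def read_gmt(path) -> GeneSetCollection:
    sets: Dict[str, List[str]] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
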