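"""Gene sets and marker panels, with GMT-style tab-separated I/O.

A GMT line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; the
description field is optional on read and written as ``na`` when absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (duplicates removed, order kept)."""

    name: str
    genes: tuple

    def __post_init__(self):
        seen: dict = {}
        for g in self.genes:
            if g not in seen:
                seen[g] = None
        object.__setattr__(self, "genes", tuple(seen))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class MarkerPanel:
    """Mapping from cell-type label to its marker GeneSet."""

    sets: Dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self):
        for label, gs in self.sets.items():
            if len(gs) == 0:
                raise ValueError(f"marker set for {label!r} is empty")

    @property
    def labels(self) -> List[str]:
        return list(self.sets)

    def __getitem__(self, label: str) -> GeneSet:
        return self.sets[label]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> List[GeneSet]:
    """Read gene sets from a GMT-style tab-separated file."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name<TAB>description<TAB>genes..."
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                logger.warning("%s:%d: set %r has no genes, skipped", path, lineno, name)
                continue
            sets.append(GeneSet(name, tuple(genes)))
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def panel_from_sets(sets: Mapping[str, Iterable[str]]) -> MarkerPanel:
    return MarkerPanel({label: GeneSet(label, tuple(genes)) for label, genes in sets.items()})
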