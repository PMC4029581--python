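"""Named gene-symbol collections and GMT I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .matrix import normalize_symbol

__all__ = ["GeneSet", "read_gmt", "write_gmt"]


@dataclass
class GeneSet:
    """A named, case-normalized, duplicate-free collection of gene symbols."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    _index: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(normalize_symbol(g), None)
        self.genes = tuple(seen)
        self._index = frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self._index


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated name, description, symbols."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        sets.append(GeneSet(parts[0], tuple(parts[2:]), description=parts[1]))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
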