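"""Gene signatures: a named pair of up- and down-regulated gene lists.

Signatures are exchanged in the GMT format used by GSEA and MSigDB: one
record per line, ``NAME<TAB>description<TAB>gene1<TAB>gene2...``.  A
signature with both directions is stored as two records, ``NAME_up`` and
``NAME_down``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError

__all__ = ["GeneSignature", "read_gmt", "write_gmt", "signature_from_gmt"]


@dataclass
class GeneSignature:
    """A named up/down gene signature.

    ``up`` and ``down`` are ordered lists (by convention, descending /
    ascending mean log2 fold change): order matters for top-N selection
    and for deterministic serialization.
    """

    name: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.up)) != len(self.up):
            raise ConfigurationError("GeneSignature.up contains duplicates")
        if len(set(self.down)) != len(self.down):
            raise ConfigurationError("GeneSignature.down contains duplicates")
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ConfigurationError(
                f"GeneSignature up/down sets overlap: {sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [genes...]}`` preserving order."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT record: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(
    signature: GeneSignature, path: str | Path, description: str = ""
) -> None:
    """Write a signature as two GMT records (``NAME_up``, ``NAME_down``)."""
    desc = description or f"{signature.name} consensus senescence signature"
    lines = []
    for direction, genes in (("up", signature.up), ("down", signature.down)):
        if genes:  # a GMT record needs at least one gene
            lines.append(
                "\t".join([f"{signature.name}_{direction}", desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def signature_from_gmt(path: str | Path, name: str) -> GeneSignature:
    """Assemble a :class:`GeneSignature` from ``NAME_up``/``NAME_down`` records.

    A GMT that only contains one of the two records yields a one-sided
    signature.
    """
    sets = read_gmt(path)
    up = sets.get(f"{name}_up", [])
    down = sets.get(f"{name}_down", [])
    if not up and not down:
        if name in sets:  # plain single-record set, treated as up
            up = sets[name]
        else:
            raise KeyError(f"no records for signature {name!r} in {path}")
    return GeneSignature(name=name, up=list(up), down=list(down))
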