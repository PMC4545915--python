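"""GMT (gene matrix transposed) reading and writing.

One set per line: name, description, then tab-separated gene identifiers.
"""

from __future__ import annotations

from pathlib import Path

from .errors import InvalidInputError
from .gsea import GeneSet


def read_gmt(path) -> list:
    """Read a GMT file into GeneSet objects (set_id = first field)."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InvalidInputError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        sets.append(GeneSet(set_id=fields[0], name=fields[1], genes=tuple(fields[2:])))
    if not sets:
        raise InvalidInputError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets, path) -> None:
    """Write signatures/sets (anything with .genes and a name) as GMT."""
    lines = []
    for s in sets:
        set_id = getattr(s, "set_id", None) or s.name
        description = getattr(s, "name", set_id)
        lines.append("\t".join([set_id, description, *s.genes]))
    Path(path).write_text("\n".join(lines) + "\n")
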