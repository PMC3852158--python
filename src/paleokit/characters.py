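"""Mixed discrete/continuous morphological character matrices and TNT I/O.

Morphological datasets mix unordered discrete characters (small integer
alphabets, '?' for both unknown and inapplicable, bracketed polymorphisms)
with continuous characters coded as real values or ranges.  This module
holds the in-memory matrix and a reader/writer for the TNT ``xread`` dialect,
the de-facto exchange format for such matrices:

    xread 'optional title'
    <nchar> <ntax>
    &[continuous]
    taxon_a  1.230 0.500-0.700 ?
    ...
    &[num]
    taxon_a  0010?[01]2...
    ...
    ;

A file may also omit the block tags entirely, in which case all characters
are discrete.  ``ccode`` statements are recognized (weights ``/w``); ordering
flags are ignored because discrete characters are scored unordered and
continuous characters additively by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["DiscreteColumn", "ContinuousColumn", "CharacterMatrix", "parse_tnt", "write_tnt"]


class TntParseError(ValueError):
    """Malformed TNT input; message carries the offending line number."""


@dataclass(frozen=True)
class DiscreteColumn:
    """One unordered discrete character: a state set per taxon.

    A missing cell ('?') is the full observed alphabet of the column — it can
    take any state for free.  Polymorphic cells list their states explicitly.
    ``cells[i]`` is a frozenset of small ints for taxon i; ``None`` marks
    missing and is resolved against ``alphabet`` lazily.
    """

    cells: tuple[frozenset | None, ...]

    def __post_init__(self) -> None:
        for c in self.cells:
            if c is not None and len(c) == 0:
                raise ValueError("discrete state sets must be nonempty")

    @property
    def alphabet(self) -> frozenset:
        observed = [c for c in self.cells if c is not None]
        return frozenset().union(*observed) if observed else frozenset({0})

    def state_sets(self) -> list[frozenset]:
        """Cells with missing resolved to the full observed alphabet."""
        alpha = self.alphabet
        return [alpha if c is None else c for c in self.cells]


@dataclass(frozen=True)
class ContinuousColumn:
    """One continuous (additive) character: value or [lo, hi] range per taxon.

    ``cells[i]`` is a (lo, hi) tuple with lo <= hi, or ``None`` for missing;
    a point value is stored as (x, x).
    """

    cells: tuple[tuple[float, float] | None, ...]

    def __post_init__(self) -> None:
        for c in self.cells:
            if c is not None and c[0] > c[1]:
                raise ValueError(f"continuous interval has lower > upper: {c}")


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters, with discrete and continuous partitions.

    ``columns`` preserves file order; ``weights`` are per-column nonnegative
    multipliers (default 1).
    """

    taxa: tuple[str, ...]
    columns: tuple[DiscreteColumn | ContinuousColumn, ...]
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        for k, col in enumerate(self.columns):
            if len(col.cells) != len(self.taxa):
                raise ValueError(f"column {k} has {len(col.cells)} cells for "
                                 f"{len(self.taxa)} taxa")
        if not self.weights:
            object.__setattr__(self, "weights", tuple(1.0 for _ in self.columns))
        elif len(self.weights) != len(self.columns):
            raise ValueError("one weight per column required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.columns)

    @property
    def discrete_columns(self) -> list[DiscreteColumn]:
        return [c for c in self.columns if isinstance(c, DiscreteColumn)]

    @property
    def continuous_columns(self) -> list[ContinuousColumn]:
        return [c for c in self.columns if isinstance(c, ContinuousColumn)]

    def with_weights(self, weights: Sequence[float]) -> "CharacterMatrix":
        return CharacterMatrix(self.taxa, self.columns, tuple(float(w) for w in weights))


# ---------------------------------------------------------------------------
# TNT xread parsing


_CELL_RE = re.compile(r"\[([0-9]+)\]|\(([0-9]+)\)|([0-9?\-])")


def _parse_discrete_row(text: str, lineno: int) -> list[frozenset | None]:
    cells: list[frozenset | None] = []
    pos = 0
    while pos < len(text):
        m = _CELL_RE.match(text, pos)
        if not m:
            raise TntParseError(f"line {lineno}: unknown symbol {text[pos]!r}")
        poly = m.group(1) or m.group(2)
        if poly is not None:
            cells.append(frozenset(int(ch) for ch in poly))
        else:
            ch = m.group(3)
            cells.append(None if ch in "?-" else frozenset({int(ch)}))
        pos = m.end()
    return cells


def _parse_continuous_cell(tok: str, lineno: int) -> tuple[float, float] | None:
    if tok in ("?", "-"):
        return None
    try:
        if "-" in tok[1:]:  # allow a leading minus sign
            cut = tok.index("-", 1)
            lo, hi = float(tok[:cut]), float(tok[cut + 1:])
        else:
            lo = hi = float(tok)
    except ValueError:
        raise TntParseError(f"line {lineno}: bad continuous value {tok!r}") from None
    if lo > hi:
        raise TntParseError(f"line {lineno}: interval lower > upper in {tok!r}")
    return (lo, hi)


def parse_tnt(path) -> CharacterMatrix:
    """Parse a TNT xread file into a :class:`CharacterMatrix`.

    Supports the continuous block tag ``&[continuous]``, discrete block tags
    (``&[num]`` or bare ``&``), '?'/'-' missing cells, bracketed
    polymorphisms, and ``ccode`` weight statements (``/w`` prefixes applied
    to the listed character indices; ordering symbols are ignored).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    # strip comments and locate xread
    it = enumerate(lines, start=1)
    nchar = ntax = None
    mode = "discrete"
    row_cells: dict[str, list] = {}
    taxon_order: list[str] = []
    blocks: list[tuple[str, dict[str, list]]] = []
    in_matrix = False
    ended = False
    ccode_lines: list[tuple[int, str]] = []

    def flush_block() -> None:
        if row_cells:
            blocks.append((mode, dict(row_cells)))
            row_cells.clear()

    for lineno, raw in it:
        line = raw.split("'")[0] if raw.strip().startswith("'") else raw
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        low = line.lower()
        if low.startswith("ccode"):
            ccode_lines.append((lineno, line.rstrip(";")))
            continue
        if low.startswith("proc"):
            continue
        if low.startswith("xread"):
            in_matrix = True
            rest = line[5:].strip().strip("'\"")
            nums = re.findall(r"\d+", rest)
            if len(nums) >= 2:
                nchar, ntax = int(nums[0]), int(nums[1])
            continue
        if not in_matrix:
            continue
        if nchar is None:
            nums = re.findall(r"\d+", line)
            if len(nums) < 2:
                raise TntParseError(f"line {lineno}: expected 'nchar ntax' dimensions")
            nchar, ntax = int(nums[0]), int(nums[1])
            continue
        if line.startswith("&"):
            flush_block()
            mode = "continuous" if "cont" in low else "discrete"
            continue
        if line == ";" or line.endswith(";"):
            body = line.rstrip(";").strip()
            if body:
                _consume_row(body, mode, row_cells, taxon_order, lineno)
            flush_block()
            ended = True
            in_matrix = False
            continue
        _consume_row(line, mode, row_cells, taxon_order, lineno)

    flush_block()
    if nchar is None or not blocks:
        raise TntParseError("no xread matrix found")
    if ntax is not None and len(taxon_order) != ntax:
        raise TntParseError(
            f"dimension mismatch: header declares {ntax} taxa, found {len(taxon_order)}"
        )

    # assemble columns block by block, in file order
    columns: list[DiscreteColumn | ContinuousColumn] = []
    for kind, rows in blocks:
        widths = {t: len(c) for t, c in rows.items()}
        if len(set(widths.values())) != 1:
            raise TntParseError(f"ragged block: per-taxon character counts {widths}")
        missing_taxa = [t for t in taxon_order if t not in rows]
        if missing_taxa:
            raise TntParseError(f"block missing taxa {missing_taxa}")
        width = next(iter(widths.values()))
        for k in range(width):
            cells = tuple(rows[t][k] for t in taxon_order)
            if kind == "continuous":
                columns.append(ContinuousColumn(cells))
            else:
                columns.append(DiscreteColumn(cells))
    if len(columns) != nchar:
        raise TntParseError(
            f"dimension mismatch: header declares {nchar} characters, found {len(columns)}"
        )

    weights = [1.0] * nchar
    for lineno, line in ccode_lines:
        for m in re.finditer(r"/(\d+(?:\.\d+)?)\s+((?:\d+\s*)+)", line):
            w = float(m.group(1))
            for tok in m.group(2).split():
                idx = int(tok)
                if not 0 <= idx < nchar:
                    raise TntParseError(f"line {lineno}: ccode index {idx} out of range")
                weights[idx] = w
    return CharacterMatrix(tuple(taxon_order), tuple(columns), tuple(weights))


def _consume_row(line, mode, row_cells, taxon_order, lineno) -> None:
    parts = line.split(None, 1)
    if len(parts) != 2:
        raise TntParseError(f"line {lineno}: expected 'taxon characters'")
    taxon, data = parts
    if taxon not in taxon_order:
        taxon_order.append(taxon)
    if mode == "continuous":
        cells = [_parse_continuous_cell(tok, lineno) for tok in data.split()]
    else:
        cells = _parse_discrete_row(data.replace(" ", ""), lineno)
    row_cells.setdefault(taxon, []).extend(cells)


def write_tnt(matrix: CharacterMatrix, path, title: str = "") -> None:
    """Write a matrix in the xread dialect (continuous block first)."""
    cont = matrix.continuous_columns
    disc = matrix.discrete_columns
    with open(path, "w") as fh:
        fh.write(f"xread '{title}'\n{matrix.n_char} {matrix.n_taxa}\n")
        if cont:
            fh.write("&[continuous]\n")
            for i, taxon in enumerate(matrix.taxa):
                toks = []
                for col in cont:
                    c = col.cells[i]
                    if c is None:
                        toks.append("?")
                    elif c[0] == c[1]:
                        toks.append(f"{c[0]:.3f}")
                    else:
                        toks.append(f"{c[0]:.3f}-{c[1]:.3f}")
                fh.write(f"{taxon}  {' '.join(toks)}\n")
        if disc:
            fh.write("&[num]\n")
            for i, taxon in enumerate(matrix.taxa):
                toks = []
                for col in disc:
                    c = col.cells[i]
                    if c is None:
                        toks.append("?")
                    elif len(c) == 1:
                        toks.append(str(next(iter(c))))
                    else:
                        toks.append("[" + "".join(str(s) for s in sorted(c)) + "]")
                fh.write(f"{taxon}  {''.join(toks)}\n")
        fh.write(";\n")
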