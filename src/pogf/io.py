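"""Readers and writers for gene lists, GMT pathway collections and result tables.

Gene lists are plain text, one symbol per non-blank line; ``#`` starts a
comment.  Pathway collections use the GMT convention (tab-separated:
name, description, gene, gene, ...).  Result tables are written as TSV or
JSON with a deterministic column order; infinite ratios are rendered as
the literal token ``Inf``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import tempfile
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, TextIO

from .exceptions import EmptyListError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneList",
    "PathwaySet",
    "read_gene_list",
    "read_gmt",
    "write_results",
]


def normalize_symbol(symbol: str, uppercase: bool = True) -> str:
    """Normalize a gene symbol (strip whitespace, optionally uppercase)."""
    symbol = symbol.strip()
    return symbol.upper() if uppercase else symbol


@dataclass(frozen=True)
class GeneList:
    """A named, ordered, de-duplicated list of gene symbols.

    Duplicates (after normalization performed by the reader) are removed on
    construction, keeping the first occurrence.
    """

    name: str
    genes: tuple[str, ...]
    source: str | None = None
    _gene_set: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[str, None] = dict.fromkeys(self.genes)
        object.__setattr__(self, "genes", tuple(seen))
        object.__setattr__(self, "_gene_set", frozenset(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self._gene_set

    @property
    def gene_set(self) -> frozenset[str]:
        return self._gene_set

    def restrict_to(self, universe: Iterable[str]) -> "GeneList":
        """Return a copy keeping only genes present in *universe* (order kept)."""
        allowed = frozenset(universe)
        return GeneList(
            name=self.name,
            genes=tuple(g for g in self.genes if g in allowed),
            source=self.source,
        )


@dataclass(frozen=True)
class PathwaySet:
    """A named set of genes (one pathway / gene-set)."""

    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def _open_maybe(source: str | os.PathLike | TextIO) -> tuple[TextIO, bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(source, "rt", encoding="utf-8"), True


def read_gene_list(
    source: str | os.PathLike | TextIO,
    name: str | None = None,
    uppercase: bool = True,
) -> GeneList:
    """Read a one-symbol-per-line gene list.

    Blank lines and lines starting with ``#`` are skipped.  Symbols are
    normalized (uppercased by default) and de-duplicated preserving the
    first occurrence; the number of duplicates dropped is logged.

    Raises
    ------
    EmptyListError
        If no usable symbol remains.
    """
    stream, close = _open_maybe(source)
    if name is None:
        name = Path(getattr(stream, "name", "genelist")).stem
    try:
        symbols: list[str] = []
        for raw in stream:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            symbols.append(normalize_symbol(line.split()[0], uppercase))
    finally:
        if close:
            stream.close()
    if not symbols:
        raise EmptyListError(f"gene list {name!r} contains no usable symbols")
    gl = GeneList(name=name, genes=tuple(symbols))
    dropped = len(symbols) - len(gl)
    if dropped:
        logger.info("gene list %s: dropped %d duplicate symbols", name, dropped)
    return gl


def read_gmt(
    source: str | os.PathLike | TextIO, uppercase: bool = True
) -> list[PathwaySet]:
    """Read a GMT pathway collection (name, description, genes...).

    The description field is ignored; empty gene fields are dropped.

    Raises
    ------
    ParseError
        For a row with fewer than three fields, or a row whose gene fields
        are all empty.
    """
    stream, close = _open_maybe(source)
    pathways: list[PathwaySet] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT row needs name, description and >=1 gene "
                    f"(got {len(fields)} fields)",
                    line_number=lineno,
                )
            genes = frozenset(
                normalize_symbol(g, uppercase) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise ParseError("GMT row has no non-empty gene fields", lineno)
            pathways.append(PathwaySet(name=fields[0].strip(), genes=genes))
    finally:
        if close:
            stream.close()
    return pathways


def _records_to_rows(results: Iterable[Any]) -> tuple[list[str], list[dict]]:
    rows: list[dict] = []
    columns: list[str] | None = None
    for rec in results:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            d = {
                f.name: getattr(rec, f.name)
                for f in dataclasses.fields(rec)
                if not f.name.startswith("_")
            }
        elif isinstance(rec, dict):
            d = dict(rec)
        else:
            raise TypeError(f"cannot serialize record of type {type(rec)!r}")
        if columns is None:
            columns = list(d)
        elif list(d) != columns:
            raise ValueError("records are not homogeneous")
        rows.append(d)
    return columns or [], rows


def _format_value(value: Any, precision: int) -> str:
    if isinstance(value, float):
        if math.isinf(value):
            return "Inf" if value > 0 else "-Inf"
        if math.isnan(value):
            return "NA"
        return f"{value:.{precision}g}"
    if value is None:
        return "NA"
    return str(value)


def write_results(
    results: Iterable[Any],
    dest: str | os.PathLike | TextIO,
    fmt: str = "tsv",
    precision: int = 4,
) -> None:
    """Write homogeneous result records (dataclasses or dicts) to TSV or JSON.

    Column order is the field order of the records.  Floats are rendered
    with *precision* significant digits; infinities as ``Inf``/``-Inf``.
    Writes are atomic when *dest* is a path.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown output format: {fmt!r}")
    columns, rows = _records_to_rows(results)

    def _render(out: TextIO) -> None:
        if fmt == "tsv":
            out.write("\t".join(columns) + "\n")
            for row in rows:
                out.write(
                    "\t".join(_format_value(row[c], precision) for c in columns)
                    + "\n"
                )
        else:
            payload = [
                {c: _format_value(v, precision) if isinstance(v, float) and not math.isfinite(v)
                 else v for c, v in row.items()}
                for row in rows
            ]
            json.dump(payload, out, indent=1, allow_nan=False)
            out.write("\n")

    if hasattr(dest, "write"):
        _render(dest)  # type: ignore[arg-type]
        return
    dest = Path(dest)
    fd, tmp = tempfile.mkstemp(dir=dest.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "wt", encoding="utf-8") as out:
            _render(out)
        os.replace(tmp, dest)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
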