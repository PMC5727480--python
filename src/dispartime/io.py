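"""Readers and writers: NEXUS character blocks, TNT xread, newick, CSV tables.

Discrete NEXUS parsing is delegated to dendropy; the continuous NEXUS block
and TNT's ``xread`` are parsed here directly (continuous cells may be ``?``,
which general-purpose NEXUS readers reject).  Writers emit the same dialect
the readers accept, and writing-then-reading any matrix is an identity.
"""

from __future__ import annotations

import csv
import io as _io
import re
from pathlib import Path

import dendropy
import numpy as np

from .datamodel import ContinuousMatrix, DiscreteMatrix, Phylogeny, TaxonRecord

__all__ = [
    "read_nexus",
    "write_nexus",
    "read_tnt",
    "read_newick",
    "write_newick",
    "read_taxon_table",
    "write_taxon_table",
]


class MatrixFormatError(ValueError):
    """Malformed character-matrix input."""


# ----------------------------------------------------------------- NEXUS

def _discrete_from_dendropy(dm: dendropy.StandardCharacterMatrix) -> DiscreteMatrix:
    taxa: list[str] = []
    states: list[list] = []
    nchar = None
    for taxon in dm:
        row = []
        for cell in dm[taxon]:
            sym = cell.symbol
            members = cell.member_states
            if sym in ("?", "-"):
                row.append(None)
            elif members is None:
                row.append(frozenset([int(sym)]))
            else:
                ints = frozenset(int(s.symbol) for s in members if s.symbol not in ("?", "-"))
                row.append(ints if ints else None)
        if nchar is None:
            nchar = len(row)
        elif len(row) != nchar:
            raise MatrixFormatError(f"row for {taxon.label!r} has wrong length")
        taxa.append(taxon.label)
        states.append(row)
    return DiscreteMatrix(taxa=taxa, states=states)


_CONT_TOKEN = re.compile(r"\?|[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _parse_continuous_nexus(text: str) -> ContinuousMatrix:
    m = re.search(r"DIMENSIONS[^;]*NTAX\s*=\s*(\d+)[^;]*NCHAR\s*=\s*(\d+)", text, re.I)
    if not m:
        raise MatrixFormatError("continuous block without DIMENSIONS NTAX/NCHAR")
    ntax, nchar = int(m.group(1)), int(m.group(2))
    mm = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not mm:
        raise MatrixFormatError("continuous block without MATRIX")
    taxa, rows = [], []
    for line in mm.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixFormatError(f"unreadable matrix line: {line!r}")
        name, rest = parts
        tokens = _CONT_TOKEN.findall(rest)
        if len(tokens) != nchar:
            raise MatrixFormatError(
                f"taxon {name!r}: {len(tokens)} continuous cells, expected {nchar}"
            )
        rows.append([np.nan if t == "?" else float(t) for t in tokens])
        taxa.append(name.strip("'\""))
    if len(taxa) != ntax:
        raise MatrixFormatError(f"NTAX={ntax} but {len(taxa)} rows present")
    return ContinuousMatrix(taxa=taxa, values=np.array(rows))


def read_nexus(path) -> DiscreteMatrix | ContinuousMatrix:
    """Read a NEXUS CHARACTERS/DATA block (STANDARD or CONTINUOUS datatype)."""
    text = Path(path).read_text()
    if re.search(r"DATATYPE\s*=\s*CONTINUOUS", text, re.I):
        return _parse_continuous_nexus(text)
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises a zoo of error types
        raise MatrixFormatError(f"cannot parse NEXUS matrix: {exc}") from exc
    mat = _discrete_from_dendropy(dm)
    m = re.search(r"DIMENSIONS[^;]*NTAX\s*=\s*(\d+)[^;]*NCHAR\s*=\s*(\d+)", text, re.I)
    if m and (mat.ntax != int(m.group(1)) or mat.nchar != int(m.group(2))):
        raise MatrixFormatError(
            f"declared {m.group(1)}x{m.group(2)} but read {mat.ntax}x{mat.nchar}"
        )
    return mat


def _format_discrete_cell(cell) -> str:
    if cell is None:
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return "{" + "".join(str(s) for s in sorted(cell)) + "}"


def write_nexus(matrix: DiscreteMatrix | ContinuousMatrix, path) -> None:
    buf = _io.StringIO()
    buf.write("#NEXUS\n")
    if isinstance(matrix, DiscreteMatrix):
        symbols = sorted({s for j in range(matrix.nchar) for s in matrix.observed_states(j)})
        buf.write("BEGIN CHARACTERS;\n")
        buf.write(f"DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.nchar};\n")
        buf.write(
            'FORMAT DATATYPE=STANDARD SYMBOLS="%s" MISSING=? GAP=-;\n'
            % "".join(str(s) for s in symbols)
        )
        buf.write("MATRIX\n")
        for name, row in zip(matrix.taxa, matrix.states):
            cells = "".join(_format_discrete_cell(c) for c in row)
            buf.write(f"{name}  {cells}\n")
    else:
        buf.write("BEGIN CHARACTERS;\n")
        buf.write(f"DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.nchar};\n")
        buf.write("FORMAT DATATYPE=CONTINUOUS MISSING=?;\n")
        buf.write("MATRIX\n")
        for name, row in zip(matrix.taxa, matrix.values):
            cells = " ".join("?" if np.isnan(v) else repr(float(v)) for v in row)
            buf.write(f"{name}  {cells}\n")
    buf.write(";\nEND;\n")
    Path(path).write_text(buf.getvalue())


# ------------------------------------------------------------------- TNT

def read_tnt(path) -> tuple[DiscreteMatrix, ContinuousMatrix]:
    """Read a TNT ``xread`` file with optional continuous and discrete blocks.

    Blocks are introduced by ``&[continuous]`` / ``&[num]`` and ``&[dna]``-style
    tags; untagged data are treated as discrete.  Continuous cells are
    whitespace-separated numbers or ``?``; discrete rows are contiguous symbol
    strings with ``[ab]`` or ``{ab}`` polymorphism.
    """
    text = Path(path).read_text()
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*?);", text, re.S | re.I)
    if not m:
        raise MatrixFormatError("no xread statement found")
    nchar_total, ntax = int(m.group(1)), int(m.group(2))
    body = m.group(3)

    # split into tagged blocks
    parts = re.split(r"(&\[[^\]]*\])", body)
    blocks: list[tuple[str, str]] = []
    current_tag = "discrete"
    pending = parts[0]
    if pending.strip():
        blocks.append((current_tag, pending))
    for tag, chunk in zip(parts[1::2], parts[2::2]):
        t = tag.lower()
        current_tag = "continuous" if ("cont" in t or "num" in t) else "discrete"
        blocks.append((current_tag, chunk))

    disc_rows: dict[str, list] = {}
    cont_rows: dict[str, list] = {}
    order: list[str] = []
    for kind, chunk in blocks:
        for line in chunk.strip().splitlines():
            line = line.strip()
            if not line or line.startswith(("ccode", "proc", "cc ")):
                continue
            parts2 = line.split(None, 1)
            if len(parts2) != 2:
                raise MatrixFormatError(f"unreadable xread line: {line!r}")
            name, rest = parts2
            name = name.strip("'\"")
            if name not in order:
                order.append(name)
            if kind == "continuous":
                vals = [np.nan if t == "?" else float(t) for t in _CONT_TOKEN.findall(rest)]
                cont_rows.setdefault(name, []).extend(vals)
            else:
                disc_rows.setdefault(name, []).extend(_parse_discrete_string(rest))

    if len(order) != ntax:
        raise MatrixFormatError(f"declared NTAX={ntax} but read {len(order)} taxa")
    n_disc = {len(v) for v in disc_rows.values()} or {0}
    n_cont = {len(v) for v in cont_rows.values()} or {0}
    if len(n_disc) > 1 or len(n_cont) > 1:
        raise MatrixFormatError("ragged rows in xread")
    nd, nc = n_disc.pop(), n_cont.pop()
    if disc_rows and set(disc_rows) != set(order):
        raise MatrixFormatError("some taxa lack discrete rows")
    if cont_rows and set(cont_rows) != set(order):
        raise MatrixFormatError("some taxa lack continuous rows")
    if nd + nc != nchar_total:
        raise MatrixFormatError(
            f"declared NCHAR={nchar_total} but read {nd} discrete + {nc} continuous"
        )
    discrete = DiscreteMatrix(
        taxa=list(order), states=[disc_rows.get(t, []) for t in order] if nd else [[] for _ in order]
    )
    continuous = ContinuousMatrix(
        taxa=list(order),
        values=np.array([cont_rows.get(t, []) for t in order], dtype=float).reshape(
            len(order), nc
        ),
    )
    return discrete, continuous


def _parse_discrete_string(s: str) -> list:
    out = []
    i = 0
    s = s.strip()
    while i < len(s):
        ch = s[i]
        if ch.isspace():
            i += 1
        elif ch in "?-":
            out.append(None)
            i += 1
        elif ch in "[{(":
            close = {"[": "]", "{": "}", "(": ")"}[ch]
            j = s.find(close, i)
            if j < 0:
                raise MatrixFormatError(f"unterminated polymorphism in {s!r}")
            inner = frozenset(int(c) for c in s[i + 1 : j] if c.isdigit())
            if not inner:
                raise MatrixFormatError(f"empty polymorphism in {s!r}")
            out.append(inner)
            i = j + 1
        elif ch.isdigit() or ch.isalpha():
            out.append(frozenset([int(ch, 36)]))
            i += 1
        else:
            raise MatrixFormatError(f"unexpected character {ch!r} in row {s!r}")
    return out


# ---------------------------------------------------------------- newick

def read_newick(path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path).read_text())


def write_newick(tree: Phylogeny, path, include_branch_lengths: bool = True) -> None:
    Path(path).write_text(tree.to_newick(include_branch_lengths) + "\n")


# ------------------------------------------------------------- CSV table

def read_taxon_table(path) -> list[TaxonRecord]:
    """Read a CSV with columns name,fad,lad,diet into validated records."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "fad", "lad"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MatrixFormatError("taxon table needs columns name,fad,lad[,diet]")
        for row in reader:
            try:
                fad, lad = float(row["fad"]), float(row["lad"])
            except ValueError as exc:
                raise MatrixFormatError(f"non-numeric age for {row['name']!r}") from exc
            diet = (row.get("diet") or "").strip() or "unknown"
            records.append(TaxonRecord(name=row["name"], fad=fad, lad=lad, diet=diet))
    return records


def write_taxon_table(records: list[TaxonRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "fad", "lad", "diet"])
        for r in records:
            w.writerow([r.name, r.fad, r.lad, r.diet])
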