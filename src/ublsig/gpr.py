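"""Reading and writing GenePix Results (GPR) scan files.

Two-channel array scanners emit tab-delimited ATF/GPR text: a short
header block of ``"Key=Value"`` lines, a column-header row, then one row
per spot with grid coordinates, protein annotation and per-wavelength
foreground/background medians.  The dialect handled here is the v3-style
one produced by :mod:`ublsig.simulate`; extra columns are tolerated and
ignored.

Wavelengths 635 nm and 532 nm are the conventional red/green channels for
the Alexa 647 / Alexa 546 secondary antibodies used to detect SUMO-1 and
Flag-ubiquitin conjugates respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["SpotRecord", "GPRParseError", "read_gpr", "write_gpr",
           "DEFAULT_CHANNEL_MAP", "WAVELENGTHS"]

WAVELENGTHS = (635, 532)

# wavelength -> UbL modifier detected in that channel
DEFAULT_CHANNEL_MAP: dict[int, str] = {635: "SUMO1", 532: "ubiquitin"}


class GPRParseError(ValueError):
    """Raised when a GPR file is malformed; the message names the line."""


@dataclass(frozen=True)
class SpotRecord:
    """One spot in one wavelength channel of one array.

    ``flag`` follows GPR semantics: negative values mark bad/absent spots.
    ``protein_id`` may be empty for unmapped spots (kept but unusable
    downstream).
    """

    array_id: str
    block: int
    row: int
    column: int
    protein_id: str
    protein_name: str
    wavelength: int
    foreground: float
    background: float
    flag: int = 0

    @property
    def unmapped(self) -> bool:
        return self.protein_id == ""

    @property
    def bad(self) -> bool:
        return self.flag < 0


_COLUMNS = ["Block", "Column", "Row", "Name", "ID", "Flags"]


def _f_col(w: int) -> str:
    return f"F{w} Median"


def _b_col(w: int) -> str:
    return f"B{w} Median"


def read_gpr(path: str | Path, array_id: str | None = None) -> list[SpotRecord]:
    """Parse a GPR file into spot records, one per spot per wavelength.

    Parameters
    ----------
    path
        GPR text file.  Must start with an ``ATF`` version line followed by
        the header-count line and the quoted key=value header block.
    array_id
        Identifier to stamp on the records; defaults to the file stem.

    Raises
    ------
    GPRParseError
        On a missing/malformed header or non-numeric intensity, naming the
        offending line number.
    """
    path = Path(path)
    aid = array_id if array_id is not None else path.stem
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise GPRParseError(f"{path}: line 1: not an ATF/GPR file")
    try:
        n_header = int(lines[1].split("\t")[0])
    except (IndexError, ValueError):
        raise GPRParseError(f"{path}: line 2: malformed header-count line")
    header_end = 2 + n_header
    if header_end >= len(lines):
        raise GPRParseError(f"{path}: header declares {n_header} lines but "
                            "file ends before the column header")
    columns = [c.strip().strip('"') for c in lines[header_end].split("\t")]
    col_idx = {c: i for i, c in enumerate(columns)}
    for c in _COLUMNS:
        if c not in col_idx:
            raise GPRParseError(
                f"{path}: line {header_end + 1}: missing column {c!r}")
    wavelengths = [w for w in WAVELENGTHS if _f_col(w) in col_idx]
    if not wavelengths:
        raise GPRParseError(
            f"{path}: line {header_end + 1}: no recognized wavelength "
            f"columns (expected e.g. {_f_col(WAVELENGTHS[0])!r})")
    for w in wavelengths:
        if _b_col(w) not in col_idx:
            raise GPRParseError(
                f"{path}: line {header_end + 1}: {_f_col(w)!r} present "
                f"without {_b_col(w)!r}")

    records: list[SpotRecord] = []
    for lineno, raw in enumerate(lines[header_end + 1:], start=header_end + 2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < len(columns):
            raise GPRParseError(f"{path}: line {lineno}: expected "
                                f"{len(columns)} fields, got {len(fields)}")

        def cell(name: str) -> str:
            return fields[col_idx[name]].strip().strip('"')

        try:
            block = int(cell("Block"))
            row = int(cell("Row"))
            column = int(cell("Column"))
            flag = int(cell("Flags"))
        except ValueError:
            raise GPRParseError(
                f"{path}: line {lineno}: non-integer grid/flag field")
        for w in wavelengths:
            try:
                fg = float(cell(_f_col(w)))
                bg = float(cell(_b_col(w)))
            except ValueError:
                raise GPRParseError(
                    f"{path}: line {lineno}: non-numeric intensity in "
                    f"{_f_col(w)!r}/{_b_col(w)!r}")
            records.append(SpotRecord(
                array_id=aid, block=block, row=row, column=column,
                protein_id=cell("ID"), protein_name=cell("Name"),
                wavelength=w, foreground=fg, background=bg, flag=flag))
    return records


def write_gpr(path: str | Path, spots: pd.DataFrame,
              header: Mapping[str, str] | None = None,
              wavelengths: Sequence[int] = WAVELENGTHS) -> None:
    """Write a GPR file from a spot table.

    ``spots`` must have one row per physical spot with columns Block, Row,
    Column, Name, ID, Flags, and ``F<w> Median`` / ``B<w> Median`` per
    wavelength.  Used by the simulator; :func:`read_gpr` round-trips its
    output exactly (intensities are written as integers).
    """
    header = dict(header or {})
    header.setdefault("Type", "GenePix Results 3")
    header.setdefault("Wavelengths", "\t".join(str(w) for w in wavelengths))
    cols = ["Block", "Column", "Row", "Name", "ID", "Flags"]
    for w in wavelengths:
        cols += [_f_col(w), _b_col(w)]
    lines = ["ATF\t1.0", f"{len(header)}\t{len(cols)}"]
    for k, v in header.items():
        lines.append(f'"{k}={v}"')
    lines.append("\t".join(f'"{c}"' for c in cols))
    body = pd.DataFrame({
        "Block": spots["Block"].astype(int).astype(str),
        "Column": spots["Column"].astype(int).astype(str),
        "Row": spots["Row"].astype(int).astype(str),
        "Name": spots["Name"].astype(str),
        "ID": spots["ID"].astype(str),
        "Flags": spots["Flags"].astype(int).astype(str),
    })
    for w in wavelengths:
        body[_f_col(w)] = spots[_f_col(w)].round().astype(int).astype(str)
        body[_b_col(w)] = spots[_b_col(w)].round().astype(int).astype(str)
    lines.extend("\t".join(r) for r in body.values)
    Path(path).write_text("\n".join(lines) + "\n")
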