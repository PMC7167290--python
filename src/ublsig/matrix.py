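"""Protein x array intensity matrices with array metadata.

The central measurement object of the pipeline: for each UbL modifier
channel (ubiquitin, SUMO-1), a proteins-by-arrays matrix of fluorescence
intensities, together with per-array metadata (experiment batch, cell
line, condition, NEM-control flag) and an append-only log of the
transforms applied to it.

Matrices exist at two granularities: *duplicate level* straight from the
scans (two sub-rows per protein, foreground and background kept
separately) and *protein level* after background correction and duplicate
averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .gpr import DEFAULT_CHANNEL_MAP, SpotRecord

__all__ = ["CONDITIONS", "IntensityMatrix", "assemble_matrix",
           "validate_meta", "save_matrix", "load_matrix"]

CONDITIONS = ("parental", "ARA-R", "DNR-R")

META_COLUMNS = ["experiment", "cell_line", "condition", "nem_control"]


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the array-metadata table and return it indexed by array_id."""
    m = meta.copy()
    if "array_id" in m.columns:
        m = m.set_index("array_id")
    if m.index.duplicated().any():
        dup = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate array metadata rows for {dup}")
    missing = [c for c in META_COLUMNS if c not in m.columns]
    if missing:
        raise ValueError(f"array metadata missing columns {missing}")
    bad = set(m["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels {sorted(bad)}")
    m["nem_control"] = m["nem_control"].astype(bool)
    nem_bad = m.loc[m["nem_control"] & (m["condition"] != "parental")]
    if len(nem_bad):
        raise ValueError("NEM-control arrays must use parental extracts: "
                         f"{nem_bad.index.tolist()}")
    return m


@dataclass
class IntensityMatrix:
    """Intensity matrices per modifier channel plus metadata and history.

    ``channels[modifier]`` is a proteins x arrays DataFrame.  At duplicate
    level the row index is a (protein_id, dup) MultiIndex and
    ``background`` holds the matching per-spot background medians; at
    protein level the index is protein_id and ``background`` is None.
    """

    channels: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    background: dict[str, pd.DataFrame] | None = None
    log: list[dict] = field(default_factory=list)

    @property
    def duplicate_level(self) -> bool:
        return self.background is not None or any(
            isinstance(df.index, pd.MultiIndex) for df in self.channels.values())

    @property
    def modifiers(self) -> list[str]:
        return list(self.channels)

    @property
    def array_ids(self) -> list[str]:
        return next(iter(self.channels.values())).columns.tolist()

    def record(self, step: str, **params) -> None:
        self.log.append({"step": step, **params})

    def copy_with(self, channels: dict[str, pd.DataFrame],
                  background: dict[str, pd.DataFrame] | None,
                  step: str, **params) -> "IntensityMatrix":
        out = IntensityMatrix(channels=channels, meta=self.meta.copy(),
                              background=background, log=list(self.log))
        out.record(step, **params)
        return out

    def permissive_arrays(self) -> list[str]:
        return self.meta.index[~self.meta["nem_control"]].tolist()

    def control_arrays(self) -> list[str]:
        return self.meta.index[self.meta["nem_control"]].tolist()


def assemble_matrix(spots: Mapping[str, Iterable[SpotRecord]] | Iterable[SpotRecord],
                    meta: pd.DataFrame,
                    channel_map: Mapping[int, str] = DEFAULT_CHANNEL_MAP,
                    ) -> IntensityMatrix:
    """Build a duplicate-level IntensityMatrix from per-array spot records.

    Every array must carry metadata and all arrays must share an identical
    protein grid (same set of mapped spot positions per protein).  Spots
    flagged bad (negative flag) are stored as missing; unmapped spots
    (empty ID) are dropped.

    The result is independent of the order in which arrays are supplied.
    """
    meta = validate_meta(meta)
    if not isinstance(spots, Mapping):
        by_array: dict[str, list[SpotRecord]] = {}
        for s in spots:
            by_array.setdefault(s.array_id, []).append(s)
    else:
        by_array = {a: list(v) for a, v in spots.items()}

    missing_meta = sorted(set(by_array) - set(meta.index))
    if missing_meta:
        raise ValueError(f"arrays without metadata: {missing_meta}")

    rows = []
    for aid in sorted(by_array):
        for s in by_array[aid]:
            if s.unmapped:
                continue
            rows.append((aid, s.protein_id, s.block, s.row, s.column,
                         s.wavelength, s.foreground, s.background, s.flag))
    df = pd.DataFrame(rows, columns=["array_id", "protein_id", "block",
                                     "row", "column", "wavelength",
                                     "foreground", "background", "flag"])
    if df.empty:
        raise ValueError("no mapped spots to assemble")

    # duplicate index: order duplicates of one protein by grid coordinates
    df = df.sort_values(["array_id", "wavelength", "protein_id",
                         "block", "row", "column"], kind="mergesort")
    df["dup"] = df.groupby(["array_id", "wavelength", "protein_id"]).cumcount() + 1

    # grid consistency: every array must present the same (protein, dup) set
    grids = df[df["wavelength"] == df["wavelength"].iloc[0]].groupby(
        "array_id")[["protein_id", "dup"]].apply(
        lambda g: frozenset(map(tuple, g.values)))
    ref = grids.iloc[0]
    bad_arrays = grids[grids != ref]
    if len(bad_arrays):
        offending = sorted(
            {p for a in bad_arrays.index
             for p, _ in (grids[a] ^ ref)})
        raise ValueError(
            f"protein grid mismatch between arrays {bad_arrays.index.tolist()}"
            f"; offending proteins: {offending[:20]}")

    df.loc[df["flag"] < 0, ["foreground", "background"]] = np.nan

    channels: dict[str, pd.DataFrame] = {}
    background: dict[str, pd.DataFrame] = {}
    for wl, modifier in channel_map.items():
        sub = df[df["wavelength"] == wl]
        if sub.empty:
            raise ValueError(f"no spots for wavelength {wl} "
                             f"(channel {modifier!r})")
        fg = sub.pivot_table(index=["protein_id", "dup"], columns="array_id",
                             values="foreground", aggfunc="first",
                             dropna=False)
        bg = sub.pivot_table(index=["protein_id", "dup"], columns="array_id",
                             values="background", aggfunc="first",
                             dropna=False)
        fg.columns.name = None
        bg.columns.name = None
        order = sorted(fg.columns)
        channels[modifier] = fg[order]
        background[modifier] = bg[order]

    out = IntensityMatrix(channels=channels,
                          meta=meta.loc[sorted(by_array)],
                          background=background)
    out.record("assemble", arrays=len(by_array),
               channel_map={str(k): v for k, v in channel_map.items()})
    return out


def save_matrix(matrix: IntensityMatrix, outdir: str | Path,
                prefix: str = "intensity") -> None:
    """Write per-modifier TSVs, a metadata CSV and the transform log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for modifier, df in matrix.channels.items():
        df.to_csv(outdir / f"{prefix}_{modifier}.tsv", sep="\t")
    matrix.meta.to_csv(outdir / f"{prefix}_meta.csv",
                       index_label="array_id")
    (outdir / f"{prefix}_log.json").write_text(
        json.dumps(matrix.log, indent=2) + "\n")


def load_matrix(outdir: str | Path, modifiers: Iterable[str],
                prefix: str = "intensity") -> IntensityMatrix:
    """Read back a protein-level matrix written by :func:`save_matrix`."""
    outdir = Path(outdir)
    channels = {}
    for modifier in modifiers:
        df = pd.read_csv(outdir / f"{prefix}_{modifier}.tsv", sep="\t",
                         index_col=0)
        channels[modifier] = df
    meta = validate_meta(pd.read_csv(outdir / f"{prefix}_meta.csv"))
    log = json.loads((outdir / f"{prefix}_log.json").read_text())
    return IntensityMatrix(channels=channels, meta=meta, log=log)
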