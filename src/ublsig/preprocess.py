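"""Array preprocessing: background correction, duplicate averaging,
within-experiment quantile normalization, cross-experiment batch
adjustment.

The chain is deterministic (no RNG) and each step appends itself to the
matrix's transform log.  A :class:`NormalizationReport` summarises a full
run for provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

__all__ = ["NormalizationReport", "correct_background", "average_duplicates",
           "quantile_normalize", "batch_adjust", "preprocess_chain"]


@dataclass
class NormalizationReport:
    """Ordered record of preprocessing steps with pre/post medians."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, matrix: IntensityMatrix, **params) -> None:
        medians = {m: float(np.nanmedian(df.values))
                   for m, df in matrix.channels.items()}
        self.steps.append({"step": name, "params": params,
                           "arrays": len(matrix.array_ids),
                           "post_median": medians})


def correct_background(matrix: IntensityMatrix,
                       floor: float = 1.0) -> IntensityMatrix:
    """Subtract per-spot background medians from foregrounds.

    ``intensity = max(foreground - background, floor)`` with a strictly
    positive floor so subsequent log transforms are defined.  Missing
    spots stay missing.
    """
    if matrix.background is None:
        raise ValueError("matrix has no background channel "
                         "(already corrected?)")
    if floor <= 0:
        raise ValueError("background floor must be positive")
    channels = {}
    for mod, fg in matrix.channels.items():
        bg = matrix.background[mod]
        corrected = (fg - bg).clip(lower=floor)
        corrected[fg.isna()] = np.nan
        channels[mod] = corrected
    return matrix.copy_with(channels, None, "correct_background", floor=floor)


def average_duplicates(matrix: IntensityMatrix) -> IntensityMatrix:
    """Collapse duplicate spots to protein-level rows by arithmetic mean.

    A single surviving duplicate passes through unchanged; if both spots
    of a protein are missing the protein row is kept as missing.  More
    than two duplicates per protein violates the array grid and raises.
    """
    channels = {}
    for mod, df in matrix.channels.items():
        if not isinstance(df.index, pd.MultiIndex):
            raise ValueError("matrix is already protein-level")
        counts = df.groupby(level="protein_id").size()
        too_many = counts[counts > 2]
        if len(too_many):
            raise ValueError(">2 duplicate spots for proteins "
                             f"{too_many.index.tolist()[:10]}")
        channels[mod] = df.groupby(level="protein_id").mean()
    return matrix.copy_with(channels, None, "average_duplicates")


def _qnorm_group(block: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of one group to their common
    mean-of-sorted-values reference.

    Missing values are left missing and excluded from the reference;
    tied input values receive the mean of the reference values at their
    rank positions.
    """
    n_valid = block.notna().sum(axis=0)
    n_ref = int(n_valid.max())
    if n_ref == 0:
        return block.copy()
    grid = np.linspace(0.0, 1.0, n_ref) if n_ref > 1 else np.array([0.0])
    ref_cols = []
    for c in block.columns:
        vals = np.sort(block[c].dropna().values)
        if vals.size == 0:
            continue
        if vals.size == 1:
            ref_cols.append(np.full(n_ref, vals[0]))
        else:
            ref_cols.append(np.interp(grid, np.linspace(0, 1, vals.size), vals))
    reference = np.mean(ref_cols, axis=0)
    out = {}
    for c in block.columns:
        nv = int(n_valid[c])
        col = block[c]
        if nv == 0:
            out[c] = col.copy()
            continue
        if nv == n_ref:
            ref_c = reference
        else:  # fewer valid entries: resample the reference to nv points
            sub = np.linspace(0.0, 1.0, nv) if nv > 1 else np.array([0.5])
            ref_c = np.interp(sub, grid, reference)
        v = col.dropna().values
        order = np.argsort(v, kind="mergesort")
        assigned = np.empty(nv)
        assigned[order] = ref_c  # rank i -> i-th reference value
        s = pd.Series(assigned, index=col.dropna().index)
        # ties share the mean of the reference values at their ranks
        s = s.groupby(pd.Series(v, index=s.index)).transform("mean")
        out[c] = s.reindex(col.index)
    return pd.DataFrame(out, index=block.index)[block.columns]


def quantile_normalize(matrix: IntensityMatrix,
                       group_by: str = "experiment") -> IntensityMatrix:
    """Equalize array intensity distributions within each experiment.

    Within each group of arrays (default: same experiment batch), each
    array's sorted values are replaced by the group's mean sorted-value
    reference, preserving within-array ranks.  Groups of a single array
    pass through with a warning.
    """
    groups = matrix.meta.groupby(group_by).groups
    channels = {}
    for mod, df in matrix.channels.items():
        out = df.copy()
        for gname, arrays in groups.items():
            cols = [a for a in arrays if a in df.columns]
            if len(cols) < 2:
                warnings.warn(f"quantile_normalize: group {gname!r} has "
                              f"{len(cols)} array(s); passing through")
                continue
            out[cols] = _qnorm_group(df[cols])
        channels[mod] = out
    return matrix.copy_with(channels, matrix.background,
                            "quantile_normalize", group_by=group_by)


def batch_adjust(matrix: IntensityMatrix, batch_by: str = "experiment",
                 method: str = "median_center") -> IntensityMatrix:
    """Remove between-experiment intensity offsets.

    ``median_center`` (default): in log2 space, shift each batch so its
    pooled per-batch median equals the global median, then back-transform.
    Monotone within each array, hence rank-preserving, and idempotent.

    ``eb_location_scale``: empirical-Bayes-style location/scale
    standardization per batch (each batch's pooled log2 mean and SD mapped
    to the global ones) with per-protein means preserved; a simplified
    ComBat-style variant for when batches differ in spread, not only
    location.
    """
    if batch_by not in matrix.meta.columns:
        raise ValueError(f"unknown batch column {batch_by!r}")
    batches = matrix.meta.groupby(batch_by).groups
    channels = {}
    for mod, df in matrix.channels.items():
        if (df.values[np.isfinite(df.values)] <= 0).any():
            raise ValueError("batch_adjust requires positive intensities")
        log2 = np.log2(df)
        global_med = float(np.nanmedian(log2.values))
        out = log2.copy()
        if method == "median_center":
            for bname, arrays in batches.items():
                cols = [a for a in arrays if a in df.columns]
                if not cols:
                    raise ValueError(f"batch {bname!r} matches no arrays")
                shift = global_med - float(np.nanmedian(log2[cols].values))
                out[cols] = log2[cols] + shift
        elif method == "eb_location_scale":
            global_mean = float(np.nanmean(log2.values))
            global_sd = float(np.nanstd(log2.values))
            for bname, arrays in batches.items():
                cols = [a for a in arrays if a in df.columns]
                b = log2[cols]
                b_mean = float(np.nanmean(b.values))
                b_sd = float(np.nanstd(b.values))
                scale = global_sd / b_sd if b_sd > 0 else 1.0
                out[cols] = (b - b_mean) * scale + global_mean
        else:
            raise ValueError(f"unknown batch adjustment method {method!r}")
        channels[mod] = 2.0 ** out
    return matrix.copy_with(channels, matrix.background, "batch_adjust",
                            batch_by=batch_by, method=method)


def preprocess_chain(matrix: IntensityMatrix, floor: float = 1.0,
                     group_by: str = "experiment",
                     batch_method: str = "median_center",
                     ) -> tuple[IntensityMatrix, NormalizationReport]:
    """Run the full preprocessing chain and return matrix plus report.

    Order: background correction -> duplicate averaging -> within-
    experiment quantile normalization -> cross-experiment batch
    adjustment.
    """
    report = NormalizationReport()
    m = correct_background(matrix, floor=floor)
    report.add("correct_background", m, floor=floor)
    m = average_duplicates(m)
    report.add("average_duplicates", m)
    m = quantile_normalize(m, group_by=group_by)
    report.add("quantile_normalize", m, group_by=group_by)
    m = batch_adjust(m, batch_by=group_by, method=batch_method)
    report.add("batch_adjust", m, method=batch_method)
    return m, report
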