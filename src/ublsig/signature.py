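"""Two-stage calling of the UbL-conjugation chemoresistance signature.

Stage 1 (:func:`call_modified`) identifies robustly modified proteins by
comparing conjugation-permissive arrays against NEM-treated control
arrays per modifier channel, requiring both the Welch and the
Wilcoxon-Mann-Whitney tests to reject (p < alpha), the permissive mean to
exceed the control mean, and the mean normalized intensity to clear an
arbitrary floor (default 800 a.u.).

Stage 2 computes resistant/parental intensity ratios for the called
proteins, pairing each resistant array with the parental array of the
same cell line and experiment batch, then calls differential modification
either *globally* (all resistant sublines pooled: Wilcoxon signed-rank
and one-sample t on log2 ratios, ratio outside [0.8, 1.25]) or
*separately* per cell line x drug (one-sample t only, ratio outside
[0.66, 1.5]).  The union of both analyses is the signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix import IntensityMatrix
from .stats import mann_whitney_u, t_test, wilcoxon_signed_rank

__all__ = ["ModificationCallSet", "RatioSet", "call_modified",
           "compute_ratios", "call_differential_global",
           "call_differential_separated", "merge_signature"]

RESISTANT_CONDITIONS = ("ARA-R", "DNR-R")


@dataclass
class ModificationCallSet:
    """Per (protein, modifier) modification-calling results.

    ``table`` columns: mean_permissive, mean_control, p_welch, p_mww,
    called.  Index: (protein_id, modifier).
    """

    table: pd.DataFrame
    alpha: float
    intensity_floor: float

    def called_pairs(self) -> set[tuple[str, str]]:
        return set(self.table.index[self.table["called"]])


@dataclass
class RatioSet:
    """Per-pair resistant/parental ratios for called proteins.

    ``table`` is long-format with columns protein_id, modifier,
    experiment, cell_line, drug, ratio (> 0).  ``scope`` is ``"global"``
    (all resistant sublines) or ``(cell_line, drug)``.
    """

    table: pd.DataFrame
    scope: str | tuple[str, str]


def _bh(p: pd.Series) -> pd.Series:
    return pd.Series(multipletests(p.values, method="fdr_bh")[1],
                     index=p.index)


def call_modified(matrix: IntensityMatrix, alpha: float = 0.05,
                  intensity_floor: float = 800.0,
                  bh_correct: bool = False) -> ModificationCallSet:
    """Call robustly UbL-modified proteins against NEM controls.

    For each (protein, modifier): Welch and Wilcoxon-Mann-Whitney tests of
    permissive-array intensities vs NEM-control intensities, two-sided.
    Called iff both p < alpha, permissive mean > control mean, and
    permissive mean > ``intensity_floor``.
    """
    permissive = matrix.permissive_arrays()
    controls = matrix.control_arrays()
    if not controls:
        raise ValueError("no NEM-control arrays in metadata")
    if len(permissive) < 2:
        raise ValueError("need at least 2 conjugation-permissive arrays")
    rows = []
    for modifier, df in matrix.channels.items():
        perm = df[permissive]
        ctrl = df[controls]
        for protein in df.index:
            x = perm.loc[protein].dropna().values
            y = ctrl.loc[protein].dropna().values
            if x.size < 2 or y.size < 1:
                rows.append((protein, modifier, np.nan, np.nan,
                             np.nan, np.nan))
                continue
            p_w = t_test(x, y, mode="welch_two_sample").p_value \
                if y.size >= 2 else np.nan
            p_m = mann_whitney_u(x, y).p_value
            rows.append((protein, modifier, x.mean(), y.mean(), p_w, p_m))
    table = pd.DataFrame(rows, columns=["protein_id", "modifier",
                                        "mean_permissive", "mean_control",
                                        "p_welch", "p_mww"])
    table = table.set_index(["protein_id", "modifier"]).sort_index()
    if bh_correct:
        for col in ("p_welch", "p_mww"):
            ok = table[col].notna()
            table.loc[ok, col] = _bh(table.loc[ok, col])
    table["called"] = ((table["p_welch"] < alpha)
                       & (table["p_mww"] < alpha)
                       & (table["mean_permissive"] > intensity_floor)
                       & (table["mean_permissive"] > table["mean_control"]))
    return ModificationCallSet(table=table, alpha=alpha,
                               intensity_floor=intensity_floor)


def compute_ratios(matrix: IntensityMatrix, calls: ModificationCallSet,
                   scope: str | tuple[str, str] = "global") -> RatioSet:
    """Resistant/parental intensity ratios for called proteins.

    Each resistant array is paired with the parental (non-NEM) array of
    the same cell line and experiment batch; batch effects cancel within
    a pair.  ``scope="global"`` keeps all resistant sublines; a
    ``(cell_line, drug)`` tuple restricts to that subline.
    """
    meta = matrix.meta[~matrix.meta["nem_control"]]
    resistant = meta[meta["condition"].isin(RESISTANT_CONDITIONS)]
    if isinstance(scope, tuple):
        line, drug = scope
        resistant = resistant[(resistant["cell_line"] == line)
                              & (resistant["condition"] == drug)]
        if resistant.empty:
            raise ValueError(f"no resistant arrays for scope {scope!r}")
    pairs = []
    for aid, arr in resistant.iterrows():
        partner = meta[(meta["condition"] == "parental")
                       & (meta["cell_line"] == arr["cell_line"])
                       & (meta["experiment"] == arr["experiment"])]
        if partner.empty:
            raise ValueError(f"resistant array {aid!r} has no parental "
                             "partner in the same experiment and cell line")
        pairs.append((aid, partner.index[0], arr["experiment"],
                      arr["cell_line"], arr["condition"]))

    called = calls.called_pairs()
    rows = []
    for modifier, df in matrix.channels.items():
        proteins = [p for p in df.index if (p, modifier) in called]
        if not proteins:
            continue
        sub = df.loc[proteins]
        for res_a, par_a, exp, line, drug in pairs:
            ratio = sub[res_a] / sub[par_a]
            for protein, r in ratio.items():
                rows.append((protein, modifier, exp, line, drug, r))
    table = pd.DataFrame(rows, columns=["protein_id", "modifier",
                                        "experiment", "cell_line", "drug",
                                        "ratio"])
    if len(table) and (table["ratio"] <= 0).any():
        raise ValueError("non-positive intensity ratio; run background "
                         "correction with a positive floor first")
    return RatioSet(table=table, scope=scope)


def _geomean(ratios: np.ndarray) -> float:
    return float(2.0 ** np.mean(np.log2(ratios)))


def call_differential_global(ratios: RatioSet, alpha: float = 0.05,
                             hi: float = 1.25, lo: float = 0.8,
                             bh_correct: bool = False) -> pd.DataFrame:
    """Differential calls pooling all resistant sublines.

    Wilcoxon signed-rank and one-sample t tests of the log2 ratios
    against 0; called iff both p < alpha and the geometric-mean ratio is
    > ``hi`` or < ``lo``.  Returns one record per (protein, modifier)
    with columns geomean_ratio, p_signed_rank, p_t, direction, called.
    """
    if ratios.scope != "global":
        raise ValueError("call_differential_global needs a global-scope "
                         "RatioSet")
    rows = []
    for (protein, modifier), grp in ratios.table.groupby(
            ["protein_id", "modifier"], sort=True):
        r = grp["ratio"].values
        if r.size < 2:
            warnings.warn(f"skipping {protein}/{modifier}: "
                          f"only {r.size} ratio(s)")
            continue
        logr = np.log2(r)
        p_sr = wilcoxon_signed_rank(logr, 0.0).p_value
        p_t = t_test(logr, 0.0, mode="one_sample").p_value
        g = _geomean(r)
        rows.append((protein, modifier, "global", g, p_sr, p_t,
                     "up" if g >= 1.0 else "down", r.size))
    out = pd.DataFrame(rows, columns=["protein_id", "modifier", "scope",
                                      "geomean_ratio", "p_signed_rank",
                                      "p_t", "direction", "n_ratios"])
    if bh_correct and len(out):
        out["p_signed_rank"] = _bh(out["p_signed_rank"])
        out["p_t"] = _bh(out["p_t"])
    out["called"] = ((out["p_signed_rank"] < alpha) & (out["p_t"] < alpha)
                     & ((out["geomean_ratio"] > hi)
                        | (out["geomean_ratio"] < lo)))
    return out


def call_differential_separated(ratios: RatioSet, alpha: float = 0.05,
                                hi: float = 1.5, lo: float = 0.66,
                                bh_correct: bool = False) -> pd.DataFrame:
    """Differential calls per cell line x drug (smaller sample size).

    One-sample t test only, on log2 ratios against 0; called iff p < alpha
    and the geometric-mean ratio is > ``hi`` or < ``lo``.  One record per
    (protein, modifier, cell_line, drug).
    """
    rows = []
    for (protein, modifier, line, drug), grp in ratios.table.groupby(
            ["protein_id", "modifier", "cell_line", "drug"], sort=True):
        r = grp["ratio"].values
        if r.size < 2:
            warnings.warn(f"skipping {protein}/{modifier} ({line}, {drug}): "
                          f"only {r.size} ratio(s)")
            continue
        logr = np.log2(r)
        p_t = t_test(logr, 0.0, mode="one_sample").p_value
        g = _geomean(r)
        rows.append((protein, modifier, f"{line}|{drug}", line, drug, g,
                     p_t, "up" if g >= 1.0 else "down", r.size))
    out = pd.DataFrame(rows, columns=["protein_id", "modifier", "scope",
                                      "cell_line", "drug", "geomean_ratio",
                                      "p_t", "direction", "n_ratios"])
    if bh_correct and len(out):
        out["p_t"] = _bh(out["p_t"])
    out["called"] = ((out["p_t"] < alpha)
                     & ((out["geomean_ratio"] > hi)
                        | (out["geomean_ratio"] < lo)))
    return out


@dataclass
class SignatureTable:
    """Merged signature across global and separated analyses.

    ``table`` has one row per (protein, modifier) with a ``source``
    column in {global, separated, both}.  ``counts`` maps modifier ->
    number of signature proteins for that modifier;
    ``n_distinct_proteins`` counts each protein once even when modified
    by both UbLs.
    """

    table: pd.DataFrame
    counts: dict[str, int]
    n_distinct_proteins: int


def merge_signature(global_records: pd.DataFrame,
                    separated_records: pd.DataFrame) -> SignatureTable:
    """Union of called global and separated differential records.

    Idempotent and commutative: only the called flags and the
    (protein, modifier) keys matter.
    """
    def _called_keys(df: pd.DataFrame) -> set[tuple[str, str]]:
        if df is None or not len(df):
            return set()
        sub = df[df["called"]] if "called" in df.columns else df
        return set(zip(sub["protein_id"], sub["modifier"]))

    g = _called_keys(global_records)
    s = _called_keys(separated_records)
    rows = []
    for protein, modifier in sorted(g | s):
        src = ("both" if (protein, modifier) in g and (protein, modifier) in s
               else "global" if (protein, modifier) in g else "separated")
        rows.append((protein, modifier, src))
    table = pd.DataFrame(rows, columns=["protein_id", "modifier", "source"])
    counts = (table.groupby("modifier")["protein_id"].nunique().to_dict()
              if len(table) else {})
    n_distinct = table["protein_id"].nunique() if len(table) else 0
    return SignatureTable(table=table, counts=counts,
                          n_distinct_proteins=int(n_distinct))
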