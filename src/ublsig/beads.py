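"""Multiplexed bead-assay quantification.

Color-coded beads, each coupled to one recombinant biomarker protein, are
incubated with cell extracts under UbL-conjugation-permissive conditions
and read by flow cytometry: two classification channels identify the bead
region (hence the biomarker) and two reporter channels measure ubiquitin
and SUMO-1 conjugation on the coupled protein.  Per (sample, biomarker)
the statistic of interest is the reporter MFI (median fluorescence
intensity); NEM-treated control extracts define the no-conjugation
background, which is subtracted before resistant/parental ratios or
responder/refractory comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .stats import t_test, TestResult

__all__ = ["assign_bead_regions", "compute_mfi", "nem_adjust",
           "nem_subtract_and_ratio", "compare_groups",
           "flag_high_modification"]

CLASSIFICATION_CHANNELS = ["CL1", "CL2"]
REPORTER_CHANNELS = {"ubiquitin": "RP_ub", "SUMO1": "RP_sumo1"}

MIN_EVENTS = 30          # common cytometry floor per region per sample
SUBTRACTION_FLOOR = 1.0  # a.u., keeps ratios defined


def assign_bead_regions(events: pd.DataFrame,
                        centroids: np.ndarray | pd.DataFrame | None = None,
                        k: int | None = None,
                        region_names: list[str] | None = None,
                        max_distance: float | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Assign each event to a bead region by classification channels.

    Either supply region ``centroids`` (rows = regions) for deterministic
    nearest-centroid gating, or ``k`` to estimate centroids with seeded
    k-means.  Events farther than ``max_distance`` from every centroid
    are marked unassigned (empty region label).
    """
    for c in CLASSIFICATION_CHANNELS:
        if c not in events.columns:
            raise ValueError(f"events missing classification channel {c!r}")
    cl = events[CLASSIFICATION_CHANNELS].values.astype(float)
    if centroids is None:
        if k is None:
            raise ValueError("supply centroids or k")
        if k > len(events):
            raise ValueError(f"k={k} exceeds {len(events)} events")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(cl)
        centroids = km.cluster_centers_
        # stable region order: by angle around the grand centroid
        order = np.argsort(np.arctan2(*(centroids - centroids.mean(0)).T[::-1]))
        centroids = centroids[order]
    centroids = np.asarray(centroids, dtype=float)
    if region_names is None:
        region_names = [f"BM{i + 1}" for i in range(len(centroids))]
    d = np.linalg.norm(cl[:, None, :] - centroids[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    labels = np.array(region_names, dtype=object)[nearest]
    if max_distance is not None:
        labels[d.min(axis=1) > max_distance] = ""
    out = events.copy()
    out["region"] = labels
    return out


def compute_mfi(labeled_events: pd.DataFrame,
                min_events: int = MIN_EVENTS) -> pd.DataFrame:
    """Median reporter fluorescence per (sample, region, modifier).

    The median of an even number of events is the midpoint mean of the
    two central values (numpy convention).  Regions with fewer than
    ``min_events`` events in a sample are flagged unusable.
    """
    ev = labeled_events[labeled_events["region"] != ""]
    rows = []
    for (sid, region), grp in ev.groupby(["sample_id", "region"], sort=True):
        for modifier, channel in REPORTER_CHANNELS.items():
            if channel not in grp.columns:
                continue
            rows.append((sid, region, modifier,
                         float(np.median(grp[channel].values)), len(grp),
                         len(grp) >= min_events))
    return pd.DataFrame(rows, columns=["sample_id", "biomarker", "modifier",
                                       "mfi", "n_events", "usable"])


def nem_adjust(mfi: pd.DataFrame, samples: pd.DataFrame,
               modifier: str = "ubiquitin",
               floor: float = SUBTRACTION_FLOOR) -> pd.DataFrame:
    """Background-subtracted MFI per (sample, biomarker).

    Each non-control sample's NEM-control MFI (named by its ``nem_pair``)
    is subtracted, floored at ``floor``.  Returns rows for non-control
    samples only, with an ``adjusted_mfi`` column.
    """
    s = samples.set_index("sample_id") if "sample_id" in samples.columns \
        else samples
    sub = mfi[(mfi["modifier"] == modifier) & mfi["usable"]]
    lookup = sub.set_index(["sample_id", "biomarker"])["mfi"]
    rows = []
    for (sid, bm), value in lookup.items():
        if sid not in s.index or bool(s.loc[sid, "nem_control"]):
            continue
        nem = s.loc[sid, "nem_pair"]
        if pd.isna(nem) or (nem, bm) not in lookup.index:
            raise KeyError(f"sample {sid!r} has no matched NEM-control MFI")
        rows.append((sid, bm, float(value),
                     max(float(value) - float(lookup[(nem, bm)]), floor)))
    return pd.DataFrame(rows, columns=["sample_id", "biomarker", "mfi",
                                       "adjusted_mfi"])


def nem_subtract_and_ratio(mfi: pd.DataFrame, samples: pd.DataFrame,
                           pairs: list[tuple[str, str]],
                           modifier: str = "ubiquitin",
                           floor: float = SUBTRACTION_FLOOR) -> pd.DataFrame:
    """Background-subtract MFIs and form resistant/parental ratios.

    ``samples`` needs sample_id, nem_control and nem_pair columns (each
    non-control sample names its NEM control).  For every (resistant,
    parental) sample pair and biomarker:
    ``adjusted = max(MFI - NEM_MFI, floor)``;
    ``ratio = adjusted_resistant / adjusted_parental``.  A parental value
    at the floor flags the ratio as unstable.
    """
    samples = samples.set_index("sample_id") if "sample_id" in samples.columns \
        else samples
    sub = mfi[(mfi["modifier"] == modifier) & mfi["usable"]]
    lookup = sub.set_index(["sample_id", "biomarker"])["mfi"]

    def adjusted(sid: str, biomarker: str) -> float:
        if (sid, biomarker) not in lookup.index:
            raise KeyError(f"no usable MFI for sample {sid!r}, "
                           f"biomarker {biomarker!r}")
        nem = samples.loc[sid, "nem_pair"]
        if pd.isna(nem) or (nem, biomarker) not in lookup.index:
            raise KeyError(f"sample {sid!r} has no matched NEM-control MFI")
        return max(float(lookup[(sid, biomarker)])
                   - float(lookup[(nem, biomarker)]), floor)

    rows = []
    biomarkers = sorted(sub["biomarker"].unique())
    for res, par in pairs:
        for bm in biomarkers:
            a_res = adjusted(res, bm)
            a_par = adjusted(par, bm)
            rows.append((res, par, bm, a_res, a_par, a_res / a_par,
                         a_par <= floor))
    return pd.DataFrame(rows, columns=["resistant", "parental", "biomarker",
                                       "adjusted_resistant",
                                       "adjusted_parental", "ratio",
                                       "unstable"])


def compare_groups(values_a, values_b, design: str = "unpaired_welch",
                   ) -> TestResult:
    """Two-group comparison of MFI-derived values.

    ``unpaired_welch`` for independent cohorts (e.g. responder vs
    refractory patients); ``paired`` for matched designs (e.g. the same
    biomarker across paired extracts).
    """
    if design == "unpaired_welch":
        return t_test(values_a, values_b, mode="welch_two_sample")
    if design == "paired":
        return t_test(values_a, values_b, mode="paired")
    raise ValueError(f"unknown design {design!r}")


def flag_high_modification(patient_mfi: pd.DataFrame,
                           responder_ids: list[str],
                           k_sd: float = 2.0,
                           value_col: str = "mfi") -> pd.DataFrame:
    """Flag patients with high modification of at least one biomarker.

    Per biomarker, the reference distribution is the responder group; a
    patient is flagged on that biomarker when their value exceeds
    reference mean + ``k_sd`` * reference SD (strictly greater than the
    mean when the reference SD is 0).  A patient is flagged overall when
    at least one biomarker is flagged.

    Returns one row per patient with per-biomarker flags and the overall
    flag.  Needs at least 3 responders per biomarker.
    """
    flags: dict[str, dict[str, bool]] = {}
    for bm, grp in patient_mfi.groupby("biomarker"):
        ref = grp[grp["sample_id"].isin(responder_ids)][value_col]
        if len(ref) < 3:
            raise ValueError(f"biomarker {bm!r}: need >= 3 reference "
                             f"responders, got {len(ref)}")
        mu, sd = float(ref.mean()), float(ref.std(ddof=1))
        threshold = mu + k_sd * sd
        for _, row in grp.iterrows():
            high = (row[value_col] > threshold if sd > 0
                    else row[value_col] > mu)
            flags.setdefault(row["sample_id"], {})[bm] = bool(high)
    rows = []
    for sid, per_bm in sorted(flags.items()):
        rows.append({"sample_id": sid, **per_bm,
                     "flagged": any(per_bm.values())})
    return pd.DataFrame(rows)
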