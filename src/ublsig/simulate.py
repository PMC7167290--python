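"""Synthetic protein-array studies and bead-assay cohorts.

The discovery pipeline was designed around a two-cell-line AML chemo-
resistance experiment: parental HL-60 and U937 lines plus cytarabine-
(ARA-R) and daunorubicin-resistant (DNR-R) sublines, probed on duplicate-
spot two-channel protein arrays over three independent experiments, with
per-experiment NEM-treated control arrays in which UbL conjugation is
chemically inhibited.  This module generates studies with exactly that
structure -- GPR scan files, an array-metadata table and a ground-truth
table of planted modified / differentially modified proteins -- so every
downstream stage can be tested for recovery of a known signal.

Signal model (log2 scale): per-protein baseline ~ Normal(mu0, sd0), plus
the modification effect on planted (protein, modifier) pairs in
conjugation-permissive arrays, plus a differential effect in the resistant
conditions in scope, plus a per-experiment batch offset and per-spot
noise.  Raw intensities are emitted as 2**log2 plus an additive scanner
background, the multiplicative-biology / additive-background convention.

All randomness flows from ``rng_seed`` through named
``numpy.random.SeedSequence`` spawn keys (one stream per concern), so runs
are bitwise reproducible and extending the design does not perturb
earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gpr import DEFAULT_CHANNEL_MAP, write_gpr
from .matrix import CONDITIONS

__all__ = ["SimulationConfig", "GroundTruth", "BeadGroundTruth",
           "simulate_protoarray_study", "simulate_bead_study",
           "simulate_score_cohort", "write_truth", "read_truth"]

# SeedSequence spawn-key roots, one stream per concern
_STREAM_TRUTH = 0
_STREAM_BATCH = 1
_STREAM_SIGNAL = 2      # sub-keyed per array
_STREAM_BEAD = 3


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_frac_modified() -> dict[str, float]:
    # roughly the proportions seen on real arrays: ~11% of the panel
    # ubiquitylated, far fewer SUMOylated (kept high enough on a 1k-protein
    # panel for stable recovery statistics)
    return {"ubiquitin": 0.10, "SUMO1": 0.05}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic protein-array study.

    Defaults mirror the reference design: 3 experiments x (2 cell lines x
    3 conditions + 2 NEM controls) = 24 arrays, duplicate spots, two
    channels (635 nm -> SUMO-1, 532 nm -> ubiquitin).  ``n_proteins``
    defaults to 1,000 -- a desk-speed stand-in for the >9,000-protein
    commercial arrays, configurable up.
    """

    n_proteins: int = 1000
    n_experiments: int = 3
    cell_lines: tuple[str, ...] = ("HL-60", "U937")
    conditions: tuple[str, ...] = CONDITIONS
    nem_controls_per_experiment: int = 2
    channels: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    frac_modified: dict[str, float] = field(
        default_factory=_default_frac_modified)
    frac_differential: float = 0.10     # of the modified set
    log2_modification_effect: float = 2.0
    log2_differential_effect: float = 1.0
    differential_scope: str = "global"  # global | per-line | per-drug
    up_fraction: float = 0.5            # planted up- vs down-regulation
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.0
    batch_log2_sd: float = 0.5
    spot_cv: float = 0.15               # duplicate-spot noise (CV scale)
    background_mean: float = 60.0
    background_sd: float = 10.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.n_experiments < 1:
            raise ConfigError("n_experiments must be >= 1")
        if not self.cell_lines:
            raise ConfigError("need at least one cell line")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ConfigError(f"unknown condition labels {sorted(unknown)}")
        if "parental" not in self.conditions:
            raise ConfigError("conditions must include 'parental'")
        for mod, f in self.frac_modified.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"frac_modified[{mod!r}] outside [0,1]")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ConfigError("frac_differential outside [0,1]")
        if not 0.0 <= self.up_fraction <= 1.0:
            raise ConfigError("up_fraction outside [0,1]")
        if self.log2_modification_effect < 0 or self.log2_differential_effect < 0:
            raise ConfigError("effect sizes must be >= 0")
        if self.differential_scope not in ("global", "per-line", "per-drug"):
            raise ConfigError(
                f"unknown differential_scope {self.differential_scope!r}")
        if not isinstance(self.rng_seed, (int, np.integer)) or self.rng_seed < 0:
            raise ConfigError("rng_seed must be a non-negative integer")


@dataclass
class GroundTruth:
    """Planted truth of one simulated array study.

    ``modified``: set of (protein_id, modifier) pairs with a conjugation
    signal.  ``differential``: set of (protein_id, modifier, scope_label,
    direction) where scope_label is ``"global"`` or a cell line / drug,
    direction in {up, down}; always a subset of ``modified`` on the
    (protein, modifier) key.  ``batch_offsets``: per-experiment log2
    offsets.  ``baselines``: per-protein baseline log2 means.
    """

    modified: set[tuple[str, str]]
    differential: set[tuple[str, str, str, str]]
    batch_offsets: dict[str, float]
    baselines: dict[str, float]

    def differential_pairs(self) -> set[tuple[str, str]]:
        return {(p, m) for p, m, _, _ in self.differential}


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _spot_grid(n_proteins: int) -> pd.DataFrame:
    """Duplicate spots laid out row-major, duplicates adjacent."""
    n_spots = 2 * n_proteins
    ncol = 40
    idx = np.arange(n_spots)
    return pd.DataFrame({
        "Block": 1,
        "Row": idx // ncol + 1,
        "Column": idx % ncol + 1,
    })


def _plan_arrays(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for e in range(1, config.n_experiments + 1):
        exp = f"E{e}"
        for line in config.cell_lines:
            for cond in config.conditions:
                rows.append((f"{exp}_{line}_{cond}", exp, line, cond, False))
        for j in range(config.nem_controls_per_experiment):
            line = config.cell_lines[j % len(config.cell_lines)]
            rows.append((f"{exp}_NEM{j + 1}_{line}", exp, line,
                         "parental", True))
    meta = pd.DataFrame(rows, columns=["array_id", "experiment", "cell_line",
                                       "condition", "nem_control"])
    return meta


def _draw_truth(config: SimulationConfig, proteins: list[str]) -> GroundTruth:
    rng = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=(_STREAM_TRUTH,)))
    baselines = dict(zip(proteins, rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd,
        size=len(proteins))))
    modified: set[tuple[str, str]] = set()
    differential: set[tuple[str, str, str, str]] = set()
    resistant_conditions = [c for c in config.conditions if c != "parental"]
    for modifier in config.channels.values():
        frac = config.frac_modified.get(modifier, 0.0)
        n_mod = int(round(frac * len(proteins)))
        mod_idx = rng.choice(len(proteins), size=n_mod, replace=False)
        mod_proteins = [proteins[i] for i in sorted(mod_idx)]
        modified.update((p, modifier) for p in mod_proteins)
        n_diff = int(round(config.frac_differential * n_mod))
        diff_idx = rng.choice(n_mod, size=n_diff, replace=False)
        for i in sorted(diff_idx):
            p = mod_proteins[i]
            direction = "up" if rng.random() < config.up_fraction else "down"
            if config.differential_scope == "global":
                scope = "global"
            elif config.differential_scope == "per-line":
                scope = str(rng.choice(config.cell_lines))
            else:  # per-drug
                scope = str(rng.choice(resistant_conditions))
            differential.add((p, modifier, scope, direction))
    rng_b = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed, spawn_key=(_STREAM_BATCH,)))
    raw_offsets = rng_b.normal(0.0, config.batch_log2_sd,
                               size=config.n_experiments)
    # batch effects are relative: center them so the study's overall
    # intensity scale is carried by the baselines, not by batch luck
    if config.n_experiments > 1:
        raw_offsets = raw_offsets - raw_offsets.mean()
    batch_offsets = {f"E{e}": float(raw_offsets[e - 1])
                     for e in range(1, config.n_experiments + 1)}
    return GroundTruth(modified=modified, differential=differential,
                       batch_offsets=batch_offsets, baselines=baselines)


def _diff_applies(scope_label: str, scope_kind: str, line: str,
                  condition: str) -> bool:
    if scope_kind == "global":
        return True
    if scope_kind == "per-line":
        return line == scope_label
    return condition == scope_label  # per-drug


def simulate_protoarray_study(config: SimulationConfig, outdir: str | Path,
                              ) -> tuple[list[Path], pd.DataFrame, GroundTruth]:
    """Simulate a full array study and write GPR files plus metadata.

    Returns the list of GPR file paths, the array-metadata table (also
    written as ``arrays.csv``) and the planted :class:`GroundTruth`.
    Byte-identical output for identical config (including seed).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins = _protein_ids(config.n_proteins)
    grid = _spot_grid(config.n_proteins)
    truth = _draw_truth(config, proteins)
    meta = _plan_arrays(config)

    baseline = np.array([truth.baselines[p] for p in proteins])
    spot_sd = math.log2(1.0 + config.spot_cv)
    effects = {}  # (modifier) -> base modification effect vector
    for modifier in config.channels.values():
        e = np.array([config.log2_modification_effect
                      if (p, modifier) in truth.modified else 0.0
                      for p in proteins])
        effects[modifier] = e
    diff_records = list(truth.differential)

    paths: list[Path] = []
    for a_idx, arr in meta.iterrows():
        rng = np.random.default_rng(np.random.SeedSequence(
            config.rng_seed, spawn_key=(_STREAM_SIGNAL, int(a_idx))))
        spots = grid.copy()
        spots["Name"] = np.repeat([f"protein_{p[1:]}" for p in proteins], 2)
        spots["ID"] = np.repeat(proteins, 2)
        spots["Flags"] = 0
        batch = truth.batch_offsets[arr["experiment"]]
        for wl, modifier in config.channels.items():
            log2sig = baseline.copy()
            if not arr["nem_control"]:
                log2sig = log2sig + effects[modifier]
                for p, mod, scope_label, direction in diff_records:
                    if mod != modifier:
                        continue
                    if arr["condition"] == "parental":
                        continue
                    if not _diff_applies(scope_label,
                                         config.differential_scope,
                                         arr["cell_line"], arr["condition"]):
                        continue
                    delta = (config.log2_differential_effect
                             if direction == "up"
                             else -config.log2_differential_effect)
                    log2sig[proteins.index(p)] += delta
            per_spot = np.repeat(log2sig + batch, 2)
            per_spot = per_spot + rng.normal(0.0, spot_sd, size=per_spot.size)
            bg = np.clip(rng.normal(config.background_mean,
                                    config.background_sd,
                                    size=per_spot.size), 0.0, None)
            spots[f"F{wl} Median"] = np.round(2.0 ** per_spot + bg)
            spots[f"B{wl} Median"] = np.round(bg)
        path = outdir / f"{arr['array_id']}.gpr"
        write_gpr(path, spots,
                  header={"ArrayID": arr["array_id"],
                          "Experiment": arr["experiment"]},
                  wavelengths=list(config.channels))
        paths.append(path)

    meta_out = meta.copy()
    for wl, modifier in config.channels.items():
        meta_out[f"channel_{wl}"] = modifier
    meta_out.to_csv(outdir / "arrays.csv", index=False)
    return paths, meta, truth


# ---------------------------------------------------------------------------
# ground-truth round-trip

def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Write the truth tables as TSV sections under a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sorted(truth.modified),
                 columns=["protein_id", "modifier"]).to_csv(
        path / "modified.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.differential),
                 columns=["protein_id", "modifier", "scope", "direction"]
                 ).to_csv(path / "differential.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.batch_offsets.items()),
                 columns=["experiment", "log2_offset"]).to_csv(
        path / "batch_offsets.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.baselines.items()),
                 columns=["protein_id", "baseline_log2"]).to_csv(
        path / "baselines.tsv", sep="\t", index=False)
    return path


def read_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    mod = pd.read_csv(path / "modified.tsv", sep="\t")
    diff = pd.read_csv(path / "differential.tsv", sep="\t")
    batches = pd.read_csv(path / "batch_offsets.tsv", sep="\t")
    baselines = pd.read_csv(path / "baselines.tsv", sep="\t")
    return GroundTruth(
        modified=set(map(tuple, mod.values)),
        differential=set(map(tuple, diff.astype(str).values)),
        batch_offsets=dict(zip(batches["experiment"],
                               batches["log2_offset"].astype(float))),
        baselines=dict(zip(baselines["protein_id"],
                           baselines["baseline_log2"].astype(float))))


# ---------------------------------------------------------------------------
# labeled cohorts for the scoring stage

def simulate_score_cohort(n_variables: int, informative: int,
                          n_samples: int, separation: float = 3.29,
                          resistant_frac: float = 0.5,
                          rng_seed: int = 0,
                          ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Labeled sample x variable matrix with a planted linear rule.

    The two classes are unit-variance Gaussians differing only on the
    first ``informative`` variables, with a total Mahalanobis separation
    ``separation`` spread evenly across them (3.29 gives a Bayes-optimal
    accuracy of ~0.95).  Returns (X, labels, informative variable names).
    """
    if not 1 <= informative <= n_variables:
        raise ConfigError("informative must be in [1, n_variables]")
    rng = np.random.default_rng(
        np.random.SeedSequence(rng_seed, spawn_key=(_STREAM_TRUTH, 99)))
    n_res = int(round(resistant_frac * n_samples))
    labels = np.array(["resistant"] * n_res
                      + ["sensitive"] * (n_samples - n_res))
    # interleave classes so any contiguous sample slice is mixed
    order = np.argsort(np.r_[np.arange(n_res) * 2,
                             np.arange(n_samples - n_res) * 2 + 1],
                       kind="stable")
    labels = labels[order]
    X = rng.normal(size=(n_samples, n_variables))
    shift = separation / math.sqrt(informative)
    X[labels == "resistant", :informative] += shift
    names = [f"v{i + 1:02d}" for i in range(n_variables)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    Xdf = pd.DataFrame(X, index=samples, columns=names)
    return Xdf, pd.Series(labels, index=samples), names[:informative]


# ---------------------------------------------------------------------------
# bead-assay simulation

@dataclass
class BeadGroundTruth:
    """Planted truth of a simulated bead-assay cohort."""

    centroids: np.ndarray                 # n_biomarkers x 2 classification
    region_labels: pd.Series              # per event, aligned to events index
    effects: pd.DataFrame                 # samples x biomarkers, log2 shift


def simulate_bead_study(n_biomarkers: int, samples: pd.DataFrame,
                        effects: pd.DataFrame | None = None,
                        events_per_region: int = 200,
                        reporter_base: float = 500.0,
                        reporter_log2_sd: float = 0.25,
                        background_mean: float = 50.0,
                        background_sd: float = 8.0,
                        cluster_sd: float = 150.0,
                        rng_seed: int = 0,
                        ) -> tuple[pd.DataFrame, BeadGroundTruth]:
    """Simulate multiplexed bead-assay event tables for a sample cohort.

    ``samples`` needs columns sample_id and nem_control (bool); every
    non-control sample must name its control in a ``nem_pair`` column.
    ``effects`` gives per (sample, biomarker) log2 shifts of the ubiquitin
    reporter over ``reporter_base`` (0 = no shift; missing = 0).

    Events carry two classification channels (CL1, CL2; one Gaussian
    cluster per biomarker, centroids on a circle) and two reporter
    channels (RP_ub, RP_sumo1).  NEM-control samples show background-only
    reporter signal.  Reproducible given ``rng_seed``.
    """
    if n_biomarkers < 1:
        raise ConfigError("need at least one biomarker")
    if samples.empty:
        raise ConfigError("empty sample table")
    samples = samples.copy()
    if "nem_control" not in samples.columns:
        raise ConfigError("samples need an nem_control column")
    non_ctrl = samples[~samples["nem_control"].astype(bool)]
    if "nem_pair" in samples.columns:
        missing = non_ctrl[~non_ctrl["nem_pair"].isin(
            samples.loc[samples["nem_control"].astype(bool), "sample_id"])]
        if len(missing):
            raise ConfigError("samples without a matched NEM control: "
                              f"{missing['sample_id'].tolist()}")
    biomarkers = [f"BM{i + 1}" for i in range(n_biomarkers)]
    if effects is None:
        effects = pd.DataFrame(0.0, index=samples["sample_id"],
                               columns=biomarkers)
    else:
        effects = effects.reindex(index=samples["sample_id"],
                                  columns=biomarkers).fillna(0.0)

    theta = 2.0 * np.pi * np.arange(n_biomarkers) / max(n_biomarkers, 3)
    centroids = np.column_stack([5000 + 3000 * np.cos(theta),
                                 5000 + 3000 * np.sin(theta)])
    rng = np.random.default_rng(
        np.random.SeedSequence(rng_seed, spawn_key=(_STREAM_BEAD,)))
    rows = []
    labels = []
    for _, s in samples.iterrows():
        sid = s["sample_id"]
        is_nem = bool(s["nem_control"])
        for b, bm in enumerate(biomarkers):
            cl = rng.normal(centroids[b], cluster_sd,
                            size=(events_per_region, 2))
            bg_ub = np.clip(rng.normal(background_mean, background_sd,
                                       size=events_per_region), 0, None)
            bg_su = np.clip(rng.normal(background_mean, background_sd,
                                       size=events_per_region), 0, None)
            if is_nem:
                rp_ub = bg_ub
                rp_su = bg_su
            else:
                shift = float(effects.loc[sid, bm])
                sig = 2.0 ** (math.log2(reporter_base) + shift
                              + rng.normal(0.0, reporter_log2_sd,
                                           size=events_per_region))
                rp_ub = bg_ub + sig
                # SUMO reporter kept at a modest constant signal
                rp_su = bg_su + 2.0 ** (
                    math.log2(reporter_base / 4.0)
                    + rng.normal(0.0, reporter_log2_sd,
                                 size=events_per_region))
            for k in range(events_per_region):
                rows.append((sid, cl[k, 0], cl[k, 1], rp_ub[k], rp_su[k]))
                labels.append(bm)
    events = pd.DataFrame(rows, columns=["sample_id", "CL1", "CL2",
                                         "RP_ub", "RP_sumo1"])
    truth = BeadGroundTruth(centroids=centroids,
                            region_labels=pd.Series(labels,
                                                    index=events.index,
                                                    name="region"),
                            effects=effects)
    return events, truth
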