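"""End-to-end orchestration of the discovery, scoring and bead stages.

Each stage reads/writes plain-text artifacts (GPR, TSV, CSV, JSON) under
an output directory and returns a run report (row counts per stage,
config hash) so that identical config + seed reproduce identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import beads as bead_ops
from .gpr import DEFAULT_CHANNEL_MAP, read_gpr
from .matrix import assemble_matrix, save_matrix
from .preprocess import preprocess_chain
from .score import (GAConfig, VariableMatrix, build_nested_subsets,
                    classify_sample, cv_accuracy, evaluate_subsets,
                    expand_variables, ga_select, lda_fit, variable_name)
from .signature import (call_differential_global, call_differential_separated,
                        call_modified, compute_ratios, merge_signature)
from .simulate import SimulationConfig, simulate_bead_study, \
    simulate_protoarray_study, write_truth

__all__ = ["run_discovery", "run_score", "run_bead", "select_panel",
           "measurements_from_arrays", "config_hash"]

log = logging.getLogger("ublsig")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_report(report: dict, outdir: Path, name: str) -> dict:
    (outdir / name).write_text(json.dumps(report, indent=2, default=str)
                               + "\n")
    return report


def run_discovery(config: dict | None = None, outdir: str | Path = "out",
                  seed: int | None = None) -> dict:
    """Simulate (optionally), preprocess and call the UbL signature.

    ``config`` keys (all optional): ``simulate`` (SimulationConfig field
    overrides, or ``{"enabled": False}`` with ``gpr_dir``/``meta_csv``
    under ``input``), ``preprocess`` (floor, batch_method), ``calling``
    (alpha, intensity_floor, global/separated ratio thresholds).
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = dict(config.get("simulate", {}))
    enabled = sim_cfg.pop("enabled", True)
    report: dict = {"stage": "discovery", "config_hash": config_hash(config)}

    try:
        if enabled:
            if seed is not None:
                sim_cfg.setdefault("rng_seed", seed)
            sc = SimulationConfig(**sim_cfg)
            paths, meta, truth = simulate_protoarray_study(sc, outdir / "gpr")
            write_truth(truth, outdir / "truth")
            channel_map = dict(sc.channels)
            report["simulated"] = True
        else:
            inp = config.get("input", {})
            gpr_dir = Path(inp["gpr_dir"])
            meta = pd.read_csv(inp["meta_csv"])
            paths = sorted(gpr_dir.glob("*.gpr"))
            channel_map = dict(DEFAULT_CHANNEL_MAP)
            report["simulated"] = False
    except (KeyError, ValueError) as exc:
        raise PipelineError(f"discovery/simulate: {exc}") from exc

    try:
        spots = {p.stem: read_gpr(p) for p in paths}
        matrix = assemble_matrix(spots, meta, channel_map)
        report["arrays"] = len(matrix.array_ids)
    except (ValueError, OSError) as exc:
        raise PipelineError(f"discovery/array_io: {exc}") from exc

    pp = config.get("preprocess", {})
    try:
        matrix, norm_report = preprocess_chain(
            matrix, floor=pp.get("floor", 1.0),
            batch_method=pp.get("batch_method", "median_center"))
        save_matrix(matrix, outdir, prefix="normalized")
        (outdir / "normalization_report.json").write_text(
            json.dumps(norm_report.steps, indent=2) + "\n")
    except ValueError as exc:
        raise PipelineError(f"discovery/preprocess: {exc}") from exc

    cal = config.get("calling", {})
    try:
        calls = call_modified(matrix, alpha=cal.get("alpha", 0.05),
                              intensity_floor=cal.get("intensity_floor", 800.0),
                              bh_correct=cal.get("bh_correct", False))
        calls.table.to_csv(outdir / "modification_calls.tsv", sep="\t")
        ratios = compute_ratios(matrix, calls, scope="global")
        glob_rec = call_differential_global(
            ratios, alpha=cal.get("alpha", 0.05),
            hi=cal.get("global_hi", 1.25), lo=cal.get("global_lo", 0.8))
        sep_rec = call_differential_separated(
            ratios, alpha=cal.get("alpha", 0.05),
            hi=cal.get("separated_hi", 1.5), lo=cal.get("separated_lo", 0.66))
        glob_rec.to_csv(outdir / "differential_global.tsv", sep="\t",
                        index=False)
        sep_rec.to_csv(outdir / "differential_separated.tsv", sep="\t",
                       index=False)
        sig = merge_signature(glob_rec, sep_rec)
        sig.table.to_csv(outdir / "signature.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise PipelineError(f"discovery/signature: {exc}") from exc

    report.update({
        "proteins_called_modified": {
            m: int(((calls.table["called"])
                    & (calls.table.index.get_level_values("modifier") == m))
                   .sum())
            for m in matrix.modifiers},
        "differential_global": int(glob_rec["called"].sum()),
        "differential_separated": int(sep_rec["called"].sum()),
        "signature_counts": sig.counts,
        "signature_distinct_proteins": sig.n_distinct_proteins,
    })
    log.info("discovery: %s", report)
    return _write_report(report, outdir, "discovery_report.json")


def measurements_from_arrays(matrix) -> tuple[pd.DataFrame, pd.Series]:
    """Per-array (protein, modifier) measurements and class labels.

    Observations are the conjugation-permissive arrays; the label is
    sensitive for parental arrays and resistant for drug-resistant
    sublines.  Values are log2 normalized intensities.
    """
    permissive = matrix.permissive_arrays()
    blocks = []
    for modifier, df in matrix.channels.items():
        b = np.log2(df[permissive]).T
        b.columns = pd.MultiIndex.from_product([b.columns, [modifier]])
        blocks.append(b)
    X = pd.concat(blocks, axis=1)
    meta = matrix.meta.loc[permissive]
    labels = pd.Series(
        np.where(meta["condition"] == "parental", "sensitive", "resistant"),
        index=meta.index)
    return X, labels


def select_panel(signature_table: pd.DataFrame,
                 global_records: pd.DataFrame,
                 separated_records: pd.DataFrame,
                 calls_table: pd.DataFrame | None = None,
                 n_proteins: int = 23) -> list[tuple[str, tuple[str, ...]]]:
    """Pick the score panel: signature proteins with the most robust
    differential signal (largest |log2 geometric-mean ratio| across the
    global and separated analyses), optionally weighted by modification
    level.  Returns (protein, modifiers) entries for expand_variables."""
    strength: dict[str, float] = {}
    for rec in (global_records, separated_records):
        if rec is None or not len(rec):
            continue
        called = rec[rec["called"]]
        for _, row in called.iterrows():
            s = abs(np.log2(row["geomean_ratio"]))
            key = row["protein_id"]
            strength[key] = max(strength.get(key, 0.0), s)
    sig_proteins = signature_table.groupby("protein_id")["modifier"] \
        .apply(lambda m: tuple(sorted(set(m))))
    ranked = sorted(sig_proteins.index,
                    key=lambda p: (-strength.get(p, 0.0), p))
    return [(p, sig_proteins[p]) for p in ranked[:n_proteins]]


def run_score(config: dict | None = None, outdir: str | Path = "out",
              variables: VariableMatrix | None = None,
              seed: int | None = None) -> dict:
    """GA selection, nested subsets, LDA evaluation and predictions.

    ``variables`` may be supplied directly; otherwise ``config["input"]
    ["variables_tsv"]`` is read (samples x variables TSV with a ``label``
    column, empty labels = samples to predict).
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stage": "score", "config_hash": config_hash(config)}
    try:
        if variables is None:
            path = config["input"]["variables_tsv"]
            df = pd.read_csv(path, sep="\t", index_col=0)
            labels = df.pop("label")
            labels = labels.where(labels.isin(["sensitive", "resistant"]))
            variables = VariableMatrix(X=df, labels=labels)
    except (KeyError, OSError, ValueError) as exc:
        raise PipelineError(f"score/input: {exc}") from exc

    ga_cfg = GAConfig(**config.get("ga", {}))
    if seed is not None:
        ga_cfg.rng_seed = seed
    scheme = config.get("cv", {}).get("scheme", "loocv")
    if isinstance(scheme, list):
        scheme = tuple(scheme)
    shrinkage = config.get("lda", {}).get("shrinkage", "auto")
    cuts = tuple(config.get("subsets", {}).get(
        "cut_points", (4, 7, 11, 17, None)))

    try:
        solutions = ga_select(variables, config=ga_cfg, scheme=scheme,
                              shrinkage=shrinkage)
        nested = build_nested_subsets(solutions, cut_points=cuts,
                                      X=variables, scheme=scheme,
                                      shrinkage=shrinkage,
                                      seed=ga_cfg.rng_seed)
        table, best = evaluate_subsets(variables, subsets=nested,
                                       scheme=scheme, shrinkage=shrinkage,
                                       seed=ga_cfg.rng_seed)
        winning = nested.subsets[best]
        Xl, yl = variables.labeled()
        model = lda_fit(Xl[winning], yl, shrinkage=shrinkage)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise PipelineError(f"score/ga_lda: {exc}") from exc

    solutions_json = [{"subset": sorted(s), "fitness": f}
                      for s, f in solutions.solutions]
    (outdir / "ga_solutions.json").write_text(
        json.dumps(solutions_json, indent=2) + "\n")
    solutions.frequencies.rename("selection_frequency").to_csv(
        outdir / "selection_frequencies.tsv", sep="\t")
    table.to_csv(outdir / "subset_accuracies.tsv", sep="\t", index=False)
    model_json = {"variables": model.variables,
                  "coefficients": model.coef.tolist(),
                  "intercept": model.intercept,
                  "shrinkage": model.shrinkage,
                  "priors": model.priors}
    (outdir / "lda_model.json").write_text(
        json.dumps(model_json, indent=2) + "\n")

    preds = []
    unlabeled = variables.X.loc[variables.labels.isna()]
    for sid, row in unlabeled[winning].iterrows():
        preds.append(classify_sample(model, row.values, sample_id=str(sid)))
    pred_df = pd.DataFrame([asdict(p) for p in preds])
    pred_df.to_csv(outdir / "predictions.tsv", sep="\t", index=False)

    report.update({
        "ga_runs": solutions.n_runs,
        "variables": len(solutions.variables),
        "variables_ever_selected": int((solutions.frequencies > 0).sum()),
        "subset_accuracies": table.to_dict("records"),
        "winning_subset": winning,
        "n_predictions": len(preds),
    })
    log.info("score: %s", report)
    return _write_report(report, outdir, "score_report.json")


def run_bead(config: dict | None = None, outdir: str | Path = "out",
             seed: int | None = None) -> dict:
    """Bead-assay stage: gating, MFI, NEM subtraction/ratios, group
    comparisons and per-patient flags.

    With ``config["simulate"]`` present (n_biomarkers, samples table
    spec, effects), a synthetic cohort is generated; otherwise
    ``config["input"]`` must point at events and samples CSVs.
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stage": "bead", "config_hash": config_hash(config)}
    sim = config.get("simulate")
    try:
        if sim is not None:
            samples = pd.DataFrame(sim["samples"])
            effects = pd.DataFrame(sim.get("effects")) \
                if sim.get("effects") is not None else None
            events, truth = simulate_bead_study(
                n_biomarkers=sim.get("n_biomarkers", 3), samples=samples,
                effects=effects,
                rng_seed=seed if seed is not None else sim.get("rng_seed", 0))
            centroids = truth.centroids
            events.to_csv(outdir / "bead_events.csv", index=False)
        else:
            inp = config["input"]
            events = pd.read_csv(inp["events_csv"])
            samples = pd.read_csv(inp["samples_csv"])
            centroids = None
        if samples.empty:
            raise ValueError("empty sample table")
    except (KeyError, OSError, ValueError) as exc:
        raise PipelineError(f"bead/input: {exc}") from exc

    gate = config.get("gating", {})
    try:
        labeled = bead_ops.assign_bead_regions(
            events, centroids=centroids, k=gate.get("k"),
            max_distance=gate.get("max_distance"),
            seed=seed if seed is not None else 0)
        mfi = bead_ops.compute_mfi(labeled,
                                   min_events=gate.get("min_events", 30))
        mfi.to_csv(outdir / "bead_mfi.tsv", sep="\t", index=False)
    except ValueError as exc:
        raise PipelineError(f"bead/gating: {exc}") from exc

    pairs = [tuple(p) for p in config.get("pairs", [])]
    ratios = None
    if pairs:
        try:
            ratios = bead_ops.nem_subtract_and_ratio(mfi, samples, pairs)
            ratios.to_csv(outdir / "bead_ratios.tsv", sep="\t", index=False)
        except KeyError as exc:
            raise PipelineError(f"bead/ratios: {exc}") from exc

    flags = None
    groups = config.get("patients")
    if groups:
        responders = groups["responders"]
        patient_mfi = mfi[mfi["modifier"] == "ubiquitin"
                          ].rename(columns={"biomarker": "biomarker"})
        patient_mfi = patient_mfi[patient_mfi["sample_id"].isin(
            groups["responders"] + groups["refractory"])]
        comparisons = []
        for bm, grp in patient_mfi.groupby("biomarker"):
            a = grp[grp["sample_id"].isin(groups["refractory"])]["mfi"]
            b = grp[grp["sample_id"].isin(responders)]["mfi"]
            res = bead_ops.compare_groups(a.values, b.values,
                                          design="unpaired_welch")
            comparisons.append((bm, res.statistic, res.p_value))
        pd.DataFrame(comparisons, columns=["biomarker", "t", "p"]).to_csv(
            outdir / "bead_comparisons.tsv", sep="\t", index=False)
        flags = bead_ops.flag_high_modification(
            patient_mfi, responder_ids=responders,
            k_sd=groups.get("k_sd", 2.0))
        flags.to_csv(outdir / "bead_flags.tsv", sep="\t", index=False)

    report.update({
        "events": len(events),
        "samples": int(events["sample_id"].nunique()),
        "mfi_rows": len(mfi),
        "ratio_rows": 0 if ratios is None else len(ratios),
        "flagged_patients": (0 if flags is None
                             else int(flags["flagged"].sum())),
    })
    log.info("bead: %s", report)
    return _write_report(report, outdir, "bead_report.json")
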