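"""Bead gating, MFI computation, NEM subtraction and patient flags."""

import numpy as np
import pandas as pd
import pytest

from ublsig.beads import (assign_bead_regions, compare_groups, compute_mfi,
                          flag_high_modification, nem_subtract_and_ratio)
from ublsig.simulate import simulate_bead_study
from ublsig.stats import t_test


def cohort_samples():
    return pd.DataFrame({
        "sample_id": ["par", "res", "par_nem", "res_nem"],
        "nem_control": [False, False, True, True],
        "nem_pair": ["par_nem", "res_nem", None, None],
    })


def test_region_assignment_matches_simulated_truth():
    ev, truth = simulate_bead_study(3, cohort_samples(), rng_seed=1)
    labeled = assign_bead_regions(ev, centroids=truth.centroids)
    acc = (labeled["region"] == truth.region_labels).mean()
    assert acc >= 0.99


def test_single_region_takes_all_events():
    ev, truth = simulate_bead_study(1, cohort_samples(), rng_seed=2)
    labeled = assign_bead_regions(ev, centroids=truth.centroids)
    assert (labeled["region"] == "BM1").all()


def test_distance_gate_unassigns_outliers():
    ev = pd.DataFrame({"sample_id": ["s"] * 3,
                       "CL1": [0.0, 1.0, 1e7],
                       "CL2": [0.0, 1.0, 1e7],
                       "RP_ub": [10.0] * 3, "RP_sumo1": [10.0] * 3})
    labeled = assign_bead_regions(ev, centroids=np.array([[0.0, 0.0]]),
                                  max_distance=100.0)
    assert labeled["region"].tolist() == ["BM1", "BM1", ""]


def test_kmeans_fallback_is_seeded():
    ev, truth = simulate_bead_study(2, cohort_samples(), rng_seed=3)
    l1 = assign_bead_regions(ev, k=2, seed=7)
    l2 = assign_bead_regions(ev, k=2, seed=7)
    assert (l1["region"] == l2["region"]).all()
    with pytest.raises(ValueError, match="exceeds"):
        assign_bead_regions(ev.head(1), k=2)


def test_mfi_median_conventions():
    def ev(values):
        return pd.DataFrame({"sample_id": "s", "region": "BM1",
                             "RP_ub": values,
                             "RP_sumo1": 1.0})
    odd = compute_mfi(ev([100.0, 200.0, 300.0]), min_events=1)
    assert odd[odd["modifier"] == "ubiquitin"]["mfi"].iloc[0] == 200.0
    even = compute_mfi(ev([100.0, 200.0, 300.0, 400.0]), min_events=1)
    assert even[even["modifier"] == "ubiquitin"]["mfi"].iloc[0] == 250.0


def test_mfi_event_minimum_flags_unusable():
    ev = pd.DataFrame({"sample_id": "s", "region": "BM1",
                       "RP_ub": np.arange(10.0), "RP_sumo1": 1.0})
    out = compute_mfi(ev, min_events=30)
    assert not out["usable"].any()


def test_mfi_invariant_to_event_order_and_median_padding():
    rng = np.random.default_rng(4)
    vals = rng.normal(500, 50, 31)
    ev = pd.DataFrame({"sample_id": "s", "region": "BM1",
                       "RP_ub": vals, "RP_sumo1": 1.0})
    shuffled = ev.sample(frac=1, random_state=1).reset_index(drop=True)
    m1 = compute_mfi(ev, min_events=1)["mfi"].iloc[0]
    m2 = compute_mfi(shuffled, min_events=1)["mfi"].iloc[0]
    assert m1 == m2
    med = np.median(vals)
    padded = pd.concat([ev, ev.head(3).assign(RP_ub=med, RP_sumo1=1.0)])
    m3 = compute_mfi(padded, min_events=1)["mfi"].iloc[0]
    assert m3 == m1


def test_nem_subtraction_and_ratio_worked_example():
    mfi = pd.DataFrame({
        "sample_id": ["res", "par", "res_nem", "par_nem"],
        "biomarker": "BM1", "modifier": "ubiquitin",
        "mfi": [500.0, 300.0, 100.0, 100.0],
        "n_events": 100, "usable": True,
    })
    out = nem_subtract_and_ratio(mfi, cohort_samples(), [("res", "par")])
    assert out["ratio"].iloc[0] == pytest.approx(2.0)  # (500-100)/(300-100)
    assert not out["unstable"].iloc[0]


def test_nem_dominating_signal_floors_and_flags():
    mfi = pd.DataFrame({
        "sample_id": ["res", "par", "res_nem", "par_nem"],
        "biomarker": "BM1", "modifier": "ubiquitin",
        "mfi": [500.0, 90.0, 100.0, 100.0],
        "n_events": 100, "usable": True,
    })
    out = nem_subtract_and_ratio(mfi, cohort_samples(), [("res", "par")])
    assert out["adjusted_parental"].iloc[0] == 1.0  # floor
    assert out["unstable"].iloc[0]


def test_self_ratio_is_one():
    mfi = pd.DataFrame({
        "sample_id": ["par", "par_nem"], "biomarker": "BM1",
        "modifier": "ubiquitin", "mfi": [400.0, 100.0],
        "n_events": 100, "usable": True,
    })
    out = nem_subtract_and_ratio(mfi, cohort_samples(), [("par", "par")])
    assert out["ratio"].iloc[0] == 1.0


def test_planted_two_fold_ratio_recovered():
    effects = pd.DataFrame({"BM1": {"par": 0.0, "res": 1.0}})  # 2x
    ev, truth = simulate_bead_study(1, cohort_samples(), effects=effects,
                                    rng_seed=5)
    labeled = assign_bead_regions(ev, centroids=truth.centroids)
    mfi = compute_mfi(labeled)
    out = nem_subtract_and_ratio(mfi, cohort_samples(), [("res", "par")])
    assert out["ratio"].iloc[0] == pytest.approx(2.0, rel=0.2)


def test_missing_nem_pairing_is_hard_error():
    mfi = pd.DataFrame({
        "sample_id": ["res", "par"], "biomarker": "BM1",
        "modifier": "ubiquitin", "mfi": [500.0, 300.0],
        "n_events": 100, "usable": True,
    })
    with pytest.raises(KeyError, match="NEM"):
        nem_subtract_and_ratio(mfi, cohort_samples(), [("res", "par")])


def test_compare_groups_delegates_to_t_tests():
    rng = np.random.default_rng(6)
    a, b = rng.normal(2, 1, 8), rng.normal(0, 1, 8)
    welch = compare_groups(a, b, design="unpaired_welch")
    assert welch.p_value == t_test(a, b, mode="welch_two_sample").p_value
    paired = compare_groups(a, b, design="paired")
    assert paired.p_value == t_test(a - b, 0.0, mode="one_sample").p_value
    identical = compare_groups(a, a, design="unpaired_welch")
    assert identical.p_value == 1.0


def test_welch_power_on_shifted_groups():
    """1.5-log2 shift, n=(29, 10): reject at alpha=0.05 in >=90% of
    replicates (a reduced version of the full power simulation)."""
    rng = np.random.default_rng(7)
    hits = 0
    n_rep = 300
    for _ in range(n_rep):
        responders = rng.normal(8.0, 1.0, 29)
        refractory = rng.normal(9.5, 1.0, 10)
        hits += t_test(refractory, responders).p_value < 0.05
    assert hits / n_rep >= 0.9


def _patient_mfi(values_by_sample, biomarker="BM1"):
    rows = [(sid, biomarker, "ubiquitin", v, 100, True)
            for sid, v in values_by_sample.items()]
    return pd.DataFrame(rows, columns=["sample_id", "biomarker", "modifier",
                                       "mfi", "n_events", "usable"])


def test_all_identical_patients_no_flags():
    mfi = _patient_mfi({f"p{i}": 100.0 for i in range(6)})
    flags = flag_high_modification(mfi, responder_ids=["p0", "p1", "p2"])
    assert not flags["flagged"].any()


def test_single_high_biomarker_flags_patient():
    ref = {f"r{i}": 100.0 + i for i in range(5)}
    mfi = pd.concat([
        _patient_mfi({**ref, "px": 100.0}, "BM1"),
        _patient_mfi({**ref, "px": 100.0}, "BM2"),
        _patient_mfi({**ref, "px": 120.0}, "BM3"),  # mean+~11 SD
    ])
    flags = flag_high_modification(mfi, responder_ids=list(ref))
    row = flags.set_index("sample_id").loc["px"]
    assert row["flagged"] and row["BM3"] and not row["BM1"]


def test_zero_reference_sd_flags_strictly_greater():
    mfi = _patient_mfi({"r0": 100.0, "r1": 100.0, "r2": 100.0,
                        "hi": 100.5, "eq": 100.0})
    flags = flag_high_modification(mfi, responder_ids=["r0", "r1", "r2"])
    f = flags.set_index("sample_id")["flagged"]
    assert f["hi"] and not f["eq"]


def test_too_few_responders_errors():
    mfi = _patient_mfi({"r0": 100.0, "r1": 100.0, "p": 200.0})
    with pytest.raises(ValueError, match="3"):
        flag_high_modification(mfi, responder_ids=["r0", "r1"])


def test_planted_refractory_cohort_flags_recovered():
    """29 responders + 10 refractory of which 6 carry a high-ubiquitylation
    effect on >= 1 of 3 biomarkers: flags match the planted truth."""
    rng = np.random.default_rng(8)
    responders = [f"resp{i:02d}" for i in range(29)]
    refractory = [f"refr{i:02d}" for i in range(10)]
    rows = []
    planted = {r: (i < 6) for i, r in enumerate(refractory)}
    for bm_i, bm in enumerate(["BM1", "BM2", "BM3"]):
        for sid in responders:
            rows.append((sid, bm, "ubiquitin", rng.normal(300, 20), 100, True))
        for i, sid in enumerate(refractory):
            high = planted[sid] and (i % 3 == bm_i)  # one biomarker each
            mu = 600 if high else 300
            rows.append((sid, bm, "ubiquitin", rng.normal(mu, 20), 100, True))
    mfi = pd.DataFrame(rows, columns=["sample_id", "biomarker", "modifier",
                                      "mfi", "n_events", "usable"])
    flags = flag_high_modification(mfi, responder_ids=responders)
    got = flags.set_index("sample_id")["flagged"]
    for sid, expect in planted.items():
        assert got[sid] == expect
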