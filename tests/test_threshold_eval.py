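"""Threshold classification rule, accuracy table, selection logic,
application to empirical samples, and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixkit.hybrid_sim import DESIGN_ORDER, HybridClass, SimulatedDataset
from admixkit.io_formats import GenotypeMatrix
from admixkit.threshold_eval import (
    accuracy_table,
    apply_to_samples,
    classify,
    run_full_pipeline,
    select_threshold,
)


def _sim_from_q(classes):
    """Minimal SimulatedDataset carrying only class labels."""
    n = len(classes)
    gm = GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        [c.value for c in classes],
        ["L1"],
        np.ones((n, 1, 2), dtype=int),
    )
    return SimulatedDataset(gm, list(classes), generation_seed=0)


def _q(qa):
    qa = np.asarray(qa, dtype=float)
    return np.column_stack([qa, 1.0 - qa])


def test_classify_rules_and_boundary():
    assert classify(0.95, 0.85) == "non-admixed-A"
    assert classify(0.05, 0.85) == "non-admixed-B"
    assert classify(0.5, 0.85) == "admixed"
    assert classify(0.85, 0.85) == "admixed"  # strict inequality
    with pytest.raises(ValueError):
        classify(0.7, 0.5)
    with pytest.raises(ValueError):
        classify(0.7, 0.4)


@settings(max_examples=60, deadline=None)
@given(
    qi=st.floats(0.0, 1.0),
    t=st.floats(0.51, 0.99),
)
def test_classify_mirror_symmetry(qi, t):
    """Calling from cluster B's perspective swaps the pure labels."""
    a = classify(qi, t)
    b = classify(1.0 - qi, t)
    swap = {"non-admixed-A": "non-admixed-B", "non-admixed-B": "non-admixed-A", "admixed": "admixed"}
    assert b == swap[a]


def test_accuracy_table_hand_counts():
    # 5 backcross individuals, 3 with qi > 0.8 -> 60% misassigned at t=0.8
    classes = (
        [HybridClass.PURE_A] * 2
        + [HybridClass.F1] * 3
        + [HybridClass.BC_A] * 5
    )
    qa = [0.95, 0.99, 0.5, 0.45, 0.55, 0.85, 0.9, 0.92, 0.7, 0.75]
    table = accuracy_table(_sim_from_q(classes), _q(qa), thresholds=(0.8,))
    t = table.set_index("hybrid_class")
    assert t.loc["pure_A", "percent_misassigned"] == 0.0
    assert t.loc["F1", "percent_misassigned"] == 0.0
    assert t.loc["BC_A", "n_misassigned"] == 3
    assert t.loc["BC_A", "percent_misassigned"] == pytest.approx(60.0)
    assert t.loc["BC_A", "qi_min"] == pytest.approx(0.7)
    assert t.loc["BC_A", "qi_max"] == pytest.approx(0.92)


def test_accuracy_table_f1_at_half_never_misassigned():
    classes = [HybridClass.PURE_A] * 2 + [HybridClass.F1] * 5
    qa = [0.99, 0.98] + [0.5] * 5
    table = accuracy_table(
        _sim_from_q(classes), _q(qa), thresholds=(0.8, 0.85, 0.9, 0.95)
    )
    f1 = table[table["hybrid_class"] == "F1"]
    assert (f1["percent_misassigned"] == 0.0).all()


def test_accuracy_table_rejects_unknown_class():
    sim = _sim_from_q([HybridClass.PURE_A, HybridClass.F1])
    sim.true_class[1] = "not_a_class"
    with pytest.raises(ValueError, match="unknown hybrid class"):
        accuracy_table(sim, _q([0.99, 0.5]))


@settings(max_examples=30, deadline=None)
@given(data=st.data())
def test_misassignment_monotone_in_threshold(data):
    """For any fixed Q: pure-class error is non-decreasing and hybrid-class
    error non-increasing in the threshold (the Fig-3 crossing shape)."""
    n = data.draw(st.integers(2, 12))
    qa = [data.draw(st.floats(0.0, 1.0)) for _ in range(n)]
    classes = [
        data.draw(st.sampled_from(list(HybridClass))) for _ in range(n)
    ]
    classes[0] = HybridClass.PURE_A  # cluster orientation needs a pure-A row
    qa[0] = max(qa[0], 0.6)
    thresholds = (0.8, 0.85, 0.9, 0.95)
    table = accuracy_table(_sim_from_q(classes), _q(qa), thresholds)
    for cls, grp in table.groupby("hybrid_class"):
        g = grp.sort_values("threshold")["percent_misassigned"].to_numpy()
        if cls in ("pure_A", "pure_B"):
            assert (np.diff(g) >= -1e-9).all()
        else:
            assert (np.diff(g) <= 1e-9).all()


def _table(rows):
    return pd.DataFrame(
        rows, columns=["hybrid_class", "threshold", "percent_misassigned"]
    )


def _full_table(per_threshold):
    """per_threshold: {t: dict of class -> percent}"""
    rows = []
    for t, d in per_threshold.items():
        for c in DESIGN_ORDER:
            rows.append((c.value, t, d.get(c.value, 0.0)))
    return _table(rows)


def test_select_threshold_study_shape():
    """Zero pure/F1/F2 error at 0.80 and 0.85, pure errors above -> 0.85."""
    table = _full_table(
        {
            0.80: {"BC_A": 60.0, "BC_B": 45.0},
            0.85: {"BC_A": 46.7, "BC_B": 28.3},
            0.90: {"pure_A": 3.3, "pure_B": 1.7},
            0.95: {"pure_A": 23.3, "pure_B": 11.7},
        }
    )
    assert select_threshold(table) == 0.85


def test_select_threshold_all_perfect_returns_largest():
    table = _full_table({t: {} for t in (0.8, 0.85, 0.9, 0.95)})
    assert select_threshold(table) == 0.95


def test_select_threshold_tie_goes_lower():
    table = _full_table(
        {
            0.80: {"pure_A": 5.0},
            0.85: {"pure_A": 5.0},
            0.90: {"pure_A": 10.0},
        }
    )
    assert select_threshold(table) == 0.80


def test_apply_to_samples_known_hybrid_summary():
    # 8 known hybrids: 6 admixed qi, 2 above threshold -> "6 of 8 confirmed"
    q = pd.DataFrame(
        {
            "individual_id": [f"h{i}" for i in range(8)] + [f"p{i}" for i in range(15)],
            "q_A": [0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9664, 0.9510]
            + [0.5] * 4 + [0.95] * 11,
            "label": ["known"] * 8 + ["putative"] * 15,
        }
    )
    calls, summary = apply_to_samples(q, 0.85)
    s = summary.set_index("label")
    assert s.loc["known", "n_admixed"] == 6
    assert s.loc["putative", "n_admixed"] == 4
    assert s.loc["putative", "percent_admixed"] == pytest.approx(100 * 4 / 15)
    assert (calls[calls["call"] == "admixed"].shape[0]) == 10


def test_apply_all_ambiguous_qi_called_admixed():
    q = pd.DataFrame(
        {"individual_id": ["a", "b"], "q_A": [0.5, 0.5], "label": ["x", "x"]}
    )
    _, summary = apply_to_samples(q, 0.9)
    assert summary["percent_admixed"].tolist() == [100.0]


def test_pipeline_smoke_and_determinism(tmp_path):
    cfg = {
        "seed": 5,
        "n_loci": 8,
        "allele_range": (3, 6),
        "n_ref": (10, 10),
        "n_per_class": 3,
        "reps": 400,
        "burnin": 100,
        "replicates": 2,
    }
    m1 = run_full_pipeline(cfg, tmp_path / "run1")
    m2 = run_full_pipeline(cfg, tmp_path / "run2")
    truth = pd.read_csv(tmp_path / "run1" / "truth.csv")
    assert len(truth) == 24
    assert truth["true_class"].nunique() == 8
    for name in ("truth.csv", "qmatrix.csv", "accuracy.csv", "pca.csv"):
        assert (tmp_path / "run1" / name).read_bytes() == (
            tmp_path / "run2" / name
        ).read_bytes()
    assert m1["selected_threshold"] == m2["selected_threshold"]
    assert (tmp_path / "run1" / "misassignment_curves.png").exists()
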