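import math

import numpy as np
import pandas as pd
import pytest

from hormonet import datasets, synthgen
from hormonet.datasets import RiskMappingError, SplitConfigError, SplitSpec
from hormonet.seqio import ProteinRecord


@pytest.mark.parametrize(
    "level,expected", [("major", "A"), ("moderate", "B"), ("MINOR", "C"), (" Major ", "A")]
)
def test_map_risk_class(level, expected):
    assert datasets.map_risk_class(level) == expected


def test_map_risk_class_unknown():
    with pytest.raises(RiskMappingError, match="unknown"):
        datasets.map_risk_class("unknown")


def _toy_inputs():
    seqs = {
        pid: ProteinRecord(pid, "ACDEFGHIKL" * 6)
        for pid in ("R1", "R2", "T1", "T2")
    }
    hr = pd.DataFrame(
        {"hormone_id": ["H1", "H2"], "receptor_id": ["R1", "R2"]}
    )
    # H2 made receptorless by dropping its row below where needed
    dt = pd.DataFrame({"drug_id": ["D1", "D2"], "target_id": ["T1", "T2"]})
    ppi = pd.DataFrame(
        {
            "protA": ["R1", "R1", "R2"],
            "protB": ["T1", "T2", "T1"],
            "label": [1, 1, 0],
        }
    )
    ddi = pd.DataFrame(
        {
            "drugA": ["H1", "H1"],
            "drugB": ["D1", "D2"],
            "level": ["major", "minor"],
        }
    )
    return hr, dt, ddi, ppi, seqs


def test_build_pairs_hand_enumeration():
    hr, dt, ddi, ppi, seqs = _toy_inputs()
    stage1, stage2 = datasets.build_pairs(hr, dt, ddi, ppi, seqs)
    # join yields (H1,D1,R1,T1,+,A), (H1,D2,R1,T2,+,C), (H2,D1,R2,T1,-)
    assert len(stage1) == 3
    assert stage1["interact"].sum() == 2
    assert len(stage2) == 2
    assert sorted(stage2["risk"]) == ["A", "C"]


def test_receptorless_hormone_contributes_nothing():
    hr, dt, ddi, ppi, seqs = _toy_inputs()
    hr = hr[hr["hormone_id"] == "H1"]  # H2 now has no receptor
    stage1, _ = datasets.build_pairs(hr, dt, ddi, ppi, seqs)
    assert "H2" not in set(stage1["hormone_id"])
    assert len(stage1) == 2


def test_missing_sequence_drops_row(caplog):
    hr, dt, ddi, ppi, seqs = _toy_inputs()
    del seqs["T2"]
    with caplog.at_level("WARNING"):
        stage1, _ = datasets.build_pairs(hr, dt, ddi, ppi, seqs)
    assert len(stage1) == 2
    assert any("T2" in r.message for r in caplog.records)


def test_stage2_subset_of_stage1_positives():
    hr, dt, ddi, ppi, seqs = _toy_inputs()
    stage1, stage2 = datasets.build_pairs(hr, dt, ddi, ppi, seqs)
    keys1 = set(map(tuple, stage1[stage1["interact"] == 1][["hormone_id", "drug_id"]].values))
    keys2 = set(map(tuple, stage2[["hormone_id", "drug_id"]].values))
    assert keys2 <= keys1


def test_build_pairs_deterministic():
    hr, dt, ddi, ppi, seqs = _toy_inputs()
    a1, a2 = datasets.build_pairs(hr, dt, ddi, ppi, seqs)
    # shuffle input row order; output must be identical
    b1, b2 = datasets.build_pairs(
        hr.iloc[::-1], dt.iloc[::-1], ddi.iloc[::-1], ppi.iloc[::-1], seqs
    )
    pd.testing.assert_frame_equal(a1, b1)
    pd.testing.assert_frame_equal(a2, b2)


def test_synthgen_round_trip_counts():
    cfg = synthgen.SynthConfig(seed=11, n_hormones=6, n_drugs=8)
    hr, dt, ddi, ppi, records, truth = synthgen.gen_relational(cfg)
    stage1, stage2 = datasets.build_pairs(hr, dt, ddi, ppi, records)
    assert len(stage1) == truth["n_stage1"]
    assert int(stage1["interact"].sum()) == truth["n_positive"]
    assert len(stage2) == truth["n_stage2"]
    assert stage2["risk"].value_counts().to_dict() == {
        k: v for k, v in truth["risk_counts"].items() if v
    }


@pytest.mark.parametrize("n,expected_test", [(4773, 1194), (11103, 2776), (10, 3)])
def test_holdout_ceiling_arithmetic(n, expected_test):
    table = pd.DataFrame({"risk": ["A"] * n})
    train, test = datasets.split(table, SplitSpec(test_fraction=0.25, seed=0))
    assert len(test) == expected_test
    assert len(train) == n - expected_test
    assert math.ceil(0.25 * n) == expected_test


def test_holdout_seed_contract():
    table = pd.DataFrame({"risk": list("AABB"), "x": range(4)})
    parts = []
    for seed in range(6):
        train, test = datasets.split(table, SplitSpec(test_fraction=0.5, seed=seed))
        assert len(test) == 2 and len(train) == 2
        parts.append(tuple(sorted(test["x"])))
    assert len(set(parts)) > 1  # different seeds explore different partitions
    # same seed reproduces
    t1 = datasets.split(table, SplitSpec(test_fraction=0.5, seed=3))[1]
    t2 = datasets.split(table, SplitSpec(test_fraction=0.5, seed=3))[1]
    assert list(t1["x"]) == list(t2["x"])


def test_stratified_holdout_covers_classes():
    table = pd.DataFrame({"risk": ["A"] * 40 + ["B"] * 8})
    _, test = datasets.split(table, SplitSpec(test_fraction=0.25, seed=1, stratified=True))
    assert set(test["risk"]) == {"A", "B"}
    assert (test["risk"] == "B").sum() == 2  # ceil(0.25 * 8)


def test_split_config_validation():
    with pytest.raises(SplitConfigError):
        SplitSpec(test_fraction=1.5)
    with pytest.raises(SplitConfigError):
        SplitSpec(test_fraction=0.0)
    with pytest.raises(SplitConfigError):
        datasets.split(pd.DataFrame({"risk": ["A"]}), SplitSpec())


def test_kfold_partition_properties():
    table = pd.DataFrame({"risk": ["A", "B", "C"] * 33 + ["A"]})  # N = 100
    folds = datasets.kfold_indices(table, SplitSpec(scheme="kfold", k=3, seed=0))
    sizes = [len(test) for _, test in folds]
    assert max(sizes) - min(sizes) <= 1
    all_test = np.concatenate([test for _, test in folds])
    assert sorted(all_test) == list(range(100))  # disjoint and exhaustive
    for train, test in folds:
        assert set(train).isdisjoint(test)
        assert len(train) + len(test) == 100
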