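import numpy as np
import pandas as pd
import pytest

from ecgnets import dataset
from ecgnets.dataset import LabelEntry


LABEL_MAP = {
    "NORM": LabelEntry("NORM", "NORM", True),
    "IMI": LabelEntry("IMI", "MI", True),
    "AMI": LabelEntry("AMI", "MI", True),
    "LVH": LabelEntry("LVH", "HYP", True),
    "SR": LabelEntry("", "", False),
}


def _meta(rows):
    """rows: list of scp_codes dicts -> metadata frame indexed by ecg_id."""
    return pd.DataFrame(
        {"scp_codes": rows}, index=pd.RangeIndex(1, len(rows) + 1, name="ecg_id")
    )


def test_filter_diagnostic_rule():
    meta = _meta([{"NORM": 100.0}] * 25 + [{"SR": 100.0}] * 3)
    kept = dataset.filter_records(meta, LABEL_MAP)
    assert len(kept) == 25
    assert all(len(c) == 1 and "NORM" in c for c in kept["scp_codes"])


def test_filter_likelihood_rule():
    meta = _meta([{"NORM": 100.0}] * 25 + [{"NORM": 50.0}] * 3
                 + [{"NORM": 100.0, "SR": 0.0}] * 5)
    kept = dataset.filter_records(meta, LABEL_MAP)
    # sub-100 diagnostic likelihood removed; non-diagnostic likelihood ignored
    assert len(kept) == 30


def test_filter_rare_subclass_rule():
    meta = _meta([{"NORM": 100.0}] * 25 + [{"LVH": 100.0}] * 5)
    kept = dataset.filter_records(meta, LABEL_MAP, min_subclass_count=20)
    assert len(kept) == 25
    subs = {s for codes in kept["scp_codes"]
            for s in dataset.record_classes(codes, LABEL_MAP, "sub")}
    assert subs == {"NORM"}


def test_filter_everything_removed_raises():
    meta = _meta([{"SR": 100.0}] * 4)
    with pytest.raises(ValueError, match="empty"):
        dataset.filter_records(meta, LABEL_MAP)


def test_assign_labels_schemes():
    meta = _meta([{"NORM": 100.0}, {"IMI": 100.0}, {"LVH": 100.0}])
    binary = dataset.assign_labels(meta, LABEL_MAP, "binary")
    assert list(binary["label"]) == ["NORM", "ABNORM", "ABNORM"]
    sup = dataset.assign_labels(meta, LABEL_MAP, "super5")
    assert list(sup["label"]) == ["NORM", "MI", "HYP"]
    sub = dataset.assign_labels(meta, LABEL_MAP, "sub20")
    assert list(sub["label"]) == ["NORM", "IMI", "LVH"]


def test_assign_labels_drops_multilabel_records():
    meta = _meta([{"NORM": 100.0, "IMI": 100.0}, {"IMI": 100.0, "AMI": 100.0}])
    sup = dataset.assign_labels(meta, LABEL_MAP, "super5")
    # first record spans two superclasses -> dropped; second is MI-only
    assert list(sup["label"]) == ["MI"]
    sub = dataset.assign_labels(meta, LABEL_MAP, "sub20")
    assert sub.empty


def test_assign_labels_unknown_scheme():
    with pytest.raises(ValueError, match="scheme"):
        dataset.assign_labels(_meta([{"NORM": 100.0}]), LABEL_MAP, "bogus")


def test_split_sizes_and_disjointness():
    n_a, n_b = 100, 40
    meta = _meta([{"NORM": 100.0}] * n_a + [{"IMI": 100.0}] * n_b)
    labeled = dataset.assign_labels(meta, LABEL_MAP, "binary")
    out = dataset.split_dataset(labeled, seed=3)
    for cls, n in (("NORM", n_a), ("ABNORM", n_b)):
        grp = out[out["label"] == cls]["split"].value_counts()
        n_train = int(np.floor(0.70 * n))
        rem = n - n_train
        assert grp["train"] == n_train
        assert grp["val"] == rem // 2
        assert grp["test"] == rem - rem // 2
    # per-record assignment is a partition by construction (one column)
    assert set(out["split"]) == {"train", "val", "test"}


def test_split_deterministic_and_seed_sensitive():
    meta = _meta([{"NORM": 100.0}] * 40)
    labeled = dataset.assign_labels(meta, LABEL_MAP, "binary")
    a = dataset.split_dataset(labeled, seed=1)["split"]
    b = dataset.split_dataset(labeled, seed=1)["split"]
    c = dataset.split_dataset(labeled, seed=2)["split"]
    assert a.equals(b)
    assert not a.equals(c)


def test_split_tiny_class_warns_and_goes_to_train():
    meta = _meta([{"NORM": 100.0}] * 10 + [{"IMI": 100.0}] * 2)
    labeled = dataset.assign_labels(meta, LABEL_MAP, "binary")
    with pytest.warns(UserWarning, match="placed in train"):
        out = dataset.split_dataset(labeled)
    assert (out[out["label"] == "ABNORM"]["split"] == "train").all()


def test_split_bad_ratios():
    meta = _meta([{"NORM": 100.0}] * 10)
    labeled = dataset.assign_labels(meta, LABEL_MAP, "binary")
    with pytest.raises(ValueError, match="sum to 1"):
        dataset.split_dataset(labeled, ratios=(0.5, 0.2, 0.2))


def test_load_metadata_parses_and_warns_on_unknown_code(tmp_path):
    meta_csv = tmp_path / "db.csv"
    meta_csv.write_text(
        "ecg_id,scp_codes,filename_lr\n"
        "1,\"{'NORM': 100.0}\",records100/00001_lr\n"
        "2,\"{'WEIRD': 100.0}\",records100/00002_lr\n"
    )
    stm_csv = tmp_path / "scp.csv"
    stm_csv.write_text(
        "code,diagnostic_subclass,diagnostic_class,diagnostic\n"
        "NORM,NORM,NORM,1\n"
    )
    with pytest.warns(UserWarning, match="WEIRD"):
        meta, label_map = dataset.load_metadata(meta_csv, stm_csv)
    assert meta.loc[1, "scp_codes"] == {"NORM": 100.0}
    assert label_map["NORM"].is_diagnostic
    assert not label_map["WEIRD"].is_diagnostic


def test_load_metadata_bad_scp_cell(tmp_path):
    meta_csv = tmp_path / "db.csv"
    meta_csv.write_text("ecg_id,scp_codes\n1,not-a-dict\n")
    stm_csv = tmp_path / "scp.csv"
    stm_csv.write_text("code,diagnostic\nNORM,1\n")
    with pytest.raises(ValueError, match="unparseable"):
        dataset.load_metadata(meta_csv, stm_csv)


def test_normalize_signal():
    rng = np.random.default_rng(0)
    sig = rng.normal(2.0, 3.0, size=(12, 1000))
    sig[4] = 1.5  # constant channel
    out = dataset.normalize_signal(sig)
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
    live = np.delete(np.arange(12), 4)
    np.testing.assert_allclose(out[live].std(axis=1), 1.0, atol=1e-12)
    assert (out[4] == 0).all()
    with pytest.raises(ValueError, match="non-finite"):
        dataset.normalize_signal(np.full((2, 5), np.nan))


def test_load_signal_from_fixture(small_fixture):
    meta, label_map = dataset.load_metadata(
        small_fixture / "ptbxl_database.csv",
        small_fixture / "scp_statements.csv")
    sig = dataset.load_signal(meta.iloc[0], small_fixture)
    assert sig.shape == (12, 1000)
    assert np.isfinite(sig).all()
    # millivolt-scale amplitudes, not raw 16-bit integers
    assert 0.1 < np.abs(sig).max() < 20
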