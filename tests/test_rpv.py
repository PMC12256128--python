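"""RPV aggregation, flagging and the interval table."""

import numpy as np
import pandas as pd
import pytest

import rpvaudit as ra
from rpvaudit.catalog import RunPartition
from rpvaudit.errors import IntegrityError
from rpvaudit.rpv import RpvRecord, brute_force_rpv


def make_log(n_runs, spec):
    """Build prediction records + single-class partitions from a scenario.

    ``spec``: {specimen_id: (current_label, [(predicted_label, n_runs_so), ...])}.
    Specimens are eligible (in the test set) for exactly the runs their
    predictions cover, consumed in run order.
    """
    rows, test_by_run = [], {rid: [] for rid in range(1, n_runs + 1)}
    for sid, (current, preds) in spec.items():
        rid = 1
        for label, count in preds:
            for _ in range(count):
                rows.append(
                    {"run_id": rid, "specimen_id": sid,
                     "current_label": current, "predicted_label": label}
                )
                test_by_run[rid].append(sid)
                rid += 1
    partitions = [
        RunPartition(run_id=rid, sampling_seed=rid,
                     train_ids={"c": []}, val_ids={"c": []},
                     test_ids={"c": sorted(ids)})
        for rid, ids in test_by_run.items()
    ]
    return pd.DataFrame(rows), partitions


class TestComputeRpv:
    def test_all_runs_same_misprediction_gives_rpv_100(self):
        # labelled B, predicted A in all 100 eligible runs -> RPV 100
        df, parts = make_log(100, {"s1": ("B", [("A", 100)])})
        (rec,) = ra.compute_rpv(df, parts).to_dict("records")
        assert rec["rpv"] == 100
        assert rec["modal_predicted_label"] == "A"
        assert rec["consistent"] is True
        assert rec["eligible_runs"] == 100

    def test_all_matching_predictions_give_rpv_zero(self):
        df, parts = make_log(10, {"s1": ("B", [("B", 10)])})
        (rec,) = ra.compute_rpv(df, parts).to_dict("records")
        assert rec["rpv"] == 0
        assert rec["modal_predicted_label"] is None
        assert rec["mismatch_runs"] == 0

    def test_mixed_mispredictions_take_modal_count(self):
        # 60 runs predict A, 5 predict C, 35 correct out of 100 eligible
        df, parts = make_log(
            100, {"s1": ("B", [("A", 60), ("C", 5), ("B", 35)])}
        )
        (rec,) = ra.compute_rpv(df, parts).to_dict("records")
        assert rec["rpv"] == 60
        assert rec["mismatch_runs"] == 65
        assert rec["modal_predicted_label"] == "A"
        assert rec["consistent"] is False
        assert rec["rpv_per_eligible"] == pytest.approx(0.6)

    def test_modal_tie_breaks_lexicographically(self):
        df, parts = make_log(10, {"s1": ("B", [("C", 4), ("A", 4), ("B", 2)])})
        (rec,) = ra.compute_rpv(df, parts).to_dict("records")
        assert rec["modal_predicted_label"] == "A"
        assert rec["rpv"] == 4
        assert rec["consistent"] is False

    def test_train_val_leakage_is_integrity_error(self):
        df, parts = make_log(5, {"s1": ("B", [("A", 5)])})
        parts[2].train_ids["c"].append("s1")  # s1 cannot be scored in run 3
        with pytest.raises(IntegrityError):
            ra.compute_rpv(df, parts)

    def test_eligibility_counted_from_partitions(self):
        df, parts = make_log(8, {"s1": ("B", [("A", 5)]), "s2": ("A", [("A", 8)])})
        out = ra.compute_rpv(df, parts).set_index("specimen_id")
        assert out.loc["s1", "eligible_runs"] == 5
        assert out.loc["s2", "eligible_runs"] == 8
        # eligibility law: eligible = n_runs - (runs sampled into train/val)
        for sid in ("s1", "s2"):
            in_train_val = sum(sid in p.all_train_val() for p in parts)
            in_test = sum(sid in p.all_test() for p in parts)
            assert out.loc[sid, "eligible_runs"] == in_test
            assert in_test <= len(parts) - in_train_val

    def test_invariants_encoded_in_record_type(self):
        with pytest.raises(ValueError):
            RpvRecord("s", "A", "B", rpv=5, mismatch_runs=3, eligible_runs=10,
                      consistent=False)
        with pytest.raises(ValueError):
            RpvRecord("s", "A", None, rpv=2, mismatch_runs=2, eligible_runs=10,
                      consistent=True)
        with pytest.raises(ValueError):
            RpvRecord("s", "A", "B", rpv=2, mismatch_runs=3, eligible_runs=10,
                      consistent=True)


class TestOracleEquivalence:
    @staticmethod
    def random_instance(rng, n_specimens, n_runs, labels=("A", "B", "C", "D")):
        sids = [f"s{i:03d}" for i in range(n_specimens)]
        current = {s: labels[rng.integers(len(labels))] for s in sids}
        rows, parts = [], []
        for rid in range(1, n_runs + 1):
            in_test = [s for s in sids if rng.random() < 0.5]
            parts.append(RunPartition(
                run_id=rid, sampling_seed=rid,
                train_ids={"c": [s for s in sids if s not in in_test]},
                val_ids={"c": []}, test_ids={"c": in_test},
            ))
            for s in in_test:
                rows.append({
                    "run_id": rid, "specimen_id": s,
                    "current_label": current[s],
                    "predicted_label": labels[rng.integers(len(labels))],
                })
        return pd.DataFrame(rows), parts

    def test_matches_brute_force_recount_on_random_logs(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            df, parts = self.random_instance(
                rng, n_specimens=int(rng.integers(5, 51)),
                n_runs=int(rng.integers(3, 21)),
            )
            fast = ra.compute_rpv(df, parts)
            slow = brute_force_rpv(df, parts)
            pd.testing.assert_frame_equal(fast, slow)


class TestFlag:
    records = pd.DataFrame(
        {
            "specimen_id": ["a", "b", "c", "d", "e"],
            "rpv": [81, 80, 100, 0, 81],
        }
    )

    def test_strict_threshold_boundary(self):
        out = ra.flag(self.records, 80)
        assert list(out["specimen_id"]) == ["c", "a", "e"]  # 80 excluded, sorted

    def test_threshold_zero_flags_every_nonzero(self):
        out = ra.flag(self.records, 0)
        assert set(out["specimen_id"]) == {"a", "b", "c", "e"}

    def test_monotone_in_threshold(self):
        sizes = [len(ra.flag(self.records, t)) for t in range(0, 101, 10)]
        assert sizes == sorted(sizes, reverse=True)


class TestIntervalTable:
    def test_single_specimen_with_max_rpv(self):
        df = pd.DataFrame({"specimen_id": ["a"], "rpv": [100]})
        table = ra.interval_table(df, 10, 100)
        assert len(table) == 10
        assert table.iloc[0]["interval"] == "91–100"
        assert table.iloc[0]["count"] == 1
        assert table.iloc[0]["percentage"] == 100.0
        assert table["count"].sum() == 1

    def test_intervals_tile_without_overlap_and_conserve_counts(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"rpv": rng.integers(0, 101, size=500)})
        df["specimen_id"] = [f"s{i}" for i in range(500)]
        table = ra.interval_table(df, 10, 100)
        assert list(table["lo"]) == [91, 81, 71, 61, 51, 41, 31, 21, 11, 1]
        assert list(table["hi"]) == [100, 90, 80, 70, 60, 50, 40, 30, 20, 10]
        assert table["count"].sum() == (df["rpv"] >= 1).sum()

    def test_printed_count_arithmetic_with_override_denominator(self):
        # 171 of 17,562 -> 0.97%; 14,639 of 17,562 -> 83.36%
        df = pd.DataFrame(
            {"specimen_id": ["x"], "rpv": [1]}
        )
        table = ra.interval_table(df, 10, 100, total_flagged_override=17562)
        assert set(table["percentage"]) <= {0.0, round(100 * 1 / 17562, 2)}
        assert ra.interval_percentages([171], 17562) == [0.97]
        assert ra.interval_percentages([14639], 17562) == [83.36]

    def test_empty_input_warns_and_returns_empty(self):
        df = pd.DataFrame({"specimen_id": [], "rpv": []})
        with pytest.warns(UserWarning):
            table = ra.interval_table(df, 10, 100)
        assert table.empty

    def test_width_must_divide_n_runs(self):
        df = pd.DataFrame({"specimen_id": ["a"], "rpv": [3]})
        with pytest.raises(ValueError):
            ra.interval_table(df, 30, 100)
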