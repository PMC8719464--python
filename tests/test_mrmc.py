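"""Observer-study analytics: ROC/AUC, rates, BI-RADS changes, times."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perceptcad.mrmc import (
    ConfusionCounts,
    DesignError,
    auc_difference_test,
    binary_metrics,
    birads_changes,
    confusion_from_rates,
    load_reader_study,
    reader_average_auc,
    roc_from_poms,
    time_comparison,
)


def _mw_auc(scores, y):
    pos, neg = scores[y == 1], scores[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (greater + 0.5 * ties) / (len(pos) * len(neg))


def _records(reader_ids, session, case_ids, poms, times=None, birads=None, calls=None):
    n = len(case_ids)
    return pd.DataFrame(
        {
            "reader_id": np.repeat(reader_ids, n),
            "session": session,
            "case_id": list(case_ids) * len(reader_ids),
            "birads": (birads if birads is not None else ["3"] * n) * len(reader_ids),
            "call": (calls if calls is not None else ["benign"] * n) * len(reader_ids),
            "pom_percent": np.concatenate([np.asarray(p, dtype=float) for p in np.atleast_2d(poms)]),
            "time_s": np.tile(times if times is not None else np.full(n, 30.0), len(reader_ids)),
        }
    )


class TestRocFromPoms:
    def test_perfect_ranking(self):
        roc = roc_from_poms([10, 20, 80, 90], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = roc_from_poms([50, 50, 50, 50], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_curve_runs_corner_to_corner(self):
        roc = roc_from_poms([10, 40, 40, 90, 70], [0, 1, 0, 1, 0])
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(8, 80))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            assert roc_from_poms(scores, y).auc == pytest.approx(
                _mw_auc(scores, y), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_from_poms([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.random(n)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            return
        base = roc_from_poms(scores, y).auc
        assert roc_from_poms(np.exp(3 * scores), y).auc == pytest.approx(base, abs=1e-12)


class TestReaderAverageAuc:
    def test_fixture_reader_averages(self):
        """The six-reader study's per-reader AUCs average to 0.850 / 0.896."""
        fx = load_reader_study()
        assert round(np.mean(fx["auc"]["unaided"]), 3) == 0.850
        assert round(np.mean(fx["auc"]["aided"]), 3) == 0.896

    def test_average_equals_mean_of_per_reader(self):
        rng = np.random.default_rng(0)
        cases = [f"c{i}" for i in range(20)]
        truth = {c: ("malignant" if i % 2 else "benign") for i, c in enumerate(cases)}
        poms = rng.integers(0, 101, (3, 20))
        records = _records([1, 2, 3], "unaided", cases, poms)
        avg, per_reader = reader_average_auc(records, truth, "unaided")
        assert avg == pytest.approx(np.mean(list(per_reader.values())), abs=1e-15)

    def test_single_reader_average_is_own_auc(self):
        cases = ["a", "b", "c", "d"]
        truth = {"a": "benign", "b": "malignant", "c": "benign", "d": "malignant"}
        records = _records([1], "aided", cases, [[10, 90, 20, 80]])
        avg, per_reader = reader_average_auc(records, truth, "aided")
        assert avg == per_reader[1] == 1.0

    def test_missing_cell_is_design_error(self):
        cases = ["a", "b", "c"]
        truth = {"a": "benign", "b": "malignant", "c": "benign"}
        records = _records([1, 2], "unaided", cases, [[10, 90, 20], [30, 70, 10]])
        records = records.drop(index=4)
        with pytest.raises(DesignError):
            reader_average_auc(records, truth, "unaided")


class TestAucDifferenceTest:
    @staticmethod
    def _two_sessions(seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        cases = [f"c{i}" for i in range(40)]
        truth = {c: ("malignant" if i < 20 else "benign") for i, c in enumerate(cases)}
        y = np.array([1] * 20 + [0] * 20)
        frames = []
        for session, boost in (("unaided", 0.0), ("aided", effect)):
            poms = np.clip(
                rng.normal(50, 20, (4, 40)) + np.outer(np.full(4, 10 + 100 * boost), y - 0.5),
                0,
                100,
            )
            frames.append(_records([1, 2, 3, 4], session, cases, poms))
        return pd.concat(frames, ignore_index=True), truth

    def test_identical_sessions_null(self):
        records, truth = self._two_sessions()
        aided = records[records["session"] == "unaided"].assign(session="aided")
        both = pd.concat([records[records["session"] == "unaided"], aided], ignore_index=True)
        out = auc_difference_test(both, truth, n_boot=200, seed=1)
        assert out["difference"] == 0.0
        assert out["p_value"] > 0.9

    def test_planted_effect_detected(self):
        records, truth = self._two_sessions(seed=3, effect=0.35)
        out = auc_difference_test(records, truth, n_boot=2000, seed=1)
        assert out["difference"] > 0
        assert out["p_value"] < 0.05

    def test_seed_reproducible(self):
        records, truth = self._two_sessions(seed=5, effect=0.1)
        a = auc_difference_test(records, truth, n_boot=300, seed=9)
        b = auc_difference_test(records, truth, n_boot=300, seed=9)
        assert a == b

    def test_fixture_difference(self):
        fx = load_reader_study()
        diff = round(np.mean(fx["auc"]["aided"]), 3) - round(np.mean(fx["auc"]["unaided"]), 3)
        assert round(diff, 3) == 0.046


class TestBinaryMetrics:
    def test_junior_reader_unaided_row(self):
        m = binary_metrics(ConfusionCounts(tp=12, fp=2, tn=27, fn=10)).rounded()
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (0.545, 0.931, 0.857, 0.730)

    def test_perfect_classifier(self):
        m = binary_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_undefined_ppv_marker(self):
        m = binary_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(m.ppv)
        assert m.specificity == 1.0


class TestConfusionFromRates:
    def test_reconstructs_junior_reader(self):
        c = confusion_from_rates(0.545, 0.931, 22, 29)
        assert (c.tp, c.fn, c.tn, c.fp) == (12, 10, 27, 2)

    def test_perfect_rates(self):
        c = confusion_from_rates(1.0, 1.0, 10, 10)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_middle_reader_ppv(self):
        c = confusion_from_rates(0.773, 0.793, 22, 29)
        assert (c.tp, c.tn) == (17, 23)
        assert binary_metrics(c).rounded().ppv == 0.739

    def test_inconsistent_rate_rejected_at_printed_precision(self):
        # 0.61 is not k/10 for any integer k at 3-decimal precision
        with pytest.raises(ValueError, match="inconsistent"):
            confusion_from_rates(0.61, 0.9, 10, 10, atol=0.0005)

    def test_flagged_sensitivity_detected_at_printed_precision(self):
        fx = load_reader_study()
        with pytest.raises(ValueError, match="sensitivity"):
            confusion_from_rates(
                fx["rates"]["sensitivity"]["aided"][4],
                fx["rates"]["specificity"]["aided"][4],
                22,
                29,
                atol=0.0005,
            )

    def test_full_study_table_reconstruction(self):
        """All printed sens/spec cells imply integer counts whose PPV/NPV
        match the printed values within 0.001 (one flagged sensitivity)."""
        fx = load_reader_study()
        n_pos, n_neg = fx["case_counts"]["malignant"], fx["case_counts"]["benign"]
        for session in ("unaided", "aided"):
            for r in range(6):
                counts = confusion_from_rates(
                    fx["rates"]["sensitivity"][session][r],
                    fx["rates"]["specificity"][session][r],
                    n_pos,
                    n_neg,
                )
                m = binary_metrics(counts)
                assert abs(m.ppv - fx["rates"]["ppv"][session][r]) <= 0.001
                assert abs(m.npv - fx["rates"]["npv"][session][r]) <= 0.001


class TestBiradsChanges:
    @staticmethod
    def _sessions(birads_u, birads_a, truths):
        cases = [f"c{i}" for i in range(len(birads_u))]
        truth = dict(zip(cases, truths))
        u = _records([1], "unaided", cases, [np.full(len(cases), 50.0)], birads=birads_u)
        a = _records([1], "aided", cases, [np.full(len(cases), 50.0)], birads=birads_a)
        return u, a, truth

    def test_identical_sessions_no_changes(self):
        u, a, truth = self._sessions(["3", "4a", "5"], ["3", "4a", "5"], ["benign"] * 3)
        table = birads_changes(u, a, truth)
        assert table.totals["n_total"] == 0

    def test_hand_enumerated_change(self):
        # one increase toward malignant truth (3 -> 4b), one decrease away
        # from benign truth is concordant, an unchanged case counts nowhere
        u, a, truth = self._sessions(
            ["3", "4a", "2"], ["4b", "3", "2"], ["malignant", "benign", "benign"]
        )
        table = birads_changes(u, a, truth)
        row = table.per_reader.loc[1]
        assert row["n_increase"] == 1
        assert row["n_decrease"] == 1
        assert row["n_closer_to_biopsy"] == 2
        assert row["n_not_matching"] == 0

    def test_plain_four_sits_between_3_and_4a(self):
        u, a, truth = self._sessions(["4", "4"], ["4a", "3"], ["malignant", "benign"])
        table = birads_changes(u, a, truth)
        assert table.per_reader.loc[1, "n_increase"] == 1
        assert table.per_reader.loc[1, "n_decrease"] == 1
        assert table.per_reader.loc[1, "n_closer_to_biopsy"] == 2

    def test_fixture_grand_totals(self):
        fx = load_reader_study()
        changes = fx["birads_changes"]
        assert sum(changes["increase"]) == 80
        assert sum(changes["decrease"]) == 48
        assert sum(changes["increase"]) + sum(changes["decrease"]) == 128
        per_reader_totals = [i + d for i, d in zip(changes["increase"], changes["decrease"])]
        assert per_reader_totals == [18, 26, 24, 22, 26, 12]

    def test_unmatched_pairs_rejected(self):
        u, a, truth = self._sessions(["3", "4"], ["3", "4"], ["benign", "benign"])
        with pytest.raises(DesignError):
            birads_changes(u, a.iloc[:1], truth)


class TestTimeComparison:
    def test_senior_reader_speedup(self):
        """Means 56.96 -> 43.96 give a -13.0 s difference, a 22.8% cut."""
        rng = np.random.default_rng(0)
        n = 51
        base = rng.gamma(8, 7, n)
        t_u = base * (56.96 / base.mean())
        t_a = base * (43.96 / base.mean())
        cases = [f"c{i}" for i in range(n)]
        u = _records([6], "unaided", cases, [np.full(n, 50.0)], times=t_u)
        a = _records([6], "aided", cases, [np.full(n, 50.0)], times=t_a)
        row = time_comparison(u, a).loc[6]
        assert row["mean_unaided_s"] == pytest.approx(56.96, abs=0.005)
        assert row["difference_s"] == pytest.approx(-13.0, abs=0.005)
        assert row["percent_change"] == pytest.approx(-22.8, abs=0.05)

    def test_identical_times_p_one(self):
        cases = ["a", "b", "c"]
        t = np.array([10.0, 20.0, 30.0])
        u = _records([1], "unaided", cases, [np.full(3, 50.0)], times=t)
        a = _records([1], "aided", cases, [np.full(3, 50.0)], times=t)
        row = time_comparison(u, a).loc[1]
        assert row["difference_s"] == 0.0
        assert row["p_value"] == 1.0

    def test_constant_shift_recovered(self):
        cases = ["a", "b", "c", "d"]
        t = np.array([10.0, 20.0, 30.0, 40.0])
        u = _records([1], "unaided", cases, [np.full(4, 50.0)], times=t)
        a = _records([1], "aided", cases, [np.full(4, 50.0)], times=t + 5)
        assert time_comparison(u, a).loc[1, "difference_s"] == pytest.approx(5.0)
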