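import numpy as np
import pandas as pd
import pytest

from meningrisk.analytics import (
    CohortTable,
    SampleRecord,
    cochromosome_groups,
    correlate_mitoses_cdkn2ab,
    crosstab,
    gate_by_calibrated_score,
    mitotic_stratum,
    sex_ratio_by,
)
from meningrisk.grading import HistologyFeatures
from meningrisk.rounding import pct, round_half_up
from meningrisk.scoring import MethylationCall


def record(sample_id="S", cs=0.95, mc="benign", sex="F"):
    return SampleRecord(
        sample_id=sample_id,
        sex=sex,
        age=60.0,
        features=HistologyFeatures(mitotic_count_local=1),
        methylation=MethylationCall(mc, cs),
    )


class TestGate:
    def test_bands(self):
        records = [record("a", 0.95), record("b", 0.9), record("c", 0.5), record("d", 0.29)]
        gated = gate_by_calibrated_score(records)
        assert [r.sample_id for r in gated.included] == ["a", "b"]
        assert [r.sample_id for r in gated.low_band] == ["c"]
        assert [r.sample_id for r in gated.unclassified] == ["d"]

    def test_partition_complete_and_disjoint(self):
        rng = np.random.default_rng(0)
        records = [record(f"s{i}", float(cs)) for i, cs in enumerate(rng.uniform(0, 1, 200))]
        gated = gate_by_calibrated_score(records)
        ids = [r.sample_id for part in gated for r in part]
        assert sorted(ids) == sorted(r.sample_id for r in records)
        assert len(set(ids)) == len(records)


class TestCohortTable:
    def test_brain_invasion_row_proportions(self):
        # printed Grade-2 brain-invasion row: counts (69, 24, 0, 2), n = 95
        counts = pd.DataFrame(
            [[69, 24, 0, 2]],
            index=["brain_invasion"],
            columns=["benign", "intermediate", "SMARCE1_altered", "malignant"],
        )
        table = CohortTable.from_counts(counts)
        assert list(table.row_proportions.loc["brain_invasion"]) == [0.73, 0.25, 0.00, 0.02]

    def test_risk_row_proportions(self):
        counts = pd.DataFrame(
            [[55, 30, 10]], index=["brain_invasion"], columns=["low", "intermediate", "high"]
        )
        table = CohortTable.from_counts(counts)
        assert list(table.row_proportions.loc["brain_invasion"]) == [0.58, 0.32, 0.11]

    def test_single_cell(self):
        counts = pd.DataFrame([[7]], index=["only"], columns=["col"])
        table = CohortTable.from_counts(counts)
        assert table.row_proportions.loc["only", "col"] == 1.00

    def test_explicit_row_totals(self):
        counts = pd.DataFrame(
            [[7, 20, 0, 2]],
            index=["bi_mit"],
            columns=["benign", "intermediate", "SMARCE1_altered", "malignant"],
        )
        table = CohortTable.from_counts(counts, row_totals=pd.Series({"bi_mit": 28}))
        assert table.row_proportions.loc["bi_mit", "intermediate"] == 0.71

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortTable.from_counts(pd.DataFrame([[-1]]))


class TestCrosstab:
    def _frame(self):
        rows = []
        for grade, mc, n in [
            ("1", "benign", 5),
            ("1", "intermediate", 3),
            ("2", "benign", 2),
            ("2", "malignant", 2),
        ]:
            rows += [{"grade": grade, "mc_class": mc}] * n
        return pd.DataFrame(rows)

    def test_counts_conserved(self):
        frame = self._frame()
        table = crosstab(frame, "grade", "mc_class")
        assert table.grand_total == len(frame)
        assert table.counts.loc["1", "benign"] == 5
        assert (table.counts.sum(axis=1) == table.row_totals).all()

    def test_reaggregation_idempotent(self):
        frame = self._frame()
        table = crosstab(frame, "grade", "mc_class")
        expanded = []
        for row_label in table.counts.index:
            for col_label in table.counts.columns:
                expanded += [{"grade": row_label, "mc_class": col_label}] * int(
                    table.counts.loc[row_label, col_label]
                )
        again = crosstab(pd.DataFrame(expanded), "grade", "mc_class")
        pd.testing.assert_frame_equal(
            again.counts.sort_index(), table.counts.sort_index(), check_names=False
        )

    def test_empty_cohort(self):
        table = crosstab(pd.DataFrame(), "grade", "mc_class")
        assert table.grand_total == 0
        assert table.counts.empty

    def test_row_proportions_sum_to_one(self):
        table = crosstab(self._frame(), "grade", "mc_class")
        sums = table.row_proportions.sum(axis=1)
        assert ((sums - 1.0).abs() <= 0.02).all()  # rounding tolerance


class TestMitoticStratum:
    @pytest.mark.parametrize(
        "count,stratum",
        [(0, "0-3"), (3, "0-3"), (4, "4-7"), (7, "4-7"), (8, "8-11"), (12, "12-15"),
         (19, "16-19"), (20, "20-30"), (30, "20-30")],
    )
    def test_bins(self, count, stratum):
        assert mitotic_stratum(count) == stratum

    def test_above_top_bin_warns(self):
        with pytest.warns(UserWarning):
            assert mitotic_stratum(35) == "20-30"

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            mitotic_stratum(-1)


class TestSexRatio:
    def _frame(self, f, m, score=6):
        return pd.DataFrame(
            [{"sex": "F", "score": score}] * f + [{"sex": "M", "score": score}] * m
        )

    def test_balanced(self):
        out = sex_ratio_by(self._frame(27, 27), "score")
        assert out.loc[6, "ratio"] == 1.0
        assert out.loc[6, "ratio_str"] == "1:1"

    def test_undefined_when_no_males(self):
        out = sex_ratio_by(self._frame(0, 3, score=9).assign(sex="M"), "score")
        assert out.loc[9, "F"] == 0 and out.loc[9, "M"] == 3
        out2 = sex_ratio_by(self._frame(4, 0, score=0), "score")
        assert np.isnan(out2.loc[0, "ratio"])
        assert out2.loc[0, "ratio_str"] == "undefined"

    def test_two_to_one(self):
        out = sex_ratio_by(self._frame(10, 5), "score")
        assert out.loc[6, "ratio"] == 2.0
        assert out.loc[6, "ratio_str"] == "2:1"


class TestCochromosomeGroups:
    def _frame(self):
        return pd.DataFrame(
            [
                {"sample_id": "a", "lost_1p": True, "lost_22q": False, "grade": "1"},
                {"sample_id": "b", "lost_1p": False, "lost_22q": False, "grade": "1"},
                {"sample_id": "c", "lost_1p": True, "lost_22q": True, "grade": "2"},
                {"sample_id": "d", "lost_1p": None, "lost_22q": None, "grade": "2"},
            ]
        )

    def test_group_mapping(self):
        grouped, n_missing = cochromosome_groups(self._frame())
        by_id = grouped.set_index("sample_id")["cochrom_group"]
        assert by_id["a"] == "1p deleted / 22q intact"
        assert by_id["b"] == "1p intact / 22q intact"
        assert by_id["c"] == "1p deleted / 22q deleted"
        assert n_missing == 1

    def test_partition_disjoint_exhaustive(self):
        grouped, n_missing = cochromosome_groups(self._frame())
        assert len(grouped) + n_missing == 4
        assert grouped["cochrom_group"].notna().all()

    def test_planted_rate_recovered(self):
        # among 1p-deleted samples, plant 25% with intact 22q
        rng = np.random.default_rng(5)
        n = 800
        lost_22q = rng.random(n) >= 0.25
        frame = pd.DataFrame(
            {"sample_id": range(n), "lost_1p": True, "lost_22q": lost_22q, "grade": "1"}
        )
        grouped, _ = cochromosome_groups(frame)
        intact = (grouped["cochrom_group"] == "1p deleted / 22q intact").mean()
        # 99.9% binomial CI half-width at n=800, p=0.25 is ~0.05
        assert abs(intact - 0.25) < 0.05


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        frame = pd.DataFrame(
            {"mitoses": [1, 2, 3, 4], "cdkn2ab_log2": [-0.1, -0.2, -0.3, -0.4]}
        )
        result = correlate_mitoses_cdkn2ab(frame)
        assert result.coefficient == pytest.approx(-1.0)

    def test_constant_values_flagged(self):
        frame = pd.DataFrame({"mitoses": [1, 2, 3], "cdkn2ab_log2": [0.0, 0.0, 0.0]})
        result = correlate_mitoses_cdkn2ab(frame)
        assert np.isnan(result.coefficient)
        assert "zero variance" in result.flag

    def test_insufficient_pairs(self):
        frame = pd.DataFrame({"mitoses": [1, 2], "cdkn2ab_log2": [0.0, -0.5]})
        assert correlate_mitoses_cdkn2ab(frame) is None

    def test_simulated_target_correlation(self):
        # generated pairs with population correlation -0.4, n=500
        rng = np.random.default_rng(42)
        rho = -0.4
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([8.0, -0.2], cov, size=500)
        frame = pd.DataFrame({"mitoses": xy[:, 0], "cdkn2ab_log2": xy[:, 1]})
        result = correlate_mitoses_cdkn2ab(frame)
        assert abs(result.coefficient - rho) < 0.1


class TestRounding:
    def test_half_up_not_bankers(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round(0.125, 2) == 0.12  # what we are avoiding

    def test_pct(self):
        assert pct(235, 455) == 52.0
        assert pct(408, 455, 1) == 89.7
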