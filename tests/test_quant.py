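"""Spectral-count pooling, replicate filtering, NSAF, and the
tryptophan-fluorescence calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucsort.quant import (
    TrpCalibration,
    category_share,
    compute_nsaf,
    filter_replicated,
    fit_trp_calibration,
    nsaf_table,
    pool_technical_replicates,
    run_id,
    to_sample_matrix,
    trp_quantify,
)


def matrix_from(cols: dict[str, list[int]], proteins: list[str]) -> pd.DataFrame:
    return to_sample_matrix(pd.DataFrame(cols, index=proteins))


class TestPooling:
    def test_tech_reps_sum(self):
        m = matrix_from(
            {
                run_id("homogenate", 1, 1): [3, 0],
                run_id("homogenate", 1, 2): [5, 0],
            },
            ["A", "B"],
        )
        pooled = pool_technical_replicates(m)
        assert pooled[("homogenate", 1)].tolist() == [8, 0]

    def test_single_tech_rep_identity(self):
        m = matrix_from({run_id("homogenate", 2, 1): [4]}, ["A"])
        pooled = pool_technical_replicates(m)
        assert pooled[("homogenate", 2)].tolist() == [4]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            matrix_from({run_id("homogenate", 1, 1): [-1]}, ["A"])


class TestReplicateFilter:
    def _pooled(self, presence):
        cols = {
            run_id("homogenate", b, 1): [5 * int(p) for p in presence[b - 1]]
            for b in (1, 2, 3)
        }
        m = matrix_from(cols, [f"P{i}" for i in range(len(presence[0]))])
        return pool_technical_replicates(m)

    def test_two_of_three_kept(self):
        # P0 in reps {1,2}; P1 only rep 2; P2 in all three
        pooled = self._pooled([[1, 0, 1], [1, 1, 1], [0, 0, 1]])
        kept = filter_replicated(pooled, min_reps=2)
        assert kept["homogenate"] == ["P0", "P2"]

    def test_single_bio_rep_dropped_despite_both_tech_reps(self):
        m = matrix_from(
            {
                run_id("homogenate", 2, 1): [7],
                run_id("homogenate", 2, 2): [9],
                run_id("homogenate", 1, 1): [0],
                run_id("homogenate", 3, 1): [0],
            },
            ["P0"],
        )
        kept = filter_replicated(pool_technical_replicates(m), min_reps=2)
        assert kept["homogenate"] == []

    def test_min_reps_exceeding_reps_errors(self):
        pooled = self._pooled([[1], [1], [1]])
        with pytest.raises(ValueError):
            filter_replicated(pooled, min_reps=4)

    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()),
                    min_size=1, max_size=12))
    def test_monotone_in_min_reps(self, presence):
        pooled = self._pooled([[p[b] for p in presence] for b in range(3)])
        kept = [set(filter_replicated(pooled, min_reps=k)["homogenate"])
                for k in (1, 2, 3)]
        assert kept[2] <= kept[1] <= kept[0]


class TestNSAF:
    def test_single_protein_is_one(self):
        got = compute_nsaf(pd.Series({"A": 9}), pd.Series({"A": 123}))
        assert got["A"] == 1.0

    def test_hand_normalized_example(self):
        # SAFs 10/100 = 0.1 and 10/200 = 0.05 -> shares 2/3, 1/3
        got = compute_nsaf(
            pd.Series({"A": 10, "B": 10}), pd.Series({"A": 100, "B": 200})
        )
        assert got["A"] == pytest.approx(2 / 3)
        assert got["B"] == pytest.approx(1 / 3)

    def test_zero_count_protein_gets_zero(self):
        got = compute_nsaf(pd.Series({"A": 5, "B": 0}), pd.Series({"A": 50, "B": 50}))
        assert got.tolist() == [1.0, 0.0]

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="empty sample"):
            compute_nsaf(pd.Series({"A": 0}), pd.Series({"A": 50}))

    @given(
        st.lists(st.tuples(st.integers(0, 500), st.integers(1, 4000)),
                 min_size=1, max_size=40).filter(lambda v: any(c for c, _ in v)),
        st.integers(1, 50),
    )
    def test_sums_to_one_and_scale_invariant(self, rows, factor):
        counts = pd.Series({f"P{i}": c for i, (c, _) in enumerate(rows)})
        lengths = pd.Series({f"P{i}": l for i, (_, l) in enumerate(rows)})
        nsaf = compute_nsaf(counts, lengths)
        assert nsaf.sum() == pytest.approx(1.0, abs=1e-9)
        scaled = compute_nsaf(counts * factor, lengths)
        assert np.allclose(nsaf, scaled)

    def test_nsaf_table_columns_sum_to_one(self):
        m = matrix_from(
            {
                run_id("homogenate", 1, 1): [3, 1],
                run_id("homogenate", 2, 1): [0, 4],
            },
            ["A", "B"],
        )
        pooled = pool_technical_replicates(m)
        table = nsaf_table(pooled, pd.Series({"A": 100, "B": 300}))
        assert np.allclose(table.sum(axis=0), 1.0)


class TestCategoryShare:
    def test_all_nuclear_is_one_by_both_measures(self):
        m = matrix_from(
            {run_id("homogenate", b, 1): [2, 3] for b in (1, 2, 3)}, ["A", "B"]
        )
        pooled = pool_technical_replicates(m)
        shares = category_share(
            pooled, pd.Series({"A": 100, "B": 100}),
            {"A": "nuclear", "B": "nuclear"},
        )
        row = shares.iloc[0]
        assert row.id_share == 1.0
        assert row.nsaf_share == pytest.approx(1.0)

    def test_equal_nsaf_half_split(self):
        m = matrix_from(
            {run_id("homogenate", b, 1): [5, 5] for b in (1, 2, 3)}, ["A", "B"]
        )
        pooled = pool_technical_replicates(m)
        shares = category_share(
            pooled, pd.Series({"A": 200, "B": 200}),
            {"A": "nuclear", "B": "other"},
        ).set_index("category")
        assert shares.loc["nuclear", "nsaf_share"] == pytest.approx(0.5)

    def test_missing_call_errors(self):
        m = matrix_from(
            {run_id("homogenate", b, 1): [5] for b in (1, 2, 3)}, ["A"]
        )
        pooled = pool_technical_replicates(m)
        with pytest.raises(ValueError, match="lack a category call"):
            category_share(pooled, pd.Series({"A": 100}), {})


class TestTrpAssay:
    def test_noiseless_line_recovered(self):
        standards = [(x, 2.0 * x) for x in (0.01, 0.1, 0.5, 1.0, 5.0)]
        cal = fit_trp_calibration(standards)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.residual_se == pytest.approx(0.0, abs=1e-9)
        assert cal.valid_range == (0.01, 5.0)

    def test_noisy_slope_recovered_against_closed_form(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0.01, 5.0, 12)
        y = 3.0 * x + 1.0 + rng.normal(0, 0.05, size=x.size)
        cal = fit_trp_calibration(list(zip(x, y)))
        # closed-form OLS oracle
        bx = np.polyfit(x, y, 1)
        assert cal.slope == pytest.approx(bx[0], rel=1e-9)
        assert cal.intercept == pytest.approx(bx[1], rel=1e-6)

    def test_too_few_standards_error(self):
        with pytest.raises(ValueError):
            fit_trp_calibration([(0.1, 1.0), (0.2, 2.0)])

    def test_degenerate_range_error(self):
        with pytest.raises(ValueError):
            fit_trp_calibration([(0.5, 1.0), (0.5, 1.1), (0.5, 0.9)])

    def test_mass_conversion_arithmetic(self):
        cal = TrpCalibration(2.0, 0.0, 0.0, (0.01, 5.0))
        # 1.95 ug trp / 0.0195 = 100 ug peptide
        assert trp_quantify(2.0 * 1.95, cal) == pytest.approx(100.0)
        assert trp_quantify(2.0 * 0.0195, cal) == pytest.approx(1.0)
        assert trp_quantify(0.0, cal) == 0.0

    def test_negative_mass_clipped_with_warning(self):
        cal = TrpCalibration(2.0, 1.0, 0.0, (0.01, 5.0))
        with pytest.warns(UserWarning):
            assert trp_quantify(0.0, cal) == 0.0

    @given(st.floats(0.01, 5.0))
    def test_quantify_inverts_calibration_line(self, trp_mass):
        cal = TrpCalibration(3.7, 0.4, 0.0, (0.01, 5.0))
        fluor = cal.slope * trp_mass + cal.intercept
        peptide = trp_quantify(fluor, cal)
        assert peptide * cal.trp_mass_fraction == pytest.approx(trp_mass, rel=1e-9)
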