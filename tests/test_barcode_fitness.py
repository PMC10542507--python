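"""Normalization, scaling, imputation, and fitness-scoring contracts.

The brute-force oracles here recompute each operation with explicit loops,
independent of the vectorized implementations they check.
"""

import numpy as np
import pandas as pd
import pytest

from oefit import barcode_fitness as bf
from oefit import synthetic
from oefit.data_model import CountMatrix, NormCountMatrix, ValidationError
from tests.conftest import make_counts


def normalize_oracle(values, threshold):
    """Two-pass per-sample oracle: explicit loops, no vectorization."""
    values = np.asarray(values, dtype=float)
    out = np.zeros_like(values)
    for j in range(values.shape[1]):
        factor = 0.0
        for i in range(values.shape[0]):
            if values[i, j] <= threshold:
                factor += values[i, j]
        for i in range(values.shape[0]):
            out[i, j] = values[i, j] / factor
    return out


class TestLibrarySizeNormalize:
    def test_forced_by_definition(self):
        cm = make_counts([[60_000], [30_000], [10_000]])
        norm = bf.library_size_normalize(cm, 50_000)
        assert norm.size_factors.iloc[0] == 40_000
        np.testing.assert_allclose(
            norm.data.iloc[:, 0], [1.5, 0.75, 0.25]
        )

    def test_reduces_to_plain_library_size(self):
        cm = make_counts([[100], [300], [600]])
        norm = bf.library_size_normalize(cm, 50_000)
        assert norm.size_factors.iloc[0] == 1000
        assert norm.data.iloc[:, 0].sum() == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            vals = rng.integers(0, 100_000, size=(50, 4))
            cm = make_counts(vals)
            norm = bf.library_size_normalize(cm, 50_000)
            np.testing.assert_array_equal(
                norm.data.to_numpy(), normalize_oracle(vals, 50_000)
            )

    def test_exclusion_is_per_sample(self):
        # the same gene is above threshold in s0 only
        cm = make_counts([[60_000, 10_000], [10_000, 10_000]])
        norm = bf.library_size_normalize(cm, 50_000)
        assert norm.size_factors.tolist() == [10_000, 20_000]

    def test_all_above_threshold_names_sample(self):
        cm = make_counts([[60_000, 10]])
        with pytest.raises(ValidationError, match="s0"):
            bf.library_size_normalize(cm, 50_000)

    def test_scale_invariance_of_scores(self, tiny_sheet, rng):
        vals = rng.integers(100, 5000, size=(30, 6))
        cm = make_counts(vals, tiny_sheet)
        scaled = bf.scale_and_round(bf.library_size_normalize(cm))
        t1 = bf.fitness_scores(scaled, tiny_sheet)
        vals2 = vals.copy()
        vals2[:, 0] *= 7  # rescale one sample's raw counts
        cm2 = make_counts(vals2, tiny_sheet)
        scaled2 = bf.scale_and_round(bf.library_size_normalize(cm2))
        t2 = bf.fitness_scores(scaled2, tiny_sheet)
        # scores unchanged up to the rounding granularity of the scaled matrix
        min_val = min(scaled.values[scaled.values > 0].min(),
                      scaled2.values[scaled2.values > 0].min())
        tol = 2 * np.log2(1 + 0.5 / min_val) + 1e-12
        diff = np.abs(t1.table["mean_score"] - t2.table["mean_score"])
        assert np.nanmax(diff.to_numpy()) <= tol


class TestScaleAndRound:
    def test_rounding_rule(self):
        norm = NormCountMatrix(
            pd.DataFrame({"s": [0.0000015, 0.0]}, index=["a", "b"]),
            size_factors=pd.Series([1.0], index=["s"]),
        )
        scaled = bf.scale_and_round(norm, 1e6)
        assert scaled.data["s"].tolist() == [2, 0]

    def test_half_away_from_zero(self):
        norm = NormCountMatrix(
            pd.DataFrame({"s": [0.5e-6, 2.5e-6]}, index=["a", "b"]),
            size_factors=pd.Series([1.0], index=["s"]),
        )
        assert bf.scale_and_round(norm, 1e6).data["s"].tolist() == [1, 3]

    def test_round_trip_bound(self, rng):
        vals = rng.random((40, 3)) * 1e-4
        norm = NormCountMatrix(
            pd.DataFrame(vals, columns=[f"s{i}" for i in range(3)]),
            size_factors=pd.Series(np.ones(3), index=[f"s{i}" for i in range(3)]),
        )
        scaled = bf.scale_and_round(norm, 1e6)
        assert np.abs(scaled.values / 1e6 - vals).max() <= 0.5 / 1e6


def run_impute(start_vals, end_vals, mode="replicate"):
    """Imputation on a single-gene, 3-replicate toy strain."""
    rows = []
    for rep in (1, 2, 3):
        for gen in (0.0, 10.0):
            rows.append(dict(sample_id=f"g{gen:g}r{rep}", strain="S",
                             condition="c", generation=gen, replicate=rep))
    from oefit.data_model import SampleSheet

    sheet = SampleSheet(pd.DataFrame(rows))
    data = {}
    for rep, (s, e) in enumerate(zip(start_vals, end_vals), 1):
        data[f"g0r{rep}"] = [s]
        data[f"g10r{rep}"] = [e]
    cm = CountMatrix(pd.DataFrame(data, index=["gene"]))
    cfg = bf.FitnessConfig(impute_mode=mode)
    out, flags = bf.impute_dropouts(cm, sheet, cfg)
    ends = [out.data.loc["gene", f"g10r{r}"] for r in (1, 2, 3)]
    return ends, flags


class TestImputation:
    """Enumerated boundary cases of the >20-in-all-starts / zero-at-end rule."""

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            # well measured, full dropout -> pseudocount everywhere
            ((25, 30, 22), (0, 0, 0), [1, 1, 1]),
            # one start replicate at or below 20 -> untouched
            ((25, 30, 15), (0, 0, 0), [0, 0, 0]),
            ((25, 30, 20), (0, 0, 0), [0, 0, 0]),  # boundary: 20 is not >20
            ((21, 21, 21), (0, 0, 0), [1, 1, 1]),  # boundary: 21 qualifies
            # partial dropout: only zero replicates imputed
            ((25, 30, 22), (0, 5, 0), [1, 5, 1]),
            # no dropout -> untouched
            ((25, 30, 22), (3, 5, 7), [3, 5, 7]),
            # poorly measured everywhere -> untouched
            ((5, 5, 5), (0, 0, 0), [0, 0, 0]),
        ],
    )
    def test_replicate_mode_golden(self, start, end, expected):
        ends, _ = run_impute(start, end)
        assert ends == expected

    def test_all_mode_requires_full_dropout(self):
        ends, _ = run_impute((25, 30, 22), (0, 5, 0), mode="all")
        assert ends == [0, 5, 0]
        ends, _ = run_impute((25, 30, 22), (0, 0, 0), mode="all")
        assert ends == [1, 1, 1]

    def test_flags_mark_imputed_cells(self):
        _, flags = run_impute((25, 30, 22), (0, 5, 0))
        assert flags.loc["gene"].sum() == 2

    def test_monotone_and_leaves_others_untouched(self, tiny_sheet, rng):
        vals = rng.integers(0, 200, size=(25, 6))
        cm = make_counts(vals, tiny_sheet)
        out, flags = bf.impute_dropouts(cm, tiny_sheet)
        before, after = cm.data.to_numpy(), out.data.to_numpy()
        assert (after >= before).all()
        assert (after[~flags.to_numpy()] == before[~flags.to_numpy()]).all()


class TestFitnessScores:
    def test_identity_and_closed_form(self, tiny_sheet):
        data = {}
        for rep in (1, 2, 3):
            data[f"S_g0_r{rep}"] = [100, 100, 100, 100]
            data[f"S_g10_r{rep}"] = [100, 400, 0, 100]
        cm = make_counts(np.column_stack([data[s] for s in tiny_sheet.sample_ids]),
                         tiny_sheet)
        ft = bf.fitness_scores(cm, tiny_sheet)
        t = ft.table.set_index("gene_id")
        assert t.loc["g0", "mean_score"] == 0.0
        assert t.loc["g1", "mean_score"] == 2.0
        assert np.isnan(t.loc["g2", "mean_score"])  # end 0: undefined, not -inf
        assert bool(t.loc["g2", "low_coverage"])

    def test_zero_start_replicate_excluded(self, tiny_sheet):
        data = {}
        for rep in (1, 2, 3):
            data[f"S_g0_r{rep}"] = [0 if rep == 1 else 100]
            data[f"S_g10_r{rep}"] = [400]
        cm = make_counts(np.column_stack([data[s] for s in tiny_sheet.sample_ids]),
                         tiny_sheet)
        t = bf.fitness_scores(cm, tiny_sheet).table
        assert t["n_reps"].iloc[0] == 2
        assert t["mean_score"].iloc[0] == 2.0

    def test_null_pool_centered(self):
        cfg = synthetic.PoolSimConfig(
            n_genes=500, depth=10_000_000, seed=21, w_neutral=1.0,
            w_deleterious=0.0, w_beneficial=0.0, neutral_sd=0.0,
            jackpot_fraction=0.0,
        )
        cm, sheet, _ = synthetic.simulate_pool_growth(cfg)
        scaled = bf.scale_and_round(bf.library_size_normalize(cm))
        t = bf.fitness_scores(scaled, sheet).table
        assert abs(np.nanmedian(t["mean_score"])) < 0.02

    def test_parameter_recovery(self, recovery_pool):
        cm, sheet, truth = recovery_pool
        scaled = bf.scale_and_round(bf.library_size_normalize(cm))
        imputed, flags = bf.impute_dropouts(scaled, sheet)
        t = bf.fitness_scores(imputed, sheet, imputed_flags=flags).table
        sub = t.dropna(subset=["mean_score"])
        exp = truth.expected_scores.loc[sub["gene_id"], "S1"]
        r = np.corrcoef(sub["mean_score"], exp)[0, 1]
        assert r >= 0.95
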