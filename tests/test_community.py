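"""Community-analysis tests: kitome arithmetic, compositional transforms,
ordination against an independent spectral oracle, and grid statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from h2sinks import (generate_asv_table, column_biomass_tests,
                     confirm_presence, hellinger, kitome_correct,
                     pca_ordination, pooled_relative_abundance,
                     relative_abundance, spatial_map)

GRID_IDS = [f"{c}{r}" for c in ("OL", "CL", "C", "CR", "OR")
            for r in range(1, 8)]


def grid_series(values):
    vals = np.asarray(values, dtype=float).ravel()
    copies = pd.Series(vals, index=GRID_IDS)
    cols = pd.Series([sid[:-1] for sid in GRID_IDS], index=GRID_IDS)
    return copies, cols


class TestKitomeCorrection:
    def test_zero_kitome_leaves_counts_unchanged(self):
        table = generate_asv_table(kitome_level=0.0, seed=2)
        corrected = kitome_correct(table)
        assert corrected.counts.equals(table.counts)
        assert not corrected.clamped.to_numpy().any()

    def test_subtraction_clamps_at_zero(self, asv_table):
        table = asv_table
        with pytest.warns(UserWarning, match="clamped"):
            # force clamping by inflating one ASV's kitome above its reads
            inflated = table.kitome.copy()
            target = table.counts.columns[-1]
            inflated[target] = int(table.counts[target].max()) + 45
            import dataclasses
            bumped = dataclasses.replace(table, kitome=inflated)
            corrected = kitome_correct(bumped)
        assert (corrected.counts[target] == 0).all()
        assert corrected.clamped[target].all()

    def test_column_sums_match_arithmetic(self, asv_table):
        corrected = kitome_correct(asv_table)
        manual = (asv_table.counts.sub(asv_table.kitome, axis=1)
                  .clip(lower=0))
        assert corrected.counts.equals(manual)

    def test_reapplying_with_zero_kitome_is_idempotent(self, asv_table):
        import dataclasses
        once = kitome_correct(asv_table)
        zero = dataclasses.replace(asv_table, counts=once.counts,
                                   kitome=once.kitome * 0)
        twice = kitome_correct(zero)
        assert twice.counts.equals(once.counts)


class TestRelativeAbundance:
    def test_rows_sum_to_one(self, asv_table):
        props = relative_abundance(kitome_correct(asv_table)).proportions
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_two_asv_proportions(self):
        table = generate_asv_table(n_asvs=2, kitome_level=0.0, seed=0)
        import dataclasses
        counts = table.counts.copy()
        counts.iloc[:] = 0
        counts.iloc[0] = [30, 10]
        fixed = dataclasses.replace(table, counts=counts)
        props = relative_abundance(kitome_correct(fixed))
        assert list(props.proportions.iloc[0]) == [0.75, 0.25]
        assert len(props.excluded) == 34  # the zeroed samples drop out

    def test_reads_first_averaging_differs_from_proportion_averaging(self,
                                                                     asv_table):
        """Averaging reads before normalizing is not the same operation as
        averaging per-sample proportions; the package does reads-first."""
        reads_first = pooled_relative_abundance(asv_table)
        props = relative_abundance(kitome_correct(asv_table)).proportions
        prop_avg = props.mean(axis=0)
        assert np.allclose(reads_first.sum(), 1.0)
        assert not np.allclose(reads_first, prop_avg, atol=1e-4)


class TestPresenceConfirmation:
    def test_mean_below_kitome_not_confirmed(self, asv_table):
        import dataclasses
        table = asv_table
        target = table.counts.columns[0]
        inflated = table.kitome.copy()
        inflated[target] = int(table.counts[target].mean()) + 5
        bumped = dataclasses.replace(table, kitome=inflated)
        assert not confirm_presence(bumped, target, bumped.grid_samples())

    def test_mean_above_zero_kitome_confirmed(self):
        table = generate_asv_table(kitome_level=0.0, seed=4)
        assert confirm_presence(table, "ASV1", table.grid_samples())

    def test_tie_is_not_confirmed(self):
        import dataclasses
        table = generate_asv_table(n_asvs=3, kitome_level=0.0, seed=5)
        target = "ASV2"
        tied = table.kitome.astype(float)
        tied[target] = float(table.counts[target].mean())
        bumped = dataclasses.replace(table, kitome=tied)
        assert not confirm_presence(bumped, target, bumped.grid_samples())

    def test_unknown_taxon_rejected(self, asv_table):
        with pytest.raises(ValueError, match="unknown taxon"):
            confirm_presence(asv_table, "ASV999", asv_table.grid_samples())

    def test_hotspot_taxon_confirmed_in_central_column(self):
        hits = sum(
            confirm_presence(t := generate_asv_table(seed=s), "ASV1",
                             t.grid_samples("C"))
            for s in range(100))
        assert hits >= 95


class TestHellingerAndPCA:
    def test_vertex_and_uniform_rows(self):
        out = hellinger(np.array([[1.0, 0.0, 0.0],
                                  [0.25, 0.25, 0.25, 0.25][:3]]))
        assert np.allclose(out[0], [1.0, 0.0, 0.0])
        uniform = hellinger(np.full((1, 4), 0.25))
        assert np.allclose(uniform, 0.5)
        assert np.allclose((uniform ** 2).sum(), 1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hellinger(np.array([[-0.1, 1.1]]))

    def test_preserves_within_row_ranking(self, asv_table):
        props = relative_abundance(kitome_correct(asv_table)).proportions
        transformed = hellinger(props)
        for i in range(3):
            assert (np.argsort(props.iloc[i].to_numpy()) ==
                    np.argsort(transformed.iloc[i].to_numpy())).all()

    def test_pca_matches_covariance_eigenvalue_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.random((12, 5))
        _, _, evr = pca_ordination(x, 4)
        eig = np.sort(np.linalg.eigvalsh(np.cov(x, rowvar=False)))[::-1]
        assert np.allclose(evr, eig[:4] / eig.sum(), atol=1e-10)
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-12

    def test_pca_scores_match_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(9)
        x = rng.random((15, 6))
        scores, _, evr = pca_ordination(x, 3)
        ref = sklearn.PCA(n_components=3).fit(x)
        assert np.allclose(np.abs(scores), np.abs(ref.transform(x)))
        assert np.allclose(evr, ref.explained_variance_ratio_)

    def test_constructed_clusters_dominate_axis_one(self):
        x = np.vstack([np.zeros((5, 4)), np.ones((5, 4)) * 3])
        x[:, 2] += np.linspace(0, 0.1, 10)  # small secondary variation
        _, _, evr = pca_ordination(x, 2)
        assert evr[0] > evr[1]

    def test_duplicated_rows_flagged_as_zero_variance(self):
        with pytest.warns(UserWarning, match="zero variance"):
            _, _, evr = pca_ordination(np.ones((4, 3)), 2)
        assert (evr == 0).all()

    def test_overlarge_component_request_truncated(self):
        rng = np.random.default_rng(10)
        x = rng.random((3, 5))  # rank <= 2 after centering
        with pytest.warns(UserWarning, match="truncated"):
            scores, _, _ = pca_ordination(x, 5)
        assert scores.shape[1] <= 2


class TestColumnBiomassTests:
    def test_near_constant_grid_yields_no_rejections(self):
        rng = np.random.default_rng(0)
        copies, cols = grid_series(100.0 + 1e-9 * rng.random(35))
        results = column_biomass_tests(copies, cols)
        assert len(results) == 4
        assert all(t.p_value > 0.05 for t in results)

    def test_shifted_center_detected_with_high_power(self):
        """Center column +3 SD: all four one-sided tests reject almost
        always (Monte-Carlo power check)."""
        rng = np.random.default_rng(123)
        all_four = 0
        n_rep = 400
        for _ in range(n_rep):
            vals = rng.normal(0.0, 1.0, (5, 7))
            vals[2] += 3.0  # center column is the third of five
            copies, cols = grid_series(vals)
            results = column_biomass_tests(copies, cols)
            all_four += all(t.p_value < 0.05 for t in results)
        assert all_four / n_rep >= 0.95

    def test_pooled_t_matches_distribution_oracle(self):
        rng = np.random.default_rng(77)
        off = rng.normal(0.0, 1.0, 7)
        center = rng.normal(0.5, 1.0, 7)
        vals = np.zeros((5, 7))
        vals[0] = off
        vals[2] = center
        # the other columns get distinct values so only OL is checked here
        vals[1] = rng.normal(0.0, 1.0, 7)
        vals[3] = rng.normal(0.0, 1.0, 7)
        vals[4] = rng.normal(0.0, 1.0, 7)
        copies, cols = grid_series(vals)
        result = [t for t in column_biomass_tests(copies, cols)
                  if t.column == "OL"][0]
        n1 = n2 = 7
        sp2 = ((n1 - 1) * np.var(off, ddof=1)
               + (n2 - 1) * np.var(center, ddof=1)) / (n1 + n2 - 2)
        t_stat = (off.mean() - center.mean()) / np.sqrt(sp2 * (1/n1 + 1/n2))
        p = stats.t.cdf(t_stat, n1 + n2 - 2)
        if result.variant == "pooled":
            assert result.t_stat == pytest.approx(t_stat, rel=1e-9)
            assert result.p_value == pytest.approx(p, rel=1e-9)

    def test_variance_gate_switches_to_welch(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.0, 1.0, (5, 7))
        vals[0] = rng.normal(0.0, 25.0, 7)  # wildly unequal variance in OL
        copies, cols = grid_series(vals)
        results = {t.column: t for t in column_biomass_tests(copies, cols)}
        assert results["OL"].variant == "unequal-variance"
        assert results["OL"].variance_p < 0.05

    def test_short_column_skipped_with_warning(self):
        copies, cols = grid_series(np.random.default_rng(1).random((5, 7)))
        copies = copies.drop([f"OL{r}" for r in range(1, 7)])  # one left
        cols = cols.drop([f"OL{r}" for r in range(1, 7)])
        with pytest.warns(UserWarning, match="fewer than 2"):
            results = column_biomass_tests(copies, cols)
        assert {t.column for t in results} == {"CL", "CR", "OR"}


class TestSpatialMap:
    def test_constant_grid_gives_constant_field(self):
        field, _, _ = spatial_map(np.full((7, 5), 3.3))
        assert np.allclose(field, 3.3)

    def test_nodes_reproduced_exactly(self):
        rng = np.random.default_rng(2)
        vals = rng.random((7, 5))
        field, rows, cols = spatial_map(vals)
        ri = [np.flatnonzero(np.isclose(rows, r))[0] for r in range(1, 8)]
        ci = [np.flatnonzero(np.isclose(cols, c))[0] for c in range(5)]
        assert np.allclose(field[np.ix_(ri, ci)], vals)

    def test_linear_ramp_interpolates_to_plane(self):
        vals = np.tile(np.arange(5.0), (7, 1))
        field, rows, cols = spatial_map(vals)
        assert np.allclose(field, np.tile(cols, (len(rows), 1)))

    def test_too_many_missing_rejected(self):
        vals = np.full((7, 5), np.nan)
        vals[0, :3] = 1.0
        with pytest.raises(ValueError, match="missing"):
            spatial_map(vals)

    def test_partial_missing_tolerated(self):
        rng = np.random.default_rng(3)
        vals = rng.random((7, 5))
        vals[0, 0] = np.nan
        field, _, _ = spatial_map(vals)
        assert np.isfinite(field).all()
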