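"""Far-Western band-table normalization, specificity and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cosine as cosine_distance

from sh2kinetics.fwtable import (
    hcluster_uncentered,
    lane_fractions,
    load_band_table,
    normalize_to_probe_max,
    relative_specificity,
    similarity_matrix,
    uncentered_correlation,
)


def wide_table(rows: dict, proteins=("EGFR", "GAB1"), times=(0, 1, 5)) -> pd.DataFrame:
    cols = pd.MultiIndex.from_product(
        [proteins, times], names=["protein", "time_min"]
    )
    index = pd.MultiIndex.from_tuples(rows.keys(), names=["probe", "replicate"])
    return pd.DataFrame(list(rows.values()), index=index, columns=cols[: len(next(iter(rows.values())))])


# ----------------------------------------------------------------------
# Normalization
# ----------------------------------------------------------------------

class TestNormalization:
    def test_single_row_scaled_to_unit_max(self):
        table = wide_table({("GRB2", 1): [2.0, 4.0, 8.0]}, proteins=("EGFR",))
        out = normalize_to_probe_max(table)
        assert out.loc["GRB2"].tolist() == [0.25, 0.5, 1.0]

    def test_idempotence_on_normalized_data(self):
        table = wide_table({("GRB2", 1): [0.25, 0.5, 1.0]}, proteins=("EGFR",))
        out = normalize_to_probe_max(table)
        again = normalize_to_probe_max(out.set_index(pd.MultiIndex.from_tuples([("GRB2", 1)])))
        assert np.allclose(out.to_numpy(), again.to_numpy())

    def test_replicates_normalized_then_averaged(self):
        table = wide_table(
            {("GRB2", 1): [1.0, 2.0, 4.0], ("GRB2", 2): [2.0, 2.0, 8.0]},
            proteins=("EGFR",),
        )
        # per-replicate normalization: {0.25, 0.5, 1} and {0.25, 0.25, 1};
        # replicate average: {0.25, 0.375, 1}
        out = normalize_to_probe_max(table)
        assert np.allclose(out.loc["GRB2"].to_numpy(), [0.25, 0.375, 1.0])

    def test_all_zero_replicate_names_the_probe(self):
        table = wide_table(
            {("GRB2", 1): [1.0, 2.0, 4.0], ("NCK1", 1): [0.0, 0.0, 0.0]},
            proteins=("EGFR",),
        )
        with pytest.raises(ValueError, match="NCK1"):
            normalize_to_probe_max(table)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        values=st.lists(st.floats(0.01, 1e4), min_size=3, max_size=3),
        scale=st.floats(0.01, 1e3),
    )
    def test_scale_invariance_per_replicate(self, values, scale):
        t1 = wide_table({("P", 1): values}, proteins=("EGFR",))
        t2 = wide_table({("P", 1): [v * scale for v in values]}, proteins=("EGFR",))
        assert np.allclose(
            normalize_to_probe_max(t1).to_numpy(),
            normalize_to_probe_max(t2).to_numpy(),
        )


# ----------------------------------------------------------------------
# Relative specificity
# ----------------------------------------------------------------------

class TestRelativeSpecificity:
    def _fraction_row(self, values, proteins=("EGFR", "GAB1"), times=(0, 5)):
        cols = pd.MultiIndex.from_product([proteins, times], names=["protein", "time_min"])
        return pd.Series(values, index=cols)

    def test_identical_profiles_give_zero(self):
        row = self._fraction_row([0.6, 0.3, 0.4, 0.7])
        out = relative_specificity(row, row)
        assert (out == 0).all()

    def test_two_band_example_and_zero_sum(self):
        sh2 = self._fraction_row([0.7, 0.6, 0.3, 0.4])
        py = self._fraction_row([0.5, 0.5, 0.5, 0.5])
        out = relative_specificity(sh2, py)
        assert out.iloc[0] == pytest.approx(0.2)
        assert out.iloc[2] == pytest.approx(-0.2)
        lane_sums = out.groupby(level="time_min").sum()
        assert np.allclose(lane_sums.to_numpy(), 0.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_zero_sum_for_random_valid_rows(self, seed):
        rng = np.random.default_rng(seed)
        raw_a = rng.uniform(0.1, 5.0, 4)
        raw_b = rng.uniform(0.1, 5.0, 4)
        sh2 = self._fraction_row(
            [raw_a[0] / (raw_a[0] + raw_a[2]), raw_a[1] / (raw_a[1] + raw_a[3]),
             raw_a[2] / (raw_a[0] + raw_a[2]), raw_a[3] / (raw_a[1] + raw_a[3])]
        )
        py = self._fraction_row(
            [raw_b[0] / (raw_b[0] + raw_b[2]), raw_b[1] / (raw_b[1] + raw_b[3]),
             raw_b[2] / (raw_b[0] + raw_b[2]), raw_b[3] / (raw_b[1] + raw_b[3])]
        )
        out = relative_specificity(sh2, py)
        assert np.allclose(out.groupby(level="time_min").sum().to_numpy(), 0.0)

    def test_unnormalized_lane_rejected(self):
        sh2 = self._fraction_row([0.7, 0.6, 0.2, 0.4])  # lane 0 sums to 0.9
        py = self._fraction_row([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="lane totals"):
            relative_specificity(sh2, py)

    def test_lane_fraction_helper(self):
        raw = self._fraction_row([3.0, 1.0, 1.0, 4.0])
        frac = lane_fractions(raw)
        assert frac.iloc[0] == pytest.approx(0.75)
        assert np.allclose(frac.groupby(level="time_min").sum().to_numpy(), 1.0)


# ----------------------------------------------------------------------
# Hierarchical clustering
# ----------------------------------------------------------------------

def scipy_flat_partition(data: np.ndarray, cutoff: float) -> set:
    """Independent oracle: scipy average linkage on cosine distance."""
    Z = linkage(data, method="average", metric="cosine")
    assignments = fcluster(Z, t=1.0 - cutoff, criterion="distance")
    out = {}
    for i, c in enumerate(assignments):
        out.setdefault(c, set()).add(i)
    return {frozenset(v) for v in out.values()}


class TestUncenteredCorrelation:
    def test_matches_cosine_similarity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert uncentered_correlation(x, y) == pytest.approx(1 - cosine_distance(x, y))

    def test_self_similarity_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0.1, 1.0, (5, 6))
        S = similarity_matrix(m)
        assert np.allclose(np.diag(S), 1.0)
        assert np.allclose(S, S.T)
        assert (S >= -1).all() and (S <= 1).all()

    def test_zero_norm_row_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            uncentered_correlation(np.zeros(4), np.ones(4))


class TestHcluster:
    def test_identical_rows_form_one_cluster(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["A", "B"])
        d = hcluster_uncentered(m)
        assert d.merges[0].similarity == pytest.approx(1.0)
        assert d.flat_clusters(0.99) == [frozenset({"A", "B"})]

    def test_orthogonal_rows_never_merge_above_cutoff(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["A", "B"])
        d = hcluster_uncentered(m)
        assert d.merges[0].similarity == pytest.approx(0.0)
        assert d.flat_clusters(0.85) == [frozenset({"A"}), frozenset({"B"})]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0.05, 1.0, (6, 7))
        dendro = hcluster_uncentered(data)
        # merge heights agree with scipy's (1 - similarity) distances
        Z = linkage(data, method="average", metric="cosine")
        ours = sorted(1.0 - m.similarity for m in dendro.merges)
        theirs = sorted(Z[:, 2])
        assert np.allclose(ours, theirs, atol=1e-9)
        # flat partitions agree at several cutoffs
        for cutoff in (0.5, 0.7, 0.85, 0.95):
            mine = {frozenset(c) for c in dendro.flat_clusters(cutoff)}
            assert mine == scipy_flat_partition(data, cutoff)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            rng.uniform(0.05, 1.0, (6, 5)), index=list("ABCDEF")
        )
        base = hcluster_uncentered(data).flat_clusters(0.85)
        perm = data.sample(frac=1.0, random_state=11)
        shuffled = hcluster_uncentered(perm).flat_clusters(0.85)
        assert base == shuffled

    def test_newick_export_is_parseable(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.uniform(0.1, 1.0, (4, 5)),
                            index=["GRB2", "CRK", "NCK1", "VAV2"])
        nwk = hcluster_uncentered(data).to_newick()
        import io
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"GRB2", "CRK", "NCK1", "VAV2"}

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hcluster_uncentered(pd.DataFrame([[1.0, 2.0]]))


def test_long_csv_roundtrip(tmp_path):
    long = pd.DataFrame(
        {
            "probe": ["GRB2"] * 4 + ["CRK"] * 4,
            "replicate": [1, 1, 2, 2] * 2,
            "protein": ["EGFR", "GAB1"] * 4,
            "time_min": [0, 0, 0, 0, 5, 5, 5, 5],
            "intensity": [4.0, 1.0, 2.0, 1.0, 3.0, 2.0, 1.0, 0.5],
        }
    )
    path = tmp_path / "bands.csv"
    long.to_csv(path, index=False)
    wide = load_band_table(path)
    assert wide.shape == (4, 4)
    assert wide.loc[("GRB2", 1)].max() == 4.0
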