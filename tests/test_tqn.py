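"""Trimmed quantile normalization: contract, ramp arithmetic, and oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctap.comparison_pairs import CohortMatrix
from ctap.tqn import (
    ColumnDecomposition,
    DegenerateColumnError,
    TQNParams,
    revise_tail,
    trimmed_quantile_normalize,
)


def tqn_oracle(frame: pd.DataFrame, trim: float) -> pd.DataFrame:
    """Literal step-by-step reference: sort, trim, rank-mean-normalize the
    middle, rebuild tails on the signed Z ramp, restore gene order."""
    n = len(frame)
    k = int(np.floor(trim * n))
    mid_len = n - 2 * k
    orders = {}
    middles = {}
    for c in frame.columns:
        order = sorted(range(n), key=lambda i: (frame[c].iloc[i], frame.index[i]))
        orders[c] = order
        vals = [frame[c].iloc[i] for i in order]
        middles[c] = vals[k : n - k]
    ref = [float(np.mean([middles[c][r] for c in frame.columns]))
           for r in range(mid_len)]
    mu = float(np.mean(ref))
    sigma = float(np.sqrt(np.mean([(v - mu) ** 2 for v in ref])))
    z = [(v - mu) / sigma for v in ref]
    n_pos = sum(1 for v in z if v > 0)
    n_neg = sum(1 for v in z if v < 0)
    anchor_small = min(i for i in range(mid_len) if z[i] >= 0)
    anchor_large = max(i for i in range(mid_len) if z[i] <= 0)
    out = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for c in frame.columns:
        small = [mu - abs(min(z)) / n_neg * (anchor_small + j) * sigma
                 for j in range(k, 0, -1)]
        large = [mu + abs(max(z)) / n_pos * ((mid_len - 1 - anchor_large) + j) * sigma
                 for j in range(1, k + 1)]
        new_sorted = small + ref + large
        for slot, i in enumerate(orders[c]):
            out.iloc[i, out.columns.get_loc(c)] = new_sorted[slot]
    return out


def _sorted_middle(arr: np.ndarray, k: int) -> np.ndarray:
    return np.sort(arr, axis=0)[k : len(arr) - k]


class TestNormalizeContract:
    def test_matches_stepwise_oracle(self, random_matrix):
        got = trimmed_quantile_normalize(random_matrix, TQNParams(0.10))
        want = tqn_oracle(random_matrix.values, 0.10)
        np.testing.assert_allclose(
            got.values.to_numpy(), want.to_numpy(), rtol=0, atol=1e-9
        )

    def test_permuted_columns_equalize_and_keep_ranks(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(3, 1, 40)
        cols = {f"c{j}": rng.permutation(base) for j in range(3)}
        m = CohortMatrix(pd.DataFrame(cols, index=[f"G{i}" for i in range(40)]))
        out = trimmed_quantile_normalize(m, TQNParams(0.10))
        arr_in = m.values.to_numpy()
        arr_out = out.values.to_numpy()
        srt = np.sort(arr_out, axis=0)
        np.testing.assert_allclose(srt - srt[:, [0]], 0.0, atol=1e-9)
        for j in range(3):
            np.testing.assert_array_equal(
                np.argsort(arr_in[:, j], kind="stable"),
                np.argsort(arr_out[:, j], kind="stable"),
            )

    def test_single_column_middle_unchanged(self):
        rng = np.random.default_rng(3)
        vals = np.sort(rng.lognormal(3, 1, 30))
        m = CohortMatrix(pd.DataFrame(
            {"only": vals}, index=[f"G{i:02d}" for i in range(30)]
        ))
        out = trimmed_quantile_normalize(m, TQNParams(0.10))
        np.testing.assert_allclose(
            _sorted_middle(out.values.to_numpy(), 3).ravel(), vals[3:27],
            atol=1e-9,
        )
        # tails were re-placed on the ramp, not kept
        assert not np.allclose(out.values["only"].to_numpy(), vals)

    def test_rank_preservation_random(self, random_matrix):
        out = trimmed_quantile_normalize(random_matrix, TQNParams(0.05))
        a = random_matrix.values.to_numpy()
        b = out.values.to_numpy()
        for j in range(a.shape[1]):
            np.testing.assert_array_equal(
                np.argsort(a[:, j], kind="stable"),
                np.argsort(b[:, j], kind="stable"),
            )

    def test_idempotent_on_middle(self, random_matrix):
        once = trimmed_quantile_normalize(random_matrix, TQNParams(0.10))
        twice = trimmed_quantile_normalize(once, TQNParams(0.10))
        np.testing.assert_allclose(
            _sorted_middle(twice.values.to_numpy(), 5),
            _sorted_middle(once.values.to_numpy(), 5),
            atol=1e-9,
        )

    @given(seed=st.integers(0, 20))
    def test_middle_multisets_identical_across_columns(self, seed):
        rng = np.random.default_rng(seed)
        shape = (30 + seed, 3)
        m = CohortMatrix(pd.DataFrame(
            rng.lognormal(4, 1.5, shape),
            index=[f"G{i:03d}" for i in range(shape[0])],
            columns=["a", "b", "c"],
        ))
        k = TQNParams(0.10).tail_size(shape[0])
        out = trimmed_quantile_normalize(m, TQNParams(0.10))
        mids = _sorted_middle(out.values.to_numpy(), k)
        np.testing.assert_allclose(mids - mids[:, [0]], 0.0, atol=1e-9)


class TestErrors:
    def test_degenerate_column_named(self):
        m = CohortMatrix(pd.DataFrame(
            {"flat": np.ones(30), "ok": np.arange(30.0)},
            index=[f"G{i:02d}" for i in range(30)],
        ))
        with pytest.raises(DegenerateColumnError, match="flat"):
            trimmed_quantile_normalize(m, TQNParams(0.10))

    def test_overtrimmed_middle_rejected(self):
        m = CohortMatrix(pd.DataFrame(
            {"a": np.arange(6.0), "b": np.arange(6.0)},
            index=list("ABCDEF"),
        ))
        with pytest.raises(ValueError, match="at least 3"):
            trimmed_quantile_normalize(m, TQNParams(0.45))

    def test_trim_fraction_bounds(self):
        for bad in (0.0, 0.5, -0.1, 1.0):
            with pytest.raises(ValueError):
                TQNParams(bad)


def _symmetric_decomp(tail: int) -> ColumnDecomposition:
    # middle with mu=10, sigma=2, z in {-1.5..1.5}, anchor at z=0
    z = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
    middle = 10.0 + 2.0 * z
    return ColumnDecomposition(
        column="c", order=np.arange(7 + 2 * tail),
        small_part=np.zeros(tail), middle_part=middle,
        large_part=np.zeros(tail),
        mu=10.0, sigma=2.0, z_m=z, n_pos=3, n_neg=3, anchor=3,
    )


class TestReviseTail:
    def test_large_tail_ramp_arithmetic(self):
        # step = |max z|/n_pos * sigma = 1.5/3*2 = 1; outermost middle gene is
        # 3 ranks from the anchor, so tail genes sit at n' = 4, 5
        out = revise_tail(_symmetric_decomp(2), "large")
        np.testing.assert_allclose(out, [14.0, 15.0])

    def test_small_tail_mirrors_below_mu(self):
        out = revise_tail(_symmetric_decomp(2), "small")
        np.testing.assert_allclose(out, [5.0, 6.0])  # ascending slot order

    def test_single_element_tails_equidistant_from_mu(self):
        d = _symmetric_decomp(1)
        lo = revise_tail(d, "small")[0]
        hi = revise_tail(d, "large")[0]
        assert d.mu - lo == pytest.approx(hi - d.mu)

    def test_empty_tail_empty_output(self):
        assert revise_tail(_symmetric_decomp(0), "large").size == 0

    def test_one_sided_middle_rejected(self):
        d = _symmetric_decomp(1)
        broken = ColumnDecomposition(
            column="c", order=d.order, small_part=d.small_part,
            middle_part=d.middle_part, large_part=d.large_part,
            mu=d.mu, sigma=d.sigma, z_m=d.z_m, n_pos=0, n_neg=3, anchor=3,
        )
        with pytest.raises(DegenerateColumnError, match="one-sided"):
            revise_tail(broken, "large")
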