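import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bluecall import (
    chebyshev,
    coarse_grain,
    count_matches,
    embed,
    mse_matrix,
    sample_entropy,
)
from bluecall.preprocess import SegmentSet

from .conftest import sampen_oracle


class TestCoarseGrain:
    def test_adjacent_pair_means(self):
        assert np.allclose(coarse_grain([1, 2, 3, 4, 5, 6], 2).values,
                           [1.5, 3.5, 5.5])

    def test_scale_one_is_identity(self, rng):
        x = rng.standard_normal(50)
        assert np.array_equal(coarse_grain(x, 1).values, x)

    def test_partial_block_dropped(self, rng):
        x = rng.standard_normal(10)
        cg = coarse_grain(x, 3)
        assert len(cg) == 3
        assert cg.values[-1] == pytest.approx(np.mean(x[6:9]))  # x[9] unused

    def test_tau_larger_than_series_errors(self):
        with pytest.raises(ValueError):
            coarse_grain([1.0, 2.0], 3)


class TestEmbed:
    def test_unit_stride_templates(self):
        E = embed([1, 2, 3, 4], 2)
        assert np.array_equal(E, [[1, 2], [2, 3], [3, 4]])

    def test_boundary_m(self):
        assert embed(list(range(5)), 4).shape == (2, 4)
        assert embed(list(range(5)), 1).shape == (5, 1)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            embed([1.0, 2.0], 2)


class TestChebyshev:
    def test_examples(self):
        assert chebyshev([1, 2], [1, 2]) == 0.0
        assert chebyshev([0, 3, 1], [1, 1, 5]) == 4.0

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=8),
           st.data())
    @settings(max_examples=50, derandomize=True)
    def test_symmetry(self, u, data):
        v = data.draw(st.lists(st.floats(-100, 100), min_size=len(u),
                               max_size=len(u)))
        assert chebyshev(u, v) == chebyshev(v, u)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            chebyshev([1, 2], [1, 2, 3])


class TestCountMatches:
    def test_constant_series_all_pairs_match(self):
        c = count_matches([5.0] * 5, m=2, r_abs=0.1)
        assert c.C_m == 6  # all pairs of the M=4 templates
        assert c.C_m1 == 3  # all pairs of the 3 (m+1)-templates

    def test_published_normaliser_substitution(self, rng):
        x = rng.standard_normal(100)
        c = count_matches(x, m=2, r_abs=0.2, norm_mode="paper")
        assert c.T_m == pytest.approx(2 * (100 - 2 + 1) / 2)  # = 99
        assert c.T_m1 == pytest.approx(3 * (100 - 2) / 2)

    def test_counts_match_bruteforce(self, rng):
        x = rng.uniform(size=60)
        c = count_matches(x, m=2, r_abs=0.15)
        C_m, C_m1, _ = sampen_oracle(x, 2, 0.15)
        assert (c.C_m, c.C_m1) == (C_m, C_m1)

    def test_nesting_counts(self, rng):
        # a Chebyshev match at m+1 implies one at m
        for _ in range(20):
            x = rng.standard_normal(rng.integers(20, 80))
            c = count_matches(x, m=2, r_abs=0.3)
            assert 0 <= c.C_m1 <= c.C_m

    def test_too_few_templates_errors(self):
        with pytest.raises(ValueError):
            count_matches([1.0, 2.0, 3.0], m=3, r_abs=0.5)


# 50 seeded cases cycling length, embedding dimension and tolerance factor
_CASES = [(seed, 50 + (seed * 3) % 151, [1, 2, 3][seed % 3],
           [0.2, 0.35, 0.5][seed % 3 if seed % 2 else (seed // 3) % 3])
          for seed in range(50)]


@pytest.mark.parametrize("norm_mode", ["paper", "standard"])
@pytest.mark.parametrize("seed,n,m,r_coef", _CASES)
def test_sample_entropy_equals_literal_oracle(seed, n, m, r_coef, norm_mode):
    """The vectorized SampEn must reproduce a literal embed/count/normalise
    double loop exactly, under both normalisation conventions."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    r = r_coef * np.std(x)
    got = sample_entropy(x, m=m, r_abs=r, norm_mode=norm_mode)
    _, _, expected = sampen_oracle(x, m, r, norm_mode)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(expected, abs=1e-12)


class TestSampleEntropy:
    def test_constant_series_standard_mode_is_zero(self):
        assert sample_entropy([3.0] * 30, m=2, r_abs=0.1,
                              norm_mode="standard") == 0.0

    def test_monotone_in_tolerance(self, rng):
        x = rng.standard_normal(150)
        sd = np.std(x)
        values = [sample_entropy(x, 2, r * sd, "standard")
                  for r in (0.1, 0.2, 0.35, 0.5, 0.8)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_undefined_entropy_is_nan(self):
        # strictly monotone series with tiny tolerance: no template matches
        assert math.isnan(sample_entropy(np.arange(30.0), 2, 1e-9, "standard"))


class TestMSEMatrix:
    def test_shape(self, rng):
        segs = rng.standard_normal((4, 600))
        mat = mse_matrix(segs, tau_max=12)
        assert mat.values.shape == (4, 12)
        assert np.all(np.isfinite(mat.values))
        assert np.allclose(mat.log_values, np.log1p(mat.values))

    def test_first_column_is_plain_sampen(self, rng):
        segs = rng.standard_normal((3, 400))
        mat = mse_matrix(segs, m=2, r_coef=0.2, tau_max=4)
        for k, row in enumerate(segs):
            se1 = sample_entropy(row, 2, 0.2 * np.std(row), "paper")
            assert mat.values[k, 0] == pytest.approx(se1)

    def test_tolerance_anchored_to_scale_one_sigma(self, rng):
        # column eta>1 uses r from the *unaggregated* segment, not the
        # coarse-grained one
        seg = rng.standard_normal(600)
        mat = mse_matrix(seg[None, :], m=2, r_coef=0.2, tau_max=3)
        cg = coarse_grain(seg, 3)
        expected = sample_entropy(cg, 2, 0.2 * np.std(seg), "paper")
        assert mat.values[0, 2] == pytest.approx(expected)

    def test_segment_too_short_for_scale_errors(self, rng):
        with pytest.raises(ValueError, match="tau"):
            mse_matrix(rng.standard_normal((2, 40)), tau_max=12)

    def test_degenerate_segment_imputed_by_column_max(self, rng):
        segs = np.vstack([rng.standard_normal((3, 600)), np.zeros((1, 600))])
        mat = mse_matrix(segs, tau_max=4)
        assert mat.n_imputed == 4
        for col in range(4):
            assert mat.values[3, col] == pytest.approx(mat.values[:3, col].max())

    def test_tsv_roundtrip(self, tmp_path, rng):
        segs = SegmentSet(rng.standard_normal((3, 600)), 6.0, 100.0,
                          labels=["noise", "call", "noise"])
        mat = mse_matrix(segs, tau_max=5)
        path = tmp_path / "mse.tsv"
        mat.to_tsv(path)
        back = type(mat).from_tsv(path)
        assert np.allclose(back.values, mat.values)
        assert back.labels == mat.labels
        assert back.norm_mode == mat.norm_mode
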