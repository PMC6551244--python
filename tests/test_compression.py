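import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpbwt import panel_from_matrix
from mpbwt.compression import (
    MAGIC,
    ContainerFormatError,
    TransformedPanel,
    decode,
    dense_occ,
    encode,
    extend_rank,
    reconstruct,
    rle_encode_column,
    transform,
)
from mpbwt.oracle import oracle_sort


class TestTransform:
    def test_worked_panel_y_arrays(self, worked_panel):
        tp = transform(worked_panel)
        assert tp.y[0].tolist() == [0, 1, 0, 2]
        assert tp.y[1].tolist() == [1, 1, 1, 0]  # column 1 through a_1=[0,2,1,3]
        assert tp.c[0].tolist() == [2, 1, 1]

    def test_identical_rows_single_run_columns(self):
        panel = panel_from_matrix(np.tile([1, 0, 2], (6, 1)))
        tp = transform(panel)
        for k in range(3):
            assert len(np.unique(tp.y[k])) == 1
            # single-run column: one (allele, M) pair behind a 1-run count
            assert rle_encode_column(tp.y[k]) == bytes([1, tp.y[k][0], 6])

    def test_occ_consistency(self, worked_panel):
        tp = transform(worked_panel, occ_stride=2)
        for k in range(worked_panel.N):
            t_k = int(tp.site_alphabet_sizes[k])
            cc = tp.cc(k)
            assert cc[-1] == tp.M
            for l in range(t_k):
                assert tp.rank(k, l, tp.M) == tp.c[k][l]
                ranks = [tp.rank(k, l, i) for i in range(tp.M + 1)]
                assert ranks == sorted(ranks)


class TestExtendRank:
    def test_worked_example(self, worked_panel):
        tp = transform(worked_panel)
        # Occ_0[1][1] = 0, CC(0) = 2
        assert tp.extend(0, 1, 1) == 2

    def test_position_zero_is_zero(self, worked_panel):
        tp = transform(worked_panel)
        assert tp.extend(0, 0, 0) == 0

    def test_top_allele_at_m_is_m(self, worked_panel):
        tp = transform(worked_panel)
        for k in range(worked_panel.N):
            t_k = int(tp.site_alphabet_sizes[k])
            assert tp.extend(k, tp.M, t_k - 1) == tp.M

    def test_out_of_alphabet(self, worked_panel):
        tp = transform(worked_panel)
        with pytest.raises(Exception):
            tp.extend(0, 0, 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_inverse_property_exhaustive(self, seed):
        """a_{k+1}[w_k(i, y_k[i])] = a_k[i] for every k and i."""
        rng = np.random.default_rng(seed)
        M = int(rng.integers(2, 12))
        N = int(rng.integers(1, 12))
        t = int(rng.choice([2, 3, 5]))
        panel = panel_from_matrix(rng.integers(0, t, size=(M, N)), alphabet_size=t)
        tp = transform(panel, occ_stride=3)
        for k in range(N):
            a_k, _ = oracle_sort(panel, k)
            a_k1, _ = oracle_sort(panel, k + 1)
            occ = dense_occ(tp.y[k], t)
            cc = tp.cc(k)
            for i in range(M):
                l = int(tp.y[k][i])
                w_dense = extend_rank(occ, cc, i, l)
                assert w_dense == tp.extend(k, i, l)
                assert a_k1[w_dense] == a_k[i]


class TestContainer:
    def test_roundtrip_identity(self, worked_panel):
        tp = transform(worked_panel, a_stride=2, occ_stride=2)
        assert decode(encode(tp)).equals(tp)

    def test_deterministic_bytes(self, worked_panel):
        assert encode(transform(worked_panel)) == encode(transform(worked_panel))

    def test_bad_magic(self):
        with pytest.raises(ContainerFormatError, match="magic"):
            decode(b"NOTIT" + bytes(32))

    def test_version_mismatch_names_versions(self, worked_panel):
        data = bytearray(encode(transform(worked_panel)))
        data[len(MAGIC)] = 9
        with pytest.raises(ContainerFormatError, match="9"):
            decode(bytes(data))

    def test_truncation(self, worked_panel):
        data = encode(transform(worked_panel))
        with pytest.raises(ContainerFormatError):
            decode(data[: len(data) // 2])

    def test_trailing_garbage(self, worked_panel):
        data = encode(transform(worked_panel))
        with pytest.raises(ContainerFormatError, match="trailing"):
            decode(data + b"\x00")


class TestReconstruct:
    def test_worked_panel(self, worked_panel):
        back = reconstruct(transform(worked_panel))
        assert np.array_equal(back.alleles, worked_panel.alleles)

    def test_single_haplotype(self):
        panel = panel_from_matrix(np.array([[0, 4, 2, 1]]))
        back = reconstruct(decode(encode(transform(panel))))
        assert np.array_equal(back.alleles, panel.alleles)

    def test_corrupt_counts_detected(self, worked_panel):
        tp = transform(worked_panel)
        tp.c[1] = tp.c[1].copy()
        tp.c[1][0] += 1
        with pytest.raises(ContainerFormatError):
            reconstruct(tp)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(1, 40))
        N = int(rng.integers(0, 60))
        t = int(rng.choice([2, 3, 10]))
        panel = panel_from_matrix(rng.integers(0, t, size=(M, N)), alphabet_size=t)
        back = reconstruct(decode(encode(transform(panel, a_stride=7, occ_stride=5))))
        assert np.array_equal(back.alleles, panel.alleles)
        assert np.array_equal(back.site_alphabet_sizes, panel.site_alphabet_sizes)
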