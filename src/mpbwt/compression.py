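"""Panel compression via the positional FM-index.

The transform stores, for every site ``k``, the column of alleles in
reversed-prefix order: ``y_k[i] = x[a_k[i]][k]``.  Under linkage
disequilibrium neighbouring haplotypes in that order tend to carry the
same allele, so each ``y_k`` is highly run-length compressible — that is
the entire point of sorting before encoding.

Alongside ``y`` the transform keeps the per-site allele counts ``c_k``
and an occurrence table ``Occ_k[l][i]`` (number of ``l``'s among
``y_k[0..i-1]``), checkpointed every ``occ_stride`` sorted positions.
With ``CC_k(l) = c_k(0) + ... + c_k(l)`` the extension function

    w_k(i, l) = Occ_k[l][i] + CC_k(l - 1)

maps sorted positions forward: ``a_{k+1}[w_k(i, y_k[i])] = a_k[i]``.
Starting from ``a_0 = identity`` this recovers every prefix array, and
scattering ``y_k`` through ``a_k`` recovers every column of the original
panel exactly.  Stored prefix-array checkpoints (every ``a_stride``
sites) allow reconstruction to start mid-panel and double as a
corruption check.

The on-disk container is little-endian, magic ``MPBWT``, one version
byte, varint-coded run lengths; building it twice from the same panel
yields identical bytes.  Only ``t_k - 1`` of the allele counts are
stored per site — the last one is ``M`` minus the rest.
"""

from __future__ import annotations

import dataclasses
import io
import struct
from typing import Dict, List, Optional

import numpy as np

from .errors import ContainerFormatError, ParameterError
from .panel_io import HaplotypePanel
from .pbwt_core import PBWTState, advance_prefix

__all__ = [
    "TransformedPanel",
    "transform",
    "extend_rank",
    "encode",
    "decode",
    "reconstruct",
    "rle_encode_column",
    "MAGIC",
    "VERSION",
]

MAGIC = b"MPBWT"
VERSION = 1


# -- varints ----------------------------------------------------------------

def _write_uvarint(buf: io.BytesIO, value: int) -> None:
    if value < 0:
        raise ValueError("uvarint cannot encode negatives")
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            buf.write(bytes((byte | 0x80,)))
        else:
            buf.write(bytes((byte,)))
            return


def _read_uvarint(buf: io.BufferedIOBase) -> int:
    shift = 0
    result = 0
    while True:
        raw = buf.read(1)
        if not raw:
            raise ContainerFormatError("truncated container (inside varint)")
        byte = raw[0]
        result |= (byte & 0x7F) << shift
        if not byte & 0x80:
            return result
        shift += 7
        if shift > 63:
            raise ContainerFormatError("varint overflow")


def rle_encode_column(values: np.ndarray) -> bytes:
    """Run-length encode one column: varint run count, then
    (allele, length) varint pairs.  Used both for ``y`` columns and, in
    compressibility comparisons, for raw panel columns."""
    values = np.asarray(values)
    buf = io.BytesIO()
    if values.size == 0:
        _write_uvarint(buf, 0)
        return buf.getvalue()
    change = np.nonzero(np.diff(values))[0] + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.append(starts, values.size))
    _write_uvarint(buf, starts.size)
    for s, ln in zip(starts, lengths):
        _write_uvarint(buf, int(values[s]))
        _write_uvarint(buf, int(ln))
    return buf.getvalue()


def _rle_decode_column(buf: io.BufferedIOBase, M: int) -> np.ndarray:
    n_runs = _read_uvarint(buf)
    out = np.empty(M, dtype=np.int32)
    pos = 0
    for _ in range(n_runs):
        allele = _read_uvarint(buf)
        length = _read_uvarint(buf)
        if length < 1 or pos + length > M:
            raise ContainerFormatError("run lengths do not sum to M")
        out[pos : pos + length] = allele
        pos += length
    if pos != M:
        raise ContainerFormatError("run lengths do not sum to M")
    return out


# -- transformed panel ------------------------------------------------------

@dataclasses.dataclass
class TransformedPanel:
    """The per-site FM-index view of a panel (see module docstring)."""

    M: int
    N: int
    site_alphabet_sizes: np.ndarray
    y: List[np.ndarray]                 # N arrays of length M
    c: List[np.ndarray]                 # N arrays of length t_k
    occ_checkpoints: List[np.ndarray]   # N arrays (n_ckpt, t_k)
    a_checkpoints: Dict[int, np.ndarray]
    occ_stride: int
    a_stride: int

    def cc(self, k: int) -> np.ndarray:
        """Cumulative allele counts CC_k; ``cc[l] = c(0) + ... + c(l)``."""
        return np.cumsum(self.c[k])

    def rank(self, k: int, l: int, i: int) -> int:
        """Occ_k[l][i]: occurrences of allele ``l`` among ``y_k[0..i-1]``,
        answered from the nearest checkpoint plus a short scan."""
        if not 0 <= l < int(self.site_alphabet_sizes[k]):
            raise ParameterError(f"allele {l} outside alphabet at site {k}")
        if not 0 <= i <= self.M:
            raise ParameterError("rank position out of range")
        ck = i // self.occ_stride
        base = int(self.occ_checkpoints[k][ck, l])
        lo = ck * self.occ_stride
        if i > lo:
            base += int(np.count_nonzero(self.y[k][lo:i] == l))
        return base

    def extend(self, k: int, i: int, l: int) -> int:
        """The extension function w_k(i, l) = Occ_k[l][i] + CC_k(l-1)."""
        cc_prev = int(self.cc(k)[l - 1]) if l > 0 else 0
        return self.rank(k, l, i) + cc_prev

    def equals(self, other: "TransformedPanel") -> bool:
        if (self.M, self.N, self.occ_stride, self.a_stride) != (
            other.M,
            other.N,
            other.occ_stride,
            other.a_stride,
        ):
            return False
        if not np.array_equal(self.site_alphabet_sizes, other.site_alphabet_sizes):
            return False
        for k in range(self.N):
            if not (
                np.array_equal(self.y[k], other.y[k])
                and np.array_equal(self.c[k], other.c[k])
                and np.array_equal(self.occ_checkpoints[k], other.occ_checkpoints[k])
            ):
                return False
        if set(self.a_checkpoints) != set(other.a_checkpoints):
            return False
        return all(
            np.array_equal(self.a_checkpoints[k], other.a_checkpoints[k])
            for k in self.a_checkpoints
        )


def extend_rank(occ: np.ndarray, cc: np.ndarray, i: int, l: int) -> int:
    """Dense-matrix form of the extension function.

    ``occ`` is the full ``(t, M+1)`` occurrence matrix of one site
    (``occ[l, i]`` = count of ``l`` among the first ``i`` sorted values),
    ``cc`` its cumulative allele counts.  Returns
    ``occ[l, i] + CC(l - 1)`` with ``CC(-1) = 0``.
    """
    t = occ.shape[0]
    if not 0 <= l < t:
        raise ParameterError(f"allele {l} outside alphabet of size {t}")
    prev = int(cc[l - 1]) if l > 0 else 0
    return int(occ[l, i]) + prev


def dense_occ(y_k: np.ndarray, t_k: int) -> np.ndarray:
    """Full ``(t_k, M+1)`` occurrence matrix of one transformed column."""
    M = y_k.shape[0]
    occ = np.zeros((t_k, M + 1), dtype=np.int64)
    for l in range(t_k):
        occ[l, 1:] = np.cumsum(y_k == l)
    return occ


def _checkpoint_occ(y_k: np.ndarray, t_k: int, stride: int) -> np.ndarray:
    M = y_k.shape[0]
    positions = np.arange(0, M + 1, stride)
    out = np.zeros((positions.size, t_k), dtype=np.int64)
    for l in range(t_k):
        cum = np.cumsum(y_k == l)
        out[1:, l] = cum[positions[1:] - 1]
    return out


def transform(
    panel: HaplotypePanel,
    a_stride: int = 32,
    occ_stride: int = 64,
) -> TransformedPanel:
    """Single sweep producing y, c, checkpointed Occ and prefix arrays."""
    if a_stride < 1 or occ_stride < 1:
        raise ParameterError("checkpoint strides must be >= 1")
    M, N = panel.M, panel.N
    y: List[np.ndarray] = []
    c: List[np.ndarray] = []
    occ_ck: List[np.ndarray] = []
    a_ck: Dict[int, np.ndarray] = {}
    state = PBWTState.initial(M, with_divergence=False)
    for k in range(N):
        if k % a_stride == 0:
            a_ck[k] = state.a.copy()
        t_k = int(panel.site_alphabet_sizes[k])
        y_k = panel.column(k)[state.a].copy()
        y.append(y_k)
        c.append(np.bincount(y_k, minlength=t_k).astype(np.int64))
        occ_ck.append(_checkpoint_occ(y_k, t_k, occ_stride))
        state = advance_prefix(state, panel.column(k), t_k)
    if N % a_stride == 0 or N == 0:
        a_ck[N] = state.a.copy()
    return TransformedPanel(
        M=M,
        N=N,
        site_alphabet_sizes=panel.site_alphabet_sizes.copy(),
        y=y,
        c=c,
        occ_checkpoints=occ_ck,
        a_checkpoints=a_ck,
        occ_stride=occ_stride,
        a_stride=a_stride,
    )


# -- container --------------------------------------------------------------

def encode(tp: TransformedPanel) -> bytes:
    """Serialize to the deterministic .mpbwt container."""
    buf = io.BytesIO()
    buf.write(MAGIC)
    buf.write(bytes((VERSION,)))
    buf.write(struct.pack("<IIII", tp.M, tp.N, tp.a_stride, tp.occ_stride))
    for t_k in tp.site_alphabet_sizes:
        _write_uvarint(buf, int(t_k))
    for k in range(tp.N):
        t_k = int(tp.site_alphabet_sizes[k])
        buf.write(rle_encode_column(tp.y[k]))
        # allele counts: all but the last (recoverable as M - rest)
        for l in range(t_k - 1):
            _write_uvarint(buf, int(tp.c[k][l]))
        # Occ checkpoints: per-block increments, row 0 is always zero
        ck = tp.occ_checkpoints[k]
        for r in range(1, ck.shape[0]):
            for l in range(t_k):
                _write_uvarint(buf, int(ck[r, l] - ck[r - 1, l]))
    _write_uvarint(buf, len(tp.a_checkpoints))
    for k in sorted(tp.a_checkpoints):
        _write_uvarint(buf, k)
        for v in tp.a_checkpoints[k]:
            _write_uvarint(buf, int(v))
    return buf.getvalue()


def decode(data: bytes) -> TransformedPanel:
    """Parse an .mpbwt container back into a :class:`TransformedPanel`."""
    buf = io.BytesIO(data)
    magic = buf.read(len(MAGIC))
    if magic != MAGIC:
        raise ContainerFormatError(f"bad magic {magic!r}, expected {MAGIC!r}")
    vraw = buf.read(1)
    if not vraw:
        raise ContainerFormatError("truncated container (no version byte)")
    version = vraw[0]
    if version != VERSION:
        raise ContainerFormatError(
            f"unsupported container version {version}, expected {VERSION}"
        )
    header = buf.read(16)
    if len(header) != 16:
        raise ContainerFormatError("truncated container header")
    M, N, a_stride, occ_stride = struct.unpack("<IIII", header)
    sizes = np.array([_read_uvarint(buf) for _ in range(N)], dtype=np.int32)
    y: List[np.ndarray] = []
    c: List[np.ndarray] = []
    occ_ck: List[np.ndarray] = []
    n_ckpt = M // occ_stride + 1
    for k in range(N):
        t_k = int(sizes[k])
        y_k = _rle_decode_column(buf, M)
        y.append(y_k)
        counts = np.zeros(t_k, dtype=np.int64)
        for l in range(t_k - 1):
            counts[l] = _read_uvarint(buf)
        rest = M - int(counts[: t_k - 1].sum())
        if rest < 0:
            raise ContainerFormatError(f"site {k}: allele counts exceed M")
        counts[t_k - 1] = rest
        c.append(counts)
        ck = np.zeros((n_ckpt, t_k), dtype=np.int64)
        for r in range(1, n_ckpt):
            for l in range(t_k):
                ck[r, l] = ck[r - 1, l] + _read_uvarint(buf)
        occ_ck.append(ck)
    n_ack = _read_uvarint(buf)
    a_ck: Dict[int, np.ndarray] = {}
    for _ in range(n_ack):
        kk = _read_uvarint(buf)
        a_ck[kk] = np.array(
            [_read_uvarint(buf) for _ in range(M)], dtype=np.int32
        )
    if buf.read(1):
        raise ContainerFormatError("trailing bytes after container payload")
    return TransformedPanel(
        M=M,
        N=N,
        site_alphabet_sizes=sizes,
        y=y,
        c=c,
        occ_checkpoints=occ_ck,
        a_checkpoints=a_ck,
        occ_stride=occ_stride,
        a_stride=a_stride,
    )


# -- reconstruction ---------------------------------------------------------

def reconstruct(tp: TransformedPanel) -> HaplotypePanel:
    """Recover the original panel exactly from the transform.

    Sweeps forward from ``a_0 = identity``: scatter ``y_k`` through
    ``a_k`` into column ``k``, then advance ``a`` with the extension
    function.  Stored prefix-array checkpoints are verified on the way;
    a mismatch means the container is corrupt.
    """
    M, N = tp.M, tp.N
    X = np.empty((M, N), dtype=np.int32)
    a = np.arange(M, dtype=np.int32)
    for k in range(N):
        if k in tp.a_checkpoints and not np.array_equal(a, tp.a_checkpoints[k]):
            raise ContainerFormatError(
                f"prefix-array checkpoint mismatch at site {k}"
            )
        y_k = tp.y[k]
        t_k = int(tp.site_alphabet_sizes[k])
        cc = tp.cc(k)
        if int(cc[-1]) != M:
            raise ContainerFormatError(
                f"site {k}: allele counts do not sum to M"
            )
        X[a, k] = y_k
        # vectorised w_k: within allele l, occupants keep their order and
        # land at CC(l-1) + running occurrence count
        a_next = np.empty_like(a)
        for l in range(t_k):
            idx = np.nonzero(y_k == l)[0]
            if idx.size == 0:
                continue
            base = int(cc[l - 1]) if l > 0 else 0
            if int(cc[l]) - base != idx.size:
                raise ContainerFormatError(
                    f"site {k}: Occ/c inconsistency for allele {l}"
                )
            a_next[base : base + idx.size] = a[idx]
        a = a_next
    if N in tp.a_checkpoints and not np.array_equal(a, tp.a_checkpoints[N]):
        raise ContainerFormatError(
            f"prefix-array checkpoint mismatch at site {N}"
        )
    return HaplotypePanel(
        alleles=X, site_alphabet_sizes=tp.site_alphabet_sizes.copy()
    )
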