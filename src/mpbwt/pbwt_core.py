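"""Positional prefix and divergence arrays for multi-allelic panels.

At each site ``k`` the panel's haplotypes are ordered by their *reversed
prefix* — the string ``x[k-1], x[k-2], ..., x[0]`` — so that haplotypes
sharing the longest suffix-of-prefix sit next to each other.  The prefix
array ``a_k`` holds that ordering; the divergence array ``d_k`` holds, for
each adjacent pair in it, the site where their current match begins.

Moving from site ``k`` to ``k+1`` is a stable t-way counting sort keyed on
the alleles at site ``k``: one bucket per allele code, ascending code
order, within-bucket order preserved.  Divergence values are maintained
with one pending-start value ``p[l]`` per allele, raised to every
divergence value seen since bucket ``l`` last received a haplotype.  The
sweep costs O(t_k + M) per site, i.e. O(N(t+M)) for the prefix arrays
alone and O(tNM) with divergence updates.

Both updates are vectorised: the counting sort via per-allele index
gathers, the divergence update via segmented maxima
(``np.maximum.reduceat``), which is algebraically identical to the scalar
p[] bookkeeping.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, List, Optional, Union

import numpy as np

from .errors import AlphabetViolationError, ParameterError
from .panel_io import HaplotypePanel

__all__ = [
    "PBWTState",
    "advance_prefix",
    "advance_prefix_divergence",
    "sweep",
    "build",
]


@dataclasses.dataclass
class PBWTState:
    """The transform's state after processing sites ``0..k-1``.

    ``a`` is a permutation of ``0..M-1`` listing haplotypes in reversed
    prefix order at ``k``.  ``d[i]`` is the site where the match between
    ``a[i]`` and ``a[i-1]`` begins (``d[0] = k`` as a sentinel: position 0
    in sorted order never extends a block upward).  ``d`` is ``None`` for
    states produced by the prefix-only update.
    """

    k: int
    a: np.ndarray
    d: Optional[np.ndarray] = None

    @classmethod
    def initial(cls, M: int, with_divergence: bool = True) -> "PBWTState":
        """State at k=0: identity order, all matches begin at site 0."""
        d = np.zeros(M, dtype=np.int32) if with_divergence else None
        return cls(k=0, a=np.arange(M, dtype=np.int32), d=d)

    @property
    def M(self) -> int:
        return self.a.shape[0]


def _allele_buckets(keys: np.ndarray, t_k: int) -> List[np.ndarray]:
    """Scan-order index lists per allele; validates the alphabet."""
    if keys.size and (keys.max() >= t_k or keys.min() < 0):
        raise AlphabetViolationError(
            f"allele code outside alphabet of size {t_k}"
        )
    return [np.nonzero(keys == l)[0] for l in range(t_k)]


def advance_prefix(state: PBWTState, column: np.ndarray, t_k: int) -> PBWTState:
    """Stable counting-sort step: ``a_k`` -> ``a_{k+1}``, divergence dropped.

    ``column`` is the full site-``k`` column of the panel in haplotype
    (not sorted) order; the sort key of sorted position ``i`` is
    ``column[a[i]]``.
    """
    column = np.asarray(column)
    keys = column[state.a]
    idx = _allele_buckets(keys, t_k)
    order = np.concatenate(idx) if idx else np.arange(0)
    return PBWTState(k=state.k + 1, a=state.a[order.astype(np.intp)], d=None)


def _segmented_divergence(
    d: np.ndarray, idx: np.ndarray, k: int
) -> np.ndarray:
    """Divergence values for one allele bucket.

    ``idx`` holds the scan positions (ascending) at which this allele
    occurred.  The bucket's first entry gets ``k+1`` (the pending value
    starts above every possible divergence); entry ``m`` gets
    ``max(d[idx[m-1]+1 .. idx[m]])`` — the pending value accumulated since
    the bucket was last reset.
    """
    n = idx.size
    vals = np.empty(n, dtype=d.dtype)
    vals[0] = k + 1
    if n > 1:
        starts = idx[:-1] + 1  # segment [prev+1, cur), may be empty
        ends = idx[1:]
        bounds = np.empty(2 * (n - 1), dtype=np.intp)
        bounds[0::2] = starts
        bounds[1::2] = ends
        # reduceat over interleaved bounds: even slots are our segments;
        # all indices < len(d) because ends are scan positions.
        seg = np.maximum.reduceat(d, bounds)[0::2]
        seg = np.where(starts < ends, seg, np.int64(-1)).astype(d.dtype)
        vals[1:] = np.maximum(seg, d[ends])
    return vals


def advance_prefix_divergence(
    state: PBWTState, column: np.ndarray, t_k: int
) -> PBWTState:
    """One full sweep step: ``(a_k, d_k)`` -> ``(a_{k+1}, d_{k+1})``."""
    if state.d is None:
        raise ParameterError("state has no divergence array")
    column = np.asarray(column)
    k, d = state.k, state.d
    keys = column[state.a]
    idx = _allele_buckets(keys, t_k)
    a_parts: List[np.ndarray] = []
    d_parts: List[np.ndarray] = []
    for bucket in idx:
        if bucket.size == 0:
            continue
        a_parts.append(state.a[bucket])
        d_parts.append(_segmented_divergence(d, bucket, k))
    a_new = np.concatenate(a_parts) if a_parts else state.a[:0]
    d_new = np.concatenate(d_parts) if d_parts else d[:0]
    return PBWTState(k=k + 1, a=a_new, d=d_new)


def sweep(
    panel: HaplotypePanel, with_divergence: bool = True
) -> Iterator[PBWTState]:
    """Yield states k=0..N, advancing one site at a time.

    The first yielded state is the initial one (identity order); state
    ``k`` is valid for scanning site ``k`` of the panel.
    """
    state = PBWTState.initial(panel.M, with_divergence=with_divergence)
    yield state
    step = advance_prefix_divergence if with_divergence else advance_prefix
    for k in range(panel.N):
        try:
            state = step(state, panel.column(k), int(panel.site_alphabet_sizes[k]))
        except AlphabetViolationError as exc:
            raise AlphabetViolationError(f"site {k}: {exc}") from exc
        yield state


def build(
    panel: HaplotypePanel,
    keep: Union[str, int] = "all",
) -> List[PBWTState]:
    """Build prefix/divergence arrays over the whole panel.

    ``keep`` selects which states are retained: ``"all"`` (N+1 states),
    ``"final"`` (the state at k=N only), or an integer stride s keeping
    every state with k % s == 0 plus the final one.  An N=0 panel yields
    only the initial state.
    """
    if isinstance(keep, int):
        if keep < 1:
            raise ParameterError("checkpoint stride must be >= 1")
        stride: Optional[int] = keep
    elif keep in ("all", "final"):
        stride = None
    else:
        raise ParameterError(f"unknown keep policy {keep!r}")

    out: List[PBWTState] = []
    last = None
    for state in sweep(panel):
        last = state
        if keep == "all":
            out.append(state)
        elif stride is not None and state.k % stride == 0:
            out.append(state)
    assert last is not None
    if keep == "final":
        out = [last]
    elif stride is not None and (not out or out[-1].k != last.k):
        out.append(last)
    return out
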