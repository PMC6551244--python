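"""Pairwise match reporting over the sorted panel.

Two kinds of report:

* **long matches** — every maximal shared segment of length >= L between
  any pair of haplotypes, found in a single sweep.  At interior sites a
  match is reported when it terminates, i.e. the pair disagrees at the
  current site; the last site is handled by a dedicated routine so that
  matches running to the end of the panel (including fully identical
  haplotype pairs, which never terminate) are reported too.
* **set-maximal matches** — for each haplotype and each end position, the
  longest match to any other haplotype ending there that can be neither
  extended nor dominated by a longer match ending at the same position.

"Length >= L" is the convention throughout: a segment of exactly L sites
is reported.  All intervals are 0-based half-open ``[start, end)`` in site
units, and records are canonicalized to ``hap_i < hap_j``.
"""

from __future__ import annotations

from typing import Iterable, Iterator, List, NamedTuple, Set, Tuple

import numpy as np

from .errors import ParameterError
from .panel_io import HaplotypePanel
from .pbwt_core import PBWTState, sweep

__all__ = [
    "MatchRecord",
    "long_matches_at",
    "long_matches_last",
    "find_long_matches",
    "iter_long_matches",
    "set_maximal_matches",
    "iter_set_maximal_matches",
    "sort_matches",
]


class MatchRecord(NamedTuple):
    """A shared segment between two haplotypes on ``[start, end)``."""

    hap_i: int
    hap_j: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _record(u: int, v: int, start: int, end: int) -> MatchRecord:
    if u > v:
        u, v = v, u
    return MatchRecord(int(u), int(v), int(start), int(end))


def sort_matches(records: Iterable[MatchRecord]) -> List[MatchRecord]:
    """Canonical report order: by end, start, hap_i, hap_j."""
    return sorted(records, key=lambda r: (r.end, r.start, r.hap_i, r.hap_j))


def _blocks(d: np.ndarray, threshold: int) -> Iterator[Tuple[int, int]]:
    """Maximal runs of sorted positions not separated by d[i] > threshold.

    A value ``d[i] > threshold`` separates positions ``i-1`` and ``i``.
    Yields half-open index ranges ``[i0, i)`` over the sorted order,
    including the final block, which no separator closes.
    """
    M = d.shape[0]
    i0 = 0
    for i in range(1, M):
        if d[i] > threshold:
            yield i0, i
            i0 = i
    yield i0, M


def long_matches_at(
    state: PBWTState, column: np.ndarray, L: int, k: int
) -> List[MatchRecord]:
    """Matches of length >= L terminating at interior site ``k``.

    Within each block of sorted haplotypes whose pairwise matches reach
    back at least to ``k - L`` (no separating divergence value above
    ``k - L``), every pair with *different* alleles at ``k`` terminates
    here and is reported; a block with fewer than two distinct alleles at
    ``k`` yields nothing.  The start of each pair's match is the running
    maximum of divergence values between their sorted positions.
    """
    if L < 1:
        raise ParameterError("minimum match length L must be >= 1")
    d = state.d
    if d is None:
        raise ParameterError("state has no divergence array")
    a = state.a
    y = np.asarray(column)[a]
    out: List[MatchRecord] = []
    for i0, i1 in _blocks(d, k - L):
        if i1 - i0 < 2:
            continue
        block = y[i0:i1]
        # the m[]/s bookkeeping: any two distinct alleles arm reporting
        if np.all(block == block[0]):
            continue
        for p in range(i0, i1 - 1):
            run_max = 0
            for q in range(p + 1, i1):
                if d[q] > run_max:
                    run_max = int(d[q])
                if y[p] != y[q]:
                    out.append(_record(a[p], a[q], run_max, k))
    return out


def long_matches_last(
    state: PBWTState, column: np.ndarray, L: int, N: int
) -> List[MatchRecord]:
    """Matches of length >= L reaching the last site ``k = N-1``.

    Blocks are cut at ``d[i] > k - L + 1`` (shared segment of at least
    L-1 sites before the last one); the allele at the last site then
    decides each pair's fate.  Agreeing pairs run to the panel end and
    are always long enough; disagreeing pairs end at ``N-1`` and are kept
    only if the segment before the last site already has length >= L.
    The final block is flushed even though no separator closes it —
    without this, matches that never terminate (identical haplotypes)
    would be lost.
    """
    if L < 1:
        raise ParameterError("minimum match length L must be >= 1")
    d = state.d
    if d is None:
        raise ParameterError("state has no divergence array")
    k = N - 1
    a = state.a
    y = np.asarray(column)[a]
    out: List[MatchRecord] = []
    for i0, i1 in _blocks(d, k - L + 1):
        for p in range(i0, i1 - 1):
            run_max = 0
            for q in range(p + 1, i1):
                if d[q] > run_max:
                    run_max = int(d[q])
                if y[p] == y[q]:
                    out.append(_record(a[p], a[q], run_max, N))
                elif run_max <= k - L:
                    out.append(_record(a[p], a[q], run_max, k))
    return out


def iter_long_matches(panel: HaplotypePanel, L: int) -> Iterator[MatchRecord]:
    """Stream all maximal pairwise matches of length >= L, one sweep.

    Records arrive grouped by terminating site but otherwise unsorted;
    each unordered pair-interval is emitted exactly once.
    """
    N = panel.N
    if not 1 <= L <= N:
        raise ParameterError(f"L must satisfy 1 <= L <= N (got L={L}, N={N})")
    states = sweep(panel)
    state = next(states)  # k = 0
    for k in range(N):
        column = panel.column(k)
        if k < N - 1:
            yield from long_matches_at(state, column, L, k)
        else:
            yield from long_matches_last(state, column, L, N)
        state = next(states)


def find_long_matches(panel: HaplotypePanel, L: int) -> List[MatchRecord]:
    """All maximal pairwise shared segments of length >= L, sorted."""
    return sort_matches(iter_long_matches(panel, L))


def _set_maximal_at(
    a: np.ndarray, d: np.ndarray, y: np.ndarray, k: int
) -> Set[MatchRecord]:
    """Set-maximal matches terminating at interior site ``k``.

    For sorted position ``i`` the longest matches end-to-date are to the
    neighbours on the side(s) attaining ``min(d[i], d[i+1])``; scanning
    outward while the divergence stays at or below that bound enumerates
    every haplotype attaining it.  If any of them carries the same allele
    at ``k`` the match extends and nothing ends here for ``i``; otherwise
    all of them are reported with end ``k``.  Sentinels ``k+1`` close both
    ends of the sorted order.
    """
    M = a.shape[0]
    sentinel = k + 1

    def dval(pos: int) -> int:
        if pos <= 0 or pos >= M:
            return sentinel
        return int(d[pos])

    out: Set[MatchRecord] = set()
    for i in range(M):
        dl = dval(i)       # start of match to the block below
        dr = dval(i + 1)   # start of match to the block above
        best = min(dl, dr)
        if best >= k:  # zero-length: nothing to report
            continue
        m = i - 1
        n = i + 1
        extendable = False
        if dl <= dr:
            while dval(m + 1) <= dl:
                if y[m] == y[i]:
                    extendable = True
                    break
                m -= 1
        if not extendable and dr <= dl:
            while dval(n) <= dr:
                if y[n] == y[i]:
                    extendable = True
                    break
                n += 1
        if extendable:
            continue
        if dl <= dr:
            for j in range(m + 1, i):
                out.add(_record(a[i], a[j], dl, k))
        if dr <= dl:
            for j in range(i + 1, n):
                out.add(_record(a[i], a[j], dr, k))
    return out


def _set_maximal_end(a: np.ndarray, d: np.ndarray, N: int) -> Set[MatchRecord]:
    """Set-maximal matches running to the panel end.

    At ``k = N`` there is no next allele to extend with, so every
    haplotype's longest match is reported unconditionally — this is the
    end-of-panel case the interior definition misses.
    """
    M = a.shape[0]
    sentinel = N + 1

    def dval(pos: int) -> int:
        if pos <= 0 or pos >= M:
            return sentinel
        return int(d[pos])

    out: Set[MatchRecord] = set()
    for i in range(M):
        dl = dval(i)
        dr = dval(i + 1)
        best = min(dl, dr)
        if best >= N:
            continue
        if dl <= dr:
            m = i - 1
            while dval(m + 1) <= dl:
                m -= 1
            for j in range(m + 1, i):
                out.add(_record(a[i], a[j], dl, N))
        if dr <= dl:
            n = i + 1
            while dval(n) <= dr:
                n += 1
            for j in range(i + 1, n):
                out.add(_record(a[i], a[j], dr, N))
    return out


def iter_set_maximal_matches(panel: HaplotypePanel) -> Iterator[MatchRecord]:
    """Stream set-maximal matches, grouped by end position.

    Within each end position duplicates (the same pair seen from both
    haplotypes' perspectives) are emitted once.
    """
    if panel.M < 2:
        raise ParameterError("set-maximal matching needs at least 2 haplotypes")
    N = panel.N
    states = sweep(panel)
    state = next(states)
    for k in range(N):
        y = panel.column(k)[state.a]
        yield from _set_maximal_at(state.a, state.d, y, k)
        state = next(states)
    yield from _set_maximal_end(state.a, state.d, N)


def set_maximal_matches(panel: HaplotypePanel) -> List[MatchRecord]:
    """All set-maximal matches in the panel, sorted, duplicates removed."""
    return sort_matches(set(iter_set_maximal_matches(panel)))
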