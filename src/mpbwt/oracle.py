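"""Independent brute-force oracles and a bi-allelic reference implementation.

Everything here is deliberately slow and simple: reversed prefixes are
sorted as explicit strings, matches are found by scanning every pair of
haplotypes directly, and the bi-allelic reference follows the classic
two-bucket (a/b, u/v, p/q) formulation with plain Python lists.  These
routines never share code with the production sweep in
:mod:`mpbwt.pbwt_core` / :mod:`mpbwt.matching`; their whole value is that
they can disagree with it.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .matching import MatchRecord, sort_matches
from .panel_io import HaplotypePanel

__all__ = [
    "oracle_sort",
    "oracle_matches",
    "oracle_set_maximal",
    "pair_maximal_segments",
    "BiallelicPBWT",
]


def oracle_sort(panel: HaplotypePanel, k: int) -> Tuple[List[int], List[int]]:
    """Prefix and divergence arrays at site ``k`` by explicit sorting.

    The prefix array is the stable sort of haplotype indices by the
    reversed prefix string ``x[k-1], ..., x[0]``; divergence values come
    from direct longest-common-suffix comparison of the k-prefixes of
    sorted neighbours, with ``d[0] = k``.
    """
    X = panel.alleles
    keys = [tuple(X[i, :k][::-1]) for i in range(panel.M)]
    a = sorted(range(panel.M), key=lambda i: keys[i])
    d = [k]
    for pos in range(1, panel.M):
        u, v = X[a[pos]], X[a[pos - 1]]
        lcs = 0
        while lcs < k and u[k - 1 - lcs] == v[k - 1 - lcs]:
            lcs += 1
        d.append(k - lcs)
    return a, d


def pair_maximal_segments(
    row_u: Sequence[int], row_v: Sequence[int]
) -> List[Tuple[int, int]]:
    """Maximal agreement runs ``[start, end)`` between two haplotypes."""
    N = len(row_u)
    runs: List[Tuple[int, int]] = []
    start = None
    for k in range(N):
        if row_u[k] == row_v[k]:
            if start is None:
                start = k
        elif start is not None:
            runs.append((start, k))
            start = None
    if start is not None:
        runs.append((start, N))
    return runs


def oracle_matches(panel: HaplotypePanel, L: int) -> List[MatchRecord]:
    """All-pairs direct scan for maximal shared segments of length >= L."""
    X = panel.alleles
    out: List[MatchRecord] = []
    for i in range(panel.M):
        for j in range(i + 1, panel.M):
            for start, end in pair_maximal_segments(X[i], X[j]):
                if end - start >= L:
                    out.append(MatchRecord(i, j, start, end))
    return sort_matches(out)


def oracle_set_maximal(panel: HaplotypePanel) -> List[MatchRecord]:
    """Exhaustive per-haplotype set-maximal matches.

    For haplotype ``q``, every maximal shared segment with every other
    haplotype is a candidate; a candidate ``[s, e)`` survives unless some
    other candidate ``[s', e')`` of ``q`` covers it with ``s' <= s`` and
    ``e' >= e`` and is strictly longer on at least one side (a longer
    match ending at the same position, or an equally long one that keeps
    extending).  Ties — several haplotypes attaining the same segment —
    are all kept.
    """
    X = panel.alleles
    N = panel.N
    out: set[MatchRecord] = set()
    for q in range(panel.M):
        cands: List[Tuple[int, int, int]] = []  # (start, end, other)
        for j in range(panel.M):
            if j == q:
                continue
            for s, e in pair_maximal_segments(X[q], X[j]):
                cands.append((s, e, j))
        # A candidate [s, e) is dominated iff another candidate has
        # (s' < s and e' >= e) or (s' == s and e' > e).
        min_start_from: List[int] = [N + 1] * (N + 2)
        max_end_at: Dict[int, int] = {}
        for s, e, _ in cands:
            if s < min_start_from[e]:
                min_start_from[e] = s
            if max_end_at.get(s, -1) < e:
                max_end_at[s] = e
        for e in range(N - 1, -1, -1):
            if min_start_from[e + 1] < min_start_from[e]:
                min_start_from[e] = min_start_from[e + 1]
        for s, e, j in cands:
            if min_start_from[e] < s or max_end_at[s] > e:
                continue
            i, jj = (q, j) if q < j else (j, q)
            out.add(MatchRecord(i, jj, s, e))
    return sort_matches(out)


class BiallelicPBWT:
    """Reference positional BWT for strictly bi-allelic panels.

    An independent re-implementation of the classic two-bucket algorithm
    (arrays ``a``/``b`` with counters ``u``/``v`` for the prefix arrays,
    scalars ``p``/``q`` for the divergence arrays) using plain Python
    lists, including length->=L match reporting with last-site handling
    and set-maximal matching.  Used only as a cross-check that the t-way
    machinery collapses to the bi-allelic algorithm when t = 2.
    """

    def __init__(self, panel: HaplotypePanel):
        if panel.N and panel.site_alphabet_sizes.max() > 2:
            raise ValueError("reference implementation is bi-allelic only")
        self.X: List[List[int]] = [list(map(int, row)) for row in panel.alleles]
        self.M = panel.M
        self.N = panel.N
        self._build()

    def _build(self) -> None:
        M, N, X = self.M, self.N, self.X
        a = list(range(M))
        d = [0] * M
        self.prefix_arrays: List[List[int]] = [list(a)]
        self.divergence_arrays: List[List[int]] = [list(d)]
        self.y_arrays: List[List[int]] = []
        for k in range(N):
            self.y_arrays.append([X[a[i]][k] for i in range(M)])
            za, zb, zd, ze = [], [], [], []
            p = q = k + 1
            for i in range(M):
                if d[i] > p:
                    p = d[i]
                if d[i] > q:
                    q = d[i]
                if X[a[i]][k] == 0:
                    za.append(a[i])
                    zd.append(p)
                    p = 0
                else:
                    zb.append(a[i])
                    ze.append(q)
                    q = 0
            a = za + zb
            d = zd + ze
            self.prefix_arrays.append(list(a))
            self.divergence_arrays.append(list(d))

    # -- matching -----------------------------------------------------

    def _segment_start(self, u: int, v: int, end: int) -> int:
        """Start of the agreement run of haplotypes u, v extending to end."""
        s = end
        while s > 0 and self.X[u][s - 1] == self.X[v][s - 1]:
            s -= 1
        return s

    def long_matches(self, L: int) -> List[MatchRecord]:
        """Pairwise matches of length >= L, reporting at termination sites
        and flushing unterminated blocks at the panel end."""
        M, N = self.M, self.N
        out: List[MatchRecord] = []
        for k in range(N):
            a = self.prefix_arrays[k]
            d = self.divergence_arrays[k]
            y = self.y_arrays[k]
            last = k == N - 1
            cut = (k - L + 1) if last else (k - L)
            i0 = 0
            for i in range(1, M + 1):
                if i < M and d[i] <= cut:
                    continue
                # block [i0, i) closed
                for p in range(i0, i - 1):
                    for q in range(p + 1, i):
                        u, v = a[p], a[q]
                        if last and y[p] == y[q]:
                            start = self._segment_start(u, v, N)
                            if N - start >= L:
                                out.append(
                                    MatchRecord(min(u, v), max(u, v), start, N)
                                )
                        elif y[p] != y[q]:
                            start = self._segment_start(u, v, k)
                            if k - start >= L:
                                out.append(
                                    MatchRecord(min(u, v), max(u, v), start, k)
                                )
                i0 = i
        return sort_matches(out)

    def set_maximal(self) -> List[MatchRecord]:
        """Set-maximal matches via the neighbour scan on (a, d), with the
        panel end treated as a terminating position."""
        M, N = self.M, self.N
        out: set[MatchRecord] = set()
        for k in range(N + 1):
            a = self.prefix_arrays[k]
            d = self.divergence_arrays[k]
            y = self.y_arrays[k] if k < N else None
            sent = k + 1

            def dv(pos: int) -> int:
                return d[pos] if 0 < pos < M else sent

            for i in range(M):
                dl, dr = dv(i), dv(i + 1)
                if min(dl, dr) >= k:
                    continue
                m, n = i - 1, i + 1
                skip = False
                if dl <= dr:
                    while dv(m + 1) <= dl:
                        if y is not None and y[m] == y[i]:
                            skip = True
                            break
                        m -= 1
                if not skip and dr <= dl:
                    while dv(n) <= dr:
                        if y is not None and y[n] == y[i]:
                            skip = True
                            break
                        n += 1
                if skip:
                    continue
                if dl <= dr:
                    for j in range(m + 1, i):
                        u, v = a[i], a[j]
                        out.add(MatchRecord(min(u, v), max(u, v), dl, k))
                if dr <= dl:
                    for j in range(i + 1, n):
                        u, v = a[i], a[j]
                        out.add(MatchRecord(min(u, v), max(u, v), dr, k))
        return sort_matches(out)
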