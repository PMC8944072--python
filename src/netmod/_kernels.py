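"""Hot loops for degree-matched set resampling and per-draw graph statistics.

Every z-score and empirical p-value in the pipeline rests on drawing many
(default 10^4) random gene sets and measuring, per draw, either the induced
largest-connected-component size, the number of edges crossing between two
sampled sets, or the number of edges within one sampled set. The draws are
degree-binned and without replacement, implemented as a partial
Fisher-Yates shuffle per bin whose swaps are undone after each draw so the
bin pools never need copying. Compiled with numba when available; the same
code runs (slowly) as plain Python otherwise.

All randomness is injected as a pre-generated ``(n_draws, k)`` uniform
matrix so determinism is owned by the caller's ``numpy`` Generator.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


STAT_LCC = 0
STAT_CROSS_EDGES = 1
STAT_WITHIN_EDGES = 2


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    # path compression
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def lcc_size_of(indptr, indices, members, label, parent, csize):
    """LCC size of the subgraph induced by ``members`` (node indices).

    ``label``, ``parent``, ``csize`` are full-length scratch arrays; label
    must arrive all-zero and is restored to all-zero before returning.
    """
    k = members.shape[0]
    if k == 0:
        return 0
    for i in range(k):
        v = members[i]
        label[v] = 1
        parent[v] = v
    for i in range(k):
        v = members[i]
        for e in range(indptr[v], indptr[v + 1]):
            w = indices[e]
            if label[w] == 1 and w > v:
                rv = _find(parent, v)
                rw = _find(parent, w)
                if rv != rw:
                    parent[rw] = rv
    best = 1
    for i in range(k):
        r = _find(parent, members[i])
        csize[r] += 1
        if csize[r] > best:
            best = csize[r]
    for i in range(k):
        v = members[i]
        csize[_find(parent, v)] = 0
        label[v] = 0
    return best


@njit(cache=True)
def sampled_statistics(
    indptr, indices, pools, offsets, counts_a, counts_b, rand, stat_code
):
    """Per-draw statistic over degree-binned random sets.

    For each of ``rand.shape[0]`` draws, samples ``counts_a[b]`` set-A and
    ``counts_b[b]`` set-B nodes without replacement from every bin
    ``pools[offsets[b]:offsets[b+1]]`` (A and B disjoint by construction),
    then computes the statistic selected by ``stat_code``:
    ``STAT_LCC`` (induced LCC size of A), ``STAT_CROSS_EDGES`` (edges
    between A and B), ``STAT_WITHIN_EDGES`` (edges inside A).
    """
    n_nodes = indptr.shape[0] - 1
    n_draws = rand.shape[0]
    n_bins = offsets.shape[0] - 1
    k = int(counts_a.sum() + counts_b.sum())
    out = np.zeros(n_draws, np.int64)
    label = np.zeros(n_nodes, np.int8)
    parent = np.empty(n_nodes, np.int64)
    csize = np.zeros(n_nodes, np.int64)
    sample = np.empty(k, np.int64)
    samp_lab = np.empty(k, np.int8)
    swaps = np.empty(k, np.int64)

    for d in range(n_draws):
        # --- draw: partial Fisher-Yates per bin, undone afterwards
        pos = 0
        r = 0
        for b in range(n_bins):
            ca = counts_a[b]
            c = ca + counts_b[b]
            if c == 0:
                continue
            start = offsets[b]
            bin_size = offsets[b + 1] - start
            for j in range(c):
                t = j + int(rand[d, r] * (bin_size - j))
                r += 1
                if t >= bin_size:
                    t = bin_size - 1
                tmp = pools[start + j]
                pools[start + j] = pools[start + t]
                pools[start + t] = tmp
                swaps[j] = t
                sample[pos] = pools[start + j]
                samp_lab[pos] = 1 if j < ca else 2
                pos += 1
            for j in range(c - 1, -1, -1):  # restore pool order
                t = swaps[j]
                tmp = pools[start + j]
                pools[start + j] = pools[start + t]
                pools[start + t] = tmp

        # --- statistic
        if stat_code == STAT_LCC:
            ka = 0
            for i in range(k):
                if samp_lab[i] == 1:
                    sample[ka] = sample[i]
                    ka += 1
            out[d] = lcc_size_of(indptr, indices, sample[:ka], label, parent, csize)
        else:
            for i in range(k):
                label[sample[i]] = samp_lab[i]
            cnt = 0
            if stat_code == STAT_CROSS_EDGES:
                for i in range(k):
                    if samp_lab[i] != 1:
                        continue
                    v = sample[i]
                    for e in range(indptr[v], indptr[v + 1]):
                        if label[indices[e]] == 2:
                            cnt += 1
            else:  # STAT_WITHIN_EDGES
                for i in range(k):
                    if samp_lab[i] != 1:
                        continue
                    v = sample[i]
                    for e in range(indptr[v], indptr[v + 1]):
                        w = indices[e]
                        if label[w] == 1 and w > v:
                            cnt += 1
            out[d] = cnt
            for i in range(k):
                label[sample[i]] = 0
    return out


def induced_lcc_size(indptr, indices, members: np.ndarray) -> int:
    """Observed-set convenience wrapper around :func:`lcc_size_of`."""
    n_nodes = indptr.shape[0] - 1
    label = np.zeros(n_nodes, np.int8)
    parent = np.empty(n_nodes, np.int64)
    csize = np.zeros(n_nodes, np.int64)
    return int(
        lcc_size_of(indptr, indices, np.asarray(members, np.int64), label, parent, csize)
    )
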