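"""Independent straightforward MCL iteration, used only as a test oracle.

Deliberately written as plain loops over a dense matrix, without the
package's pruning/threshold vectorization shortcuts, so that agreement with
``lpscourse.network.MarkovClustering`` is a meaningful cross-check rather
than a tautology.
"""

import numpy as np


def naive_mcl_clusters(adj, inflation, tol=1e-8, max_iter=200, prune=1e-5):
    a = np.array(adj, dtype=float)
    n = a.shape[0]
    for i in range(n):
        a[i, i] = 0.0
    for i in range(n):
        col_max = max(a[j, i] for j in range(n))
        a[i, i] = col_max if col_max > 0 else 1.0
    m = a / a.sum(axis=0)

    for _ in range(max_iter):
        prev = m.copy()
        m = m @ m
        m = m ** inflation
        m = m / m.sum(axis=0)
        m[m < prune] = 0.0
        sums = m.sum(axis=0)
        sums[sums == 0] = 1.0
        m = m / sums
        if np.abs(m - prev).max() < tol:
            break

    groups = []
    for i in range(n):
        if m[i, i] > 1e-9:
            groups.append(set(np.flatnonzero(m[i] > 1e-9)) | {i})
    merged = []
    for group in groups:
        keep = []
        for other in merged:
            if other & group:
                group |= other
            else:
                keep.append(other)
        merged = keep + [group]
    covered = set().union(*merged) if merged else set()
    for i in range(n):
        if i not in covered:
            merged.append({i})
    return sorted(tuple(sorted(c)) for c in merged)
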