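"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the alignment oracle is
a full (unbanded, unseeded) dynamic-programming edit-distance computation,
and the clustering oracle enumerates connected components from an explicit
all-vs-all similarity graph.
"""

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq):
    return seq.translate(_COMPLEMENT)[::-1]


def semiglobal_edit_distance(query, target):
    """Minimum edit distance of the whole query against any target infix.

    Full O(nm) dynamic programme: free leading/trailing gaps in the target,
    the query fully consumed. Row recurrence with a prefix-min scan for the
    left-gap term.
    """
    qa = np.frombuffer(query.encode(), dtype="S1")
    ta = np.frombuffer(target.encode(), dtype="S1")
    m = ta.size
    j = np.arange(m + 1)
    prev = np.zeros(m + 1, dtype=np.int64)
    for i in range(1, qa.size + 1):
        cost = (ta != qa[i - 1]).astype(np.int64)
        mid = np.empty(m + 1, dtype=np.int64)
        mid[0] = i
        mid[1:] = np.minimum(prev[:-1] + cost, prev[1:] + 1)
        prev = np.minimum.accumulate(mid - j) + j
    return int(prev.min())


def best_fragment_identity(fragment, reference):
    """Oracle fragment identity: best of both strands, 1 - dist/len."""
    d_fwd = semiglobal_edit_distance(fragment, reference)
    d_rev = semiglobal_edit_distance(revcomp(fragment), reference)
    return max(0.0, 1.0 - min(d_fwd, d_rev) / len(fragment))


def connected_components(ids, edges):
    """Exhaustive component enumeration by repeated closure."""
    remaining = set(ids)
    components = []
    adjacency = {i: set() for i in ids}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    while remaining:
        start = min(remaining)
        group = {start}
        frontier = {start}
        while frontier:
            frontier = set().union(*(adjacency[g] for g in frontier)) - group
            group |= frontier
        components.append(sorted(group))
        remaining -= group
    return sorted(components)


def window_identity_by_columns(msa, reference_id, window_size=50):
    """Direct per-column window identity count (plain Python loops)."""
    ref = msa[reference_id]
    ref_positions = [i for i, c in enumerate(ref) if c != "-"]
    windows = [
        ref_positions[k : k + window_size]
        for k in range(0, len(ref_positions), window_size)
    ]
    out = {}
    for qid, qseq in msa.items():
        if qid == reference_id:
            continue
        identities = []
        for cols in windows:
            matches = sum(
                1 for c in cols if qseq[c] != "-" and qseq[c] == ref[c]
            )
            identities.append(matches / len(cols))
        out[qid] = identities
    return out
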