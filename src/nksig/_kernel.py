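"""Compiled chamber-indexed direct-method SSA kernel.

One exact Gillespie event loop over the whole lattice: chamber totals are
kept in a binary sum tree (O(log C) chamber selection and update), and
per-chamber channel propensities plus hop totals are maintained
incrementally through a precomputed species->channel adjacency.  All
per-event work is written inline in the main loop (compiled helper-call
overhead dominates at these event rates).  Agreement in law with the
pure-Python reference sampler in :mod:`nksig.engine` is asserted by the
validation suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TYPE_UNI = 1
TYPE_BI = 2
TYPE_HOMO = 3
TYPE_TRANS = 4

# adjacency entry kinds (species -> channel updates)
KIND_UNI = 0
KIND_BI = 1
KIND_HOMO = 2
KIND_TRANS_ENZ = 3

_RESYNC = 4_000_000  # events between full propensity rebuilds (float drift)


@njit(cache=True)
def _channel_prop(r, c, counts, neighbors, n_neighbors,
                  r_type, r_rate, r_s1, r_s2):
    t = r_type[r]
    if t == TYPE_UNI:
        return r_rate[r] * counts[c, r_s1[r]]
    if t == TYPE_BI:
        return r_rate[r] * counts[c, r_s1[r]] * counts[c, r_s2[r]]
    if t == TYPE_HOMO:
        n = counts[c, r_s1[r]]
        return r_rate[r] * n * (n - 1) * 0.5
    tgt = counts[c, r_s2[r]]
    for m in range(n_neighbors[c]):
        tgt += counts[neighbors[c, m], r_s2[r]]
    return r_rate[r] * counts[c, r_s1[r]] * tgt


@njit(cache=True)
def _rebuild(tree, cp, A, H, counts, hopfac, neighbors, n_neighbors,
             r_type, r_rate, r_s1, r_s2):
    C = counts.shape[0]
    S = counts.shape[1]
    R = A.shape[1]
    tree[:] = 0.0
    for c in range(C):
        tot = 0.0
        for r in range(R):
            a = _channel_prop(r, c, counts, neighbors, n_neighbors,
                              r_type, r_rate, r_s1, r_s2)
            A[c, r] = a
            tot += a
        h = 0.0
        for s in range(S):
            h += hopfac[s, c] * counts[c, s]
        H[c] = h
        tree[cp + c] = tot + h
    for i in range(cp - 1, 0, -1):
        tree[i] = tree[2 * i] + tree[2 * i + 1]


@njit(cache=True, fastmath=True)
def run_kernel(counts, neighbors, n_neighbors, hopfac, mask,
               r_type, r_rate, r_s1, r_s2, r_nch, r_chsp, r_chd,
               adj_idx, adj_r, adj_kind, adj_rate, adj_partner,
               tr_idx, tr_r, tr_rate, tr_s1, tr_s2,
               t_end, sample_times, out_totals,
               record_chambers, chamber_out, seed):
    """Run the event loop to ``t_end``; fills ``out_totals`` in place.

    Returns (n_events, absorbed, bad): ``bad`` is -1 on success, else the
    index of an offending channel (invariant violation).
    """
    np.random.seed(seed)
    C = counts.shape[0]
    S = counts.shape[1]
    R = r_type.shape[0]
    cp = 1
    while cp < C:
        cp *= 2
    tree = np.zeros(2 * cp, dtype=np.float64)
    A = np.zeros((C, R), dtype=np.float64)
    H = np.zeros(C, dtype=np.float64)
    _rebuild(tree, cp, A, H, counts, hopfac, neighbors, n_neighbors,
             r_type, r_rate, r_s1, r_s2)
    totals_vec = np.zeros(S, dtype=np.int64)
    for c in range(C):
        for s in range(S):
            totals_vec[s] += counts[c, s]

    # pending count changes of the current event (chamber, species, delta)
    pend_c = np.zeros(4, dtype=np.int64)
    pend_s = np.zeros(4, dtype=np.int64)
    pend_d = np.zeros(4, dtype=np.int64)

    n_samples = sample_times.shape[0]
    i_samp = 0
    t = 0.0
    n_events = 0
    absorbed = 0
    since_rebuild = 0
    bad = -1

    while True:
        total = tree[1]
        if not np.isfinite(total):
            return n_events, absorbed, 0
        if total <= 1e-300:
            absorbed = 1
            while i_samp < n_samples:
                for s in range(S):
                    out_totals[i_samp, s] = totals_vec[s]
                if record_chambers == 1:
                    for c in range(C):
                        for s in range(S):
                            chamber_out[i_samp, c, s] = counts[c, s]
                i_samp += 1
            break
        u = np.random.random()
        dt = -np.log(1.0 - u) / total
        t_next = t + dt
        if i_samp < n_samples and sample_times[i_samp] <= t_next + 1e-12:
            while i_samp < n_samples and sample_times[i_samp] <= t_next + 1e-12:
                for s in range(S):
                    out_totals[i_samp, s] = totals_vec[s]
                if record_chambers == 1:
                    for c in range(C):
                        for s in range(S):
                            chamber_out[i_samp, c, s] = counts[c, s]
                i_samp += 1
        if t_next >= t_end and i_samp >= n_samples:
            break
        t = t_next

        # --- select chamber via tree descent
        u2 = np.random.random() * total
        i = 1
        while i < cp:
            i *= 2
            if u2 > tree[i]:
                u2 -= tree[i]
                i += 1
        c = i - cp
        if c >= C:
            c = C - 1

        # --- select event within chamber: hops first (they dominate)
        hop_sp = -1
        chosen = -1
        if u2 <= H[c]:
            acc = 0.0
            for s in range(S):
                acc += hopfac[s, c] * counts[c, s]
                if u2 <= acc:
                    hop_sp = s
                    break
        else:
            acc = H[c]
            for r in range(R):
                acc += A[c, r]
                if u2 <= acc:
                    chosen = r
                    break
        if hop_sp < 0 and chosen < 0:
            # float mismatch between cached totals and row sums: resync
            _rebuild(tree, cp, A, H, counts, hopfac, neighbors, n_neighbors,
                     r_type, r_rate, r_s1, r_s2)
            since_rebuild = 0
            continue

        # --- stage the count changes of this event
        n_pend = 0
        if hop_sp >= 0:
            s = hop_sp
            na = 0
            for m in range(n_neighbors[c]):
                if mask[s, neighbors[c, m]] == 1:
                    na += 1
            if na == 0:
                _rebuild(tree, cp, A, H, counts, hopfac, neighbors, n_neighbors,
                         r_type, r_rate, r_s1, r_s2)
                since_rebuild = 0
                continue
            k = int(np.random.random() * na)
            if k >= na:
                k = na - 1
            b = -1
            for m in range(n_neighbors[c]):
                bb = neighbors[c, m]
                if mask[s, bb] == 1:
                    if k == 0:
                        b = bb
                        break
                    k -= 1
            pend_c[0] = c
            pend_s[0] = s
            pend_d[0] = -1
            pend_c[1] = b
            pend_s[1] = s
            pend_d[1] = 1
            n_pend = 2
        else:
            r = chosen
            target = c
            if r_type[r] == TYPE_TRANS:
                s2 = r_s2[r]
                wsum = float(counts[c, s2])
                for m in range(n_neighbors[c]):
                    wsum += counts[neighbors[c, m], s2]
                if wsum <= 0.0:
                    _rebuild(tree, cp, A, H, counts, hopfac, neighbors, n_neighbors,
                             r_type, r_rate, r_s1, r_s2)
                    since_rebuild = 0
                    continue
                u3 = np.random.random() * wsum
                accw = float(counts[c, s2])
                if u3 > accw:
                    for m in range(n_neighbors[c]):
                        b = neighbors[c, m]
                        accw += counts[b, s2]
                        if u3 <= accw:
                            target = b
                            break
            for m in range(r_nch[r]):
                pend_c[n_pend] = target
                pend_s[n_pend] = r_chsp[r, m]
                pend_d[n_pend] = r_chd[r, m]
                n_pend += 1

        # --- apply changes with inline incremental propensity updates
        for q in range(n_pend):
            cq = pend_c[q]
            sq = pend_s[q]
            dq = pend_d[q]
            counts[cq, sq] += dq
            totals_vec[sq] += dq
            if counts[cq, sq] < 0:
                return n_events, absorbed, (chosen if chosen >= 0 else R)
            d = hopfac[sq, cq] * dq
            H[cq] += d
            for ii in range(adj_idx[sq], adj_idx[sq + 1]):
                rr = adj_r[ii]
                kind = adj_kind[ii]
                if kind == KIND_BI:
                    new = adj_rate[ii] * counts[cq, sq] * counts[cq, adj_partner[ii]]
                elif kind == KIND_UNI:
                    new = adj_rate[ii] * counts[cq, sq]
                elif kind == KIND_HOMO:
                    nn = counts[cq, sq]
                    new = adj_rate[ii] * nn * (nn - 1) * 0.5
                else:  # trans channel, sq is the enzyme
                    tgt = counts[cq, adj_partner[ii]]
                    for m in range(n_neighbors[cq]):
                        tgt += counts[neighbors[cq, m], adj_partner[ii]]
                    new = adj_rate[ii] * counts[cq, sq] * tgt
                d += new - A[cq, rr]
                A[cq, rr] = new
            i = cp + cq
            while i >= 1:
                tree[i] += d
                i >>= 1
            # sq is the remote target of a trans channel: that channel's
            # propensity changes here and in every lateral neighbour
            for ii in range(tr_idx[sq], tr_idx[sq + 1]):
                rr = tr_r[ii]
                e = tr_s1[ii]
                tgt = counts[cq, sq]
                for m in range(n_neighbors[cq]):
                    tgt += counts[neighbors[cq, m], sq]
                new = tr_rate[ii] * counts[cq, e] * tgt
                i = cp + cq
                dd = new - A[cq, rr]
                A[cq, rr] = new
                while i >= 1:
                    tree[i] += dd
                    i >>= 1
                for m in range(n_neighbors[cq]):
                    bq = neighbors[cq, m]
                    tgt = counts[bq, sq]
                    for mm in range(n_neighbors[bq]):
                        tgt += counts[neighbors[bq, mm], sq]
                    new = tr_rate[ii] * counts[bq, e] * tgt
                    dd = new - A[bq, rr]
                    A[bq, rr] = new
                    i = cp + bq
                    while i >= 1:
                        tree[i] += dd
                        i >>= 1

        n_events += 1
        since_rebuild += 1
        if since_rebuild >= _RESYNC:
            _rebuild(tree, cp, A, H, counts, hopfac, neighbors, n_neighbors,
                     r_type, r_rate, r_s1, r_s2)
            since_rebuild = 0

    return n_events, absorbed, bad
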