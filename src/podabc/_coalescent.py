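"""Discrete-event structured-coalescent kernel.

Simulates unlinked biallelic loci under a demography given as a list of
timed events over a fixed set of populations.  Time runs backward from the
present in generations; within a population of diploid size N the pairwise
coalescence rate is 1/(2N) per generation, so k lineages coalesce at total
rate k(k-1)/(4N).  Waiting times are exact exponentials between events
(piecewise-constant rates).  Each locus receives exactly one mutation placed
uniformly at random on the total branch length of its genealogy; the locus
is retained only if the pooled minor-allele frequency reaches ``min_maf``
(SNP-chip ascertainment), otherwise the whole locus is redrawn.

Event encoding (arrays sorted by time, ties applied in array order):

* type 0 — size change: population ``a`` takes diploid size ``x``.
* type 1 — lineage movement: every lineage currently in population ``a``
  moves to ``b`` with probability ``x`` and to ``c`` otherwise.  A clean
  split is ``x = 1`` with ``b == c``; an admixture pulse into ``a`` uses
  ``c == a``.

The kernel is numba-compiled; all state lives in preallocated arrays.
Status codes: >= 0 success (value = number of ascertainment redraws),
-1 a locus exhausted its redraw budget, -2 lineages can never fully
coalesce under the supplied events (invalid demography).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_RETRY_EXHAUSTED = -1
STATUS_NO_COALESCENCE = -2


@njit(cache=True)
def simulate_loci(samp, init_N, ev_time, ev_type, ev_a, ev_b, ev_c, ev_x,
                  n_loci, min_maf, max_retry, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n_pop = samp.shape[0]
    n_hap = 0
    for p in range(n_pop):
        n_hap += samp[p]
    n_nodes = 2 * n_hap - 1
    n_events = ev_time.shape[0]

    hap = np.zeros((n_loci, n_hap), dtype=np.int8)
    tmrca = np.zeros(n_loci, dtype=np.float64)

    members = np.empty((n_pop, n_hap), dtype=np.int64)
    tmp = np.empty(n_hap, dtype=np.int64)
    k = np.empty(n_pop, dtype=np.int64)
    N = np.empty(n_pop, dtype=np.float64)
    birth = np.empty(n_nodes, dtype=np.float64)
    blen = np.empty(n_nodes, dtype=np.float64)
    child1 = np.empty(n_nodes, dtype=np.int64)
    child2 = np.empty(n_nodes, dtype=np.int64)
    stack = np.empty(n_nodes, dtype=np.int64)

    total_retries = 0
    for locus in range(n_loci):
        accepted = False
        for _attempt in range(max_retry):
            # --- reset state -------------------------------------------------
            idx = 0
            for p in range(n_pop):
                k[p] = 0
                N[p] = init_N[p]
            for p in range(n_pop):
                for _i in range(samp[p]):
                    members[p, k[p]] = idx
                    k[p] += 1
                    birth[idx] = 0.0
                    idx += 1
            t = 0.0
            ei = 0
            next_node = n_hap
            n_active = n_hap

            # --- genealogy ---------------------------------------------------
            while n_active > 1:
                lam = 0.0
                for p in range(n_pop):
                    kp = k[p]
                    if kp > 1:
                        lam += kp * (kp - 1) / (4.0 * N[p])
                if lam > 0.0:
                    w = np.random.exponential(1.0 / lam)
                else:
                    w = np.inf
                if ei < n_events and (lam == 0.0 or t + w >= ev_time[ei]):
                    t = ev_time[ei]
                    if ev_type[ei] == 0:
                        N[ev_a[ei]] = ev_x[ei]
                    else:
                        pa = ev_a[ei]
                        pb = ev_b[ei]
                        pc = ev_c[ei]
                        r = ev_x[ei]
                        kpa = k[pa]
                        for m in range(kpa):
                            tmp[m] = members[pa, m]
                        k[pa] = 0
                        for m in range(kpa):
                            if np.random.random() < r:
                                dest = pb
                            else:
                                dest = pc
                            members[dest, k[dest]] = tmp[m]
                            k[dest] += 1
                    ei += 1
                    continue
                if lam == 0.0:
                    return hap, tmrca, STATUS_NO_COALESCENCE
                t += w
                # choose population proportional to its coalescence rate
                u = np.random.random() * lam
                acc = 0.0
                psel = -1
                for p in range(n_pop):
                    kp = k[p]
                    if kp > 1:
                        acc += kp * (kp - 1) / (4.0 * N[p])
                        if u <= acc:
                            psel = p
                            break
                if psel < 0:
                    for p in range(n_pop - 1, -1, -1):
                        if k[p] > 1:
                            psel = p
                            break
                kp = k[psel]
                i = np.random.randint(0, kp)
                j = np.random.randint(0, kp - 1)
                if j >= i:
                    j += 1
                a = members[psel, i]
                b = members[psel, j]
                blen[a] = t - birth[a]
                blen[b] = t - birth[b]
                child1[next_node] = a
                child2[next_node] = b
                birth[next_node] = t
                members[psel, i] = next_node
                members[psel, j] = members[psel, kp - 1]
                k[psel] = kp - 1
                next_node += 1
                n_active -= 1

            root = next_node - 1

            # --- one mutation, uniform on total branch length ---------------
            total_len = 0.0
            for node in range(root):
                total_len += blen[node]
            u = np.random.random() * total_len
            acc = 0.0
            sel = root - 1
            for node in range(root):
                acc += blen[node]
                if u <= acc:
                    sel = node
                    break
            sp = 0
            stack[sp] = sel
            sp = 1
            d = 0
            while sp > 0:
                sp -= 1
                nd = stack[sp]
                if nd < n_hap:
                    hap[locus, nd] = 1
                    d += 1
                else:
                    stack[sp] = child1[nd]
                    sp += 1
                    stack[sp] = child2[nd]
                    sp += 1

            maf = min(d, n_hap - d) / n_hap
            if maf >= min_maf:
                tmrca[locus] = birth[root]
                accepted = True
                break
            # rejected: clear the row and redraw the locus from scratch
            for h in range(n_hap):
                hap[locus, h] = 0
            total_retries += 1
        if not accepted:
            return hap, tmrca, STATUS_RETRY_EXHAUSTED

    return hap, tmrca, total_retries
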