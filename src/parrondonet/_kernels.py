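"""Compiled inner loop of the round-by-round simulation.

The kernel consumes the graph in CSR form and runs ``rounds`` subject
selections with a single Mersenne-Twister stream seeded once per run.  The
draw order is frozen (and mirrored bit-exactly by the pure-Python reference
engine in :mod:`parrondonet.engine`):

1. subject:   ``i = int(u * n)`` from one uniform ``u``
2. game choice (mixed mode only): one uniform, game A iff ``u < p``
3. game A: neighbor ``j = nbrs[int(u * deg)]`` from one uniform, then one
   pattern variate *only if the pattern is stochastic in the current state*
   (Matthew always; PCRC only when subject capital <= object capital;
   random always; harmony and cooperation never)
4. game B: one uniform compared against the branch win probability

The Matthew rank phi_i = |{k : W_k <= W_i}| / n is maintained with a Fenwick
tree over fitness values (each round changes at most two fitnesses by one
unit), so a rank query costs O(log rounds) instead of O(n).
"""

import numpy as np
from numba import njit

# integer codes shared with engine.py
MODE_A_ONLY = 0
MODE_B_ONLY = 1
MODE_A_PLUS_B = 2

PAT_MATTHEW = 0
PAT_HARMONY = 1
PAT_COOPERATION = 2
PAT_PCRC = 3
PAT_RANDOM = 4


@njit(inline="always")
def _bit_add(bit, pos, val):
    while pos < bit.shape[0]:
        bit[pos] += val
        pos += pos & (-pos)


@njit(inline="always")
def _bit_prefix(bit, pos):
    s = 0
    while pos > 0:
        s += bit[pos]
        pos -= pos & (-pos)
    return s


@njit(cache=True)
def run_kernel(indptr, indices, n, rounds, mode, pattern, p, p1, p2, c0, seed):
    """Simulate one run; returns (capitals, branch1_plays, branch2_plays)."""
    np.random.seed(seed)
    C = np.full(n, c0, dtype=np.int64)
    b1 = np.zeros(n, dtype=np.int64)
    b2 = np.zeros(n, dtype=np.int64)

    # Fenwick tree over fitness W = C - c0 in [-rounds, rounds], 1-based
    use_rank = pattern == PAT_MATTHEW and mode != MODE_B_ONLY
    offset = rounds + 1
    bit = np.zeros(2 * rounds + 2 if use_rank else 1, dtype=np.int64)
    if use_rank:
        _bit_add(bit, offset, n)

    for _ in range(rounds):
        i = np.int64(np.random.random() * n)
        if mode == MODE_A_PLUS_B:
            play_a = np.random.random() < p
        else:
            play_a = mode == MODE_A_ONLY

        if play_a:
            start = indptr[i]
            deg = indptr[i + 1] - start
            j = indices[start + np.int64(np.random.random() * deg)]
            if pattern == PAT_MATTHEW:
                phi = _bit_prefix(bit, C[i] - c0 + offset) / n
                i_pays = not (np.random.random() < phi)
            elif pattern == PAT_HARMONY:
                i_pays = C[i] > C[j]
            elif pattern == PAT_COOPERATION:
                i_pays = True
            elif pattern == PAT_PCRC:
                if C[i] > C[j]:
                    i_pays = True
                else:
                    i_pays = not (np.random.random() < 0.5)
            else:  # PAT_RANDOM: one variate, [0,.25) object pays,
                # [.25,.5) competitive subject pays, [.5,1) cooperative
                i_pays = not (np.random.random() < 0.25)
            if i_pays:
                payer, payee = i, j
            else:
                payer, payee = j, i
            if use_rank:
                _bit_add(bit, C[payer] - c0 + offset, -1)
                _bit_add(bit, C[payer] - c0 + offset - 1, 1)
                _bit_add(bit, C[payee] - c0 + offset, -1)
                _bit_add(bit, C[payee] - c0 + offset + 1, 1)
            C[payer] -= 1
            C[payee] += 1
        else:
            start = indptr[i]
            deg = indptr[i + 1] - start
            s = np.int64(0)
            for idx in range(start, indptr[i + 1]):
                s += C[indices[idx]]
            branch1 = C[i] * deg <= s
            u = np.random.random()
            if branch1:
                b1[i] += 1
                win = u <= p1
            else:
                b2[i] += 1
                win = u <= p2
            delta = 1 if win else -1
            if use_rank:
                _bit_add(bit, C[i] - c0 + offset, -1)
                _bit_add(bit, C[i] - c0 + offset + delta, 1)
            C[i] += delta
    return C, b1, b2


@njit(cache=True)
def run_many_mean_fitness(
    indptr, indices, n, rounds, mode, pattern, p, p1, p2, c0, seed0, n_reps
):
    """Mean fitness d of replicates seeded seed0, seed0+1, ...; one kernel
    call for the whole batch (used for high-replicate oracle comparisons)."""
    d = np.empty(n_reps)
    for r in range(n_reps):
        C, _, _ = run_kernel(
            indptr, indices, n, rounds, mode, pattern, p, p1, p2, c0, seed0 + r
        )
        s = np.int64(0)
        for i in range(n):
            s += C[i] - c0
        d[r] = s / n
    return d
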