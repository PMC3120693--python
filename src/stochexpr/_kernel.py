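"""Numba-jitted inner loop of the delayed stochastic simulation algorithm.

The kernel consumes a flat array encoding of a reaction system (built by
:mod:`stochexpr.delayed_ssa`) and runs the event loop to ``t_stop``.  The
waiting list for delayed products is a binary min-heap keyed on
``(release_time, insertion_sequence)`` so that equal release times are served
first-in-first-out.

Delay encoding per product entry (``d_kind``):
  0 — no delay (product appears when the reaction fires)
  1 — constant delay; ``d_p1`` is the delay in seconds
  2 — gamma-distributed delay; ``d_p1`` is the shape, ``d_p2`` the scale

Status codes returned: 0 ok, 1 negative copy number (invariant violation).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NEGATIVE_COUNT = 1


@njit(cache=True)
def _heap_swap(h_t, h_s, h_c, h_q, i, j):
    h_t[i], h_t[j] = h_t[j], h_t[i]
    h_s[i], h_s[j] = h_s[j], h_s[i]
    h_c[i], h_c[j] = h_c[j], h_c[i]
    h_q[i], h_q[j] = h_q[j], h_q[i]


@njit(cache=True)
def _heap_less(h_t, h_q, i, j):
    if h_t[i] != h_t[j]:
        return h_t[i] < h_t[j]
    return h_q[i] < h_q[j]


@njit(cache=True)
def _heap_push(h_t, h_s, h_c, h_q, n, t, s, c, q):
    h_t[n] = t
    h_s[n] = s
    h_c[n] = c
    h_q[n] = q
    i = n
    while i > 0:
        parent = (i - 1) // 2
        if _heap_less(h_t, h_q, i, parent):
            _heap_swap(h_t, h_s, h_c, h_q, i, parent)
            i = parent
        else:
            break
    return n + 1


@njit(cache=True)
def _heap_pop(h_t, h_s, h_c, h_q, n):
    """Remove the root; root payload must be read *before* calling."""
    n -= 1
    _heap_swap(h_t, h_s, h_c, h_q, 0, n)
    i = 0
    while True:
        left = 2 * i + 1
        right = left + 1
        smallest = i
        if left < n and _heap_less(h_t, h_q, left, smallest):
            smallest = left
        if right < n and _heap_less(h_t, h_q, right, smallest):
            smallest = right
        if smallest == i:
            break
        _heap_swap(h_t, h_s, h_c, h_q, i, smallest)
        i = smallest
    return n


@njit(cache=True)
def run_core(re_idx, re_sto, rates,
             p_start, p_count, p_species, p_sto,
             d_kind, d_p1, d_p2,
             init_counts, t_stop, sample_times, seed):
    """Run the delayed SSA from t = 0 to t_stop.

    Returns (final_counts, sampled_counts, sampled_pending, n_events, status).
    ``sampled_counts[k]`` is the state just before time ``sample_times[k]``
    (left-limit convention); ``sampled_pending`` the per-species totals still
    on the waiting list at that instant.
    """
    np.random.seed(seed)
    n_species = init_counts.shape[0]
    n_reactions = rates.shape[0]
    x = init_counts.copy()
    pending = np.zeros(n_species, dtype=np.int64)

    cap = 64
    h_t = np.empty(cap, dtype=np.float64)
    h_s = np.empty(cap, dtype=np.int64)
    h_c = np.empty(cap, dtype=np.int64)
    h_q = np.empty(cap, dtype=np.int64)
    heap_n = 0
    seq = 0

    n_samples = sample_times.shape[0]
    samp = np.zeros((n_samples, n_species), dtype=np.int64)
    samp_pend = np.zeros((n_samples, n_species), dtype=np.int64)
    si = 0

    props = np.empty(n_reactions, dtype=np.float64)
    t = 0.0
    n_events = 0
    status = STATUS_OK

    while t < t_stop:
        a0 = 0.0
        for r in range(n_reactions):
            a = rates[r]
            for k in range(2):
                sp = re_idx[r, k]
                if sp >= 0:
                    st = re_sto[r, k]
                    if st == 1:
                        a *= x[sp]
                    else:  # at most second order
                        a *= x[sp] * (x[sp] - 1) / 2.0
            props[r] = a
            a0 += a

        t_min = h_t[0] if heap_n > 0 else np.inf

        if a0 <= 0.0:
            # No reaction can fire: pure waiting-list mode, or termination.
            t_event = t_min  # inf when the list is empty
            fire = False
        else:
            t1 = -np.log(np.random.random()) / a0
            if t + t1 < t_min:
                t_event = t + t1
                fire = True
            else:
                # Release precedes the drawn reaction (ties included); the
                # discarded SSA candidate is redrawn next round (memoryless).
                t_event = t_min
                fire = False

        if t_event > t_stop:
            t_event = t_stop
            fire = False
            do_release = False
        else:
            do_release = not fire and heap_n > 0

        # Record samples falling strictly before the event time.
        while si < n_samples and sample_times[si] < t_event:
            for s in range(n_species):
                samp[si, s] = x[s]
                samp_pend[si, s] = pending[s]
            si += 1

        t = t_event
        if not fire and not do_release:
            break  # clamped to t_stop (nothing left to execute before it)

        if fire:
            # Select the reaction by inversion on the propensity vector.
            u = np.random.random() * a0
            acc = 0.0
            r1 = n_reactions - 1
            for r in range(n_reactions):
                acc += props[r]
                if u < acc:
                    r1 = r
                    break
            for k in range(2):
                sp = re_idx[r1, k]
                if sp >= 0:
                    x[sp] -= re_sto[r1, k]
                    if x[sp] < 0:
                        status = STATUS_NEGATIVE_COUNT
                        break
            if status != STATUS_OK:
                break
            for j in range(p_start[r1], p_start[r1] + p_count[r1]):
                kind = d_kind[j]
                if kind == 0:
                    x[p_species[j]] += p_sto[j]
                else:
                    if kind == 1:
                        delay = d_p1[j]
                    else:
                        delay = np.random.gamma(d_p1[j], d_p2[j])
                    if heap_n >= cap:
                        new_cap = cap * 2
                        nh_t = np.empty(new_cap, dtype=np.float64)
                        nh_s = np.empty(new_cap, dtype=np.int64)
                        nh_c = np.empty(new_cap, dtype=np.int64)
                        nh_q = np.empty(new_cap, dtype=np.int64)
                        nh_t[:cap] = h_t
                        nh_s[:cap] = h_s
                        nh_c[:cap] = h_c
                        nh_q[:cap] = h_q
                        h_t, h_s, h_c, h_q = nh_t, nh_s, nh_c, nh_q
                        cap = new_cap
                    heap_n = _heap_push(h_t, h_s, h_c, h_q, heap_n,
                                        t + delay, p_species[j], p_sto[j], seq)
                    seq += 1
                    pending[p_species[j]] += p_sto[j]
            n_events += 1
        elif do_release:
            s = h_s[0]
            c = h_c[0]
            heap_n = _heap_pop(h_t, h_s, h_c, h_q, heap_n)
            x[s] += c
            pending[s] -= c
            n_events += 1

    # Remaining sample times (at or past t_stop boundary) get the final state.
    while si < n_samples:
        for s in range(n_species):
            samp[si, s] = x[s]
            samp_pend[si, s] = pending[s]
        si += 1

    return x, samp, samp_pend, n_events, status
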