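"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration, deliberately
sharing no code with the implementation it checks.
"""

import itertools
import math

import numpy as np


def arc_t_oracle(x, min_width):
    """Exhaustive double loop over all circular arcs: max |t| and its arc.

    Scores every arc [i, j) with both arc and complement holding at least
    ``min_width`` markers using the pooled two-sample t statistic computed
    directly from the two groups.  Ties broken by smallest start, then
    smallest end.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    best_t, best_arc = -1.0, None
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            arc, comp = x[i:j], np.concatenate([x[:i], x[j:]])
            d = arc.mean() - comp.mean()
            ss = float(((arc - arc.mean()) ** 2).sum()
                       + ((comp - comp.mean()) ** 2).sum())
            if ss <= 0.0:
                t = math.inf if abs(d) > 0 else 0.0
            else:
                s = math.sqrt(ss / (n - 2))
                t = abs(d) / (s * math.sqrt(1.0 / k + 1.0 / (n - k)))
            if t > best_t:
                best_t, best_arc = t, (i, j - 1)
    return best_t, best_arc


def perm_p_oracle(x, t_obs, min_width):
    """Exact permutation p-value by enumerating every ordering of x."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    thresh = t_obs * (1.0 - 1e-12) - 1e-15
    count = 0
    total = 0
    for perm in itertools.permutations(x):
        t, _ = arc_t_oracle(np.asarray(perm), min_width)
        if t >= thresh:
            count += 1
        total += 1
    return count / total


def overlap_oracle(a_start, a_end, b_start, b_end):
    """>=1 bp overlap of two 1-based inclusive spans."""
    return max(a_start, b_start) <= min(a_end, b_end)


def sd_undo_oracle(means, sizes, threshold):
    """All terminal boundary sets reachable by any below-threshold removal
    order (merged means recomputed size-weighted).  Returns a set of
    tuples of surviving segment means, rounded for comparability."""
    results = set()

    def recurse(ms, ns):
        gaps = [abs(ms[i + 1] - ms[i]) for i in range(len(ms) - 1)]
        removable = [i for i, g in enumerate(gaps) if g < threshold]
        if not removable:
            results.add(tuple(round(m, 12) for m in ms))
            return
        for i in removable:
            m = (ms[i] * ns[i] + ms[i + 1] * ns[i + 1]) / (ns[i] + ns[i + 1])
            recurse(ms[:i] + [m] + ms[i + 2:], ns[:i] + [ns[i] + ns[i + 1]] + ns[i + 2:])

    recurse(list(means), list(sizes))
    return results
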