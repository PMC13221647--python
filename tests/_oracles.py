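"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by exhaustive enumeration or direct
summation and share no logic with the package's run-length / closed-form
code paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import stats


def brute_force_spans(passes):
    """Maximal cluster windows by enumerating every contiguous window.

    A window [i, j) is valid when it has no failing gene and >= 6 genes, or
    exactly one failing gene at an interior position and >= 8 genes; a valid
    window is reported iff no other valid window strictly contains it.
    """
    n = len(passes)
    valid = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            fails = [k for k in range(i, j) if not passes[k]]
            if not fails and j - i >= 6:
                valid.append((i, j, None))
            elif len(fails) == 1 and j - i >= 8 and i < fails[0] < j - 1:
                valid.append((i, j, fails[0]))
    maximal = [
        w for w in valid
        if not any((v[0], v[1]) != (w[0], w[1]) and v[0] <= w[0] and v[1] >= w[1]
                   for v in valid)
    ]
    return sorted(maximal)


@njit(cache=False)
def _nb_valid_windows(p, starts, stops, gaps):
    n = p.size
    cnt = 0
    for i in range(n):
        fails = 0
        fpos = -1
        for j in range(i, n):
            if p[j] == 0:
                fails += 1
                fpos = j
            length = j - i + 1
            if fails == 0 and length >= 6:
                starts[cnt] = i; stops[cnt] = j + 1; gaps[cnt] = -1; cnt += 1
            elif fails == 1 and length >= 8 and fpos != i and fpos != j:
                starts[cnt] = i; stops[cnt] = j + 1; gaps[cnt] = fpos; cnt += 1
            elif fails >= 2:
                break
    return cnt


@njit(cache=False)
def _nb_maximal(p, out):
    cap = p.size * (p.size + 1) // 2 + 1
    starts = np.empty(cap, np.int32)
    stops = np.empty(cap, np.int32)
    gaps = np.empty(cap, np.int32)
    cnt = _nb_valid_windows(p, starts, stops, gaps)
    m = 0
    for a in range(cnt):
        dominated = False
        for b in range(cnt):
            if (starts[b] <= starts[a] and stops[b] >= stops[a]
                    and not (starts[b] == starts[a] and stops[b] == stops[a])):
                dominated = True
                break
        if not dominated:
            out[m, 0] = starts[a]; out[m, 1] = stops[a]; out[m, 2] = gaps[a]
            m += 1
    return m


def fast_brute_force_spans(pattern: np.ndarray, _out=np.empty((8192, 3), np.int32)):
    """Compiled version of :func:`brute_force_spans` for large sweeps."""
    m = _nb_maximal(np.ascontiguousarray(pattern, dtype=np.uint8), _out)
    return sorted(
        (int(_out[k, 0]), int(_out[k, 1]),
         None if _out[k, 2] < 0 else int(_out[k, 2]))
        for k in range(m)
    )


def binom_two_sided_by_summation(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p by direct pmf summation of both tails."""
    pmf = [float(stats.binom.pmf(x, n, p0)) for x in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2.0 * min(lower, upper))


def all_bit_patterns(n: int) -> np.ndarray:
    """All 2**n pass/fail vectors as a (2**n, n) uint8 array."""
    masks = np.arange(1 << n, dtype=np.uint32)
    return ((masks[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.uint8)
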