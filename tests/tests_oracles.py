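"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_on_stream(fz_stream, threshold, min_sep):
    """Exhaustive peak oracle on a single-channel stream.

    Enumerate strict local maxima over the threshold (first sample of a
    flat maximum), drop those within ``min_sep`` of either edge, then
    iteratively remove the smaller of any pair closer than ``min_sep``.
    """
    t = fz_stream.timestamps
    x = fz_stream.values[:, 0]
    n = x.size
    cand = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if x[i] > x[i - 1] and (j + 1 < n and x[i] > x[j + 1]) and x[i] >= threshold:
            cand.append(i)
        i = j + 1
    cand = [i for i in cand if t[i] - t[0] >= min_sep and t[-1] - t[i] >= min_sep]
    changed = True
    while changed:
        changed = False
        for a in range(len(cand)):
            for b in range(a + 1, len(cand)):
                if abs(t[cand[b]] - t[cand[a]]) < min_sep:
                    cand.pop(a if x[cand[a]] <= x[cand[b]] else b)
                    changed = True
                    break
            if changed:
                break
    idx = sorted(cand)
    return t[idx], x[idx]
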