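"""Independent brute-force reference implementations used as test oracles.

Deliberately written with different mechanics from the package (plain
sample-by-sample walks, no vectorized run-length encoding) so agreement is
meaningful.
"""

from __future__ import annotations


def oracle_bouts_tsk(times, tsk, valid, threshold, cadence):
    """Brute-force scan: list of (kind, start, end, left_cens, right_cens).

    Contract: the state becomes normothermic at the first sample of ≥2
    consecutive valid samples strictly above the threshold, torpid at the
    first sample of ≥2 consecutive samples at-or-below; single samples never
    flip; bouts never span invalid gaps; segment-edge bouts are censored.
    """
    out = []
    n = len(times)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        out.extend(_segment_scan(times, tsk, threshold, cadence, i, j))
        i = j
    return out


def _segment_scan(times, tsk, threshold, cadence, lo, hi):
    if hi - lo < 2:
        return []
    above = [tsk[k] > threshold for k in range(lo, hi)]
    m = len(above)
    # initial state: first pair of equal consecutive states
    state = None
    for k in range(m - 1):
        if above[k] == above[k + 1]:
            state = above[k]
            break
    if state is None:
        return []
    boundaries = [times[lo]]
    kinds = []
    cur = state
    for k in range(m - 1):
        if above[k] != cur and above[k + 1] == above[k]:
            kinds.append("arousal" if cur else "torpor")
            boundaries.append(times[lo + k])
            cur = above[k]
    kinds.append("arousal" if cur else "torpor")
    boundaries.append(times[hi - 1] + cadence)
    bouts = []
    for b in range(len(kinds)):
        bouts.append(
            (
                kinds[b],
                boundaries[b],
                boundaries[b + 1],
                b == 0,
                b == len(kinds) - 1,
            )
        )
    return bouts


def oracle_merge_movements(intervals, merge_gap):
    """Brute-force movement merging: repeatedly join the first mergeable pair."""
    merged = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for k in range(len(merged) - 1):
            if merged[k + 1][0] - merged[k][1] < merge_gap:
                merged[k][1] = merged[k + 1][1]
                del merged[k + 1]
                changed = True
                break
    return [tuple(iv) for iv in merged]
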