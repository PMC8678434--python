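"""Independent brute-force oracles used to validate the package.

These are deliberately written as direct transcriptions of the rules, with
different algorithms from the package implementations, and must stay
independent of the code paths they check.
"""
from __future__ import annotations

import datetime as _dt

# day status codes for diary patterns
ON, OFF, MISSING, UNDEF = "1", "0", ".", "x"


def oracle_segment(pattern: str) -> list[tuple[int, int, int, int]]:
    """Brute-force episode segmentation of a day-status pattern.

    ``pattern[t]`` gives day t's status: '1' flare-on entry, '0' flare-off
    entry, 'x' entry without a flare score, '.' no entry. Starts from each
    flare-on day as its own one-day interval and repeatedly merges a pair
    of consecutive intervals whenever they are adjacent, or separated by
    exactly one intervening day that has no entry, until no merge applies.
    Returns (start, end, n_recorded_flare_days, bridged) tuples.
    """
    intervals = [[t, t] for t, c in enumerate(pattern) if c == ON]
    changed = True
    while changed:
        changed = False
        for j in range(len(intervals) - 1):
            a, b = intervals[j], intervals[j + 1]
            gap_days = list(range(a[1] + 1, b[0]))
            if not gap_days or (len(gap_days) == 1 and pattern[gap_days[0]] == MISSING):
                intervals[j] = [a[0], b[1]]
                del intervals[j + 1]
                changed = True
                break
    out = []
    for start, end in intervals:
        n_on = sum(1 for t in range(start, end + 1) if pattern[t] == ON)
        out.append((start, end, n_on, (end - start + 1) - n_on))
    return out
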