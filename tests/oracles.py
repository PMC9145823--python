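"""Independent brute-force oracles the implementation is checked against.

These deliberately restate the detection rules from scratch — plain
loops over the written-out rule table — and never call the package's
own logic.
"""

from __future__ import annotations

from collections import Counter


def brute_force_groups(votes, gap_threshold):
    """Split a sorted vote multiset at every gap > gap_threshold; report
    each group's most-voted row, ties to the smaller row."""
    vs = sorted(votes)
    if not vs:
        return []
    groups = [[vs[0]]]
    for a, b in zip(vs, vs[1:]):
        if b - a > gap_threshold:
            groups.append([])
        groups[-1].append(b)
    walls = []
    for g in groups:
        cnt = Counter(g)
        top = max(cnt.values())
        walls.append(min(r for r, c in cnt.items() if c == top))
    return walls


def brute_force_new_particles(previous, current, tol=1.0):
    """Rule table for repeat suppression, spelled out case by case.

    previous/current are lists of (row, col) already rounded to 0.1 px.
    Returns the NEW subset of current (duplicates collapsed), in order.
    Rules: (i) row farther than tol from every previous row -> NEW;
    (ii) column changed while the row is outside tol of the matched
    previous row -> NEW (subsumed by (i)); (iii) exactly identical
    (row, col) -> NEW (a real particle cannot be stationary).  A row
    within tol of a previous row with a different position -> repeat.
    """
    seen = []
    for p in current:
        if p not in seen:
            seen.append(p)
    new = []
    for r, c in seen:
        exact = any(r == pr and c == pc for pr, pc in previous)
        row_isolated = all(abs(r - pr) > tol for pr, pc in previous)
        if exact or row_isolated:
            new.append((r, c))
    return new
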