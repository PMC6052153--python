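"""Independent reference implementations used as test oracles.

Deliberately naive: each recomputes a quantity by direct enumeration or
a textbook formulation, sharing no code with the package internals.
"""

from functools import lru_cache

_NEG = -1.0e9


def bruteforce_affine_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal global alignment score by plain 3-state recursion with
    memoisation; gap of length L costs gap_open + L * gap_extend."""
    go = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "S" else _NEG
        best = _NEG
        if state == "M" and i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            best = max(f(i - 1, j - 1, st) for st in "SMXY") + s
        elif state == "X" and i > 0:
            best = max(
                f(i - 1, j, "X") + gap_extend,
                max(f(i - 1, j, st) for st in "SMY") + go,
            )
        elif state == "Y" and j > 0:
            best = max(
                f(i, j - 1, "Y") + gap_extend,
                max(f(i, j - 1, st) for st in "SMX") + go,
            )
        return best

    result = max(f(len(a), len(b), st) for st in "MXY")
    f.cache_clear()
    return result


def components_oracle(labels: list[str], matrix, threshold: float) -> set[frozenset]:
    """Connected components of the graph joining pairs strictly below
    the threshold, by depth-first search."""
    n = len(labels)
    seen = [False] * n
    comps = set()
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = set()
        while stack:
            v = stack.pop()
            if seen[v]:
                continue
            seen[v] = True
            comp.add(labels[v])
            for w in range(n):
                if w != v and not seen[w] and matrix[v][w] < threshold:
                    stack.append(w)
        comps.add(frozenset(comp))
    return comps


def count_p_oracle(a: str, b: str) -> tuple[int, int]:
    """(mismatches, compared sites) by direct per-column inspection."""
    sites = 0
    diffs = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            sites += 1
            if x != y:
                diffs += 1
    return diffs, sites


def apply_indels(reference: str, ref_offset: int, ref_end: int, events) -> str:
    """Reconstruct the gap-free partial's indel structure by replaying
    called events onto the aligned reference interval."""
    segment = reference[ref_offset - 1 : ref_end]
    out = []
    pos = ref_offset  # 1-based reference coordinate of segment[cursor]
    cursor = 0
    for ev in sorted(events, key=lambda e: e.ref_position):
        upto = ev.ref_position - (ref_offset - 1)
        out.append(segment[cursor:upto])
        cursor = upto
        if ev.kind == "insertion":
            out.append(ev.residues)
        else:
            cursor += ev.length
    out.append(segment[cursor:])
    return "".join(out)
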