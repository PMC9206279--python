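"""Brute-force enumeration oracle for the equal-stem topology parse.

Independent of the library implementation: enumerates stem placements by
depth-first search over sequence positions (one stem per maximal G-run,
contiguous run windows, terminal stems anchored at the window's outer run
edges, every loop 1-12 nt) and collects every admissible placement
explicitly.  The library instead prunes with forward/backward reachability
over offset domains; agreement between the two is the correctness check.
"""

from __future__ import annotations

import re
from typing import Optional

Q_MAX = 8
LOOP_MAX = 12
STEMS_MIN = 4
STEMS_MAX = 12


def g_runs(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end() - m.start()) for m in re.finditer(r"[gG]+", seq)]


def oracle_parse(seq: str) -> Optional[tuple[int, int, int, int, int]]:
    """(q, n_stems, window_start, loop_min, loop_max) or None."""
    runs = g_runs(seq)
    n = len(runs)
    best_key = None
    best_val = None
    for k in range(STEMS_MIN, min(STEMS_MAX, n) + 1):
        for i in range(n - k + 1):
            win = runs[i : i + k]
            q = min(Q_MAX, min(length for _, length in win))
            placements: list[tuple[int, ...]] = []

            def dfs(j: int, prev_end: int, loops: list[int]) -> None:
                if j == k:
                    placements.append(tuple(loops))
                    return
                start_j, len_j = win[j]
                if j == 0:
                    offsets = [0]
                elif j == k - 1:
                    offsets = [len_j - q]
                else:
                    offsets = range(len_j - q + 1)
                for o in offsets:
                    stem_start = start_j + o
                    if j > 0:
                        loop = stem_start - prev_end
                        if not 1 <= loop <= LOOP_MAX:
                            continue
                        loops.append(loop)
                    dfs(j + 1, stem_start + q, loops)
                    if j > 0:
                        loops.pop()

            dfs(0, -1, [])
            if not placements:
                continue
            key = (q, -k, -win[0][0])
            if best_key is None or key > best_key:
                best_key = key
                lmin = min(min(p) for p in placements)
                lmax = max(max(p) for p in placements)
                best_val = (q, k, win[0][0], lmin, lmax)
    return best_val
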