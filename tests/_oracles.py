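"""Brute-force enumeration oracles for co-occurrence pairs and runs.

Deliberately naive, dict-based, per-pixel Python loops — structurally
independent of the vectorized implementations they check.
"""

from __future__ import annotations


def brute_diff_hist(levels, mask, offset, ng):
    """Difference histogram by ordered pair enumeration over +/- offset.

    ``levels``/``mask`` are 2-D sequences; returns (probs dict k->p,
    pair_count). Pairs must have both members inside the mask.
    """
    h, w = len(levels), len(levels[0])
    dr, dc = offset
    tallies: dict[int, int] = {}
    pairs = 0
    for r in range(h):
        for c in range(w):
            if not mask[r][c]:
                continue
            for sr, sc in ((dr, dc), (-dr, -dc)):
                r2, c2 = r + sr, c + sc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2][c2]:
                    k = abs(levels[r][c] - levels[r2][c2])
                    tallies[k] = tallies.get(k, 0) + 1
                    pairs += 1
    probs = {k: v / pairs for k, v in tallies.items()} if pairs else {}
    return probs, pairs


def brute_runs(levels, mask, offset):
    """Run counts {(level, length): n} by walking every maximal run.

    A pixel starts a run when its predecessor along the (primitive)
    offset is out of bounds, outside the mask, or holds another level.
    """
    h, w = len(levels), len(levels[0])
    dr, dc = offset

    def inside(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r][c]

    counts: dict[tuple[int, int], int] = {}
    for r in range(h):
        for c in range(w):
            if not mask[r][c]:
                continue
            pr, pc = r - dr, c - dc
            if inside(pr, pc) and levels[pr][pc] == levels[r][c]:
                continue  # not a run start
            length = 1
            nr, nc = r + dr, c + dc
            while inside(nr, nc) and levels[nr][nc] == levels[r][c]:
                length += 1
                nr, nc = nr + dr, nc + dc
            key = (levels[r][c], length)
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_lre(counts):
    """Long-run emphasis from a {(level, length): n} run-count dict."""
    num = sum(k * k * n for (_, k), n in counts.items())
    den = sum(counts.values())
    return num / den
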