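"""Independent brute-force oracles, deliberately written from the
definitions rather than sharing any code path with the package.

* ``oracle_scan`` restates the perfect-SSR definition: a maximal
  p-periodic run over {A,C,G,T} with at least the per-period number of
  complete units, reported at the smallest period of the tract, with
  explicit suppression of candidates contained in a smaller-period locus.
* The bitmap helpers realise interval arithmetic as per-base boolean
  arrays.
"""

from __future__ import annotations

ACGT = set("ACGT")
DEFAULT_MIN_UNITS = (12, 7, 5, 4, 4, 4)


def _smallest_period_bruteforce(tract: str) -> int:
    for q in range(1, len(tract) + 1):
        if all(tract[k] == tract[k - q] for k in range(q, len(tract))):
            return q
    return len(tract)


def oracle_scan(seq: str, min_units=DEFAULT_MIN_UNITS, max_period: int = 6):
    """All (start, end, period) perfect SSR loci per the definition."""
    n = len(seq)
    kept = []
    for p in range(1, max_period + 1):
        for a in range(n - p):
            # left-maximal at period p?
            if a > 0 and seq[a - 1] in ACGT and seq[a - 1] == seq[a - 1 + p]:
                continue
            if any(seq[a + k] not in ACGT for k in range(p)):
                continue
            b = a + p
            while b < n and seq[b] in ACGT and seq[b] == seq[b - p]:
                b += 1
            if b == a + p:
                continue  # no repetition at all
            if (b - a) // p < min_units[p - 1]:
                continue
            if _smallest_period_bruteforce(seq[a:b]) != p:
                continue
            kept.append((a, b, p))
    # explicit containment suppression (smaller-period locus wins)
    out = [
        (a, b, p)
        for (a, b, p) in kept
        if not any(
            q < p and a2 <= a and b <= b2 and (a2, b2, q) != (a, b, p)
            for (a2, b2, q) in kept
        )
    ]
    return sorted(out)


# ---------------------------------------------------------------------------
# per-base bitmap interval oracle


def bitmap(intervals, length: int):
    bits = [False] * length
    for s, e in intervals:
        for i in range(max(0, s), min(length, e)):
            bits[i] = True
    return bits


def bits_to_intervals(bits):
    out = []
    start = None
    for i, b in enumerate(bits):
        if b and start is None:
            start = i
        elif not b and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(bits)))
    return out


def bitmap_subtract(a, b, length: int):
    ba, bb = bitmap(a, length), bitmap(b, length)
    return bits_to_intervals([x and not y for x, y in zip(ba, bb)])


def bitmap_intersect(a, b, length: int):
    ba, bb = bitmap(a, length), bitmap(b, length)
    return bits_to_intervals([x and y for x, y in zip(ba, bb)])


def bitmap_complement(a, length: int):
    return bits_to_intervals([not x for x in bitmap(a, length)])


def bitmap_overlaps(intervals, start: int, end: int, length: int) -> bool:
    bits = bitmap(intervals, length)
    return any(bits[i] for i in range(max(0, start), min(length, end)))
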