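"""Small shared helpers: sequence utilities and interval arithmetic."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted minimal set."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def complement_intervals(
    intervals: list[tuple[int, int]], length: int, pad: int = 0, min_len: int = 1
) -> list[tuple[int, int]]:
    """Half-open intervals of [0, length) not covered by ``intervals``.

    Each uncovered interval is widened by ``pad`` on both sides (clipped to the
    sequence) so that features abutting a covered region are not lost.
    """
    covered = merge_intervals(intervals)
    out = []
    cursor = 0
    for s, e in covered + [(length, length)]:
        if s > cursor:
            a, b = max(0, cursor - pad), min(length, s + pad)
            if b - a >= min_len:
                out.append((a, b))
        cursor = max(cursor, e)
    return out


def overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the overlap of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
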