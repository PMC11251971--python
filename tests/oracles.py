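"""Independent brute-force oracles the implementation is checked against.

These deliberately use naive loop-based algorithms (no shared code paths
with the package internals beyond numpy arithmetic).
"""

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def brute_window_mean(profile, window: int, step: int):
    """NaN-excluding running mean, one python loop per window."""
    out = []
    for start in range(0, len(profile) - window + 1, step):
        vals = [v for v in profile[start:start + window] if not math.isnan(v)]
        out.append(sum(vals) / len(vals) if vals else float("nan"))
    return out


def brute_best_identity(seq: str, query_start: int, w: int, strand: str):
    """Best ungapped identity of the query window anywhere else.

    Returns (identity, forward-strand match start) or (0.0, -1) when no
    non-overlapping candidate exists. N matches nothing.
    """
    L = len(seq)
    query = seq[query_start:query_start + w]
    target = seq if strand == "direct" else revcomp(seq)
    best, best_start = -1, -1
    for c in range(L - w + 1):
        fwd = c if strand == "direct" else L - c - w
        if fwd > query_start - w and fwd < query_start + w:
            continue  # overlaps query
        cand = target[c:c + w]
        count = sum(1 for a, b in zip(query, cand)
                    if a == b and a != "N")
        if count > best:
            best, best_start = count, fwd
    if best < 0:
        return 0.0, -1
    return best / w, best_start


def brute_pixel_means(positions, values, region, width_px: int):
    """Per-pixel mean of values with centers inside each pixel span."""
    start, end = region
    bpp = (end - start) / width_px
    out = []
    for j in range(width_px):
        lo = start + j * bpp
        hi = start + (j + 1) * bpp
        got = [v for p, v in zip(positions, values)
               if lo <= p < hi and not math.isnan(v) and start <= p < end]
        # the last pixel's upper edge is inclusive of end-start rounding
        out.append(sum(got) / len(got) if got else float("nan"))
    return out


def brute_gc_skew(seq: str, window: int, step: int):
    out = []
    for start in range(0, len(seq) - window + 1, step):
        win = seq[start:start + window]
        g, c = win.count("G"), win.count("C")
        out.append((g - c) / (g + c) if g + c else float("nan"))
    return out


def brute_at_content(seq: str, window: int, step: int):
    out = []
    for start in range(0, len(seq) - window + 1, step):
        win = seq[start:start + window]
        out.append((win.count("A") + win.count("T")) / window)
    return out
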