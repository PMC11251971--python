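"""Global direct- and inverted-repeat lanes.

For each query window (default 100 bp) the best ungapped (Hamming) identity
against every other same-length window of the sequence — on the same strand
(direct) or the reverse complement (inverted) — is binned to an integer
0-9: bin 9 means more than 90% identity, bin 0 less than 10%.

Candidate windows sharing any base with the query interval are excluded
(otherwise every query matches itself at identity 1). N never matches
anything, on either side.

Two search paths are provided and must agree exactly:

* ``exhaustive`` — vectorised scan of every candidate window; the ground
  truth, O(n * w) per query.
* ``seeded`` — the query is cut into ``floor(w / seed)`` non-overlapping
  seed blocks; exact seed hits propose candidate diagonals which are fully
  verified. By the pigeonhole principle this finds every candidate with
  fewer than ``floor(w / seed)`` mismatches, so whenever the seeded best is
  that good it is provably optimal; otherwise the exhaustive scan runs as a
  fallback (skipped only with ``approximate=True``, which then reports a
  lower bound for the low bins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .scales import encode
from .seqio import SequenceRecord
from .tracks import Track

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100
DEFAULT_SEED = 12


def bin_identity(identity: float) -> int:
    """Bin a fractional identity to 0-9: min(floor(identity * 10), 9)."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity {identity} outside [0, 1]")
    # tiny epsilon so exact rationals like 30/100 do not floor down a bin
    return min(int(math.floor(identity * 10 + 1e-9)), 9)


@dataclass(frozen=True)
class RepeatHit:
    """Best match elsewhere in the sequence for one query window."""

    query_center: int
    best_identity: float
    bin: int
    match_start: int  # forward-strand start of the matching window; -1 if none
    match_strand: str  # 'direct' or 'inverted'


def _encode_two_sided(seq: SequenceRecord) -> tuple[np.ndarray, np.ndarray]:
    """Query-side and target-side encodings where N never equals anything."""
    codes = encode(seq)
    q = np.where(codes == 4, -1, codes).astype(np.int8)
    t = np.where(codes == 4, -2, codes).astype(np.int8)
    return q, t


def _candidate_windows(t_codes: np.ndarray, w: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(t_codes, w)


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out >= 0
    out[acgt] = 3 - out[acgt]
    return out


class RepeatSearcher:
    """Reusable per-sequence search state (window views and seed indexes)."""

    def __init__(self, seq: SequenceRecord, window: int = DEFAULT_WINDOW,
                 seed: int = DEFAULT_SEED):
        self.seq = seq
        self.window = window
        self.seed = min(seed, window)
        self.length = seq.length
        q, t = _encode_two_sided(seq)
        self.q_codes = q
        self.targets = {"direct": t, "inverted": _rc_codes(t)}
        self._windows: dict[str, np.ndarray] = {}
        self._seed_index: dict[str, dict[int, list[int]]] = {}

    def windows(self, strand: str) -> np.ndarray:
        if strand not in self._windows:
            self._windows[strand] = _candidate_windows(self.targets[strand],
                                                       self.window)
        return self._windows[strand]

    def seed_index(self, strand: str) -> dict[int, list[int]]:
        if strand not in self._seed_index:
            index: dict[int, list[int]] = {}
            t = self.targets[strand].tolist()
            s = self.seed
            code = 0
            ok = 0
            mod = 4 ** s
            for i, v in enumerate(t):
                code = (code * 4 + (v if v >= 0 else 0)) % mod
                ok = ok + 1 if v >= 0 else 0
                if i >= s - 1 and ok >= s:
                    index.setdefault(code, []).append(i - s + 1)
            self._seed_index[strand] = index
        return self._seed_index[strand]

    # -- candidate geometry --------------------------------------------------

    def _overlap_mask(self, query_start: int, strand: str) -> np.ndarray:
        """True where a candidate start overlaps the query in original coords."""
        w, L = self.window, self.length
        n_cand = L - w + 1
        starts = np.arange(n_cand)
        if strand == "direct":
            fwd_starts = starts
        else:
            # candidate at rc-position c covers original [L - c - w, L - c)
            fwd_starts = L - starts - w
        return (fwd_starts > query_start - w) & (fwd_starts < query_start + w)

    def _match_start_original(self, cand_start: int, strand: str) -> int:
        if strand == "direct":
            return cand_start
        return self.length - cand_start - self.window

    # -- exhaustive ----------------------------------------------------------

    def best_match_exhaustive(self, query_start: int, strand: str) -> RepeatHit:
        w, L = self.window, self.length
        query = self.q_codes[query_start:query_start + w]
        center = query_start + w // 2
        if L < 2 * w:
            logger.info("sequence shorter than 2 windows: no non-overlapping "
                        "placement for query at %d", query_start)
            return RepeatHit(center, 0.0, 0, -1, strand)
        counts = (self.windows(strand) == query).sum(axis=1)
        counts[self._overlap_mask(query_start, strand)] = -1
        best = int(np.argmax(counts))
        if counts[best] < 0:
            return RepeatHit(center, 0.0, 0, -1, strand)
        ident = counts[best] / w
        return RepeatHit(center, float(ident), bin_identity(ident),
                         self._match_start_original(best, strand), strand)

    # -- seeded --------------------------------------------------------------

    def best_match_seeded(self, query_start: int, strand: str,
                          approximate: bool = False) -> RepeatHit:
        w, L, s = self.window, self.length, self.seed
        center = query_start + w // 2
        if L < 2 * w:
            logger.info("sequence shorter than 2 windows: no non-overlapping "
                        "placement for query at %d", query_start)
            return RepeatHit(center, 0.0, 0, -1, strand)
        n_blocks = w // s
        query = self.q_codes[query_start:query_start + w]
        index = self.seed_index(strand)
        cand: set[int] = set()
        for b in range(n_blocks):
            off = b * s
            block = query[off:off + s]
            if np.any(block < 0):
                continue
            code = 0
            for v in block:
                code = code * 4 + int(v)
            for pos in index.get(code, ()):
                diag = pos - off
                if 0 <= diag <= L - w:
                    cand.add(diag)
        overlap = self._overlap_mask(query_start, strand)
        windows = self.windows(strand)
        best_count, best_start = -1, -1
        for c in sorted(cand):
            if overlap[c]:
                continue
            count = int((windows[c] == query).sum())
            if count > best_count:
                best_count, best_start = count, c
        # the seed scheme provably finds every candidate with < n_blocks
        # mismatches; anything worse needs the exhaustive fallback
        if best_count >= 0 and (w - best_count) < n_blocks:
            ident = best_count / w
            return RepeatHit(center, float(ident), bin_identity(ident),
                             self._match_start_original(best_start, strand),
                             strand)
        if approximate:
            ident = max(best_count, 0) / w
            start = (self._match_start_original(best_start, strand)
                     if best_start >= 0 else -1)
            return RepeatHit(center, float(ident), bin_identity(ident),
                             start, strand)
        return self.best_match_exhaustive(query_start, strand)


def best_match(seq: SequenceRecord, query_start: int, window: int = DEFAULT_WINDOW,
               strand: str = "direct", method: str = "seeded",
               approximate: bool = False, seed: int = DEFAULT_SEED) -> RepeatHit:
    """Best non-overlapping ungapped match for one query window."""
    if strand not in ("direct", "inverted"):
        raise ValueError(f"strand must be 'direct' or 'inverted', got {strand!r}")
    if not 0 <= query_start <= seq.length - window:
        raise ValueError("query window outside sequence")
    searcher = RepeatSearcher(seq, window=window, seed=seed)
    if method == "exhaustive":
        return searcher.best_match_exhaustive(query_start, strand)
    return searcher.best_match_seeded(query_start, strand, approximate=approximate)


def repeat_hits(seq: SequenceRecord, window: int = DEFAULT_WINDOW,
                step: int | None = None, strand: str = "direct",
                method: str = "seeded", approximate: bool = False,
                seed: int = DEFAULT_SEED) -> list[RepeatHit]:
    if strand not in ("direct", "inverted"):
        raise ValueError(f"strand must be 'direct' or 'inverted', got {strand!r}")
    if window > seq.length:
        raise ValueError("window exceeds sequence")
    step = step or window
    searcher = RepeatSearcher(seq, window=window, seed=seed)
    hits = []
    for qs in range(0, seq.length - window + 1, step):
        if method == "exhaustive":
            hits.append(searcher.best_match_exhaustive(qs, strand))
        else:
            hits.append(searcher.best_match_seeded(qs, strand,
                                                   approximate=approximate))
    return hits


def repeat_track(seq: SequenceRecord, window: int = DEFAULT_WINDOW,
                 step: int | None = None, strand: str = "direct",
                 method: str = "seeded", approximate: bool = False,
                 seed: int = DEFAULT_SEED) -> Track:
    """Track of repeat bins, one per query window.

    With the default 100-bp window the first value sits at 50 bp and the
    last within 50 bp of the sequence end.
    """
    step = step or window
    hits = repeat_hits(seq, window=window, step=step, strand=strand,
                       method=method, approximate=approximate, seed=seed)
    name = f"{strand}_repeats"
    return Track(name=name, values=np.array([h.bin for h in hits], dtype=float),
                 window=window, step=step, units="identity bin 0-9")
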