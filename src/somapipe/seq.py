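"""Sequence primitives: gap-free local alignment, DUST low-complexity scoring,
k-mer decomposition and exact-match scanning.

The aligner is deliberately gap-free (seed-and-extend with match +1 /
mismatch -1): every rule it backs downstream — perfect-match read support,
100%-identity misalignment detection, >99%-identity breakpoint overhangs,
contig-vs-chimera comparison — is phrased in terms of contiguous matching
bases, so affine gaps would add nothing but ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LocalAlignment:
    """A maximal gap-free aligned segment.

    ``query_start/query_end`` and ``target_start/target_end`` are half-open
    spans of equal length (gap-free core). ``identity = matches / aligned_length``
    and ``aligned_length = matches + mismatches``.
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    matches: int
    mismatches: int

    @property
    def aligned_length(self) -> int:
        return self.matches + self.mismatches

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length

    @property
    def score(self) -> int:
        return self.matches - self.mismatches


def _check_seq(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"empty input: {name}")


def local_align(query: str, target: str, min_seed: int = 11) -> list[LocalAlignment]:
    """All per-diagonal maximal gap-free alignments seeded by exact ``min_seed``-mers.

    For every diagonal carrying at least one exact ``min_seed``-mer match, the
    single maximal-scoring segment (match +1, mismatch -1; leftmost on ties) is
    reported if its ``aligned_length >= min_seed`` and its score is positive.
    With ``min_seed == 1`` every diagonal is scanned, so the top score equals
    the exhaustive gap-free Smith-Waterman optimum.

    Results are sorted by (score desc, target_start asc, query_start asc).
    """
    _check_seq(query, "query")
    _check_seq(target, "target")
    if min_seed < 1:
        raise ValueError("min_seed must be >= 1")
    query = query.upper()
    target = target.upper()

    # seed: index target min_seed-mers, collect diagonals d = tpos - qpos
    diagonals: set[int] = set()
    if min_seed == 1:
        diagonals = set(range(-(len(query) - 1), len(target)))
    else:
        index: dict[str, list[int]] = {}
        for t in range(len(target) - min_seed + 1):
            index.setdefault(target[t : t + min_seed], []).append(t)
        for q in range(len(query) - min_seed + 1):
            for t in index.get(query[q : q + min_seed], ()):
                diagonals.add(t - q)

    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    tarr = np.frombuffer(target.encode(), dtype=np.uint8)
    out: list[LocalAlignment] = []
    for d in sorted(diagonals):
        q0 = max(0, -d)
        t0 = q0 + d
        n = min(len(query) - q0, len(target) - t0)
        if n < min_seed:
            continue
        is_match = qarr[q0 : q0 + n] == tarr[t0 : t0 + n]
        seg = _best_segment(is_match)
        if seg is None:
            continue
        s, e, matches = seg
        mism = (e - s) - matches
        if (e - s) < min_seed or matches - mism <= 0:
            continue
        out.append(
            LocalAlignment(q0 + s, q0 + e, t0 + s, t0 + e, matches, mism)
        )
    out.sort(key=lambda a: (-a.score, a.target_start, a.query_start))
    return out


def _best_segment(is_match: np.ndarray) -> tuple[int, int, int] | None:
    """Maximal-scoring contiguous segment of a +1/-1 sequence (Kadane).

    Ties broken by leftmost start, then shortest extent. Returns
    (start, end, matches) or None when no positive-scoring segment exists.
    """
    scores = np.where(is_match, 1, -1)
    best_score = 0
    best_span = None
    cur = 0
    cur_start = 0
    cur_matches = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = 0
            cur_start = i
            cur_matches = 0
        cur += int(s)
        if s == 1:
            cur_matches += 1
        if cur > best_score:
            best_score = cur
            best_span = (cur_start, i + 1, cur_matches)
    return best_span


def exact_match_runs(query: str, target: str, min_len: int) -> list[LocalAlignment]:
    """All maximal runs of >= min_len consecutive identical bases (100% identity)."""
    _check_seq(query, "query")
    _check_seq(target, "target")
    query, target = query.upper(), target.upper()
    k = min_len
    index: dict[str, list[int]] = {}
    for t in range(len(target) - k + 1):
        index.setdefault(target[t : t + k], []).append(t)
    seen: set[tuple[int, int]] = set()
    out: list[LocalAlignment] = []
    for q in range(len(query) - k + 1):
        for t in index.get(query[q : q + k], ()):
            d = t - q
            # extend to maximal run on this diagonal
            qs, ts = q, t
            while qs > 0 and ts > 0 and query[qs - 1] == target[ts - 1]:
                qs -= 1
                ts -= 1
            qe, te = q + k, t + k
            while qe < len(query) and te < len(target) and query[qe] == target[te]:
                qe += 1
                te += 1
            key = (d, qs)
            if key in seen:
                continue
            seen.add(key)
            out.append(LocalAlignment(qs, qe, ts, te, qe - qs, 0))
    out.sort(key=lambda a: (-a.score, a.target_start, a.query_start))
    return out


def dust_score(window: str) -> float:
    """Low-complexity score in [0, 100] from overlapping-triplet repetitiveness.

    With n overlapping trinucleotides and c_t the count of triplet t,
    ``score = 100 * sum_t c_t(c_t-1)/2 / (n(n-1)/2)``. Triplets containing N
    are ignored; the scale is fraction-of-maximum so a homopolymer scores 100.
    """
    window = window.upper()
    if len(window) < 3:
        raise ValueError("window shorter than 3")
    counts: dict[str, int] = {}
    for i in range(len(window) - 2):
        t = window[i : i + 3]
        if "N" in t:
            continue
        counts[t] = counts.get(t, 0) + 1
    n = sum(counts.values())
    if n < 2:
        return 0.0
    numer = sum(c * (c - 1) // 2 for c in counts.values())
    return 100.0 * numer / (n * (n - 1) / 2)


def kmerize(read: str, fraction: float) -> list[str]:
    """Overlapping k-mers with k = round(fraction * len) (banker's rounding), min 3."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    _check_seq(read, "read")
    k = max(3, round(fraction * len(read)))
    if len(read) < k:
        raise ValueError("read shorter than k")
    return [read[i : i + k] for i in range(len(read) - k + 1)]
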