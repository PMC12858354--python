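"""Semi-global (infix) edit-distance search.

Barcode and primer matching both need the minimal unit-cost edit distance
(substitutions + indels) between a short query and *any substring* of a
longer text, i.e. a semi-global alignment with free gaps at both ends of
the text.  This is the same alignment mode edlib calls "HW"; it is
implemented here as a numpy dynamic program because no infix aligner is
available in the installed stack.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class InfixHit(NamedTuple):
    """Best occurrence of a query inside a text."""

    start: int  # 0-based, inclusive
    end: int  # exclusive
    distance: int


def _forward_column_distances(query: str, text: str) -> np.ndarray:
    """Distance of the best alignment of ``query`` ending at each text index.

    Returns an array d of length len(text)+1 where d[j] is the minimal edit
    distance between query and any suffix of text[:j].
    """
    m = len(query)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    col = np.arange(m + 1)  # column for empty text prefix
    out = np.empty(len(text) + 1, dtype=np.int64)
    out[0] = col[-1]
    for j, tc in enumerate(t):
        sub = col[:-1] + (q != tc)  # diagonal: match/mismatch
        dele = col[1:] + 1  # gap in text (consume query char)
        new = np.empty_like(col)
        new[0] = 0  # free start anywhere in text
        np.minimum(sub, dele, out=new[1:])
        # gap in text (consume query char) runs down the column:
        # new[i] = min_k<=i (new[k] + i - k), done as a prefix-min scan
        rows = np.arange(m + 1)
        np.minimum.accumulate(new - rows, out=new)
        new += rows
        col = new
        out[j + 1] = col[-1]
    return out


def _best_start_for_end(query: str, text: str, end: int, distance: int) -> int:
    """Smallest start such that lev(query, text[start:end]) == distance."""
    rq = query[::-1]
    rt = text[:end][::-1]
    d = _forward_column_distances(rq, rt)
    lengths = np.flatnonzero(d == distance)
    if lengths.size == 0:  # pragma: no cover - defensive
        raise RuntimeError("inconsistent traceback")
    return end - int(lengths.max())


def find_infix(query: str, text: str, max_edits: Optional[int] = None) -> Optional[InfixHit]:
    """Locate the minimal-edit-distance occurrence of ``query`` in ``text``.

    Ties are broken by the leftmost start, then the leftmost end.  Returns
    ``None`` when the best distance exceeds ``max_edits`` (if given) or the
    query is empty.
    """
    if not query or not text:
        return None
    d = _forward_column_distances(query, text)
    best = int(d[1:].min())  # end must consume at least zero text; allow j>=1
    best = min(best, int(d[0]))
    if max_edits is not None and best > max_edits:
        return None
    ends = np.flatnonzero(d == best)
    candidates = []
    for end in ends:
        start = _best_start_for_end(query, text, int(end), best)
        candidates.append((start, int(end)))
    start, end = min(candidates)
    return InfixHit(start=start, end=end, distance=best)


def levenshtein(a: str, b: str) -> int:
    """Plain global edit distance (used by tests' brute-force oracles too)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = np.arange(len(b) + 1)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    for i, ac in enumerate(av):
        cur = np.empty_like(prev)
        cur[0] = i + 1
        sub = prev[:-1] + (bv != ac)
        dele = prev[1:] + 1
        np.minimum(sub, dele, out=cur[1:])
        cols = np.arange(len(b) + 1)
        np.minimum.accumulate(cur - cols, out=cur)
        cur += cols
        prev = cur
    return int(prev[-1])
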