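"""Shared fixtures and brute-force helpers for the test suite."""

from __future__ import annotations

import re
from typing import List, Tuple

import numpy as np
import pysam
import pytest

from lorespl import simulate


def make_header(chrom: str = "chrS", length: int = 100_000) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]})


_OP_CODE = {"M": pysam.CMATCH, "I": pysam.CINS, "D": pysam.CDEL,
            "N": pysam.CREF_SKIP, "S": pysam.CSOFT_CLIP, "=": pysam.CEQUAL,
            "X": pysam.CDIFF}


def make_alignment(cigar: str, pos: int = 0, chrom: str = "chrS",
                   read_id: str = "read1", sample: str = "",
                   header: pysam.AlignmentHeader | None = None) -> pysam.AlignedSegment:
    """Build an AlignedSegment from a CIGAR string like "50M100N50M"."""
    header = header or make_header(chrom)
    a = pysam.AlignedSegment(header)
    a.query_name = read_id
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigartuples = [(_OP_CODE[op], int(n)) for n, op in re.findall(r"(\d+)([MIDNS=X])", cigar)]
    qlen = sum(n for code, n in a.cigartuples
               if code in (pysam.CMATCH, pysam.CINS, pysam.CSOFT_CLIP,
                           pysam.CEQUAL, pysam.CDIFF))
    a.query_sequence = "A" * qlen
    a.flag = 0
    if sample:
        a.set_tag("RG", sample)
    return a


def naive_levenshtein(a: str, b: str) -> int:
    """Textbook O(nm) edit distance, independent of the package's DP."""
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, 1):
            cur = min(prev + (ca != cb), dp[j] + 1, dp[j - 1] + 1)
            prev, dp[j] = dp[j], cur
    return dp[-1]


def brute_force_best_substring(query: str, text: str) -> Tuple[int, int, int]:
    """Minimal edit distance over every substring; ties -> smallest (start, end)."""
    best = None
    for s in range(len(text) + 1):
        for e in range(s, len(text) + 1):
            d = naive_levenshtein(query, text[s:e])
            if best is None or d < best[2] or (d == best[2] and (s, e) < best[:2]):
                best = (s, e, d)
    return best


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def small_design() -> simulate.SimulationDesign:
    """Two 3-exon genes, 2 conditions x 3 replicates, default error rate."""
    return simulate.SimulationDesign(n_genes=2, exons_per_gene=3, abundance=40, seed=7)


@pytest.fixture(scope="session")
def small_reference(small_design) -> simulate.Reference:
    return simulate.make_reference(small_design)
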