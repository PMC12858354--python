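"""Barcode demultiplexing of multiplexed long cDNA reads.

Reads produced by barcoded oligo-dT priming carry, in first-strand cDNA
orientation, the layout ``[barcode][poly-T][reverse-complemented
insert][common primer]``.  A read is assigned to a sample by (1) locating
the poly-T tract and/or the common primer on either strand, (2) searching
a bounded window adjacent to those anchors for each sample's barcode with
an edit-distance matcher, and (3) requiring that exactly one barcode
matches within ``max_mismatch`` edits.  Reads matching no barcode are
UNASSIGNED; reads matching barcodes of two or more samples are AMBIGUOUS,
and both classes are excluded from downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, TextIO, Tuple

import pandas as pd

from ._align import InfixHit, find_infix, reverse_complement

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"

#: nt of sequence flanking an anchor feature probed for barcodes
BARCODE_WINDOW = 40

#: nt the barcode window reaches into the poly-T anchor itself, because the
#: fuzzy tract boundary can absorb T-adjacent barcode bases
ANCHOR_OVERLAP = 8

#: poly-T detector: minimum tract length and minimum T content
POLYT_MIN_LEN = 12
POLYT_MIN_FRAC = 0.90


@dataclass(frozen=True)
class BarcodeSet:
    """Sample barcodes plus the shared strand-switch (common) primer."""

    entries: Dict[str, str]
    common_primer: str
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode set is empty")
        seqs = list(self.entries.values())
        if any(not s for s in seqs):
            raise ValueError("empty barcode sequence")
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcodes are not unique")
        if self.max_mismatch >= min(len(s) for s in seqs):
            raise ValueError("max_mismatch must be below the shortest barcode length")

    @classmethod
    def from_tsv(cls, path: str | Path, common_primer: str, max_mismatch: int = 3) -> "BarcodeSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "barcode"} <= set(df.columns):
            raise ValueError("barcode manifest needs sample_id and barcode columns")
        return cls(dict(zip(df["sample_id"], df["barcode"])), common_primer, max_mismatch)


@dataclass
class DemuxedRead:
    read_id: str
    assigned_sample: str  # sample_id, UNASSIGNED or AMBIGUOUS
    orientation: str = "forward"  # strand on which the barcode layout was found
    insert: Optional[str] = None  # trimmed, sense-strand insert
    barcode_span: Optional[Tuple[int, int]] = None  # on the oriented read
    polyt_span: Optional[Tuple[int, int]] = None
    primer_span: Optional[Tuple[int, int]] = None
    distance: Optional[int] = None
    reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.assigned_sample not in (UNASSIGNED, AMBIGUOUS)


def find_polyT(sequence: str) -> Optional[Tuple[int, int]]:
    """Longest window of >= 12 nt with >= 90 % T content, extended maximally.

    Seeds are 12-nt windows meeting the T-content threshold; each seed is
    greedily extended right then left while the window stays above
    threshold.  The longest resulting window wins, leftmost on ties.
    """
    n = len(sequence)
    if n < POLYT_MIN_LEN:
        return None
    is_t = [c in "Tt" for c in sequence]
    prefix = [0]
    for v in is_t:
        prefix.append(prefix[-1] + v)

    def frac(i: int, j: int) -> float:
        return (prefix[j] - prefix[i]) / (j - i)

    best: Optional[Tuple[int, int]] = None
    i = 0
    while i + POLYT_MIN_LEN <= n:
        if frac(i, i + POLYT_MIN_LEN) < POLYT_MIN_FRAC:
            i += 1
            continue
        j = i + POLYT_MIN_LEN
        while j < n and frac(i, j + 1) >= POLYT_MIN_FRAC:
            j += 1
        s = i
        while s > 0 and frac(s - 1, j) >= POLYT_MIN_FRAC:
            s -= 1
        if best is None or (j - s) > (best[1] - best[0]):
            best = (s, j)
        i += 1
    if best is not None:
        # the 90% rule lets the ends absorb flanking non-T bases; a poly-T
        # span should start and end on a T
        s, j = best
        while not is_t[s]:
            s += 1
        while not is_t[j - 1]:
            j -= 1
        best = (s, j)
    return best


def find_primer(sequence: str, primer: str, max_edits: int = 3) -> Optional[InfixHit]:
    """Best infix edit-distance occurrence of the primer; leftmost on ties."""
    if not primer:
        raise ValueError("primer is empty")
    return find_infix(primer, sequence, max_edits=max_edits)


def _barcode_window(seq: str, polyt: Optional[Tuple[int, int]], primer: Optional[InfixHit],
                    max_barcode_len: int) -> Optional[Tuple[int, int]]:
    """Region of the oriented read probed for a barcode.

    The barcode lies 5' of the poly-T tract.  With no poly-T located, the
    common primer at the 3' end still fixes the orientation, and the
    barcode must sit at the very start of the read.
    """
    if polyt is not None:
        return (max(0, polyt[0] - BARCODE_WINDOW),
                min(len(seq), polyt[0] + ANCHOR_OVERLAP))
    if primer is not None:
        return (0, min(len(seq), max_barcode_len + BARCODE_WINDOW))
    return None


def _locate_features(seq: str, barcode_set: BarcodeSet):
    polyt = find_polyT(seq)
    primer = find_primer(seq, barcode_set.common_primer, barcode_set.max_mismatch)
    return polyt, primer


def assign_barcode(read_id: str, sequence: str, barcode_set: BarcodeSet) -> DemuxedRead:
    """Assign a read to a sample, or mark it UNASSIGNED / AMBIGUOUS.

    Both strands are probed; a barcode matches when its best edit distance
    inside the anchored window is <= max_mismatch.  A read matching
    barcodes of two or more samples (on either strand) is AMBIGUOUS and
    excluded downstream; the same sample matching on both strands keeps
    the better-scoring orientation.
    """
    max_bc = max(len(b) for b in barcode_set.entries.values())
    if len(sequence) < min(len(b) for b in barcode_set.entries.values()):
        return DemuxedRead(read_id, UNASSIGNED, reason="read shorter than barcodes")

    hits: Dict[str, Tuple[int, str, Tuple[int, int]]] = {}  # sample -> (dist, orient, span)
    features: Dict[str, tuple] = {}
    anchored = False
    for orient, seq in (("forward", sequence), ("reverse", reverse_complement(sequence))):
        polyt, primer = _locate_features(seq, barcode_set)
        features[orient] = (polyt, primer)
        window = _barcode_window(seq, polyt, primer, max_bc)
        if window is None:
            continue
        anchored = True
        ws, we = window
        for sample, barcode in barcode_set.entries.items():
            hit = find_infix(barcode, seq[ws:we], max_edits=barcode_set.max_mismatch)
            if hit is None:
                continue
            span = (ws + hit.start, ws + hit.end)
            prev = hits.get(sample)
            if prev is None or hit.distance < prev[0]:
                hits[sample] = (hit.distance, orient, span)

    if not hits:
        reason = "no anchor features located" if not anchored else "no barcode within mismatch limit"
        return DemuxedRead(read_id, UNASSIGNED, reason=reason)
    if len(hits) > 1:
        return DemuxedRead(read_id, AMBIGUOUS, reason="multiple barcodes matched")

    (sample, (dist, orient, span)), = hits.items()
    polyt, primer = features[orient]
    return DemuxedRead(
        read_id, sample, orientation=orient, barcode_span=span,
        polyt_span=polyt, primer_span=(primer.start, primer.end) if primer else None,
        distance=dist,
    )


def trim_read(demuxed: DemuxedRead, sequence: str) -> Optional[str]:
    """Trim located features and return the sense-strand insert.

    The insert lies between the poly-T tract and the common primer on the
    oriented (barcode-first) read and is reverse complemented back to
    mRNA sense.  Reads whose feature spans overlap inconsistently are
    dropped (returns None) with the reason logged on the record.
    """
    if not demuxed.assigned:
        raise ValueError("cannot trim an unassigned read")
    seq = sequence if demuxed.orientation == "forward" else reverse_complement(sequence)
    start = 0
    spans = [s for s in (demuxed.barcode_span, demuxed.polyt_span) if s is not None]
    for s in spans:
        start = max(start, s[1])
    end = len(seq)
    if demuxed.primer_span is not None:
        end = demuxed.primer_span[0]
    if end <= start:
        demuxed.reason = "feature spans overlap; no insert remains"
        logger.warning("read %s dropped: %s", demuxed.read_id, demuxed.reason)
        return None
    insert = reverse_complement(seq[start:end])
    demuxed.insert = insert
    return insert


def demultiplex(reads: Iterable[Tuple[str, str]], barcode_set: BarcodeSet) -> Iterator[DemuxedRead]:
    """Assign and trim an iterable of (read_id, sequence) pairs."""
    for read_id, seq in reads:
        rec = assign_barcode(read_id, seq, barcode_set)
        if rec.assigned:
            trim_read(rec, seq)
        yield rec


def read_fastq(path: str | Path) -> Iterator[Tuple[str, str]]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].split()[0], seq


def demultiplex_fastq(fastq: str | Path, barcode_set: BarcodeSet, outdir: str | Path) -> pd.DataFrame:
    """Demultiplex a FASTQ into per-sample FASTQs plus a TSV report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handles: Dict[str, TextIO] = {}
    rows: List[dict] = []
    try:
        for read_id, seq in read_fastq(fastq):
            rec = assign_barcode(read_id, seq, barcode_set)
            insert = trim_read(rec, seq) if rec.assigned else None
            rows.append({
                "read_id": rec.read_id,
                "sample": rec.assigned_sample,
                "distance": rec.distance,
                "orientation": rec.orientation if rec.assigned else "",
                "reason": rec.reason,
            })
            if insert is not None:
                fh = handles.get(rec.assigned_sample)
                if fh is None:
                    fh = open(outdir / f"{rec.assigned_sample}.fastq", "w")
                    handles[rec.assigned_sample] = fh
                fh.write(f"@{read_id}\n{insert}\n+\n{'I' * len(insert)}\n")
    finally:
        for fh in handles.values():
            fh.close()
    report = pd.DataFrame(rows, columns=["read_id", "sample", "distance", "orientation", "reason"])
    report.to_csv(outdir / "demux_report.tsv", sep="\t", index=False)
    counts = report["sample"].value_counts()
    logger.info("demultiplexed %d reads: %s", len(report), counts.to_dict())
    return report
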