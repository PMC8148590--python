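"""Chimeric-contig screen by strict (mismatch-free) read re-alignment.

Merged reads are re-aligned to annotated transcripts keeping only perfect,
gap-free occurrences (on either strand, at every matching locus). A
transcript with any zero-coverage base is removed automatically - at an
assembly-chimera junction no read can span the joint, so coverage collapses
there. Surviving transcripts are screened site-by-site for imbalance
between the average aligned read length on either side of the site
(relative difference > 75% flags the transcript); reads truncate at a
chimeric junction, so flanking lengths become one-sided there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from venomkit.io import revcomp
from venomkit.readproc import MergedRead

SEED = 25


@dataclass
class StrictAlignment:
    read_id: str
    transcript_id: str
    start: int
    end: int
    strand: str  # "+" or "-"


@dataclass
class ChimeraVerdict:
    transcript_id: str
    status: str                              # pass | removed_zero_coverage | flagged_imbalance
    flagged_sites: list[int] = field(default_factory=list)
    max_imbalance: float = 0.0


def _transcript_index(transcripts: dict[str, str], seed: int = SEED) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        for pos in range(len(seq) - seed + 1):
            index.setdefault(seq[pos : pos + seed], []).append((tid, pos))
    return index


def strict_align(reads, transcripts: dict[str, str],
                 _index: dict | None = None) -> list[StrictAlignment]:
    """All perfect full-length occurrences of each read across all transcripts.

    Reads are (id, seq) pairs or MergedRead objects. A read with no exact
    occurrence on either strand is discarded (the mismatch rule); one with
    several perfect loci yields one alignment per locus. Matching is seeded
    on the read's leading 25-mer against a transcript k-mer index, which is
    exact and complete for reads of at least the seed length; shorter reads
    fall back to a direct scan.
    """
    if not transcripts:
        raise ValueError("strict_align requires at least one transcript")
    index = _index if _index is not None else _transcript_index(transcripts)
    out: list[StrictAlignment] = []
    for read in reads:
        rid, seq = (read.id, read.seq) if isinstance(read, MergedRead) else (read[0], read[1])
        rc = revcomp(seq)
        for strand, s in (("+", seq), ("-", rc)):
            if strand == "-" and rc == seq:
                continue
            if len(s) >= SEED:
                for tid, pos in index.get(s[:SEED], ()):
                    if transcripts[tid].startswith(s, pos):
                        out.append(StrictAlignment(rid, tid, pos, pos + len(s), strand))
            else:
                for tid, tseq in transcripts.items():
                    pos = tseq.find(s)
                    while pos != -1:
                        out.append(StrictAlignment(rid, tid, pos, pos + len(s), strand))
                        pos = tseq.find(s, pos + 1)
    return out


def coverage_profile(alignments: list[StrictAlignment], transcript_len: int) -> np.ndarray:
    """Per-base coverage: coverage[i] = number of alignments with start <= i < end."""
    diff = np.zeros(transcript_len + 1, dtype=np.int64)
    for a in alignments:
        diff[a.start] += 1
        diff[a.end] -= 1
    return np.cumsum(diff[:-1])


def _imbalance_profile(alignments: list[StrictAlignment], transcript_len: int,
                       exclude_boundary: bool = False):
    """Vectorized D_i over all sites via prefix sums of starts/ends.

    For reads overlapping site i, L = mean(i - start + 1) and
    R = mean(end - i - 1); D_i = |L - R| / max(L, R), 0 where undefined.
    With ``exclude_boundary``, alignments touching either transcript end are
    ignored: their flanking lengths are censored by the contig boundary
    (the strict-matching analog of soft-clipped reads), so they say nothing
    about read-length symmetry and would otherwise fake imbalance wherever
    edge-anchored fragments pile up.
    """
    if exclude_boundary:
        alignments = [a for a in alignments if a.start > 0 and a.end < transcript_len]
    cov_d = np.zeros(transcript_len + 1, dtype=np.float64)
    s_d = np.zeros(transcript_len + 1, dtype=np.float64)
    e_d = np.zeros(transcript_len + 1, dtype=np.float64)
    for a in alignments:
        cov_d[a.start] += 1
        cov_d[a.end] -= 1
        s_d[a.start] += a.start
        s_d[a.end] -= a.start
        e_d[a.start] += a.end
        e_d[a.end] -= a.end
    cov = np.cumsum(cov_d[:-1])
    s_sum = np.cumsum(s_d[:-1])
    e_sum = np.cumsum(e_d[:-1])
    i = np.arange(transcript_len, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        left = (i + 1.0) - s_sum / cov
        right = e_sum / cov - i - 1.0
        hi = np.maximum(left, right)
        d = np.where((cov > 0) & (hi > 0), np.abs(left - right) / np.where(hi > 0, hi, 1.0), 0.0)
    return cov, d


def imbalance_statistic(alignments: list[StrictAlignment], transcript_len: int, site: int) -> float:
    """D at one site: relative difference of mean flanking aligned lengths."""
    overlapping = [a for a in alignments if a.start <= site < a.end]
    if not overlapping:
        raise ValueError(f"site {site} has zero coverage")
    left = float(np.mean([site - a.start + 1 for a in overlapping]))
    right = float(np.mean([a.end - site - 1 for a in overlapping]))
    hi = max(left, right)
    return abs(left - right) / hi if hi > 0 else 0.0


def screen(transcripts: dict[str, str], reads, imbalance_threshold: float = 0.75,
           min_flank: int | None = None, min_support: int = 10,
           keep_flagged: bool = False) -> tuple[list[ChimeraVerdict], dict[str, str]]:
    """Run the full screen: zero-coverage removal, then imbalance flagging.

    ``min_flank`` restricts the imbalance statistic to internal sites at
    least that far from either transcript end (default: the mean aligned
    read length, below which read truncation at the ends makes D large even
    for genuine transcripts). Boundary-touching alignments are excluded
    from the statistic (their flanking lengths are censored), and a site
    must be overlapped by at least ``min_support`` interior reads to be
    flaggable - with fewer, D is sampling noise (a single read gives D ~ 1
    near its own ends). Flagged transcripts are removed unless
    ``keep_flagged`` - the automated stand-in for a manual check.
    Returns (verdicts in transcript order, surviving transcripts).
    """
    alignments = strict_align(reads, transcripts)
    by_tx: dict[str, list[StrictAlignment]] = {tid: [] for tid in transcripts}
    for a in alignments:
        by_tx[a.transcript_id].append(a)
    if min_flank is None:
        spans = [a.end - a.start for a in alignments]
        min_flank = int(round(float(np.mean(spans)))) if spans else 0

    verdicts: list[ChimeraVerdict] = []
    surviving: dict[str, str] = {}
    for tid, seq in transcripts.items():
        alns = by_tx[tid]
        cov = coverage_profile(alns, len(seq))
        if (cov == 0).any():
            verdicts.append(ChimeraVerdict(tid, "removed_zero_coverage"))
            continue
        icov, d = _imbalance_profile(alns, len(seq), exclude_boundary=True)
        d = np.where(icov >= min_support, d, 0.0)
        lo, hi = min_flank, len(seq) - min_flank
        internal = d[lo:hi] if hi > lo else np.array([])
        max_d = float(internal.max()) if internal.size else 0.0
        if max_d > imbalance_threshold:
            sites = (np.flatnonzero(internal > imbalance_threshold) + lo).tolist()
            verdicts.append(ChimeraVerdict(tid, "flagged_imbalance", sites, max_d))
            if keep_flagged:
                surviving[tid] = seq
        else:
            verdicts.append(ChimeraVerdict(tid, "pass", [], max_d))
            surviving[tid] = seq
    return verdicts, surviving
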