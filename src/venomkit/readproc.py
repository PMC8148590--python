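"""Quality trimming, overlap merging of read pairs, and run summaries.

Trimming removes 3' bases below a Phred threshold (default < 5). Merging
finds the overlap offset between R1 and the reverse complement of R2 that
maximizes matching bases; an overlap is accepted when it is long enough and
clean enough, with disagreements resolved toward the higher-quality call.
``summarize_runs`` computes the per-study sequencing summary (mean +/-
population SD of read pairs, per-sample merge percentages, pooled merge
percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from venomkit.io import revcomp

ReadPair = tuple[str, str, str, str, str]  # id, seq1, qual1, seq2, qual2


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: str
    overlap_length: int


@dataclass
class SampleRunStats:
    sample_id: str
    read_pairs: int
    merged_reads: int

    @property
    def merge_pct(self) -> float:
        return 100.0 * self.merged_reads / self.read_pairs if self.read_pairs else 0.0


def quality_trim(pairs: list[ReadPair], q_threshold: int = 5) -> tuple[list[ReadPair], int]:
    """3'-trim both mates at a hard Phred threshold; drop pairs with an emptied mate.

    Returns (surviving pairs, number of dropped pairs).
    """
    floor = chr(q_threshold + 33)
    out: list[ReadPair] = []
    dropped = 0
    for rid, s1, q1, s2, q2 in pairs:
        if len(s1) != len(q1) or len(s2) != len(q2):
            raise ValueError(f"read {rid}: sequence/quality length mismatch")
        k1 = _trim_point(q1, floor)
        k2 = _trim_point(q2, floor)
        if k1 == 0 or k2 == 0:
            dropped += 1
            continue
        out.append((rid, s1[:k1], q1[:k1], s2[:k2], q2[:k2]))
    return out, dropped


def _trim_point(qual: str, floor: str) -> int:
    k = len(qual)
    while k > 0 and qual[k - 1] < floor:
        k -= 1
    return k


def merge_pairs(pairs: list[ReadPair], min_overlap: int = 10,
                max_mismatch_frac: float = 0.1) -> tuple[list[MergedRead], list[ReadPair]]:
    """Merge overlapping mates; return (merged reads, unmerged pairs).

    The best overlap is the offset maximizing the overlap alignment score
    (matches minus mismatches) between the 3' end of R1 and the 5' end of
    reverse-complemented R2, ties broken toward the longest overlap; raw
    match count would let long spurious overlaps (a quarter of whose bases
    match by chance) outscore short true ones. The best overlap is accepted
    iff it is >= ``min_overlap`` long with mismatch fraction
    <= ``max_mismatch_frac``. Overlap bases take the higher-quality call;
    overlap qualities are the per-base maximum. Implementation is
    vectorized across pairs grouped by mate lengths.
    """
    merged: list[MergedRead] = []
    unmerged: list[ReadPair] = []
    groups: dict[tuple[int, int], list[int]] = {}
    for i, p in enumerate(pairs):
        groups.setdefault((len(p[1]), len(p[3])), []).append(i)

    for (l1, l2), idxs in groups.items():
        n = len(idxs)
        a1 = np.frombuffer("".join(pairs[i][1] for i in idxs).encode(), dtype=np.uint8).reshape(n, l1)
        rc2 = np.frombuffer("".join(revcomp(pairs[i][3]) for i in idxs).encode(), dtype=np.uint8).reshape(n, l2)
        max_o = min(l1, l2)
        best_o = np.zeros(n, dtype=int)
        best_score = np.full(n, -(10**9))
        best_mism = np.zeros(n, dtype=int)
        for o in range(min_overlap, max_o + 1):
            matches = (a1[:, l1 - o :] == rc2[:, :o]).sum(axis=1)
            score = 2 * matches - o  # matches - mismatches
            better = score >= best_score  # >= : ties favor the longer overlap
            best_o[better] = o
            best_mism[better] = o - matches[better]
            best_score[better] = score[better]
        ok = (best_o > 0) & (best_mism <= max_mismatch_frac * best_o)
        for j, i in enumerate(idxs):
            rid, s1, q1, s2, q2 = pairs[i]
            if not ok[j]:
                unmerged.append(pairs[i])
                continue
            o = int(best_o[j])
            rs2, rq2 = revcomp(s2), q2[::-1]
            head, tail = s1[: l1 - o], rs2[o:]
            ov1, ovq1 = s1[l1 - o :], q1[l1 - o :]
            ov2, ovq2 = rs2[:o], rq2[:o]
            mid = "".join(b1 if bq1 >= bq2 else b2 for b1, bq1, b2, bq2 in zip(ov1, ovq1, ov2, ovq2))
            midq = "".join(max(x, y) for x, y in zip(ovq1, ovq2))
            merged.append(MergedRead(rid, head + mid + tail, q1[: l1 - o] + midq + rq2[o:], o))
    return merged, unmerged


def summarize_runs(stats: list[SampleRunStats]) -> dict:
    """Study-level sequencing summary with population (n-denominator) SDs.

    The pooled merge percent is 100 * sum(merged) / sum(pairs), which is how
    an "average" merge rate over samples of unequal depth is reported.
    """
    if not stats:
        raise ValueError("summarize_runs requires at least one sample")
    pairs = np.array([s.read_pairs for s in stats], dtype=float)
    merged = np.array([s.merged_reads for s in stats], dtype=float)
    pcts = 100.0 * merged / pairs
    return {
        "n_samples": len(stats),
        "mean_read_pairs": float(pairs.mean()),
        "sd_read_pairs": float(pairs.std(ddof=0)),
        "min_read_pairs": float(pairs.min()),
        "max_read_pairs": float(pairs.max()),
        "merge_pct_per_sample": [float(p) for p in pcts],
        "merge_pct_min": float(pcts.min()),
        "merge_pct_max": float(pcts.max()),
        "merge_pct_pooled": float(100.0 * merged.sum() / pairs.sum()),
        "sd_merge_pct": float(pcts.std(ddof=0)),
    }


def stats_table(stats: list[SampleRunStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in stats],
            "read_pairs": [s.read_pairs for s in stats],
            "merged_reads": [s.merged_reads for s in stats],
            "merge_pct": [round(s.merge_pct, 1) for s in stats],
        }
    )
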