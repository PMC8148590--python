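"""Toxin/nontoxin annotation of contigs by translated similarity search.

Contigs are translated in all six frames and searched against a curated
protein reference (toxins with family labels and signal peptides, plus
nontoxins) by seeded local BLOSUM62 alignment. Significance uses the
Karlin-Altschul formula E = K * m * n * exp(-lambda * S) with fixed gapped
constants (lambda = 0.267, K = 0.041), so E-values are approximate but
deterministic. Hits with amino-acid identity above 80% are auto-annotated
and inherit the reference's family and signal-peptide coordinates; weaker
hits passing the E-value floor are proposed for manual annotation; the rest
stay unannotated and are excluded from consensus building downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from venomkit._align import aa_local_align
from venomkit.io import revcomp

LAMBDA = 0.267
KAPPA = 0.041
SEED_SIZE = 5

FAMILY_VOCABULARY = (
    "3FTx", "CRISP", "SVMPIII", "CTL", "AChE", "fused", "KUN", "PDE",
    "PLA2", "PLB", "VEGF", "waprin", "nontoxin",
)


@dataclass
class ReferenceProtein:
    id: str
    aa_seq: str
    family: str
    signal_peptide: tuple[int, int] | None = None  # 0-based half-open aa interval

    def __post_init__(self):
        if self.family not in FAMILY_VOCABULARY:
            raise ValueError(f"unknown family {self.family!r} for reference {self.id}")
        if self.signal_peptide is not None:
            s, e = self.signal_peptide
            if not 0 <= s < e <= len(self.aa_seq):
                raise ValueError(f"signal peptide {self.signal_peptide} outside {self.id}")


class ReferenceSet:
    """Curated reference with a k-mer seed index for the translated search."""

    def __init__(self, records: list[ReferenceProtein], seed_size: int = SEED_SIZE):
        if not records:
            raise ValueError("reference set is empty")
        self.records = list(records)
        self.seed_size = seed_size
        self.total_aa = sum(len(r.aa_seq) for r in records)
        self._index: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            seen = set()
            for j in range(len(rec.aa_seq) - seed_size + 1):
                kmer = rec.aa_seq[j : j + seed_size]
                if kmer not in seen:
                    self._index.setdefault(kmer, []).append(i)
                    seen.add(kmer)

    def candidates(self, peptide: str) -> list[int]:
        hits: set[int] = set()
        for j in range(len(peptide) - self.seed_size + 1):
            hits.update(self._index.get(peptide[j : j + self.seed_size], ()))
        return sorted(hits)


@dataclass
class Hit:
    reference_id: str
    family: str
    score: float
    evalue: float
    identity: float
    frame: int                               # 0..2 forward, -1..-3 reverse
    query_nt: tuple[int, int]                # aligned region, contig nt coords (hit strand)
    ref_aa: tuple[int, int]
    signal_peptide_nt: tuple[int, int] | None


@dataclass
class Annotation:
    contig_id: str
    reference_id: str | None
    family: str | None
    identity: float
    evalue: float
    mode: str                                # auto | manual | unannotated
    signal_peptide_nt: tuple[int, int] | None = None


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E = K * m * n * exp(-lambda * S) with the fixed gapped constants."""
    expo = math.log(KAPPA * m * n) - LAMBDA * score
    return math.exp(expo) if expo > -700 else 0.0


def _translate_frame(nt_seq: str, frame: int) -> str:
    """Full-frame translation including stop symbols; codons with N give X."""
    seq = nt_seq if frame >= 0 else revcomp(nt_seq)
    off = frame if frame >= 0 else -frame - 1
    coding = seq[off : off + 3 * ((len(seq) - off) // 3)]
    if len(coding) < 3:
        return ""
    return str(Seq(coding).translate())


def translate(nt_seq: str, frame: int = 0, to_stop: bool = True) -> str:
    """Translate one frame with the standard code.

    Frames 0..2 translate the forward strand at that offset; -1..-3
    translate the reverse complement at offsets 0..2. By default
    translation terminates at the first stop codon; with
    ``to_stop=False`` the full frame is returned with ``*`` at stops.
    """
    aa = _translate_frame(nt_seq, frame)
    if to_stop:
        stop = aa.find("*")
        return aa if stop == -1 else aa[:stop]
    return aa


def longest_orf(nt_seq: str) -> tuple[str, dict]:
    """Longest start-to-stop (or frame-end) ORF over all six frames.

    Returns (aa sequence without the stop, info) where info carries the
    frame and the 0-based half-open nt coordinates on the frame's strand.
    """
    best = ("", {"frame": 0, "start_nt": 0, "end_nt": 0})
    for frame in (0, 1, 2, -1, -2, -3):
        aa = _translate_frame(nt_seq, frame)
        off = frame if frame >= 0 else -frame - 1
        pos = 0
        while True:
            m = aa.find("M", pos)
            if m == -1:
                break
            stop = aa.find("*", m)
            end = stop if stop != -1 else len(aa)
            orf = aa[m:end]
            if len(orf) > len(best[0]):
                best = (orf, {"frame": frame, "start_nt": off + 3 * m, "end_nt": off + 3 * end})
            pos = end if stop == -1 else stop + 1
        # remaining starts after the last stop were covered by the loop
    return best


def _map_ref_to_query(alignment, ref_pos: int) -> int | None:
    """Map a reference (target) coordinate through a local alignment to the query."""
    q_blocks, t_blocks = alignment.aligned
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        if ts <= ref_pos < te:
            return qs + (ref_pos - ts)
    return None


def translated_search(contig_seq: str, reference: ReferenceSet,
                      evalue_max: float = 1e-4) -> list[Hit]:
    """Seeded six-frame local search of a contig against the reference set.

    Frame translations are split at stop codons; segments sharing an exact
    ``seed_size``-mer with a reference are aligned (local, BLOSUM62,
    gap open 11 / extend 1). E = K * m * n * exp(-lambda * S) with m the
    frame's translated length and n the summed reference length. Hits with
    E <= ``evalue_max`` are returned sorted by (E, -score), one per
    reference (its best).
    """
    best_per_ref: dict[int, Hit] = {}
    n = reference.total_aa
    L = len(contig_seq)
    for frame in (0, 1, 2, -1, -2, -3):
        aa = _translate_frame(contig_seq, frame)
        m = len(aa)
        if m < reference.seed_size:
            continue
        off = frame if frame >= 0 else -frame - 1
        seg_start = 0
        for segment in aa.split("*"):
            seg_off = seg_start
            seg_start += len(segment) + 1
            if len(segment) < reference.seed_size:
                continue
            for ri in reference.candidates(segment):
                rec = reference.records[ri]
                aln = aa_local_align(segment, rec.aa_seq)
                if aln is None:
                    continue
                score = float(aln.score)
                expo = math.log(KAPPA * m * n) - LAMBDA * score
                evalue = math.exp(expo) if expo > -700 else 0.0
                if evalue > evalue_max:
                    continue
                counts = aln.counts()
                aligned_cols = counts.identities + counts.mismatches
                identity = counts.identities / aligned_cols if aligned_cols else 0.0
                q_blocks, t_blocks = aln.aligned
                q_aa = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
                ref_aa = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
                query_nt = (off + 3 * (seg_off + q_aa[0]), off + 3 * (seg_off + q_aa[1]))
                sp_nt = None
                if rec.signal_peptide is not None:
                    sp_s, sp_e = rec.signal_peptide
                    qs = _map_ref_to_query(aln, sp_s)
                    qe = _map_ref_to_query(aln, sp_e - 1)
                    if qs is not None and qe is not None:
                        sp_nt = (off + 3 * (seg_off + qs), off + 3 * (seg_off + qe + 1))
                        if frame < 0:  # convert to forward-strand contig coords
                            sp_nt = (L - sp_nt[1], L - sp_nt[0])
                hit = Hit(rec.id, rec.family, score, evalue, identity, frame, query_nt, ref_aa, sp_nt)
                prev = best_per_ref.get(ri)
                if prev is None or (hit.evalue, -hit.score) < (prev.evalue, -prev.score):
                    best_per_ref[ri] = hit
    return sorted(best_per_ref.values(), key=lambda h: (h.evalue, -h.score, h.reference_id))


def annotate_contig(contig_id: str, contig_seq: str, reference: ReferenceSet,
                    auto_threshold: float = 0.80, evalue_max: float = 1e-4) -> Annotation:
    """Annotate one contig: auto above the identity threshold, else manual, else none.

    Auto-annotation (best-hit amino-acid identity > ``auto_threshold``)
    copies the family and maps the reference's signal-peptide interval
    through the alignment onto the contig. Weaker hits passing the E-value
    floor propose the best hit's family in manual mode.
    """
    hits = translated_search(contig_seq, reference, evalue_max)
    if not hits:
        return Annotation(contig_id, None, None, 0.0, math.inf, "unannotated")
    best = hits[0]
    mode = "auto" if best.identity > auto_threshold else "manual"
    return Annotation(contig_id, best.reference_id, best.family, best.identity,
                      best.evalue, mode, best.signal_peptide_nt if mode == "auto" else None)


def assign_family(annotations: list[Annotation], mean_tpm: dict[str, float]) -> dict[str, str]:
    """Paralog numbering: ``<family>-<k>`` by descending mean TPM within family.

    Ties break toward the lexicographically smaller contig id; unannotated
    contigs are excluded.
    """
    by_family: dict[str, list[Annotation]] = {}
    for ann in annotations:
        if ann.family is not None:
            by_family.setdefault(ann.family, []).append(ann)
    labels: dict[str, str] = {}
    for family, members in by_family.items():
        members.sort(key=lambda a: (-mean_tpm.get(a.contig_id, 0.0), a.contig_id))
        for k, ann in enumerate(members, start=1):
            labels[ann.contig_id] = f"{family}-{k}"
    return labels


def peptide_fragment_scan(peptide_aa: str, proteins: dict[str, str]) -> pd.DataFrame:
    """Ungapped sliding scan of a short peptide across translated transcripts.

    The peptide slides over every offset, including partial overhangs; the
    maximum identical-residue count and its offset are reported for each
    protein, ranked by match count. This mirrors matching a de novo peptide
    fragment (e.g. a 14-residue venom fragment) against candidate toxins.
    """
    if not peptide_aa:
        raise ValueError("peptide must be nonempty")
    rows = []
    lp = len(peptide_aa)
    for pid, prot in proteins.items():
        best, best_off = 0, 0
        for off in range(-(lp - 1), len(prot)):
            n = sum(
                1
                for j in range(lp)
                if 0 <= off + j < len(prot) and prot[off + j] == peptide_aa[j]
            )
            if n > best:
                best, best_off = n, off
        rows.append({"protein_id": pid, "max_matches": best, "offset": best_off})
    df = pd.DataFrame(rows, columns=["protein_id", "max_matches", "offset"])
    return df.sort_values(["max_matches", "protein_id"], ascending=[False, True]).reset_index(drop=True)
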