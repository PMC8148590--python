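"""Shared alignment primitives.

Nucleotide identity uses a global alignment with match +1 / mismatch -1 /
gap -2 (the scoring behind the clustering thresholds); protein search uses
local BLOSUM62 alignment with affine gaps (open 11 / extend 1). Both run
through Bio.Align.PairwiseAligner. edlib provides a provably conservative
edit-distance pre-filter so that greedy clustering does not pay for full
alignments of obviously dissimilar pairs.
"""

from __future__ import annotations

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices

from venomkit.io import revcomp

_NT_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=-1.0,
    open_gap_score=-2.0,
    extend_gap_score=-2.0,
)

_AA_ALIGNER = PairwiseAligner(mode="local", open_gap_score=-11.0, extend_gap_score=-1.0)
_AA_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")


def nt_global_identity_one_strand(a: str, b: str) -> float:
    """Identity of the optimal global alignment: identical bases / shorter length."""
    aln = _NT_ALIGNER.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / min(len(a), len(b))


def nt_identity(a: str, b: str) -> float:
    """Strand-max global-alignment identity between two nucleotide sequences."""
    if not a or not b:
        raise ValueError("pairwise identity requires two nonempty sequences")
    if a == b:
        return 1.0
    fwd = nt_global_identity_one_strand(a, b)
    if fwd == 1.0:
        return 1.0
    rev = nt_global_identity_one_strand(a, revcomp(b))
    return max(fwd, rev)


def may_reach_identity(a: str, b: str, threshold: float) -> bool:
    """Cheap edit-distance screen: False only if identity(a, b) < threshold.

    For an optimal global (+1/-1/-2) alignment with identities >= t * Ls
    (Ls = shorter length), the unit-cost edit distance is at most
    2 * (1 - t) * Ls + |len(a) - len(b)|; we allow a further 50% margin so
    that the screen is safely conservative.
    """
    ls = min(len(a), len(b))
    k = int(3.0 * (1.0 - threshold) * ls + abs(len(a) - len(b))) + 5
    if edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"] != -1:
        return True
    return edlib.align(a, revcomp(b), mode="NW", task="distance", k=k)["editDistance"] != -1


def aa_local_align(query: str, target: str):
    """Best local BLOSUM62 alignment of two protein sequences, or None."""
    alns = _AA_ALIGNER.align(query, target)
    try:
        return alns[0]
    except IndexError:
        return None
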