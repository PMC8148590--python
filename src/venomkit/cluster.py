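"""Duplicate removal and greedy identity clustering of assembled contigs.

The clustering reimplements the cd-hit-est strategy at desk scale: contigs
sorted longest-first, each joining the first cluster whose representative
it matches at or above the identity threshold (98% within an individual to
collapse allelic variation, 95% across individuals for the species
consensus). Identity is the strand-max global-alignment identity with the
shorter sequence as denominator - cd-hit-est's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from venomkit._align import may_reach_identity, nt_identity
from venomkit.io import revcomp


@dataclass
class Contig:
    id: str
    seq: str
    individual_id: str = ""
    assembler_tag: str = ""

    def __post_init__(self):
        if not self.seq or set(self.seq) - set("ACGTN"):
            raise ValueError(f"contig {self.id}: sequence must be nonempty over ACGTN")


@dataclass
class Cluster:
    representative: Contig
    members: list[Contig] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)
    threshold: float = 1.0


def remove_duplicates(contigs: list[Contig]) -> list[Contig]:
    """Collapse exact duplicates (including reverse-complement duplicates).

    Each group of identical sequences keeps a single record - the one with
    the lexicographically smallest id. Output preserves no particular input
    order beyond first occurrence of each canonical sequence.
    """
    best: dict[str, Contig] = {}
    order: list[str] = []
    for c in contigs:
        key = min(c.seq, revcomp(c.seq))
        if key not in best:
            best[key] = c
            order.append(key)
        elif c.id < best[key].id:
            best[key] = c
    return [best[k] for k in order]


def pairwise_identity(a: str | Contig, b: str | Contig) -> float:
    """Global-alignment identity (match +1 / mismatch -1 / gap -2), strand-max.

    Identity = identical aligned bases / length of the shorter sequence, so
    an exact substring scores 1.0.
    """
    sa = a.seq if isinstance(a, Contig) else a
    sb = b.seq if isinstance(b, Contig) else b
    return nt_identity(sa, sb)


def greedy_cluster(contigs: list[Contig], threshold: float, prefilter: bool = True) -> list[Cluster]:
    """Longest-first greedy clustering at an identity threshold.

    Ties in length break by id, so the partition is deterministic. With
    ``prefilter`` a conservative edit-distance screen skips full alignments
    that provably cannot reach the threshold; the partition is identical
    either way.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(contigs, key=lambda c: (-len(c.seq), c.id))
    clusters: list[Cluster] = []
    for contig in ordered:
        placed = False
        for cl in clusters:
            rep = cl.representative.seq
            if prefilter and not may_reach_identity(contig.seq, rep, threshold):
                continue
            ident = nt_identity(contig.seq, rep)
            if ident >= threshold:
                cl.members.append(contig)
                cl.identities.append(ident)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(contig, [contig], [1.0], threshold))
    return clusters


def cluster_representatives(clusters: list[Cluster]) -> list[Contig]:
    return [cl.representative for cl in clusters]


def build_consensus(per_individual: list[list[Contig]], threshold: float = 0.95) -> list[Cluster]:
    """Cluster the union of per-individual transcriptomes into a consensus.

    Inputs are expected to be each individual's 98%-clustered representative
    set; the union is re-clustered at the consensus threshold (default 95%).
    Member provenance (contributing individuals) survives in each cluster's
    member list.
    """
    pooled = [c for ind_set in per_individual for c in ind_set]
    if not pooled:
        raise ValueError("consensus requires at least one contig")
    return greedy_cluster(pooled, threshold)


def membership_table(clusters: list[Cluster]) -> pd.DataFrame:
    rows = []
    for k, cl in enumerate(clusters):
        for member, ident in zip(cl.members, cl.identities):
            rows.append({
                "cluster_id": k, "representative": cl.representative.id,
                "member": member.id, "identity": round(ident, 4),
            })
    return pd.DataFrame(rows, columns=["cluster_id", "representative", "member", "identity"])
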