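"""FASTA/FASTQ reading and writing (Biopython-backed) and header conventions.

Reference protein FASTA headers are structured as ``id|family|sp:start-end``
with 1-based inclusive amino-acid coordinates for the signal peptide, or
``sp:-`` when none is annotated (nontoxins).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: Iterable[tuple[str, str]] | dict, path) -> None:
    if isinstance(records, dict):
        records = records.items()
    with _open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ into ``[(id, seq, qual_string), ...]``."""
    out = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.description, str(rec.seq).upper(), qual))
    return out


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with _open(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def format_ref_header(ref_id: str, family: str, signal_peptide: tuple[int, int] | None) -> str:
    sp = f"sp:{signal_peptide[0] + 1}-{signal_peptide[1]}" if signal_peptide else "sp:-"
    return f"{ref_id}|{family}|{sp}"


def parse_ref_header(header: str) -> tuple[str, str, tuple[int, int] | None]:
    """Parse ``id|family|sp:start-end`` into (id, family, 0-based half-open aa interval)."""
    ref_id, family, sp = header.split("|")
    if not sp.startswith("sp:"):
        raise ValueError(f"malformed reference header: {header!r}")
    coords = sp[3:]
    if coords in ("-", ""):
        return ref_id, family, None
    start, end = coords.split("-")
    return ref_id, family, (int(start) - 1, int(end))


def iter_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield ``(id, seq1, qual1, seq2, qual2)`` from two synchronized FASTQ files."""
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError(f"paired FASTQ files differ in length: {len(r1)} vs {len(r2)}")
    for (id1, s1, q1), (_id2, s2, q2) in zip(r1, r2):
        yield id1.split()[0], s1, q1, s2, q2
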