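"""Expression quantification: mismatch-bounded mapping, EM over multireads,
TPM, family aggregation, compositional zero imputation, and the composition
report.

Merged reads are mapped to the consensus transcriptome allowing up to two
substitutions (no indels); multi-mapping reads are resolved by an
expectation-maximization over transcript abundances with effective-length
weighting, yielding fractional expected counts (EC) and, after length
normalization, transcripts per million (TPM). Family-level matrices are
member sums; zeros are replaced multiplicatively (half the smallest nonzero
per sample, with nonzero entries rescaled so each sample still closes to
1e6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from venomkit.io import revcomp
from venomkit.readproc import MergedRead

logger = logging.getLogger(__name__)

SEED = 25


@dataclass
class CompatibilityRecord:
    read_id: str
    transcript_ids: tuple[str, ...]


@dataclass
class MappingResult:
    records: list[CompatibilityRecord]
    n_unmapped: int
    mean_read_length: float


def _hamming_le(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def map_reads(reads, transcripts: dict[str, str], max_mismatches: int = 2) -> MappingResult:
    """List each read's compatible transcripts (<= ``max_mismatches`` substitutions).

    Candidate loci come from exact lookups of three disjoint 25-mer windows
    of the read (pigeonhole: with at most two substitutions at least one
    window is error-free), so the search is complete for reads of >= 75
    bases; both strands are tried. Unmapped reads are dropped and counted.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        for pos in range(len(seq) - SEED + 1):
            index.setdefault(seq[pos : pos + SEED], []).append((tid, pos))

    n_windows = max_mismatches + 1
    records: list[CompatibilityRecord] = []
    n_unmapped = 0
    total_len = 0
    for read in reads:
        rid, seq = (read.id, read.seq) if isinstance(read, MergedRead) else (read[0], read[1])
        compatible: set[str] = set()
        for s in (seq, revcomp(seq)):
            L = len(s)
            if L < SEED * n_windows:
                for tid, tseq in transcripts.items():
                    if any(_hamming_le(s, tseq[p : p + L], max_mismatches)
                           for p in range(len(tseq) - L + 1)):
                        compatible.add(tid)
                continue
            candidates: set[tuple[str, int]] = set()
            for w in range(n_windows):
                off = w * SEED
                for tid, pos in index.get(s[off : off + SEED], ()):
                    start = pos - off
                    if start >= 0 and start + L <= len(transcripts[tid]):
                        candidates.add((tid, start))
            for tid, start in candidates:
                if tid in compatible:
                    continue
                if _hamming_le(s, transcripts[tid][start : start + L], max_mismatches):
                    compatible.add(tid)
        if compatible:
            records.append(CompatibilityRecord(rid, tuple(sorted(compatible))))
            total_len += len(seq)
        else:
            n_unmapped += 1
    mean_len = total_len / len(records) if records else 0.0
    return MappingResult(records, n_unmapped, mean_len)


def effective_lengths(lengths: pd.Series, mean_read_length: float) -> pd.Series:
    """Effective length: max(L - mean merged read length + 1, 1)."""
    return np.maximum(lengths - mean_read_length + 1.0, 1.0)


def em_expected_counts(records: list[CompatibilityRecord], eff_lengths: pd.Series,
                       tol: float = 1e-6, max_iter: int = 1000) -> tuple[pd.Series, dict]:
    """EM for expected counts with effective-length-weighted assignment.

    E-step: each read is assigned fractionally over its compatible set with
    weight theta_t / efflen_t; M-step: theta proportional to the fractional
    sums. Uniform initialization; iterate until max |d theta| < tol.
    Returns (EC per transcript, info) where info carries iterations,
    convergence flag, and the per-iteration log-likelihood trace (which is
    non-decreasing).
    """
    tx_ids = list(eff_lengths.index)
    tx_pos = {t: i for i, t in enumerate(tx_ids)}
    ell = eff_lengths.to_numpy(dtype=float)

    classes: dict[tuple[str, ...], int] = {}
    for rec in records:
        if not rec.transcript_ids:
            raise ValueError(f"read {rec.read_id} has an empty compatibility set")
        classes[rec.transcript_ids] = classes.get(rec.transcript_ids, 0) + 1
    class_sets = [np.array([tx_pos[t] for t in key]) for key in classes]
    class_counts = np.array(list(classes.values()), dtype=float)
    n_reads = class_counts.sum()

    T = len(tx_ids)
    theta = np.full(T, 1.0 / T)
    ll_trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ec = np.zeros(T)
        ll = 0.0
        for members, count in zip(class_sets, class_counts):
            w = theta[members] / ell[members]
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(members), 1.0 / len(members))
                tot = 1.0
                ll += count * np.log(1e-300)
            else:
                ll += count * np.log(tot)
            np.add.at(ec, members, count * w / tot)
        ll_trace.append(float(ll))
        new_theta = ec / n_reads if n_reads > 0 else theta
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations (last delta step)", max_iter)
    ec = theta * n_reads
    return pd.Series(ec, index=tx_ids), {"iterations": n_iter, "converged": converged, "loglik": ll_trace}


def compute_tpm(ec: pd.Series, eff_lengths: pd.Series) -> pd.Series:
    """TPM_t = 1e6 * (EC_t / efflen_t) / sum_u (EC_u / efflen_u)."""
    rate = ec / eff_lengths.reindex(ec.index)
    total = rate.sum()
    if total <= 0:
        logger.warning("all expected counts are zero; TPM set to zero")
        return rate * 0.0
    return 1e6 * rate / total


@dataclass
class ExpressionMatrix:
    ec: pd.DataFrame            # transcripts x samples
    tpm: pd.DataFrame
    eff_length: pd.Series


@dataclass
class FamilyMatrix:
    ec: pd.DataFrame            # families x samples
    tpm: pd.DataFrame
    toxin_share: pd.Series      # per sample, fraction of TPM on toxin families


def quantify_samples(reads_by_sample: dict[str, list], transcripts: dict[str, str],
                     max_mismatches: int = 2) -> ExpressionMatrix:
    """Map + EM + TPM for several samples against one consensus transcriptome."""
    lengths = pd.Series({t: len(s) for t, s in transcripts.items()}, dtype=float)
    ec_cols, tpm_cols = {}, {}
    eff = None
    for sample, reads in reads_by_sample.items():
        mapping = map_reads(reads, transcripts, max_mismatches)
        eff_s = effective_lengths(lengths, mapping.mean_read_length)
        ec, _ = em_expected_counts(mapping.records, eff_s)
        ec_cols[sample] = ec
        tpm_cols[sample] = compute_tpm(ec, eff_s)
        eff = eff_s if eff is None else eff  # report the first sample's efflen scale
    return ExpressionMatrix(pd.DataFrame(ec_cols), pd.DataFrame(tpm_cols), eff)


def aggregate_families(matrix: ExpressionMatrix, family_map: dict[str, str],
                       toxin_families: set[str] | None = None) -> FamilyMatrix:
    """Sum EC and TPM across paralogous transcripts of the same family.

    Every transcript must carry a family (nontoxins included); an
    unannotated transcript in the matrix is an upstream pipeline error.
    """
    missing = [t for t in matrix.tpm.index if t not in family_map]
    if missing:
        raise ValueError(f"unannotated transcripts in expression matrix: {missing[:5]}")
    fams = pd.Series({t: family_map[t] for t in matrix.tpm.index})
    fam_ec = matrix.ec.groupby(fams).sum()
    fam_tpm = matrix.tpm.groupby(fams).sum()
    if toxin_families is None:
        toxin_families = set(fam_tpm.index) - {"nontoxin"}
    tox = fam_tpm.loc[sorted(set(fam_tpm.index) & toxin_families)]
    share = tox.sum(axis=0) / fam_tpm.sum(axis=0)
    return FamilyMatrix(fam_ec, fam_tpm, share)


def impute_zeros(matrix: pd.DataFrame, total: float = 1e6) -> pd.DataFrame:
    """Multiplicative zero replacement preserving compositional closure.

    Per sample (column), zeros become delta = half the smallest nonzero
    value, and nonzero entries are scaled by (1 - sum(delta)/total) so the
    column still sums to ``total``.
    """
    out = matrix.astype(float).copy()
    for col in out.columns:
        x = out[col].to_numpy()
        if (x == 0).all():
            raise ValueError(f"sample {col} is all zero; cannot impute")
        zeros = x == 0
        if not zeros.any():
            continue
        delta = 0.5 * x[~zeros].min()
        scale = 1.0 - delta * zeros.sum() / total
        x = np.where(zeros, delta, x * scale)
        out[col] = x
    return out


def composition_report(family: FamilyMatrix, toxin_families: set[str] | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent contribution of each toxin family to the toxin transcriptome.

    Per sample: 100 * family TPM / total toxin TPM. The average column is
    computed from mean per-family TPM across samples, then converted to a
    percent (not the mean of the per-sample percentages). Returns
    (numeric table, formatted table with values rounded to 0.1 and
    sub-0.1% entries printed as "<0.1%").
    """
    fam_tpm = family.tpm
    if toxin_families is None:
        toxin_families = set(fam_tpm.index) - {"nontoxin"}
    tox = fam_tpm.loc[sorted(set(fam_tpm.index) & toxin_families)]
    totals = tox.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero toxin TPM in samples: {bad}")
    pct = 100.0 * tox / totals
    avg_tpm = tox.mean(axis=1)
    pct["Avg."] = 100.0 * avg_tpm / avg_tpm.sum()
    pct = pct.sort_values("Avg.", ascending=False)
    formatted = pct.map(lambda v: "<0.1%" if 0 < v < 0.05 else f"{v:.1f}%")
    return pct, formatted
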