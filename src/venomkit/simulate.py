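"""Synthetic venom-gland transcriptome generator with known ground truth.

Emulates the data a small rear-fanged snake DVG RNA-seq study produces:
a curated toxin/nontoxin protein reference with family labels and signal
peptides, per-individual expression profiles structured by toxin family
(three-finger-toxin dominated, as in the study species), three perturbed
assembly sets per individual (duplicates, end truncations, both alleles of
heterozygous loci, injected chimeras), and 150 bp paired-end reads drawn
from ~400 bp fragments. Everything downstream of sequencing is therefore
testable against exact truth without any download.

The twelve-family vocabulary and the default family profile follow the
composition reported for Tantilla nigriceps (3FTx 54.3%, CRISP 24.0%,
SVMPIII 18.4%, CTL 3.1% of toxin expression, with eight minor families
sharing the remaining 0.2%), with toxins accounting for 63.7% of overall
expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from venomkit.cluster import Contig
from venomkit.io import revcomp

logger = logging.getLogger(__name__)

TOXIN_FAMILIES = (
    "3FTx", "CRISP", "SVMPIII", "CTL", "AChE", "fused",
    "KUN", "PDE", "PLA2", "PLB", "VEGF", "waprin",
)
NONTOXIN = "nontoxin"

#: Average percent of toxin expression per family, as proportions; the eight
#: minor families split 0.2% equally.
DEFAULT_FAMILY_PROFILE: dict[str, float] = {
    "3FTx": 0.543, "CRISP": 0.240, "SVMPIII": 0.184, "CTL": 0.031,
    **{fam: 0.00025 for fam in ("AChE", "fused", "KUN", "PDE", "PLA2", "PLB", "VEGF", "waprin")},
}

#: Unique toxin transcripts per family in the consensus transcriptome of the
#: study species (36 total).
DEFAULT_FAMILY_COUNTS: dict[str, int] = {
    "3FTx": 9, "CRISP": 2, "SVMPIII": 8, "CTL": 7, "AChE": 3, "fused": 1,
    "KUN": 1, "PDE": 1, "PLA2": 1, "PLB": 1, "VEGF": 1, "waprin": 1,
}

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for aa in _BACK_TABLE:
    _BACK_TABLE[aa].sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)

_Q_OK = chr(37 + 33)      # Q37 for correct base calls
_Q_ERR = chr(11 + 33)     # Q11 at substitution-error positions
_Q_TAIL = chr(2 + 33)     # Q2 in the optional low-quality 3' tail

ASSEMBLER_TAGS = ("asm1", "asm2", "asm3")


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Rates are probabilities in [0, 1]; lengths in bases. ``family_profile``
    gives each toxin family's expected share of toxin expression and must
    sum to 1; ``toxin_fraction`` is the toxin share of total expression.
    ``family_counts`` fixes the number of reference transcripts per family
    (defaults to the study's 36-toxin breakdown); when None, ``n_toxin_refs``
    is allocated proportionally to the profile with at least one per family.
    """

    n_individuals: int = 6
    n_toxin_refs: int = 36
    family_profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FAMILY_PROFILE))
    family_counts: dict[str, int] | None = field(default_factory=lambda: dict(DEFAULT_FAMILY_COUNTS))
    n_nontoxins: int = 200
    toxin_fraction: float = 0.637
    read_length: int = 150
    mean_fragment: int = 400
    fragment_log_sd: float = 0.8
    edge_piece_prob: float = 0.4
    per_base_error: float = 0.0
    chimera_rate: float = 0.1
    allelic_divergence: float = 0.005
    het_rate: float = 0.3
    dup_rate: float = 0.05
    trunc_rate: float = 0.10
    max_trunc_frac: float = 0.10
    paralog_divergence: float = 0.25
    family_sigma: float = 0.3
    transcript_sigma: float = 0.5
    toxin_len_range: tuple[int, int] = (160, 240)      # aa, signal peptide included
    nontoxin_len_range: tuple[int, int] = (160, 280)   # aa
    signal_peptide_len: int = 20                       # codons
    low_quality_tail: int = 0                          # Q2 bases at each mate's 3' end
    seed: int = 0

    def __post_init__(self):
        nonzero = {f: p for f, p in self.family_profile.items() if p > 0}
        if not nonzero:
            raise ConfigurationError("family_profile has no family with nonzero proportion")
        total = sum(self.family_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"family_profile proportions sum to {total}, expected 1")
        if self.read_length > self.mean_fragment:
            raise ConfigurationError("read_length must not exceed mean_fragment")
        for name in ("per_base_error", "chimera_rate", "allelic_divergence", "het_rate",
                     "dup_rate", "trunc_rate", "max_trunc_frac", "toxin_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.family_counts is None and self.n_toxin_refs < len(nonzero):
            raise ConfigurationError("n_toxin_refs smaller than the number of nonzero-profile families")


@dataclass
class ReferenceRecord:
    id: str
    family: str
    protein: str
    cds: str                                  # coding sequence including stop codon
    signal_peptide: tuple[int, int] | None    # 0-based half-open aa interval

    @property
    def is_toxin(self) -> bool:
        return self.family != NONTOXIN


@dataclass
class IndividualTruth:
    """Ground truth for one individual: expressed alleles and their TPM."""

    individual: str
    transcripts: dict[str, str]               # allele id -> sequence
    tpm: pd.Series                            # index = allele id, sums to 1e6
    family: dict[str, str]
    source: dict[str, str]                    # allele id -> reference id
    chimeras: dict[str, dict] = field(default_factory=dict)  # contig id -> {junction, parents}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "transcript_id": tid, "individual": self.individual,
                "true_tpm": float(self.tpm[tid]), "family": self.family[tid],
                "is_chimera": False, "source_ref": self.source[tid], "junction": -1,
            }
            for tid in self.transcripts
        ]
        for cid, info in self.chimeras.items():
            rows.append({
                "transcript_id": cid, "individual": self.individual, "true_tpm": 0.0,
                "family": "chimera", "is_chimera": True,
                "source_ref": "+".join(info["parents"]), "junction": info["junction"],
            })
        return pd.DataFrame(rows)


def _rng(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *key])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.integers(0, len(_AA_ALPHABET), size=length - 1)
    return "M" + "".join(_AA_ALPHABET[i] for i in body)


def _mutate_protein(rng: np.random.Generator, protein: str, divergence: float) -> str:
    n_mut = rng.binomial(len(protein) - 1, divergence)
    if n_mut == 0:
        return protein
    positions = rng.choice(np.arange(1, len(protein)), size=n_mut, replace=False)
    seq = list(protein)
    for pos in positions:
        current = seq[pos]
        options = [a for a in _AA_ALPHABET if a != current]
        seq[pos] = options[rng.integers(0, len(options))]
    return "".join(seq)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [_BACK_TABLE[aa][rng.integers(0, len(_BACK_TABLE[aa]))] for aa in protein]
    codons.append(_STOP_CODONS[rng.integers(0, len(_STOP_CODONS))])
    return "".join(codons)


def _allocate_counts(config: GeneratorConfig) -> dict[str, int]:
    if config.family_counts is not None:
        counts = {f: int(n) for f, n in config.family_counts.items()
                  if config.family_profile.get(f, 0.0) > 0 and n > 0}
        if not counts:
            raise ConfigurationError("family_counts leaves no nonzero-profile family populated")
        return counts
    nonzero = {f: p for f, p in config.family_profile.items() if p > 0}
    total = sum(nonzero.values())
    counts = {f: 1 for f in nonzero}
    remaining = config.n_toxin_refs - len(nonzero)
    if remaining < 0:
        raise ConfigurationError("n_toxin_refs smaller than the number of nonzero-profile families")
    quotas = {f: remaining * p / total for f, p in nonzero.items()}
    for f in nonzero:
        counts[f] += int(quotas[f])
    leftovers = sorted(nonzero, key=lambda f: (-(quotas[f] - int(quotas[f])), f))
    for f in leftovers[: remaining - sum(int(quotas[f]) for f in nonzero)]:
        counts[f] += 1
    return counts


def build_reference(config: GeneratorConfig) -> list[ReferenceRecord]:
    """Generate the curated toxin/nontoxin protein + coding reference set.

    Toxin families descend from a per-family ancestor protein, with paralogs
    diverged at ``paralog_divergence``; nontoxins are independent random
    proteins. Each record's coding sequence back-translates the protein with
    randomly chosen synonymous codons plus a stop, so its translation equals
    the protein exactly. Deterministic for a fixed seed.
    """
    rng = _rng(config, 1)
    counts = _allocate_counts(config)
    records: list[ReferenceRecord] = []
    sp = (0, config.signal_peptide_len)
    lo, hi = config.toxin_len_range
    for family in sorted(counts, key=lambda f: (TOXIN_FAMILIES.index(f) if f in TOXIN_FAMILIES else 99, f)):
        ancestor = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        for k in range(counts[family]):
            protein = ancestor if k == 0 else _mutate_protein(rng, ancestor, config.paralog_divergence)
            cds = _reverse_translate(rng, protein)
            records.append(ReferenceRecord(f"{family}_{k + 1}", family, protein, cds, sp))
    nlo, nhi = config.nontoxin_len_range
    for k in range(config.n_nontoxins):
        protein = _random_protein(rng, int(rng.integers(nlo, nhi + 1)))
        cds = _reverse_translate(rng, protein)
        records.append(ReferenceRecord(f"NT{k + 1:04d}", NONTOXIN, protein, cds, None))
    return records


def simulate_expression(reference: list[ReferenceRecord], config: GeneratorConfig,
                        individual_index: int, family_sigma: float | None = None) -> IndividualTruth:
    """Draw one individual's expressed transcripts (with heterozygosity) and true TPM.

    Family proportions are log-normal perturbations of the configured profile
    (sigma = ``family_sigma``), renormalized within the toxin share;
    transcript weights within a family are log-normal with
    ``transcript_sigma``. Heterozygous loci (probability ``het_rate``)
    express two alleles - the reference sequence and a variant diverged at
    ``allelic_divergence`` - each with half the locus TPM. TPM sums to 1e6.
    """
    sigma = config.family_sigma if family_sigma is None else family_sigma
    rng = _rng(config, 2, individual_index)
    ind = f"ind{individual_index + 1}"

    toxins = [r for r in reference if r.is_toxin]
    nontoxins = [r for r in reference if not r.is_toxin]
    fam_props = {}
    for fam in sorted({r.family for r in toxins}):
        base = config.family_profile.get(fam, 0.0)
        fam_props[fam] = base * float(np.exp(sigma * rng.standard_normal())) if base > 0 else 0.0
    total = sum(fam_props.values())
    fam_props = {f: p / total for f, p in fam_props.items()}

    weights: dict[str, float] = {}
    for fam in sorted(fam_props):
        members = [r for r in toxins if r.family == fam]
        w = np.exp(config.transcript_sigma * rng.standard_normal(len(members)))
        w = w / w.sum() * fam_props[fam] * config.toxin_fraction
        for r, wi in zip(members, w):
            weights[r.id] = float(wi)
    if nontoxins:
        w = np.exp(config.transcript_sigma * rng.standard_normal(len(nontoxins)))
        w = w / w.sum() * (1.0 - config.toxin_fraction)
        for r, wi in zip(nontoxins, w):
            weights[r.id] = float(wi)

    by_id = {r.id: r for r in reference}
    transcripts: dict[str, str] = {}
    tpm: dict[str, float] = {}
    family: dict[str, str] = {}
    source: dict[str, str] = {}
    for rid in weights:
        rec = by_id[rid]
        het = rng.random() < config.het_rate and config.allelic_divergence > 0
        if het:
            variant = _mutate_nt(rng, rec.cds, config.allelic_divergence)
            alleles = {f"{rid}.a": rec.cds, f"{rid}.b": variant}
        else:
            alleles = {rid: rec.cds}
        share = weights[rid] / len(alleles)
        for aid, seq in alleles.items():
            transcripts[aid] = seq
            tpm[aid] = share
            family[aid] = rec.family
            source[aid] = rid

    tpm_s = pd.Series(tpm, dtype=float)
    tpm_s = tpm_s / tpm_s.sum() * 1e6
    return IndividualTruth(ind, transcripts, tpm_s, family, source)


def _mutate_nt(rng: np.random.Generator, seq: str, divergence: float) -> str:
    n_mut = rng.binomial(len(seq), divergence)
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        options = [b for b in "ACGT" if b != out[pos]]
        out[pos] = options[rng.integers(0, 3)]
    return "".join(out)


class GenerationError(RuntimeError):
    pass


def simulate_assemblies(truth: IndividualTruth, config: GeneratorConfig) -> dict[str, list[Contig]]:
    """Emulate three assemblers' contig sets for one individual.

    Each set carries every expressed transcript with set-specific
    perturbations: occasional exact duplicates (``dup_rate``), 5'/3'
    truncations of up to ``max_trunc_frac`` (``trunc_rate``), and injected
    chimeras (5' half of one transcript joined to the 3' half of another)
    at ``chimera_rate`` per base contig. Chimera junctions are recorded in
    the truth table.
    """
    idx = int(truth.individual.removeprefix("ind")) - 1
    rng = _rng(config, 3, idx)
    tx_ids = sorted(truth.transcripts)
    if config.chimera_rate > 0 and len(tx_ids) < 2:
        raise GenerationError("chimera injection requires at least two transcripts")
    sets: dict[str, list[Contig]] = {}
    for tag in ASSEMBLER_TAGS:
        contigs: list[Contig] = []
        for tid in tx_ids:
            seq = truth.transcripts[tid]
            if rng.random() < config.trunc_rate and len(seq) > config.read_length * 2:
                cut = int(rng.integers(1, max(2, int(len(seq) * config.max_trunc_frac)) + 1))
                seq = seq[cut:] if rng.random() < 0.5 else seq[:-cut]
            cid = f"{truth.individual}.{tag}.{tid}"
            contigs.append(Contig(cid, seq, truth.individual, tag))
            if rng.random() < config.dup_rate:
                contigs.append(Contig(cid + ".dup", seq, truth.individual, tag))
        n_chim = rng.binomial(len(tx_ids), config.chimera_rate)
        for j in range(n_chim):
            a, b = rng.choice(len(tx_ids), size=2, replace=False)
            seq_a, seq_b = truth.transcripts[tx_ids[a]], truth.transcripts[tx_ids[b]]
            junction = len(seq_a) // 2
            chim = seq_a[:junction] + seq_b[len(seq_b) // 2 :]
            cid = f"{truth.individual}.{tag}.chim{j + 1}"
            contigs.append(Contig(cid, chim, truth.individual, tag))
            truth.chimeras[cid] = {"junction": junction, "parents": (tx_ids[a], tx_ids[b])}
        sets[tag] = contigs
    return sets


def simulate_reads(truth: IndividualTruth, n_pairs: int,
                   config: GeneratorConfig) -> list[tuple[str, str, str, str, str]]:
    """Simulate paired 150 bp reads as ``(id, seq1, qual1, seq2, qual2)`` tuples.

    Fragment lengths are log-normal with mean ``mean_fragment`` (truncated
    below at ``read_length`` and above at the transcript length); given a
    fragment length f, the source transcript is drawn with probability
    proportional to TPM x (number of valid start positions), then the start
    uniformly - the standard generative model under which TPM is the
    recoverable quantity. R1 is the first ``read_length`` bases of the
    fragment, R2 the reverse complement of the last. Substitution errors at
    ``per_base_error`` are marked Q11; correct calls are Q37. Read ids embed
    the true source as ``id|transcript|start-end``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    idx = int(truth.individual.removeprefix("ind")) - 1
    rng = _rng(config, 4, idx)
    rl = config.read_length

    tx_ids = sorted(truth.transcripts)
    lengths = np.array([len(truth.transcripts[t]) for t in tx_ids])
    tpm = np.array([truth.tpm[t] for t in tx_ids], dtype=float)
    usable = lengths >= rl
    if not usable.all():
        dropped = [tx_ids[i] for i in np.flatnonzero(~usable)]
        logger.warning("excluding %d transcripts shorter than read_length: %s", len(dropped), dropped[:5])
        tpm = np.where(usable, tpm, 0.0)
    if tpm.sum() <= 0:
        raise GenerationError("no transcript long enough to sample reads from")

    mu = np.log(config.mean_fragment) - 0.5 * config.fragment_log_sd**2
    frags = np.rint(rng.lognormal(mu, config.fragment_log_sd, size=n_pairs)).astype(int)
    frags = np.maximum(frags, rl)

    tx_choice = np.empty(n_pairs, dtype=int)
    order = np.argsort(frags, kind="stable")
    sorted_f = frags[order]
    boundaries = np.flatnonzero(np.diff(sorted_f)) + 1
    groups = np.split(order, boundaries)
    for grp in groups:
        f = frags[grp[0]]
        w = tpm * np.clip(lengths - f + 1, 1, None)
        tx_choice[grp] = rng.choice(len(tx_ids), size=len(grp), p=w / w.sum())

    # Fragment placement emulates shearing of intact molecules. Each sheared
    # molecule yields two end pieces among roughly L/f interior ones, so a
    # substantial fraction of fragments is anchored at a molecule boundary
    # (``edge_piece_prob``); the remainder start anywhere, with the virtual
    # start allowed up to (f - read_length) bases before the 5' end and the
    # piece clipped at the boundaries. Edge bases therefore see the same
    # order of coverage as interior bases, as in real libraries.
    L_sel = lengths[tx_choice]
    f_capped = np.minimum(frags, L_sel + frags - 2 * rl)  # keep the start range valid
    lo = rl - f_capped
    hi = L_sel - rl
    starts_virtual = lo + (rng.random(n_pairs) * (hi - lo + 1)).astype(int)
    u = rng.random(n_pairs)
    is_head = u < 0.5 * config.edge_piece_prob
    is_tail = (u >= 0.5 * config.edge_piece_prob) & (u < config.edge_piece_prob)
    starts_virtual[is_head] = 0
    starts_virtual[is_tail] = (L_sel - f_capped)[is_tail]
    starts = np.maximum(starts_virtual, 0)
    ends = np.minimum(starts_virtual + f_capped, L_sel)
    f_eff = ends - starts

    err = config.per_base_error
    tail = config.low_quality_tail
    base_qual = _Q_OK * rl
    if tail > 0:
        base_qual = base_qual[: rl - tail] + _Q_TAIL * min(tail, rl)
    pairs = []
    for i in range(n_pairs):
        tid = tx_ids[tx_choice[i]]
        seq = truth.transcripts[tid]
        s, f = int(starts[i]), int(f_eff[i])
        frag = seq[s : s + f]
        r1 = frag[:rl]
        r2 = revcomp(frag[-rl:])
        q1 = q2 = base_qual
        if err > 0:
            r1, q1 = _apply_errors(rng, r1, q1, err)
            r2, q2 = _apply_errors(rng, r2, q2, err)
        rid = f"{truth.individual}.rd{i + 1}|{tid}|{s}-{s + f}"
        pairs.append((rid, r1, q1, r2, q2))
    return pairs


def _apply_errors(rng: np.random.Generator, seq: str, qual: str, rate: float) -> tuple[str, str]:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq, qual
    s, q = list(seq), list(qual)
    for pos in hits:
        options = [b for b in "ACGT" if b != s[pos]]
        s[pos] = options[rng.integers(0, 3)]
        q[pos] = _Q_ERR
    return "".join(s), "".join(q)


def expected_sampling_weight(lengths: np.ndarray, config: GeneratorConfig,
                             n_grid: int = 20000) -> np.ndarray:
    """Expected per-transcript read-sampling weight (up to TPM), E_f[max(L-f+1, 1)].

    Useful for convergence tests: marginal read counts are proportional to
    TPM times this length-dependent weight.
    """
    mu = np.log(config.mean_fragment) - 0.5 * config.fragment_log_sd**2
    rng = np.random.default_rng(12345)
    f = np.maximum(np.rint(rng.lognormal(mu, config.fragment_log_sd, size=n_grid)), config.read_length)
    return np.array([np.mean(np.clip(L - f + 1, 1, None)) for L in np.asarray(lengths)])


def simulate_metadata(config: GeneratorConfig) -> pd.DataFrame:
    """Per-individual life-history covariates (sex, SVL, state, latitude, longitude).

    Drawn once per seed from plausible ranges for a Chihuahuan Desert /
    southern Great Plains colubrid: SVL 140-250 mm, latitudes 27-35 N,
    longitudes 106-98 W, two states.
    """
    rng = _rng(config, 5)
    n = config.n_individuals
    rows = []
    for i in range(n):
        state = "TX" if rng.random() < 0.5 else "NM"
        rows.append({
            "individual": f"ind{i + 1}",
            "sex": "F" if rng.random() < 0.5 else "M",
            "SVL": float(np.round(rng.uniform(140, 250), 1)),
            "state": state,
            "latitude": float(np.round(rng.uniform(27.5, 35.0), 3)),
            "longitude": float(np.round(rng.uniform(-106.0, -98.0), 3)),
        })
    df = pd.DataFrame(rows).set_index("individual")
    # guarantee both binary covariates have two levels
    if df["sex"].nunique() == 1:
        df.iloc[0, df.columns.get_loc("sex")] = "M" if df["sex"].iloc[0] == "F" else "F"
    if df["state"].nunique() == 1:
        df.iloc[0, df.columns.get_loc("state")] = "NM" if df["state"].iloc[0] == "TX" else "TX"
    return df


def reference_protein_fasta(reference: list[ReferenceRecord]) -> list[tuple[str, str]]:
    from venomkit.io import format_ref_header

    return [(format_ref_header(r.id, r.family, r.signal_peptide), r.protein) for r in reference]


def reference_coding_fasta(reference: list[ReferenceRecord]) -> list[tuple[str, str]]:
    return [(r.id, r.cds) for r in reference]
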