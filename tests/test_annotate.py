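"""Translation, translated search with E-values, annotation rules, peptide scan."""

import math

import numpy as np
import pytest

from venomkit.annotate import (
    Annotation,
    ReferenceProtein,
    ReferenceSet,
    annotate_contig,
    assign_family,
    karlin_altschul_evalue,
    longest_orf,
    peptide_fragment_scan,
    translate,
    translated_search,
)
from venomkit.io import revcomp
from venomkit.simulate import build_reference, simulate_expression

from conftest import small_generator_config

AA = "ACDEFGHIKLMNPQRSTVWY"


def refset_from(records):
    return ReferenceSet([ReferenceProtein(r.id, r.protein, r.family, r.signal_peptide)
                         for r in records])


def dinucleotide_shuffle(rng, seq):
    pairs = [seq[i : i + 2] for i in range(0, len(seq) - 1, 2)]
    rng.shuffle(pairs)
    return "".join(pairs)


class TestTranslate:
    def test_stop_terminates_translation(self):
        assert translate("ATGAAATAA", 0) == "MK"

    def test_full_frame_keeps_stops(self):
        assert translate("ATGAAATAAATG", 0, to_stop=False) == "MK*M"

    def test_n_codon_gives_x(self):
        assert translate("ATGANA", 0, to_stop=False) == "MX"

    def test_too_short_sequence(self):
        assert translate("AT", 0) == ""

    def test_reverse_frames_translate_reverse_complement(self):
        cds = "ATGAAACCCGGGTAA"
        assert translate(revcomp(cds), -1) == translate(cds, 0)


class TestLongestOrf:
    def test_recovers_generator_protein(self, small_reference):
        for rec in small_reference[:8]:
            orf, info = longest_orf(rec.cds)
            assert orf == rec.protein
            assert info["frame"] == 0

    def test_strand_symmetric(self, small_reference):
        rec = small_reference[0]
        orf_fwd, _ = longest_orf(rec.cds)
        orf_rev, info = longest_orf(revcomp(rec.cds))
        assert orf_rev == orf_fwd
        assert info["frame"] < 0


class TestEvalue:
    def test_formula_example(self):
        # S=60, m=100, n=1000: E = 0.041 * 1e5 * exp(-0.267*60) ~ 4.5e-4
        e = karlin_altschul_evalue(60, 100, 1000)
        assert e == pytest.approx(0.041 * 1e5 * math.exp(-0.267 * 60), rel=1e-12)
        assert e == pytest.approx(4.51e-4, rel=0.01)
        assert e > 1e-4  # rejected at the annotation floor

    def test_huge_scores_underflow_to_zero(self):
        assert karlin_altschul_evalue(10_000, 100, 1000) == 0.0


class TestTranslatedSearch:
    def test_exact_coding_contig_hits_its_reference(self, small_reference):
        refset = refset_from(small_reference)
        rec = small_reference[0]
        hits = translated_search(rec.cds, refset)
        assert hits and hits[0].reference_id == rec.id
        assert hits[0].evalue < 1e-10
        assert hits[0].identity == 1.0

    def test_reverse_strand_contig_found(self, small_reference):
        refset = refset_from(small_reference)
        rec = small_reference[3]
        hits = translated_search(revcomp(rec.cds), refset)
        assert hits and hits[0].reference_id == rec.id
        assert hits[0].frame < 0

    def test_shuffled_contigs_yield_no_hits(self, small_reference):
        refset = refset_from(small_reference)
        rng = np.random.default_rng(0)
        for k in range(20):
            shuffled = dinucleotide_shuffle(rng, small_reference[k % 5].cds)
            assert translated_search(shuffled, refset) == []


class TestAnnotateContig:
    def test_exact_copy_auto_annotated_with_signal_peptide(self, small_reference):
        refset = refset_from(small_reference)
        rec = next(r for r in small_reference if r.family == "3FTx")
        ann = annotate_contig("c1", rec.cds, refset)
        assert ann.mode == "auto"
        assert ann.family == "3FTx"
        assert ann.signal_peptide_nt == (0, 60)

    def test_divergent_copy_goes_to_manual(self, small_reference):
        rng = np.random.default_rng(1)
        refset = refset_from(small_reference)
        rec = small_reference[0]
        protein = list(rec.protein)
        for pos in rng.choice(np.arange(1, len(protein)), size=int(0.3 * len(protein)),
                              replace=False):
            protein[pos] = rng.choice([a for a in AA if a != protein[pos]])
        from venomkit.simulate import _reverse_translate
        contig = _reverse_translate(rng, "".join(protein))
        ann = annotate_contig("c1", contig, refset)
        assert ann.mode == "manual"
        assert ann.evalue <= 1e-4
        assert ann.identity < 0.80

    def test_random_sequence_unannotated(self, small_reference):
        rng = np.random.default_rng(2)
        refset = refset_from(small_reference)
        contig = "".join(rng.choice(list("ACGT"), 600))
        ann = annotate_contig("c1", contig, refset)
        assert ann.mode == "unannotated"
        assert ann.family is None

    def test_independent_of_reference_ordering(self, small_reference):
        rec = small_reference[2]
        fwd = annotate_contig("c", rec.cds, refset_from(small_reference))
        rev = annotate_contig("c", rec.cds, refset_from(small_reference[::-1]))
        assert (fwd.reference_id, fwd.family, fwd.mode) == (rev.reference_id, rev.family, rev.mode)
        assert fwd.identity == rev.identity

    def test_synthetic_recovery_of_true_families(self, small_config, small_reference):
        # generator output at default divergence: every non-chimeric toxin
        # transcript annotates to its true family
        refset = refset_from(small_reference)
        truth = simulate_expression(small_reference, small_config, 0)
        n = correct = 0
        for tid, seq in truth.transcripts.items():
            fam = truth.family[tid]
            if fam == "nontoxin":
                continue
            n += 1
            correct += annotate_contig(tid, seq, refset).family == fam
        assert n > 0 and correct == n


class TestAssignFamily:
    def test_single_member(self):
        anns = [Annotation("c1", "r", "3FTx", 1.0, 0.0, "auto")]
        assert assign_family(anns, {"c1": 10.0}) == {"c1": "3FTx-1"}

    def test_ordering_by_mean_tpm(self):
        anns = [Annotation(c, "r", "3FTx", 1.0, 0.0, "auto") for c in ("a", "b", "c")]
        labels = assign_family(anns, {"a": 10.0, "b": 30.0, "c": 20.0})
        assert labels == {"b": "3FTx-1", "c": "3FTx-2", "a": "3FTx-3"}

    def test_tie_breaks_toward_smaller_id(self):
        anns = [Annotation(c, "r", "CTL", 1.0, 0.0, "auto") for c in ("z", "a")]
        labels = assign_family(anns, {"z": 5.0, "a": 5.0})
        assert labels == {"a": "CTL-1", "z": "CTL-2"}

    def test_unannotated_excluded(self):
        anns = [Annotation("u", None, None, 0.0, math.inf, "unannotated")]
        assert assign_family(anns, {}) == {}


class TestPeptideFragmentScan:
    def test_exact_containment_scores_full_length(self):
        prot = "MKTLLLTLVVVTIVCLDLGYTAAAA"
        peptide = prot[5:19]
        table = peptide_fragment_scan(peptide, {"p": prot})
        assert table.loc[0, "max_matches"] == 14

    def test_disjoint_alphabets_score_zero(self):
        assert peptide_fragment_scan("AAAAA", {"p": "CCCCC"}).loc[0, "max_matches"] == 0

    def test_partial_match_verified_by_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        peptide = "".join(rng.choice(list(AA), 14))
        # protein sharing exactly 7 residues at offset 4, low background
        prot = list("".join(rng.choice(list("WY"), 40)))
        clean_pep = peptide.replace("W", "A").replace("Y", "A")
        for j in range(7):
            prot[4 + j] = clean_pep[j]
        prot = "".join(prot)
        best = max(
            sum(1 for j in range(14) if 0 <= off + j < len(prot) and prot[off + j] == clean_pep[j])
            for off in range(-13, len(prot))
        )
        table = peptide_fragment_scan(clean_pep, {"p": prot})
        assert table.loc[0, "max_matches"] == best == 7

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            peptide_fragment_scan("", {"p": "AAA"})

    def test_empty_transcript_set(self):
        assert peptide_fragment_scan("AAA", {}).empty
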