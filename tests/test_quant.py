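"""Read mapping, EM expected counts, TPM, family aggregation, imputation."""

import numpy as np
import pandas as pd
import pytest

from venomkit.quant import (
    CompatibilityRecord,
    ExpressionMatrix,
    aggregate_families,
    composition_report,
    compute_tpm,
    effective_lengths,
    em_expected_counts,
    impute_zeros,
    map_reads,
    quantify_samples,
)
from venomkit.simulate import build_reference, simulate_expression, simulate_reads
from venomkit.readproc import merge_pairs

from conftest import small_generator_config


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestMapReads:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.t1 = rand_seq(rng, 400)
        shared = self.t1[100:300]
        self.t2 = rand_seq(rng, 80) + shared + rand_seq(rng, 120)
        self.tx = {"t1": self.t1, "t2": self.t2}

    def test_unique_exact_read_maps_once(self):
        res = map_reads([("r", self.t1[0:150])], self.tx)
        assert res.records[0].transcript_ids == ("t1",)

    def test_shared_region_maps_to_both(self):
        res = map_reads([("r", self.t1[110:260])], self.tx)
        assert res.records[0].transcript_ids == ("t1", "t2")

    def test_two_mismatches_tolerated_three_rejected(self):
        read = list(self.t1[10:190])
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for pos in (30, 90):
            read[pos] = flip[read[pos]]
        assert map_reads([("r", "".join(read))], self.tx).records
        read[150] = flip[read[150]]
        res = map_reads([("r", "".join(read))], self.tx)
        assert not res.records and res.n_unmapped == 1


class TestEmExpectedCounts:
    def test_unique_mappings_equal_raw_counts(self):
        eff = pd.Series({"a": 100.0, "b": 100.0})
        recs = [CompatibilityRecord(f"r{i}", ("a",)) for i in range(3)]
        recs += [CompatibilityRecord("r4", ("b",))]
        ec, info = em_expected_counts(recs, eff)
        assert ec["a"] == pytest.approx(3.0, abs=1e-9)
        assert ec["b"] == pytest.approx(1.0, abs=1e-9)
        assert info["iterations"] <= 2

    def test_shared_reads_fixed_point(self):
        # 2 reads unique to A and 2 shared: the EM fixed point pushes all
        # shared mass to A (equal lengths), EC -> (4, 0)
        eff = pd.Series({"a": 100.0, "b": 100.0})
        recs = [CompatibilityRecord("u1", ("a",)), CompatibilityRecord("u2", ("a",)),
                CompatibilityRecord("s1", ("a", "b")), CompatibilityRecord("s2", ("a", "b"))]
        ec, info = em_expected_counts(recs, eff, tol=1e-9)
        assert ec["a"] == pytest.approx(4.0, abs=1e-6)
        assert ec["b"] == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_problem_splits_evenly(self):
        eff = pd.Series({"a": 100.0, "b": 100.0})
        recs = [CompatibilityRecord(f"s{i}", ("a", "b")) for i in range(6)]
        ec, _ = em_expected_counts(recs, eff)
        assert ec["a"] == pytest.approx(3.0, abs=1e-6)

    def test_loglik_is_monotone(self):
        rng = np.random.default_rng(1)
        tx = [f"t{i}" for i in range(8)]
        eff = pd.Series(rng.uniform(50, 400, 8), index=tx)
        recs = []
        for i in range(300):
            k = int(rng.integers(1, 4))
            members = tuple(sorted(rng.choice(tx, size=k, replace=False)))
            recs.append(CompatibilityRecord(f"r{i}", members))
        _, info = em_expected_counts(recs, eff)
        ll = info["loglik"]
        assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))

    def test_ec_sums_to_read_count(self):
        eff = pd.Series({"a": 10.0, "b": 20.0, "c": 30.0})
        recs = [CompatibilityRecord(f"r{i}", ("a", "b") if i % 2 else ("b", "c"))
                for i in range(11)]
        ec, _ = em_expected_counts(recs, eff)
        assert ec.sum() == pytest.approx(11.0, abs=1e-6)

    def test_empty_compatibility_rejected(self):
        with pytest.raises(ValueError):
            em_expected_counts([CompatibilityRecord("r", ())], pd.Series({"a": 1.0}))


class TestComputeTpm:
    def test_single_transcript_gets_the_million(self):
        tpm = compute_tpm(pd.Series({"a": 7.0}), pd.Series({"a": 123.0}))
        assert tpm["a"] == pytest.approx(1e6)

    def test_length_normalization_example(self):
        tpm = compute_tpm(pd.Series({"a": 10.0, "b": 10.0}), pd.Series({"a": 100.0, "b": 200.0}))
        assert tpm["a"] == pytest.approx(666666.67, abs=0.01)
        assert tpm["b"] == pytest.approx(333333.33, abs=0.01)

    def test_scale_invariance(self):
        ec = pd.Series({"a": 3.0, "b": 11.0})
        eff = pd.Series({"a": 130.0, "b": 310.0})
        assert np.allclose(compute_tpm(ec, eff), compute_tpm(2 * ec, eff))

    def test_effective_length_floor(self):
        eff = effective_lengths(pd.Series({"a": 500.0, "b": 120.0}), 180.0)
        assert eff["a"] == pytest.approx(321.0)
        assert eff["b"] == 1.0


class TestAggregateAndCompose:
    def _matrix(self):
        tpm = pd.DataFrame({"s1": [10.0, 20.0, 30.0, 940_000.0],
                            "s2": [5.0, 15.0, 40.0, 939_940.0]},
                           index=["x1", "x2", "y1", "n1"])
        ec = tpm / 10
        return ExpressionMatrix(ec, tpm, pd.Series(1.0, index=tpm.index))

    def test_family_sums(self):
        fams = {"x1": "3FTx", "x2": "3FTx", "y1": "CRISP", "n1": "nontoxin"}
        fam = aggregate_families(self._matrix(), fams)
        assert fam.tpm.loc["3FTx", "s1"] == pytest.approx(30.0)
        assert fam.tpm.sum(axis=0).tolist() == pytest.approx(
            self._matrix().tpm.sum(axis=0).tolist())

    def test_unannotated_transcript_rejected(self):
        with pytest.raises(ValueError, match="unannotated"):
            aggregate_families(self._matrix(), {"x1": "3FTx"})

    def test_composition_single_family(self):
        fams = {"x1": "3FTx", "x2": "3FTx", "y1": "3FTx", "n1": "nontoxin"}
        fam = aggregate_families(self._matrix(), fams)
        pct, formatted = composition_report(fam)
        assert pct.loc["3FTx", "s1"] == pytest.approx(100.0)
        assert formatted.loc["3FTx", "s1"] == "100.0%"

    def test_composition_ratio_and_row_sums(self):
        tpm = pd.DataFrame({"s1": [750.0, 250.0, 10.0]}, index=["a1", "b1", "n"])
        m = ExpressionMatrix(tpm / 10, tpm, pd.Series(1.0, index=tpm.index))
        fam = aggregate_families(m, {"a1": "CRISP", "b1": "CTL", "n": "nontoxin"})
        pct, _ = composition_report(fam)
        assert pct.loc["CRISP", "s1"] == pytest.approx(75.0)
        assert pct.loc["CTL", "s1"] == pytest.approx(25.0)
        assert pct["s1"].sum() == pytest.approx(100.0, abs=0.3)

    def test_zero_toxin_sample_rejected(self):
        tpm = pd.DataFrame({"s1": [0.0, 1e6]}, index=["a1", "n"])
        m = ExpressionMatrix(tpm, tpm, pd.Series(1.0, index=tpm.index))
        fam = aggregate_families(m, {"a1": "CRISP", "n": "nontoxin"})
        with pytest.raises(ValueError, match="zero toxin"):
            composition_report(fam)


class TestImputeZeros:
    def test_no_zero_identity(self):
        m = pd.DataFrame({"s": [400_000.0, 600_000.0]})
        assert impute_zeros(m).equals(m)

    def test_worked_example(self):
        m = pd.DataFrame({"s": [0.0, 999_900.0, 100.0]})
        out = impute_zeros(m)
        assert out.loc[0, "s"] == pytest.approx(50.0)
        assert out.loc[1, "s"] == pytest.approx(999_900.0 * (1 - 50 / 1e6))
        assert out["s"].sum() == pytest.approx(1e6, abs=1e-3)

    def test_imputed_values_below_all_originals(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(100, 1000, 20)
        col[[3, 7]] = 0.0
        col = col / col.sum() * 1e6
        out = impute_zeros(pd.DataFrame({"s": col}))
        imputed = out.loc[[3, 7], "s"]
        others = out.drop(index=[3, 7])["s"]
        assert (imputed > 0).all() and (imputed < others.min()).all()

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            impute_zeros(pd.DataFrame({"s": [0.0, 0.0]}))


def test_tpm_recovery_on_error_free_reads():
    """Quantifying the generator's own merged reads against the true
    transcript set recovers TPM proportions within +/-2% absolute."""
    cfg = small_generator_config(seed=31, het_rate=0.0, chimera_rate=0.0,
                                 n_nontoxins=10, transcript_sigma=1.0)
    ref = build_reference(cfg)
    truth = simulate_expression(ref, cfg, 0)
    pairs = simulate_reads(truth, 60_000, cfg)
    merged, _ = merge_pairs(pairs)
    matrix = quantify_samples({"s1": merged}, dict(truth.transcripts))
    est = matrix.tpm["s1"] / 1e6
    true_prop = truth.tpm / 1e6
    assert (est - true_prop.reindex(est.index)).abs().max() < 0.02
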