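import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from rnasefam.codon_align import CodonAlignment
from rnasefam.evodist import (PairwiseCounts, SaturationError, bootstrap_se,
                              count_codon_differences, count_nucleotide_pair,
                              distance_matrix, jukes_cantor, k2p_distance,
                              nei_gojobori_modified, p_distance,
                              syn_site_fraction)
from rnasefam.gene_models import STOP_CODONS
from rnasefam.synthetic_data import evolve_codon_sequence, make_root_sequence

from _oracles import SENSE_CODONS, ng_pair_oracle

RNG = np.random.default_rng(2024)


def random_codon_rows(rng, length, diverge=0.25):
    c1 = [SENSE_CODONS[rng.integers(61)] for _ in range(length)]
    c2 = [c if rng.random() > diverge else SENSE_CODONS[rng.integers(61)]
          for c in c1]
    return c1, c2


class TestPDistance:
    def test_identity_is_zero(self):
        assert p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    @pytest.mark.parametrize("ndiff,length,expected", [
        (2, 100, 0.02), (21, 105, 0.2)])
    def test_analytic_values(self, ndiff, length, expected):
        a = "A" * length
        b = "C" * ndiff + "A" * (length - ndiff)
        assert p_distance(a, b) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            p_distance("", "")


class TestK2P:
    def test_no_differences_gives_zero(self):
        assert k2p_distance(PairwiseCounts(100, 0, 0, 0)) == 0.0

    def test_closed_form_spot_value(self):
        d = k2p_distance(PairwiseCounts(100, 0.15, P=0.1, Q=0.05))
        assert d == pytest.approx(0.17017, abs=5e-5)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(PairwiseCounts(100, 0.55, P=0.45, Q=0.10))

    def test_correction_inflates_distance(self):
        """k2p >= p for all valid (P, Q); equality only at zero divergence."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            P = rng.uniform(0, 0.3)
            Q = rng.uniform(0, 0.3)
            if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
                continue
            d = k2p_distance(PairwiseCounts(100, P + Q, P, Q))
            assert d >= P + Q - 1e-12
        assert k2p_distance(PairwiseCounts(10, 0, 0, 0)) == 0.0

    def test_counts_from_sequences(self):
        counts = count_nucleotide_pair("AAGG", "AGGT")
        assert counts.P == pytest.approx(0.25)  # A->G transition
        assert counts.Q == pytest.approx(0.25)  # G->T transversion
        assert counts.p == pytest.approx(counts.P + counts.Q)


class TestNeiGojobori:
    def test_identical_rows_give_zero(self):
        c1, _ = random_codon_rows(np.random.default_rng(0), 10, 0)
        est = nei_gojobori_modified(c1, c1)
        assert est.Sd == est.Nd == 0.0
        assert est.dS == est.dN == 0.0

    def test_single_synonymous_change_matches_oracle(self):
        c1 = ["ATG", "AAA", "CCT", "GGT", "TTT", "GCA", "CAA", "GAA",
              "TGC", "CTG"]
        c2 = list(c1)
        c2[3] = "GGC"  # third-position synonymous change
        est = nei_gojobori_modified(c1, c2, R=2.0)
        oracle = ng_pair_oracle(c1, c2, R=2.0)
        assert est.Nd == 0.0 and est.dN == 0.0
        assert est.Sd == pytest.approx(1.0)
        assert est.dS == pytest.approx(oracle["dS"])

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            c1, c2 = random_codon_rows(rng, 8)
            est = nei_gojobori_modified(c1, c2, R=rng.uniform(0.5, 5))
            assert est.S + est.N == pytest.approx(3 * est.codon_columns)

    def test_oracle_agreement_on_short_rows(self):
        """Exact agreement with the brute-force pathway-enumeration oracle
        on random codon rows of length <= 5, across R values."""
        rng = np.random.default_rng(123)
        for _ in range(150):
            L = int(rng.integers(1, 6))
            c1, c2 = random_codon_rows(rng, L, diverge=0.5)
            R = float(rng.choice([0.5, 1.0, 2.0, 4.0]))
            est = nei_gojobori_modified(c1, c2, R=R)
            oracle = ng_pair_oracle(c1, c2, R=R)
            assert est.S == pytest.approx(oracle["S"])
            assert est.Sd == pytest.approx(oracle["Sd"])
            assert est.Nd == pytest.approx(oracle["Nd"])
            if not math.isnan(oracle["dS"]):
                assert est.dS == pytest.approx(oracle["dS"])
            if not math.isnan(oracle["dN"]):
                assert est.dN == pytest.approx(oracle["dN"])

    def test_r_equal_one_matches_classic_nei_gojobori(self):
        """With R=1 the modified method reduces to the unweighted classic
        computation; cross-checked against Biopython's NG86 on pairs whose
        minimal pathways avoid stop codons (identical conventions there)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(77)
        compared = 0
        for _ in range(40):
            c1, c2 = random_codon_rows(rng, 20)
            if _any_blocked_pathway(c1, c2):
                continue
            est = nei_gojobori_modified(c1, c2, R=1.0)
            dn, ds = cal_dn_ds(CodonSeq("".join(c1)), CodonSeq("".join(c2)),
                               method="NG86")
            assert est.dS == pytest.approx(ds, abs=1e-9)
            assert est.dN == pytest.approx(dn, abs=1e-9)
            compared += 1
        assert compared >= 10

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(9)
        c1, c2 = random_codon_rows(rng, 15)
        a = nei_gojobori_modified(c1, c2)
        b = nei_gojobori_modified(c2, c1)
        assert a.dS == pytest.approx(b.dS)
        assert a.dN == pytest.approx(b.dN)

    def test_stop_codon_in_compared_column_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori_modified(["TAA"], ["ATG"])

    def test_neutral_simulation_recovers_ratio_near_one(self):
        """Mean pairwise dN/dS over >= 20 neutral (omega=1) pairs sits in
        [0.8, 1.2]."""
        ratios = []
        for s in range(22):
            rng = np.random.default_rng(400 + s)
            anc = make_root_sequence(rng, 300)
            a = evolve_codon_sequence(anc, 0.15, 1.0, 2.0, rng)
            b = evolve_codon_sequence(anc, 0.15, 1.0, 2.0, rng)
            est = nei_gojobori_modified(a[:-3], b[:-3], R=2.0)
            if est.ratio is not None:
                ratios.append(est.ratio)
        assert len(ratios) >= 20
        assert 0.8 <= np.mean(ratios) <= 1.2


def _any_blocked_pathway(c1, c2):
    for a, b in zip(c1, c2):
        diff = [i for i in range(3) if a[i] != b[i]]
        if len(diff) < 2:
            continue
        for order in itertools.permutations(diff):
            cur = a
            for pos in order:
                cur = cur[:pos] + b[pos] + cur[pos + 1:]
                if cur in STOP_CODONS and cur != b:
                    return True
    return False


class TestDistanceMatrix:
    def _alignment(self, n, length=60, seed=0):
        rng = np.random.default_rng(seed)
        anc = make_root_sequence(rng, length)
        rows = []
        for k in range(n):
            seq = evolve_codon_sequence(anc, 0.08, 0.8, 2.0,
                                        np.random.default_rng(seed * 100 + k))
            rows.append((f"Xx-RNase1{chr(65 + k)}", seq[:-3]))
        return CodonAlignment(rows=rows)

    def test_eighteen_rows_give_153_unique_entries(self):
        aln = self._alignment(18)
        mat, flags = distance_matrix(aln, model="k2p")
        n = len(mat)
        tri = mat.to_numpy()[np.triu_indices(n, 1)]
        assert tri.size == 153
        assert not flags.to_numpy().any()

    def test_matrix_matches_per_pair_computation(self):
        aln = self._alignment(4)
        mat, _ = distance_matrix(aln, model="dS", R=2.0)
        est = nei_gojobori_modified(aln.row_codons(0), aln.row_codons(2), R=2.0)
        assert mat.iloc[0, 2] == pytest.approx(est.dS)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 0.0)

    def test_two_rows_give_single_entry(self):
        aln = self._alignment(2)
        mat, _ = distance_matrix(aln, model="p")
        assert mat.shape == (2, 2)

    def test_saturated_pair_is_flagged(self):
        rows = [("a", "ATACCTGGT" * 5), ("b", "GCGGGACAA" * 5),
                ("c", "ATACCTGGA" * 5)]
        mat, flags = distance_matrix(CodonAlignment(rows=rows), model="dS")
        assert flags.to_numpy().any()


class TestBootstrapSE:
    def test_constant_estimator_has_zero_se(self):
        ses, dropped = bootstrap_se(lambda cols: 1.23, n_columns=50,
                                    replicates=100, seed=5)
        assert ses["value"] == pytest.approx(0.0, abs=1e-12)
        assert dropped == 0

    def test_same_seed_bit_identical(self):
        def est(cols):
            return float(np.mean(cols))
        a, _ = bootstrap_se(est, 40, 200, seed=9)
        b, _ = bootstrap_se(est, 40, 200, seed=9)
        assert a == b

    def test_failing_replicates_dropped_and_counted(self):
        state = {"k": 0}

        def flaky(cols):
            state["k"] += 1
            if state["k"] % 4 == 0:
                raise ValueError("degenerate")
            return float(np.mean(cols))

        _, dropped = bootstrap_se(flaky, 30, 100, seed=1)
        assert dropped == 25


class TestJukesCantor:
    def test_zero_maps_to_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_saturated_proportion_is_nan(self):
        assert math.isnan(jukes_cantor(0.76))
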