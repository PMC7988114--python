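"""Molecular weight, composition, net charge and isoelectric point."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteomap.physchem import (
    CANONICAL_LETTERS,
    CLEAN_LETTERS,
    DEFAULT_PKA_SET,
    PKA_SETS,
    WATER_MASS,
    MassTable,
    composition,
    compute_record,
    count_matrix,
    get_pka_set,
    isoelectric_point,
    isoelectric_point_batch,
    molecular_weight,
    net_charge,
)

peptides = st.text(alphabet=CANONICAL_LETTERS, min_size=1, max_size=60)


class TestMolecularWeight:
    def test_single_glycine(self):
        # hand sum: 57.0519 + 18.0153
        assert molecular_weight("G") == pytest.approx(75.0672, abs=1e-9)

    @given(peptides, peptides)
    @settings(max_examples=200, deadline=None)
    def test_concatenation_adds_one_fewer_water(self, s1, s2):
        lhs = molecular_weight(s1 + s2)
        rhs = molecular_weight(s1) + molecular_weight(s2) - WATER_MASS
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_x_policy_mean_of_20(self):
        mean20 = sum(MassTable().residue_mass[a] for a in CANONICAL_LETTERS) / 20
        assert molecular_weight("X") == pytest.approx(WATER_MASS + mean20)

    def test_x_policy_zero(self):
        table = MassTable(x_policy="zero")
        assert molecular_weight("AXA", table) == pytest.approx(
            molecular_weight("AA", table) + 0.0, rel=1e-12)

    def test_x_policy_reject_names_position(self):
        table = MassTable(x_policy="reject")
        with pytest.raises(ValueError, match="position 1"):
            molecular_weight("AXA", table)

    def test_sec_and_pyl_carry_no_mass(self):
        assert molecular_weight("AUA") == pytest.approx(molecular_weight("AA"))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            molecular_weight("")


class TestComposition:
    def test_counts_and_percentages(self):
        counts, pct = composition("AAG")
        assert counts == {"A": 2, "G": 1}
        assert pct["A"] == pytest.approx(100 * 2 / 3)
        assert pct["G"] == pytest.approx(100 / 3)

    def test_x_counted_over_full_length(self):
        counts, pct = composition("AXG")
        assert counts["X"] == 1
        assert pct["X"] == pytest.approx(100 / 3)

    @given(peptides)
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance_and_sum(self, seq):
        shuffled = "".join(sorted(seq))
        assert composition(seq)[0] == composition(shuffled)[0]
        counts, pct = composition(seq)
        assert sum(counts.values()) == len(seq)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)

    def test_count_matrix_matches_composition(self):
        seqs = ["AAG", "WXY", "KKKK"]
        mat = count_matrix(seqs)
        for row, seq in zip(mat, seqs):
            counts, _ = composition(seq)
            for a, c in counts.items():
                assert row[CLEAN_LETTERS.index(a)] == c
        assert mat.sum() == sum(len(s) for s in seqs)


class TestNetCharge:
    def test_high_ph_limit_is_minus_acid_count(self):
        counts, _ = composition("DDEEA")  # 4 side-chain acids + Cterm
        assert net_charge(counts, 15.9) == pytest.approx(-5.0, abs=0.01)

    def test_two_group_symmetry_point(self):
        counts, _ = composition("GG")
        mid = (DEFAULT_PKA_SET.pKa["Nterm"] + DEFAULT_PKA_SET.pKa["Cterm"]) / 2
        assert net_charge(counts, mid) == pytest.approx(0.0, abs=1e-12)

    @given(peptides)
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_ph(self, seq):
        counts, _ = composition(seq)
        assert net_charge(counts, 4.0) > net_charge(counts, 10.0)

    def test_ph_domain_error(self):
        counts, _ = composition("GG")
        with pytest.raises(ValueError):
            net_charge(counts, 20.0)


class TestIsoelectricPoint:
    def test_two_group_peptide_is_pka_midpoint(self):
        counts, _ = composition("GG")
        mid = (DEFAULT_PKA_SET.pKa["Nterm"] + DEFAULT_PKA_SET.pKa["Cterm"]) / 2
        assert isoelectric_point(counts, tol=1e-6) == pytest.approx(mid, abs=1e-5)

    def test_arginine_rich_closed_form(self):
        # 84 R + 21 K + termini: with every other group saturated the root
        # equation reduces to pI = pKa_R + log10(83)
        counts = {"R": 84, "K": 21, "A": 100}
        expected = DEFAULT_PKA_SET.pKa["R"] + math.log10(83)
        assert isoelectric_point(counts) == pytest.approx(expected, abs=2e-3)

    @given(peptides)
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, seq):
        a = isoelectric_point(composition(seq)[0])
        b = isoelectric_point(composition(seq[::-1])[0])
        assert a == pytest.approx(b, abs=1e-12)

    @given(peptides)
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_acid_and_base_counts(self, seq):
        counts, _ = composition(seq)
        base = isoelectric_point(counts, tol=1e-6)
        plus_acid = dict(counts)
        plus_acid["D"] = plus_acid.get("D", 0) + 1
        plus_base = dict(counts)
        plus_base["R"] = plus_base.get("R", 0) + 1
        assert isoelectric_point(plus_acid, tol=1e-6) <= base + 1e-5
        assert isoelectric_point(plus_base, tol=1e-6) >= base - 1e-5

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list(CANONICAL_LETTERS), size=rng.integers(2, 50)))
                for _ in range(50)]
        mat = count_matrix(seqs)
        batch = isoelectric_point_batch(mat, tol=1e-6)
        for seq, got in zip(seqs, batch):
            assert got == pytest.approx(
                isoelectric_point(composition(seq)[0], tol=1e-6), abs=1e-5)

    def test_alternative_pka_sets_shift_pi(self):
        counts, _ = composition("DDKKR")
        default = isoelectric_point(counts)
        emboss = isoelectric_point(counts, pka=get_pka_set("EMBOSS"))
        assert default != pytest.approx(emboss, abs=1e-3)

    def test_unknown_pka_set_lists_available(self):
        with pytest.raises(KeyError, match="IPC_protein"):
            get_pka_set("nope")


class TestComputeRecord:
    def test_rounding_and_fields(self):
        rec = compute_record("acc", "AL")
        assert rec.length == 2
        assert rec.mw_da == pytest.approx(202.2535)
        assert rec.mw_kda == 0.202
        assert rec.pi == round(rec.pi, 3)
        assert 0 < rec.pi < 14
        assert sum(rec.composition_percent.values()) == pytest.approx(100.0)

    def test_pka_sets_all_complete(self):
        for name, pka in PKA_SETS.items():
            for group in ("Nterm", "Cterm", "C", "D", "E", "H", "K", "R", "Y"):
                assert 0 < pka.pKa[group] < 14
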