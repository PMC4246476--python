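"""Nearest-neighbor duplex thermodynamics: hand-summed oracle, cancellation
identities, allele antisymmetry and haplotype grouping."""


import pytest

from mresscan.energy import (
    T_37,
    NNParams,
    duplex_energy,
    haplotype_scores,
    load_params,
    snp_delta,
)
from mresscan.errors import DomainError
from mresscan.seeds import AllelicSiteEffect

MIRNA_SEG = "AGCUUAU"          # seed 2-8 of the worked microRNA
TARGET = "AUAAGCU"             # exact reverse complement
TARGET_MM = "AUACGCU"          # single central mismatch


def hand_summed_dg(params, mirna_seg, target, clamp="CCC"):
    """Independent summation: explicit stack labels over the clamped duplex."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    rc_clamp = "".join(comp[b] for b in reversed(clamp))
    top = clamp + mirna_seg + clamp
    bot = rc_clamp + target + rc_clamp
    L = len(top)
    dh, ds = params.initiation
    for i in range(L - 1):
        label = f"{top[i]}{top[i + 1]}/{bot[L - 2 - i]}{bot[L - 1 - i]}"
        entry = params.lookup(label)
        if entry is None:
            entry = (params.fallback_dh, params.fallback_ds)
        dh, ds = dh + entry[0], ds + entry[1]
    return dh - T_37 * ds


def test_fully_complementary_duplex_matches_hand_sum(nn_params):
    e = duplex_energy(MIRNA_SEG, TARGET, nn_params)
    assert e.n_fallback == 0
    assert e.dg37 == pytest.approx(hand_summed_dg(nn_params, MIRNA_SEG, TARGET))
    assert e.dg37 == pytest.approx(e.dh - T_37 * e.ds)
    # recomputation is bitwise identical
    assert duplex_energy(MIRNA_SEG, TARGET, nn_params) == e


def test_central_mismatch_destabilises(nn_params):
    matched = duplex_energy(MIRNA_SEG, TARGET, nn_params)
    mismatched = duplex_energy(MIRNA_SEG, TARGET_MM, nn_params)
    assert mismatched.n_fallback == 2
    assert mismatched.dg37 > matched.dg37


def test_length_mismatch_and_alphabet_errors(nn_params):
    with pytest.raises(DomainError):
        duplex_energy("AGC", "AU", nn_params)
    with pytest.raises(DomainError):
        duplex_energy("AGN", "AUC", nn_params)


def _effect(wild, mutant, site_start=0, site_end=7, snp_offset=3, stype="7mer(2-8)",
            members=("m1",)):
    return AllelicSiteEffect(
        snp_id="rs1", transcript_id="tx", gene="G", seed_kind="2-8", seed="AGCUUAU",
        members=members, site_type=stype, effect="loss", wild_window=wild,
        mutant_window=mutant, window_start=0, site_start=site_start,
        site_end=site_end, snp_offset=snp_offset,
    )


MIRNA_SEQS = {"m1": "GAGCUUAUCAGACUGAUGUUGA", "m2": "CAGCUUAUCAGACUGAUGUUGA"}


class TestSnpDelta:
    def test_degenerate_identical_alleles_zero(self, nn_params):
        d = snp_delta(_effect(TARGET, TARGET), MIRNA_SEQS, nn_params)
        assert d.ddg == 0.0 and d.abs_ddg == 0.0

    def test_loss_snp_positive_ddg(self, nn_params):
        d = snp_delta(_effect(TARGET, TARGET_MM), MIRNA_SEQS, nn_params)
        assert d.ddg > 0
        assert d.effect == "loss"

    def test_allele_swap_negates_exactly(self, nn_params):
        fwd = snp_delta(_effect(TARGET, TARGET_MM), MIRNA_SEQS, nn_params)
        rev = snp_delta(_effect(TARGET_MM, TARGET), MIRNA_SEQS, nn_params)
        assert rev.ddg == pytest.approx(-fwd.ddg)

    def test_clamp_choice_cancels_for_interior_snp(self, nn_params):
        vals = [
            snp_delta(_effect(TARGET, TARGET_MM), MIRNA_SEQS, nn_params, clamp=c).ddg
            for c in ("CCC", "GGG", "GCG", "")
        ]
        for v in vals[1:]:
            assert v == pytest.approx(vals[0])

    def test_initiation_term_cancels(self, nn_params):
        shifted = NNParams(
            stacks=nn_params.stacks,
            initiation=(nn_params.initiation[0] + 5000, nn_params.initiation[1] - 3),
            terminal_au=nn_params.terminal_au,
        )
        a = snp_delta(_effect(TARGET, TARGET_MM), MIRNA_SEQS, nn_params).ddg
        b = snp_delta(_effect(TARGET, TARGET_MM), MIRNA_SEQS, shifted).ddg
        assert b == pytest.approx(a)

    def test_multi_member_average_flagged(self, nn_params):
        # members differing at mature position 1 in an 8-base duplex
        eff = _effect(TARGET + "A", TARGET_MM + "A", site_end=8, stype="8mer-1a",
                      members=("m1", "m2"))
        d = snp_delta(eff, MIRNA_SEQS, nn_params)
        singles = [
            snp_delta(_effect(TARGET + "A", TARGET_MM + "A", site_end=8,
                              stype="8mer-1a", members=(m,)), MIRNA_SEQS, nn_params).ddg
            for m in ("m1", "m2")
        ]
        assert d.flagged
        assert d.ddg == pytest.approx(sum(singles) / 2)

    def test_snp_outside_footprint_rejected(self, nn_params):
        with pytest.raises(DomainError):
            snp_delta(_effect(TARGET, TARGET_MM, snp_offset=9), MIRNA_SEQS, nn_params)


def test_strand_symmetry_of_parameter_table(nn_params):
    """Reading the duplex from the other strand gives the same dG37."""
    e1 = duplex_energy(MIRNA_SEG, TARGET, nn_params, clamp="")
    e2 = duplex_energy(TARGET, MIRNA_SEG, nn_params, clamp="")
    assert e1.dg37 == pytest.approx(e2.dg37)


class TestHaplotypes:
    def _delta(self, snp, tx="tx1", abs_ddg=1000.0):
        from mresscan.energy import SnpEnergyDelta

        return SnpEnergyDelta(snp, tx, "7mer(2-8)", "loss", abs_ddg, abs(abs_ddg), False)

    def test_linked_pair_sums(self):
        deltas = [self._delta("a", abs_ddg=3000.0), self._delta("b", abs_ddg=4000.0)]
        haps = haplotype_scores(deltas, [("a", "b", 1.0, 0.9)])
        assert len(haps) == 1
        assert haps[0].score == pytest.approx(7000.0)
        assert haps[0].member_snp_ids == ("a", "b")

    def test_unlinked_snps_emit_nothing(self):
        deltas = [self._delta("a"), self._delta("b")]
        assert haplotype_scores(deltas, [("a", "b", 0.5, 0.2)]) == []

    def test_chain_forms_one_connected_component(self):
        deltas = [self._delta(s) for s in "abc"]
        haps = haplotype_scores(deltas, [("a", "b", 1.0, 0.9), ("b", "c", 1.0, 0.9)])
        assert len(haps) == 1
        assert haps[0].member_snp_ids == ("a", "b", "c")
        assert haps[0].score == pytest.approx(3000.0)

    def test_r2_rule(self):
        deltas = [self._delta("a"), self._delta("b")]
        haps = haplotype_scores(deltas, [("a", "b", 0.2, 0.95)], rule="r2", threshold=0.8)
        assert len(haps) == 1

    def test_cross_transcript_snps_never_grouped(self):
        deltas = [self._delta("a", tx="tx1"), self._delta("b", tx="tx2")]
        assert haplotype_scores(deltas, [("a", "b", 1.0, 1.0)]) == []
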