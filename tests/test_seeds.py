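"""Seed extraction, site scanning vs a brute-force oracle, allelic effects,
and the human-mouse conservation filter."""

import numpy as np
import pytest

from mresscan.errors import DomainError, IntegrityError
from mresscan.io import Snp, Transcript
from mresscan.seeds import (
    SITE_7MER_1_7,
    SITE_7MER_2_8,
    SITE_8MER,
    SITE_8MER_1A,
    call_allelic_effects,
    conservation_filter,
    extract_seeds,
    revcomp,
    scan_sites,
)

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def oracle_sites(utr, mirnas):
    """Exhaustive per-position complement enumeration, independent of the
    scanner's pattern-matching path. Yields (start, end, type, mirna)."""
    out = set()
    for mid, mat in mirnas:
        if len(mat) < 8:
            continue
        for i in range(len(utr) - 6):
            # seed 1-7: utr[i+6-j] complements mat[j] for j in 0..6
            if all(utr[i + 6 - j] == COMP[mat[j]] for j in range(7)):
                if i > 0 and utr[i - 1] == COMP[mat[7]]:
                    out.add((i - 1, i + 7, SITE_8MER, mid))
                else:
                    out.add((i, i + 7, SITE_7MER_1_7, mid))
            # seed 2-8: utr[i+6-j] complements mat[j+1]
            if all(utr[i + 6 - j] == COMP[mat[j + 1]] for j in range(7)):
                nxt = utr[i + 7] if i + 7 < len(utr) else None
                if nxt is not None and nxt == COMP[mat[0]]:
                    out.add((i, i + 8, SITE_8MER, mid))
                elif nxt == "A":
                    out.add((i, i + 8, SITE_8MER_1A, mid))
                else:
                    out.add((i, i + 7, SITE_7MER_2_8, mid))
    return out


def expand(sites):
    return {(s.start, s.end, s.site_type, m) for s in sites for m in s.members}


def test_extract_seeds_by_definition():
    groups = extract_seeds([("m1", "GAGCUUAUCAGACUGAUGUUGA")])
    by_kind = {g.seed_kind: g for g in groups}
    assert by_kind["1-7"].seed_sequence == "GAGCUUA"
    assert by_kind["2-8"].seed_sequence == "AGCUUAU"
    assert by_kind["1-7"].base8 == ("U",)  # mature position 8
    assert by_kind["2-8"].base8 == ("G",)  # mature position 1


def test_extract_seeds_groups_shared_seed_and_drops_short():
    with pytest.warns(UserWarning):
        groups = extract_seeds(
            [("m1", "GAGCUUAUCAGACUGAUGUUGA"), ("m2", "GAGCUUAUAAAAAAAA"), ("short", "GAGCUUA")]
        )
    g17 = next(g for g in groups if g.seed_kind == "1-7" and g.seed_sequence == "GAGCUUA")
    assert g17.members == ("m1", "m2")
    assert all("short" not in g.members for g in groups)


@pytest.mark.parametrize(
    "utr,expected",
    [
        # site = rc of seed 2-8 "AGCUUAU" -> "AUAAGCU"; followed by A -> 8mer-1a
        ("AAAUAAGCUAAA", {(2, 10, SITE_8MER_1A, "m1")}),
        # followed by C = complement of position-1 G -> full 8mer
        ("AAAUAAGCUCAA", {(2, 10, SITE_8MER, "m1")}),
        # poly-A UTR vs a G/C-containing seed: nothing
        ("AAAAAAAA", set()),
    ],
)
def test_scan_sites_frozen_examples(utr, expected):
    mirnas = [("m1", "GAGCUUAUCAGACUGAUGUUGA")]
    groups = extract_seeds(mirnas)
    assert oracle_sites(utr, mirnas) == expected  # the oracle itself agrees
    got = {
        (s.start, s.end, s.site_type, m)
        for s in scan_sites(utr, groups)
        for m in s.members
    }
    assert got == expected


def test_scan_sites_equals_oracle_on_random_sequences():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGU"))
    for _ in range(30):
        mirnas = [
            (f"m{k}", "".join(bases[rng.integers(0, 4, size=22)])) for k in range(12)
        ]
        utr = "".join(bases[rng.integers(0, 4, size=400)])
        groups = extract_seeds(mirnas)
        assert expand(scan_sites(utr, groups)) == oracle_sites(utr, mirnas)


def test_scan_sites_deterministic_and_sorted(small_bundle, small_groups):
    utr = small_bundle.transcripts[0].utr3_sequence
    a = scan_sites(utr, small_groups, "t")
    b = scan_sites(utr, small_groups, "t")
    assert a == b
    keys = [(s.start, s.end, s.site_type, s.seed) for s in a]
    assert keys == sorted(keys)


def _plus_transcript(utr, chrom="1", start=1000):
    return Transcript("NM_T", "GENE_T", chrom, "+", [("3UTR", start, start + len(utr))], utr)


class TestAllelicEffects:
    MIRNAS = [("m1", "GAGCUUAUCAGACUGAUGUUGA")]  # seed 2-8 site pattern AUAAGCU

    def groups(self):
        return extract_seeds(self.MIRNAS)

    def test_loss_call(self):
        # G->C in the 5th base of the site footprint abolishes the 7mer(2-8)
        utr = "AAAAAAAAAAAUAAGCUGAAAAAAAAAAA"
        t = _plus_transcript(utr)
        snp = Snp("rs1", "1", 1000 + 14, "G", "C")
        effects = call_allelic_effects(t, snp, self.groups())
        assert [(e.effect, e.site_type) for e in effects] == [("loss", SITE_7MER_2_8)]
        assert (effects[0].utr_start, effects[0].utr_end) == (10, 17)

    def test_snp_outside_any_footprint_yields_nothing(self):
        utr = "AAAAAAAAAAAUAAGCUGAAAAAAAAAAA"
        t = _plus_transcript(utr)
        assert call_allelic_effects(t, Snp("rs2", "1", 1000 + 25, "A", "G"), self.groups()) == []

    def test_type_transition_persisting_7mer_reported_in_neither_class(self):
        # U->A at the position just 3' of a 7mer(2-8) creates an 8mer-1a;
        # the persisting 7mer(2-8) never covers the SNP, so no loss is called
        utr = "AAAAAAAAAAAUAAGCUUAAAAAAAAAAA".replace("UU", "UU", 1)
        utr = "AAAAAAAAAAA" + "AUAAGCU" + "U" + "AAAAAAAAAA"
        t = _plus_transcript(utr)
        snp = Snp("rs3", "1", 1000 + 18, "T", "A")  # the +1 position (U in RNA)
        effects = call_allelic_effects(t, snp, self.groups())
        assert [(e.effect, e.site_type) for e in effects] == [("create", SITE_8MER_1A)]

    def test_same_interval_type_switch_gives_one_loss_and_one_create(self):
        # following base A -> C turns an 8mer-1a into a full 8mer
        utr = "AAAAAAAAAAA" + "AUAAGCU" + "A" + "AAAAAAAAAA"
        t = _plus_transcript(utr)
        snp = Snp("rs4", "1", 1000 + 18, "A", "C")
        effects = call_allelic_effects(t, snp, self.groups())
        got = sorted((e.effect, e.site_type) for e in effects)
        assert got == [("create", SITE_8MER), ("loss", SITE_8MER_1A)]

    def test_ref_allele_mismatch_raises_integrity_error(self):
        t = _plus_transcript("A" * 60)
        with pytest.raises(IntegrityError, match="rs5"):
            call_allelic_effects(t, Snp("rs5", "1", 1010, "G", "C"), self.groups())

    def test_snp_outside_utr_raises_domain_error(self):
        t = _plus_transcript("A" * 60)
        with pytest.raises(DomainError):
            call_allelic_effects(t, Snp("rs6", "1", 10, "A", "G"), self.groups())

    def test_minus_strand_alleles_are_complemented(self):
        # minus-strand transcript: file alleles are forward-strand DNA
        utr = "AAAAAAAAAAAUAAGCUGAAAAAAAAAAA"
        t = Transcript("NM_M", "GM", "1", "-", [("3UTR", 1000, 1000 + len(utr))], utr)
        # sense offset 14 (the site's G) sits at genomic 1000+len-1-14
        gpos = t.utr_offset_to_genomic(14)
        snp = Snp("rs7", "1", gpos, "C", "G")  # forward C == sense G
        effects = call_allelic_effects(t, snp, extract_seeds(self.MIRNAS))
        assert [(e.effect, e.site_type) for e in effects] == [("loss", SITE_7MER_2_8)]


def test_allele_swap_symmetry_on_random_snps(small_bundle, small_groups):
    """Swapping ref/alt exchanges create and loss labels exactly."""
    rng = np.random.default_rng(5)
    checked = 0
    for t in small_bundle.transcripts[:40]:
        utr = t.utr3_sequence
        off = int(rng.integers(0, len(utr)))
        ref_s = utr[off]
        alt_s = "ACGU"[(("ACGU".index(ref_s)) + 1 + int(rng.integers(0, 3))) % 4]
        if alt_s == ref_s:
            continue
        to_dna = {"A": "A", "C": "C", "G": "G", "U": "T"}
        dcomp = {"A": "T", "C": "G", "G": "C", "T": "A"}

        def dna(b):
            return to_dna[b] if t.strand == "+" else dcomp[to_dna[b]]

        gpos = t.utr_offset_to_genomic(off)
        fwd = call_allelic_effects(t, Snp("s", t.chrom, gpos, dna(ref_s), dna(alt_s)), small_groups)
        mutated = utr[:off] + alt_s + utr[off + 1 :]
        t_swapped = Transcript(t.transcript_id, t.gene_symbol, t.chrom, t.strand, t.regions, mutated)
        rev = call_allelic_effects(
            t_swapped, Snp("s", t.chrom, gpos, dna(alt_s), dna(ref_s)), small_groups
        )
        flip = {"create": "loss", "loss": "create"}
        assert sorted((flip[e.effect], e.site_type, e.utr_start) for e in fwd) == sorted(
            (e.effect, e.site_type, e.utr_start) for e in rev
        )
        checked += 1
    assert checked >= 20


class TestConservation:
    def _sites(self, utr, mirnas):
        return scan_sites(utr, extract_seeds(mirnas))

    def test_identity_alignment_conserves_everything(self):
        utr = "AAAAAAAAAAAUAAGCUGAAAAAAAAAAA"
        sites = self._sites(utr, [("m1", "GAGCUUAUCAGACUGAUGUUGA")])
        out = conservation_filter(utr, utr, sites)
        assert out and all(s.conserved for s in out)

    def test_deletion_spanning_site_breaks_conservation(self):
        utr = "AAAAAAAAAAAUAAGCUGAAAAAAAAAAA"
        sites = self._sites(utr, [("m1", "GAGCUUAUCAGACUGAUGUUGA")])
        mouse = utr[:10] + utr[19:]  # deletion across the footprint
        out = conservation_filter(utr, mouse, sites)
        assert all(not s.conserved for s in out)

    def test_mismatch_inside_vs_outside_footprint(self):
        utr = "GCGCGCGCGCAUAAGCUGGCGCGCGCGCG"
        sites = self._sites(utr, [("m1", "GAGCUUAUCAGACUGAUGUUGA")])
        (site,) = sites
        inside = list(utr)
        inside[site.start + 3] = {"A": "C", "C": "A", "G": "U", "U": "G"}[inside[site.start + 3]]
        out = conservation_filter(utr, "".join(inside), sites)
        assert not out[0].conserved
        outside = list(utr)
        outside[2] = "A" if outside[2] != "A" else "U"
        out = conservation_filter(utr, "".join(outside), sites)
        assert out[0].conserved

    def test_missing_ortholog_flags_unconserved_with_warning(self):
        utr = "AAAAAAAAAAAUAAGCUGAAAAAAAAAAA"
        sites = self._sites(utr, [("m1", "GAGCUUAUCAGACUGAUGUUGA")])
        with pytest.warns(UserWarning):
            out = conservation_filter(utr, None, sites)
        assert all(not s.conserved for s in out)

    def test_exempt_position_allows_snp_base(self):
        utr = "GCGCGCGCGCAUAAGCUGGCGCGCGCGCG"
        sites = self._sites(utr, [("m1", "GAGCUUAUCAGACUGAUGUUGA")])
        (site,) = sites
        mouse = list(utr)
        pos = site.start + 3
        mouse[pos] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mouse[pos]]
        out = conservation_filter(utr, "".join(mouse), sites, exempt={0: pos})
        assert out[0].conserved
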