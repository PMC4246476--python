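"""Generator determinism, generator-scanner agreement, planted-signal wiring."""

import filecmp

import pytest

from mresscan.errors import ConfigError
from mresscan.pipeline import scan_all_effects, seed_groups_from_mirnas
from mresscan.simulate import SimConfig, simulate, simulate_bundle, truth_compare

SMALL = dict(n_genes=60, n_mirnas=20, n_snps=800, n_causal=6, n_disease_genes=12)


def test_identical_seed_identical_output(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate(SimConfig(seed=5, **SMALL), d1)
    simulate(SimConfig(seed=5, **SMALL), d2)
    files = [p.relative_to(d1) for p in d1.rglob("*") if p.is_file()]
    assert files
    for f in files:
        assert filecmp.cmp(d1 / f, d2 / f, shallow=False), f


def test_different_seed_different_output(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate(SimConfig(seed=5, **SMALL), d1)
    simulate(SimConfig(seed=6, **SMALL), d2)
    assert (d1 / "snps.tsv").read_bytes() != (d2 / "snps.tsv").read_bytes()


def test_every_planted_site_rediscovered_by_scanner(small_bundle, small_groups):
    from mresscan.seeds import scan_sites

    by_id = {t.transcript_id: t for t in small_bundle.transcripts}
    for site in small_bundle.truth.planted_sites:
        t = by_id[site.transcript_id]
        found = scan_sites(t.utr3_sequence, small_groups, t.transcript_id)
        assert any(
            s.start == site.start and s.end == site.end
            and s.site_type == site.site_type and site.mirna in s.members
            for s in found
        ), site


def test_planted_effect_directions_match_allelic_calls(small_bundle, small_groups):
    by_id = {t.transcript_id: t for t in small_bundle.transcripts}
    by_snp = {s.snp_id: s for s in small_bundle.snps}
    for eff in small_bundle.truth.planted_effects:
        t = by_id[eff.transcript_id]
        from mresscan.seeds import call_allelic_effects

        called = call_allelic_effects(t, by_snp[eff.snp_id], small_groups)
        assert any(
            c.effect == eff.effect and eff.mirna in c.members for c in called
        ), eff


def test_frac_causal_zero_gives_empty_truth():
    cfg = SimConfig(seed=2, frac_causal=0.0, **{k: v for k, v in SMALL.items() if k != "n_causal"})
    b = simulate_bundle(cfg)
    assert b.truth.causal_snps == set()


def test_infeasible_config_rejected_before_writing(tmp_path):
    cfg = SimConfig(seed=1, n_genes=5, n_mirnas=5, n_snps=100, n_causal=50,
                    n_disease_genes=2)
    out = tmp_path / "never"
    with pytest.raises(ConfigError):
        simulate(cfg, out)
    assert not out.exists()


def test_causal_snps_are_mress_snps(small_bundle, small_groups):
    scan = scan_all_effects(small_bundle.transcripts, small_bundle.snps, small_groups)
    assert small_bundle.truth.causal_snps <= scan.mress_snp_ids


def test_mouse_orthologs_protect_planted_sites(small_bundle):
    by_id = {t.transcript_id: t for t in small_bundle.transcripts}
    for site in small_bundle.truth.planted_sites:
        h = by_id[site.transcript_id].utr3_sequence[site.start : site.end]
        m = small_bundle.mouse_utr3[site.transcript_id][site.start : site.end]
        assert h == m


def test_truth_compare_metrics():
    out = truth_compare({"a", "b", "x"}, {"a", "b", "c", "d"})
    assert out["recall"] == pytest.approx(0.5)
    assert out["precision"] == pytest.approx(2 / 3)
    empty = truth_compare(set(), {"a"})
    assert empty["precision"] is None and empty["recall"] == 0.0


def test_bundle_loads_back_through_io(tmp_path, small_bundle):
    """The written bundle round-trips through the io loaders."""
    from mresscan import io

    small_bundle.write(tmp_path)
    transcripts, snps, report = io.load_reference(
        tmp_path / "utr3_human.fa", tmp_path / "regions.tsv", tmp_path / "snps.tsv"
    )
    assert len(snps) == len(small_bundle.snps)
    assert report["multi_allelic"] == 0
    kept = {t.transcript_id for t in transcripts}
    dropped = {t.transcript_id for t in small_bundle.transcripts} - kept
    assert all(
        t.utr3_length < 50 for t in small_bundle.transcripts if t.transcript_id in dropped
    )
    gwas = io.load_gwas_table(tmp_path / "gwas.tsv")
    assert gwas.keys() == small_bundle.evidence.gwas.keys()
    assert io.load_positives(tmp_path / "positives.txt") == small_bundle.evidence.positives
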