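"""Seed extraction, seed-site scanning, allelic create/loss calls, conservation.

The model: a microRNA's 5'-end seed dominates target recognition. Two seed
definitions are used in parallel, positions 1-7 and positions 2-8 of the
mature sequence. A target site in a 3'UTR is the reverse complement of the
seed (antiparallel Watson-Crick pairing), optionally extended:

* seed 1-7 match whose 5'-adjacent UTR base also complements microRNA
  position 8 -> ``8mer`` (footprint 8 nt), otherwise ``7mer(1-7)``;
* seed 2-8 match whose 3'-adjacent UTR base complements position 1 ->
  ``8mer``; else if that base is an ``A`` -> ``8mer-1a`` (the adenosine is
  anchored opposite position 1 regardless of identity); else ``7mer(2-8)``.

A located occurrence gets exactly one type (8mer > 8mer-1a > 7mer), so the
four classes partition sites. If position 1 is ``U`` an A-followed 2-8 match
is a full 8mer and is typed 8mer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from Bio import Align

from .errors import DomainError, IntegrityError
from .io import Snp, Transcript

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

SITE_7MER_1_7 = "7mer(1-7)"
SITE_7MER_2_8 = "7mer(2-8)"
SITE_8MER_1A = "8mer-1a"
SITE_8MER = "8mer"
SITE_TYPES = (SITE_7MER_1_7, SITE_7MER_2_8, SITE_8MER_1A, SITE_8MER)

KIND_1_7 = "1-7"
KIND_2_8 = "2-8"


def revcomp(seq: str) -> str:
    return "".join(RNA_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SeedGroup:
    """MicroRNAs sharing one 7-nt seed under one seed definition.

    ``base8`` holds, per member, the base used for 8-nt extension: mature
    position 8 for kind 1-7, mature position 1 for kind 2-8.
    """

    seed_kind: str
    seed_sequence: str
    members: tuple[str, ...]
    base8: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.seed_sequence) != 7:
            raise DomainError("seed must be exactly 7 bases")


@dataclass(frozen=True)
class SeedSite:
    """A located seed-match site in a 3'UTR (0-based half-open offsets)."""

    transcript_id: str
    start: int
    end: int
    site_type: str
    seed_kind: str
    seed: str
    members: tuple[str, ...]
    conserved: bool | None = None

    def __post_init__(self) -> None:
        if self.end - self.start not in (7, 8):
            raise DomainError("site footprint must be 7 or 8 bases")


@dataclass(frozen=True)
class AllelicSiteEffect:
    """A create/loss call for one SNP against one (seed group, site).

    Windows are the identical +/-flank subsequences of the 3'UTR around the
    SNP, differing only at the SNP offset. ``utr_start``/``utr_end`` locate
    the site footprint in full-UTR coordinates.
    """

    snp_id: str
    transcript_id: str
    gene: str
    seed_kind: str
    seed: str
    members: tuple[str, ...]
    site_type: str
    effect: str  # "create" | "loss"
    wild_window: str
    mutant_window: str
    window_start: int
    site_start: int  # window-relative
    site_end: int
    snp_offset: int  # window-relative

    @property
    def utr_start(self) -> int:
        return self.window_start + self.site_start

    @property
    def utr_end(self) -> int:
        return self.window_start + self.site_end


def extract_seeds(mirnas: list[tuple[str, str]]) -> list[SeedGroup]:
    """Group microRNAs by identical seed, for both seed definitions.

    Sequences shorter than 8 nt are excluded with a warning. Every microRNA
    appears in exactly one group per seed kind.
    """
    buckets: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for mid, seq in mirnas:
        if len(seq) < 8:
            warnings.warn(f"microRNA {mid} shorter than 8 nt; excluded from seed groups")
            continue
        buckets.setdefault((KIND_1_7, seq[0:7]), []).append((mid, seq[7]))
        buckets.setdefault((KIND_2_8, seq[1:8]), []).append((mid, seq[0]))
    groups = []
    for (kind, seed), pairs in sorted(buckets.items()):
        pairs.sort()
        groups.append(
            SeedGroup(
                seed_kind=kind,
                seed_sequence=seed,
                members=tuple(m for m, _ in pairs),
                base8=tuple(b for _, b in pairs),
            )
        )
    return groups


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def scan_sites(
    utr3_sequence: str, seed_groups: list[SeedGroup], transcript_id: str = ""
) -> list[SeedSite]:
    """All seed-match sites of the four types in one 3'UTR.

    Overlapping sites from different groups are all reported; duplicate
    (interval, members, type) records arising from the same 8mer being found
    through both seed kinds are reported once (the 2-8 record is kept).
    """
    found: dict[tuple, SeedSite] = {}
    for group in seed_groups:
        pattern = revcomp(group.seed_sequence)
        for i in _find_all(utr3_sequence, pattern):
            # split members by the outcome of the 8-nt extension test
            by_site: dict[tuple[int, int, str], list[str]] = {}
            if group.seed_kind == KIND_1_7:
                prev = utr3_sequence[i - 1] if i > 0 else None
                for member, b8 in zip(group.members, group.base8):
                    if prev is not None and prev == RNA_COMPLEMENT[b8]:
                        by_site.setdefault((i - 1, i + 7, SITE_8MER), []).append(member)
                    else:
                        by_site.setdefault((i, i + 7, SITE_7MER_1_7), []).append(member)
            else:
                nxt = utr3_sequence[i + 7] if i + 7 < len(utr3_sequence) else None
                for member, b1 in zip(group.members, group.base8):
                    if nxt is not None and nxt == RNA_COMPLEMENT[b1]:
                        by_site.setdefault((i, i + 8, SITE_8MER), []).append(member)
                    elif nxt == "A":
                        by_site.setdefault((i, i + 8, SITE_8MER_1A), []).append(member)
                    else:
                        by_site.setdefault((i, i + 7, SITE_7MER_2_8), []).append(member)
            for (s, e, stype), members in by_site.items():
                key = (s, e, stype, tuple(sorted(members)))
                prior = found.get(key)
                if prior is None or group.seed_kind == KIND_2_8:
                    found[key] = SeedSite(
                        transcript_id=transcript_id,
                        start=s,
                        end=e,
                        site_type=stype,
                        seed_kind=group.seed_kind,
                        seed=group.seed_sequence,
                        members=tuple(sorted(members)),
                    )
    return sorted(
        found.values(), key=lambda x: (x.start, x.end, x.site_type, x.seed, x.members)
    )


def call_allelic_effects(
    transcript: Transcript,
    snp: Snp,
    seed_groups: list[SeedGroup],
    flank: int = 50,
) -> list[AllelicSiteEffect]:
    """Create/loss calls for one 3'UTR SNP.

    The wild and mutant windows are the identical +/-``flank`` subsequences
    around the SNP (truncated at UTR boundaries) carrying the reference and
    alternate allele respectively; both are scanned and only sites whose
    footprint covers the SNP offset are compared. Wild-only records are
    losses, mutant-only records creates; a site persisting in both alleles
    (same footprint, type and members) is reported in neither class.
    """
    off = transcript.genomic_to_utr_offset(snp.pos)
    if off is None:
        raise DomainError(f"{snp.snp_id}: position not in 3'UTR of {transcript.transcript_id}")
    utr = transcript.utr3_sequence
    sense_ref = transcript.sense_allele(snp.ref_allele)
    sense_alt = transcript.sense_allele(snp.alt_allele)
    if utr[off] != sense_ref:
        raise IntegrityError(
            f"{snp.snp_id}: reference allele {sense_ref} (sense) disagrees with "
            f"3'UTR base {utr[off]} of {transcript.transcript_id}"
        )
    ws = max(0, off - flank)
    we = min(len(utr), off + flank + 1)
    rel = off - ws
    wild = utr[ws:we]
    mutant = wild[:rel] + sense_alt + wild[rel + 1 :]

    # only groups whose match pattern occurs in either window can yield sites
    kmers = {
        w[i : i + 7] for w in (wild, mutant) for i in range(len(w) - 6)
    }
    groups = [g for g in seed_groups if revcomp(g.seed_sequence) in kmers]

    def covering(window: str) -> dict[tuple, SeedSite]:
        return {
            (s.start, s.end, s.site_type, s.seed_kind, s.seed, s.members): s
            for s in scan_sites(window, groups, transcript.transcript_id)
            if s.start <= rel < s.end
        }

    wild_sites = covering(wild)
    mutant_sites = covering(mutant)
    effects = []
    for key, site in sorted(wild_sites.items()):
        if key not in mutant_sites:
            effects.append(("loss", site))
    for key, site in sorted(mutant_sites.items()):
        if key not in wild_sites:
            effects.append(("create", site))
    return [
        AllelicSiteEffect(
            snp_id=snp.snp_id,
            transcript_id=transcript.transcript_id,
            gene=transcript.gene_symbol,
            seed_kind=site.seed_kind,
            seed=site.seed,
            members=site.members,
            site_type=site.site_type,
            effect=effect,
            wild_window=wild,
            mutant_window=mutant,
            window_start=ws,
            site_start=site.start,
            site_end=site.end,
            snp_offset=rel,
        )
        for effect, site in effects
    ]


# ---------------------------------------------------------------------------
# Human-mouse conservation


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def conserved_positions(
    human: str,
    mouse: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -4.0,
) -> dict[int, bool]:
    """Map human position -> aligned-to-identical-mouse-base flag.

    Positions opposite a gap are absent from the mapping. The first optimal
    global alignment is used (the aligner's enumeration order is
    deterministic; ties resolve toward diagonal moves first).
    """
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(human, mouse)[0]
    status: dict[int, bool] = {}
    for (hs, he), (ms, me) in zip(*aln.aligned):
        for k in range(he - hs):
            status[hs + k] = human[hs + k] == mouse[ms + k]
    return status


def conservation_filter(
    human_utr3: str,
    mouse_utr3: str | None,
    sites: list[SeedSite],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -4.0,
    exempt: dict[int, int] | None = None,
) -> list[SeedSite]:
    """Flag each site conserved iff its whole footprint is aligned gap-free
    to identical mouse bases.

    ``exempt`` maps a site index to one UTR position excused from the
    base-identity requirement (the SNP position of a mutant-created site,
    which cannot be identical in the reference-based alignment). A missing
    ortholog flags every site unconserved with a warning.
    """
    if not mouse_utr3:
        warnings.warn("missing mouse ortholog; all sites flagged unconserved")
        return [replace(s, conserved=False) for s in sites]
    status = conserved_positions(
        human_utr3, mouse_utr3, match, mismatch, gap_open, gap_extend
    )
    out = []
    for idx, site in enumerate(sites):
        skip = exempt.get(idx) if exempt else None
        ok = all(
            status.get(p, False) or p == skip
            for p in range(site.start, site.end)
        )
        # an exempt position must still be aligned (gap-free), just not identical
        if skip is not None and site.start <= skip < site.end:
            ok = ok and skip in status
        out.append(replace(site, conserved=ok))
    return out
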