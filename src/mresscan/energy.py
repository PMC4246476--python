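"""Nearest-neighbor thermodynamics for allele-specific seed duplexes.

The binding free energy of a short antiparallel RNA/RNA duplex is the sum of
consecutive base-pair stack contributions plus an initiation term:

    dG37 = dH - 310.15 * dS        (cal/mol at 37 C)

Stack dH/dS values are the 1 M Na+ Watson-Crick measurements shipped in
``data/rna_nn_params.tsv``. A stack label is written with both strands
5'->3' (``GC/GC`` is 5'GC3' over 3'CG5'); a duplex read from the other
strand gives the swapped label, so lookups try both orientations.

Because the nearest-neighbor decomposition has no terminal-mismatch terms,
three complementary clamp pairs (default C-G) are appended to both duplex
ends before summation. The clamp and initiation contributions are identical
for the two alleles of a SNP and cancel exactly in ddG = dG37(alt) -
dG37(ref), which is the only quantity the pipeline reports.

Stacks containing a non-Watson-Crick pair (single internal mismatches, G-U
wobbles) fall back to a configurable destabilising term (default dG37
+1000 cal/mol, dH 0) and the record is flagged; ddG direction and the
cancellation identities do not depend on the fallback value.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .errors import DomainError
from .seeds import (
    SITE_7MER_1_7,
    SITE_7MER_2_8,
    SITE_8MER,
    SITE_8MER_1A,
    AllelicSiteEffect,
)

T_37 = 310.15  # K
RNA_BASES = frozenset("ACGU")


@dataclass(frozen=True)
class NNParams:
    """Nearest-neighbor parameter set (cal/mol and cal/(mol*K))."""

    stacks: dict[str, tuple[float, float]]
    initiation: tuple[float, float]
    terminal_au: tuple[float, float]
    fallback_dg37: float = 1000.0
    fallback_dh: float = 0.0

    @property
    def fallback_ds(self) -> float:
        return (self.fallback_dh - self.fallback_dg37) / T_37

    def lookup(self, label: str) -> tuple[float, float] | None:
        """Try the label and its strand-swapped equivalent."""
        hit = self.stacks.get(label)
        if hit is not None:
            return hit
        top, bottom = label.split("/")
        return self.stacks.get(f"{bottom}/{top}")


def load_params(path=None, fallback_dg37: float = 1000.0) -> NNParams:
    """Load the shipped (or a user-supplied) parameter TSV."""
    if path is None:
        source = resources.files("mresscan").joinpath("data/rna_nn_params.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    stacks: dict[str, tuple[float, float]] = {}
    initiation = terminal_au = None
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        entry = (float(row["dh_cal_mol"]), float(row["ds_cal_mol_k"]))
        if row["stack"] == "INITIATION":
            initiation = entry
        elif row["stack"] == "TERMINAL_AU":
            terminal_au = entry
        else:
            stacks[row["stack"]] = entry
    if initiation is None or terminal_au is None:
        raise DomainError("parameter table missing INITIATION or TERMINAL_AU rows")
    return NNParams(stacks, initiation, terminal_au, fallback_dg37=fallback_dg37)


@dataclass(frozen=True)
class DuplexEnergy:
    dh: float  # cal/mol
    ds: float  # cal/(mol*K)
    dg37: float  # cal/mol, == dh - 310.15 * ds
    n_fallback: int  # stacks priced by the fallback term
    allele: str = ""


@dataclass(frozen=True)
class SnpEnergyDelta:
    snp_id: str
    transcript_id: str
    site_type: str
    effect: str
    ddg: float  # cal/mol, alt - ref
    abs_ddg: float
    flagged: bool  # fallback stacks used, or multi-member average


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def duplex_energy(
    mirna_segment: str,
    target_segment: str,
    params: NNParams,
    clamp: str = "CCC",
    allele: str = "",
) -> DuplexEnergy:
    """dH/dS/dG37 of one antiparallel duplex.

    ``mirna_segment`` and ``target_segment`` are both 5'->3' and equally
    long; position i of the microRNA pairs position L-1-i of the target.
    ``clamp`` (5'->3' on the microRNA side) is appended complementarily to
    both ends before summation; pass ``""`` to disable.
    """
    for seq in (mirna_segment, target_segment):
        bad = set(seq) - RNA_BASES
        if bad:
            raise DomainError(f"non-RNA characters {sorted(bad)} in duplex segment")
    if len(mirna_segment) != len(target_segment):
        raise DomainError("duplex segments must have equal length")
    if len(mirna_segment) < 2 and not clamp:
        raise DomainError("duplex needs at least two pairs")
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    rc_clamp = "".join(comp[b] for b in reversed(clamp))
    top = clamp + mirna_segment + clamp
    bottom = rc_clamp + target_segment + rc_clamp
    L = len(top)
    dh, ds = params.initiation
    n_fallback = 0
    for i in range(L - 1):
        # bottom partner of top[i] is bottom[L-1-i]; the stack's bottom
        # dinucleotide read 5'->3' is bottom[L-2-i], bottom[L-1-i]
        label = f"{top[i]}{top[i + 1]}/{bottom[L - 2 - i]}{bottom[L - 1 - i]}"
        entry = params.lookup(label)
        if entry is None:
            entry = (params.fallback_dh, params.fallback_ds)
            n_fallback += 1
        dh += entry[0]
        ds += entry[1]
    for pair in ((top[0], bottom[L - 1]), (top[-1], bottom[0])):
        if pair in (("A", "U"), ("U", "A")):
            dh += params.terminal_au[0]
            ds += params.terminal_au[1]
    return DuplexEnergy(dh=dh, ds=ds, dg37=dh - T_37 * ds, n_fallback=n_fallback, allele=allele)


_SEG_SLICE = {
    SITE_7MER_1_7: slice(0, 7),
    SITE_7MER_2_8: slice(1, 8),
    SITE_8MER: slice(0, 8),
    SITE_8MER_1A: slice(0, 8),
}


def snp_delta(
    effect: AllelicSiteEffect,
    mirna_seqs: dict[str, str],
    params: NNParams,
    clamp: str = "CCC",
) -> SnpEnergyDelta:
    """ddG = dG37(alt duplex) - dG37(ref duplex) for one effect record.

    The duplex is the site-type-matched seed segment (microRNA positions 1-7,
    2-8 or 1-8) against the site footprint carrying each allele. When the
    group's members differ over the segment (8mer-1a groups can differ at
    position 1), the per-member ddG values are averaged and the record is
    flagged.
    """
    if not (effect.site_start <= effect.snp_offset < effect.site_end):
        raise DomainError(
            f"{effect.snp_id}: SNP offset outside the site footprint"
        )
    seg_slice = _SEG_SLICE[effect.site_type]
    ref_site = effect.wild_window[effect.site_start : effect.site_end]
    alt_site = effect.mutant_window[effect.site_start : effect.site_end]
    ddgs = []
    any_fallback = False
    segments = []
    for member in effect.members:
        seg = mirna_seqs[member][seg_slice]
        if len(seg) != effect.site_end - effect.site_start:
            raise DomainError(f"{member}: mature sequence too short for {effect.site_type}")
        segments.append(seg)
    for seg in segments:
        ref_e = duplex_energy(seg, ref_site, params, clamp=clamp, allele="ref")
        alt_e = duplex_energy(seg, alt_site, params, clamp=clamp, allele="alt")
        ddgs.append(alt_e.dg37 - ref_e.dg37)
        any_fallback = any_fallback or ref_e.n_fallback > 0 or alt_e.n_fallback > 0
    multi = len(set(segments)) > 1
    ddg = sum(ddgs) / len(ddgs)
    return SnpEnergyDelta(
        snp_id=effect.snp_id,
        transcript_id=effect.transcript_id,
        site_type=effect.site_type,
        effect=effect.effect,
        ddg=ddg,
        abs_ddg=abs(ddg),
        flagged=any_fallback or multi,
    )


def aggregate_snp_ddg(deltas: list[SnpEnergyDelta]) -> dict[tuple[str, str], float]:
    """Per (transcript, SNP) mean |ddG| over that SNP's effect records."""
    sums: dict[tuple[str, str], list[float]] = {}
    for d in deltas:
        sums.setdefault((d.transcript_id, d.snp_id), []).append(d.abs_ddg)
    return {k: sum(v) / len(v) for k, v in sums.items()}


@dataclass(frozen=True)
class HaplotypeScore:
    transcript_id: str
    member_snp_ids: tuple[str, ...]
    ld_rule: str
    score: float  # sum of members' |ddG|, cal/mol


def haplotype_scores(
    deltas: list[SnpEnergyDelta],
    ld_pairs: list[tuple[str, str, float, float]],
    rule: str = "dprime",
    threshold: float = 1.0,
) -> list[HaplotypeScore]:
    """Accumulated |ddG| over linked seed-site SNPs in one 3'UTR.

    Within each transcript, SNPs form the connected components of the graph
    whose edges are LD pairs satisfying the rule (``dprime`` or ``r2`` >=
    threshold); components of size >= 2 are emitted with the sum of their
    members' |ddG|.
    """
    if rule not in ("dprime", "r2"):
        raise DomainError(f"unknown LD grouping rule {rule!r}")
    measure = {(min(a, b), max(a, b)): (dp if rule == "dprime" else r2) for a, b, dp, r2 in ld_pairs}
    per_snp = aggregate_snp_ddg(deltas)
    by_tx: dict[str, list[str]] = {}
    for tx, snp in per_snp:
        by_tx.setdefault(tx, []).append(snp)
    out = []
    for tx in sorted(by_tx):
        snps = sorted(set(by_tx[tx]))
        parent = {s: s for s in snps}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(snps):
            for b in snps[i + 1 :]:
                if measure.get((min(a, b), max(a, b)), -1.0) >= threshold:
                    parent[find(a)] = find(b)
        components: dict[str, list[str]] = {}
        for s in snps:
            components.setdefault(find(s), []).append(s)
        for members in sorted(components.values()):
            if len(members) >= 2:
                out.append(
                    HaplotypeScore(
                        transcript_id=tx,
                        member_snp_ids=tuple(sorted(members)),
                        ld_rule=f"{rule}>={threshold}",
                        score=sum(per_snp[(tx, s)] for s in members),
                    )
                )
    return out
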