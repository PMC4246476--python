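"""File formats, domain records, coordinate conventions and configuration.

Conventions
-----------
* All genomic coordinates in files are 1-based inclusive (dbSNP/NCBI style);
  internally every interval is 0-based half-open.
* Sequences are normalised to uppercase RNA (``T`` -> ``U``) on load.
* SNP alleles in files are given on the forward genomic strand as DNA bases;
  orientation into a transcript's sense strand happens downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import DomainError, IntegrityError, ParseError, UsageError

RNA_ALPHABET = frozenset("ACGU")
DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

REGION_TYPES = ("5UTR", "CDS", "3UTR")


def normalize_rna(seq: str) -> str:
    """Uppercase a sequence and convert DNA ``T`` to RNA ``U``."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise DomainError(f"non-RNA characters {sorted(bad)} in sequence")
    return s


def to_internal_coords(pos_1based: int) -> int:
    """1-based file coordinate -> 0-based internal coordinate."""
    if pos_1based < 1:
        raise DomainError(f"1-based position must be >= 1, got {pos_1based}")
    return pos_1based - 1


def to_file_coords(pos_0based: int) -> int:
    """Inverse of :func:`to_internal_coords`."""
    if pos_0based < 0:
        raise DomainError(f"0-based position must be >= 0, got {pos_0based}")
    return pos_0based + 1


@dataclass
class Snp:
    """A bi-allelic single-nucleotide polymorphism.

    ``pos`` is 0-based internally; ``maf`` is the global minor-allele
    frequency (``None`` when the source lacks frequency data) and
    ``n_chromosomes`` the number of chromosomes the frequency was observed on.
    """

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float | None = None
    n_chromosomes: int = 0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise DomainError(f"{self.snp_id}: ref and alt alleles are equal")
        for a in (self.ref_allele, self.alt_allele):
            if a not in DNA_COMPLEMENT:
                raise DomainError(f"{self.snp_id}: allele {a!r} is not a single DNA base")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise DomainError(f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class Transcript:
    """A protein-coding transcript with region coordinates and its 3'UTR.

    ``regions`` holds ``(region_type, start, end)`` genomic intervals,
    0-based half-open, non-overlapping within the transcript.
    ``utr3_sequence`` is the sense-strand 3'UTR, 5'->3', RNA alphabet.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    regions: list[tuple[str, int, int]]
    utr3_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DomainError(f"{self.transcript_id}: strand must be + or -")
        ivs = sorted((s, e) for _, s, e in self.regions)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise IntegrityError(
                    f"{self.transcript_id}: overlapping regions at {s2} < {e1}"
                )
        if len(self.utr3_sequence) != self.utr3_length:
            raise IntegrityError(
                f"{self.transcript_id}: 3'UTR sequence length "
                f"{len(self.utr3_sequence)} != summed region length {self.utr3_length}"
            )

    @property
    def utr3_length(self) -> int:
        return sum(e - s for t, s, e in self.regions if t == "3UTR")

    def _utr3_intervals_sense(self) -> list[tuple[int, int]]:
        ivs = sorted(((s, e) for t, s, e in self.regions if t == "3UTR"))
        if self.strand == "-":
            ivs = ivs[::-1]
        return ivs

    def utr3_genomic_intervals(self) -> list[tuple[int, int]]:
        """3'UTR intervals in genomic order (0-based half-open)."""
        return sorted((s, e) for t, s, e in self.regions if t == "3UTR")

    def genomic_to_utr_offset(self, pos: int) -> int | None:
        """Map a genomic position into the sense 3'UTR, or ``None`` if outside."""
        off = 0
        for s, e in self._utr3_intervals_sense():
            if s <= pos < e:
                return off + (pos - s if self.strand == "+" else e - 1 - pos)
            off += e - s
        return None

    def utr_offset_to_genomic(self, off: int) -> int:
        """Inverse of :meth:`genomic_to_utr_offset`."""
        if off < 0:
            raise DomainError("negative UTR offset")
        for s, e in self._utr3_intervals_sense():
            if off < e - s:
                return s + off if self.strand == "+" else e - 1 - off
            off -= e - s
        raise DomainError(f"{self.transcript_id}: UTR offset beyond 3'UTR end")

    def sense_allele(self, dna_allele: str) -> str:
        """Orient a forward-strand DNA allele into the sense RNA alphabet."""
        base = dna_allele if self.strand == "+" else DNA_COMPLEMENT[dna_allele]
        return base.replace("T", "U")


@dataclass
class EvidenceBundle:
    """All per-dataset evidence tables the selection pipeline consumes."""

    gwas: dict[str, dict[str, float]] = field(default_factory=dict)
    ld_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    go_annotations: dict[str, set[str]] = field(default_factory=dict)
    disease_genes: dict[str, set[str]] = field(default_factory=dict)
    coexpression: dict[tuple[str, str], float] = field(default_factory=dict)
    mirna_disease: list[tuple[str, str]] = field(default_factory=list)
    gene_disease: list[tuple[str, str]] = field(default_factory=list)
    positives: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for ds, table in self.gwas.items():
            for snp, p in table.items():
                if not (0.0 < p <= 1.0) or math.isnan(p):
                    raise IntegrityError(f"GWAS p-value {p} for {snp} in {ds} outside (0,1]")
        for a, b, dp, r2 in self.ld_pairs:
            if not (0.0 <= dp <= 1.0) or not (0.0 <= r2 <= 1.0):
                raise IntegrityError(f"LD measures out of range for pair ({a},{b})")
        for pair, r in self.coexpression.items():
            if not (-1.0 <= r <= 1.0):
                raise IntegrityError(f"correlation {r} for pair {pair} outside [-1,1]")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default."""

    flank: int = 50
    p_snp: float = 0.01
    p_go: float = 0.05
    maf_common: float = 0.01
    min_chromosomes: int = 100
    dprime_min: float = 1.0
    gap_open: float = -10.0
    gap_extend: float = -4.0
    match_score: float = 1.0
    mismatch_score: float = -1.0
    min_utr_len: int = 50
    ld_group_rule: str = "dprime"
    ld_group_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__},
                sort_keys=True,
            )
        )


# ---------------------------------------------------------------------------
# FASTA / TSV loading


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: normalised RNA sequence}``.

    The first word of the header is the record id.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
                break
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty header")
        records[rec.id] = normalize_rna(str(rec.seq))
    return records


def load_mirnas(path: str | Path) -> list[tuple[str, str]]:
    """Mature microRNA sequences as ``(id, sequence)`` in file order."""
    return list(read_fasta(path).items())


def load_region_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"transcript", "gene", "chrom", "strand", "region_type", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: region table missing columns {sorted(missing)}")
    return df


def load_reference(
    utr3_fasta: str | Path,
    region_table_path: str | Path,
    snp_table_path: str | Path,
    min_utr_len: int = 50,
) -> tuple[list[Transcript], list[Snp], dict[str, int]]:
    """Load transcripts and SNPs; returns ``(transcripts, snps, load_report)``.

    Transcripts whose 3'UTR is shorter than ``min_utr_len`` are dropped
    (counted as ``short_utr``); non-bi-allelic SNP rows are rejected
    (``multi_allelic``); SNPs with a malformed single allele are rejected
    (``bad_allele``).
    """
    seqs = read_fasta(utr3_fasta)
    regions = load_region_table(region_table_path)
    report = {"short_utr": 0, "multi_allelic": 0, "bad_allele": 0, "no_sequence": 0}

    transcripts: list[Transcript] = []
    for tx_id, grp in regions.groupby("transcript", sort=True):
        gene = str(grp["gene"].iloc[0])
        chrom = str(grp["chrom"].iloc[0])
        strand = str(grp["strand"].iloc[0])
        regs = [
            (str(r.region_type), to_internal_coords(int(r.start)), int(r.end))
            for r in grp.itertuples()
        ]
        if tx_id not in seqs:
            report["no_sequence"] += 1
            continue
        utr3 = seqs[tx_id]
        utr3_len = sum(e - s for t, s, e in regs if t == "3UTR")
        if len(utr3) != utr3_len:
            raise IntegrityError(
                f"{tx_id}: 3'UTR region length {utr3_len} does not match "
                f"sequence length {len(utr3)}"
            )
        if utr3_len < min_utr_len:
            report["short_utr"] += 1
            continue
        transcripts.append(Transcript(str(tx_id), gene, chrom, strand, regs, utr3))

    snp_df = pd.read_csv(snp_table_path, sep="\t", dtype={"chrom": str})
    snps: list[Snp] = []
    for row in snp_df.itertuples():
        ref, alt = str(row.ref), str(row.alt)
        if "," in ref or "," in alt or "/" in alt or "/" in ref:
            report["multi_allelic"] += 1
            continue
        if len(ref) != 1 or len(alt) != 1 or ref not in DNA_COMPLEMENT or alt not in DNA_COMPLEMENT:
            report["bad_allele"] += 1
            continue
        maf = None if pd.isna(row.maf) else float(row.maf)
        snps.append(
            Snp(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=to_internal_coords(int(row.pos)),
                ref_allele=ref,
                alt_allele=alt,
                maf=maf,
                n_chromosomes=int(row.n_chromosomes),
            )
        )
    snps.sort(key=lambda s: (s.chrom, s.pos, s.snp_id))
    transcripts.sort(key=lambda t: t.transcript_id)
    return transcripts, snps, report


def load_two_column(path: str | Path, key: str, value: str) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if key not in df.columns or value not in df.columns:
        raise ParseError(f"{path}: expected columns {key!r}, {value!r}")
    return [(str(a), str(b)) for a, b in zip(df[key], df[value])]


def load_go_annotations(path: str | Path) -> dict[str, set[str]]:
    """2-column gene<->term TSV into ``{gene: set(term)}``."""
    out: dict[str, set[str]] = {}
    for gene, term in load_two_column(path, "gene", "term"):
        out.setdefault(gene, set()).add(term)
    return out


def load_gwas_table(path: str | Path) -> dict[str, dict[str, float]]:
    """TSV with columns ``dataset, snp_id, p`` into nested dicts."""
    df = pd.read_csv(path, sep="\t", dtype={"dataset": str, "snp_id": str})
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.dataset), {})[str(row.snp_id)] = float(row.p)
    return out


def load_ld_pairs(path: str | Path) -> list[tuple[str, str, float, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"snpA": str, "snpB": str})
    return [
        (str(r.snpA), str(r.snpB), float(r.dprime), float(r.r2)) for r in df.itertuples()
    ]


def load_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """TSV with columns ``dataset, gene`` into ``{dataset: gene set}``."""
    out: dict[str, set[str]] = {}
    for ds, gene in load_two_column(path, "dataset", "gene"):
        out.setdefault(ds, set()).add(gene)
    return out


def load_coexpression(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "gene": str})
    return {(str(r.mirna), str(r.gene)): float(r.r) for r in df.itertuples()}


def load_positives(path: str | Path) -> set[str]:
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


# ---------------------------------------------------------------------------
# Report writing

REPORT_SCHEMAS: dict[str, list[str]] = {
    "sites": ["transcript_id", "start", "end", "site_type", "seed_kind", "seed", "members", "conserved"],
    "effects": [
        "snp_id", "transcript_id", "gene", "site_type", "effect", "seed_kind", "seed",
        "members", "utr_start", "utr_end", "wild_window", "mutant_window",
    ],
    "assignments": ["dataset", "snp_id", "inherited_p", "proxies"],
    "candidates": ["dataset", "snp_id", "gene", "inherited_p", "terms"],
    "energies": ["snp_id", "transcript_id", "site_type", "effect", "ddg", "abs_ddg", "flagged"],
    "density": ["region", "maf_class", "snp_count", "total_kb", "density"],
    "enrichment": ["term_id", "k", "K", "n", "N", "p"],
}

_PVALUE_COLUMNS = {"inherited_p", "p"}
_FLOAT_PRECISION = ".10g"


def _format_value(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return format(v, _FLOAT_PRECISION)
    return str(v)


def write_report(records: Sequence[Mapping], path: str | Path, kind: str) -> None:
    """Write records of a declared schema as a deterministic TSV.

    Columns follow the schema order, rows are sorted by the full column
    tuple, and floats use a fixed precision so reruns are byte-identical.
    """
    if kind not in REPORT_SCHEMAS:
        raise UsageError(f"unknown report kind {kind!r}; known: {sorted(REPORT_SCHEMAS)}")
    cols = REPORT_SCHEMAS[kind]
    rows: list[list[str]] = []
    for rec in records:
        missing = [c for c in cols if c not in rec]
        if missing:
            raise UsageError(f"record missing fields {missing} for kind {kind!r}")
        for c in cols:
            v = rec[c]
            if c in _PVALUE_COLUMNS and isinstance(v, float) and math.isnan(v):
                raise IntegrityError(f"NaN value in column {c!r} of a {kind!r} record")
        rows.append([_format_value(rec[c]) for c in cols])
    rows.sort()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_report(path: str | Path, kind: str) -> list[dict]:
    """Re-read a report written by :func:`write_report`."""
    if kind not in REPORT_SCHEMAS:
        raise UsageError(f"unknown report kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        rec: dict = {}
        for c in REPORT_SCHEMAS[kind]:
            raw = row[c]
            if raw in ("True", "False"):
                rec[c] = raw == "True"
                continue
            for caster in (int, float):
                try:
                    rec[c] = caster(raw)
                    break
                except ValueError:
                    continue
            else:
                rec[c] = raw
        out.append(rec)
    return out
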