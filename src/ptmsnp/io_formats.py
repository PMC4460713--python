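"""File formats and domain record types.

Everything the pipeline reads or writes lives here: FASTA proteomes
(two "databases" whose sequences may disagree), tab-separated tables for
nsSNPs, PTM sites, disease-SNP catalogs and genotype counts, and the three
result tables (hits, enrichment, per-trait disease summary).

Conventions
-----------
* Coordinates are 1-based, inclusive, in protein space.
* The window pad character is ``-`` and marks absence of sequence beyond a
  terminus; it is distinct from the unknown residue ``X``, which is real
  sequence that never matches anything.
* TSV dialect: tab-separated, UTF-8, ``#``-prefixed comment lines ignored,
  header row mandatory.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

PAD = "-"
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXU*")
DB_TAGS = ("snp_db", "ptm_db")
SNP_CLASSES = ("missense", "stopgain")
EVIDENCE_LEVELS = ("experimental", "predicted")
CATALOG_SOURCES = ("nhgri", "gad", "dbgap", "user")


class ParseError(ValueError):
    """Malformed input file."""


class SchemaError(ValueError):
    """A table is missing mandatory columns."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowPeptide:
    """A fixed-width peptide window around a focal residue.

    ``residues`` has length ``2*flank + 1`` (15 by default); positions that
    fall outside the protein are padded with ``-``.  ``center_index`` is the
    0-based index of the focal residue (== flank).
    """

    residues: str
    center_index: int

    def __post_init__(self) -> None:
        if len(self.residues) != 2 * self.center_index + 1:
            raise ValueError(
                f"window length {len(self.residues)} inconsistent with "
                f"center_index {self.center_index}"
            )
        if self.residues[self.center_index] == PAD:
            raise ValueError("window center may not be the pad character")
        core = self.residues.strip(PAD)
        if PAD in core:
            raise ValueError("pad characters must be a contiguous prefix/suffix")

    @property
    def flank(self) -> int:
        return self.center_index

    @property
    def depadded(self) -> str:
        return self.residues.strip(PAD)

    @property
    def n_lead_pads(self) -> int:
        return len(self.residues) - len(self.residues.lstrip(PAD))


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence from one of the two source databases."""

    accession: str
    db_tag: str
    sequence: str

    def __post_init__(self) -> None:
        if self.db_tag not in DB_TAGS:
            raise ValueError(f"db_tag must be one of {DB_TAGS}, got {self.db_tag!r}")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.accession}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SnpRecord:
    """One non-synonymous SNP on a protein from the SNP database."""

    rs_id: str
    protein_ac: str
    position: int
    ref_aa: str
    alt_aa: str
    snp_class: str  # missense | stopgain
    snp_window: WindowPeptide | None = None

    def __post_init__(self) -> None:
        if self.snp_class not in SNP_CLASSES:
            raise ValueError(f"bad snp_class {self.snp_class!r}")
        if (self.snp_class == "stopgain") != (self.alt_aa == "*"):
            raise ValueError(
                f"{self.rs_id}: snp_class {self.snp_class} inconsistent with "
                f"alt_aa {self.alt_aa!r} (stopgain iff alt is '*')"
            )
        if self.position < 1:
            raise ValueError(f"{self.rs_id}: position must be >= 1")


@dataclass(frozen=True)
class PtmSite:
    """One post-translational modification site from the PTM database."""

    protein_ac: str
    position: int
    residue: str
    ptm_type: str
    evidence: str  # experimental | predicted
    ptm_window: WindowPeptide | None = None

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(f"bad evidence {self.evidence!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.protein_ac, self.position, self.ptm_type)


@dataclass(frozen=True)
class DiseaseSnp:
    """One catalog entry linking an rsID to a trait."""

    rs_id: str
    trait: str
    p_value: float | None
    source: str

    def __post_init__(self) -> None:
        if self.source not in CATALOG_SOURCES:
            raise ValueError(f"bad source {self.source!r}")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.rs_id}: p_value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def extract_window(sequence: str, position: int, flank: int = 7) -> WindowPeptide:
    """Extract the ±flank peptide window around 1-based ``position``.

    Positions beyond either terminus are padded with ``-`` so the returned
    window always has length ``2*flank + 1`` with the focal residue at the
    center.
    """
    if not 1 <= position <= len(sequence):
        raise IndexError(
            f"position {position} out of range for sequence of length {len(sequence)}"
        )
    lo = position - flank  # 1-based, may be < 1
    hi = position + flank  # may exceed len
    left_pad = max(0, 1 - lo)
    right_pad = max(0, hi - len(sequence))
    core = sequence[max(lo, 1) - 1 : min(hi, len(sequence))]
    return WindowPeptide(PAD * left_pad + core + PAD * right_pad, flank)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, db_tag: str) -> list[ProteinRecord]:
    """Read a protein FASTA; accession = first whitespace token of the header."""
    path = Path(path)
    # pre-scan for a sequence line before any header, naming the offending line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        ac = rec.id
        if ac in seen:
            raise ParseError(f"{path}: duplicate accession {ac!r}")
        seen.add(ac)
        records.append(ProteinRecord(ac, db_tag, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def index_proteins(records: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {rec.accession: rec for rec in records}


# ---------------------------------------------------------------------------
# TSV input tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return df


def _parse_window(text: str) -> WindowPeptide | None:
    text = text.strip()
    if not text:
        return None
    if len(text) % 2 == 0:
        raise ValueError(f"window {text!r} has even length")
    return WindowPeptide(text, (len(text) - 1) // 2)


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read snps.tsv.  Rows with unparseable mandatory fields are rejected
    (count logged); duplicate (rs_id, protein_ac, position) rows collapse to
    the first occurrence."""
    df = _read_tsv(path, ["rs_id", "protein_ac", "position", "ref_aa", "alt_aa", "snp_class"])
    records: list[SnpRecord] = []
    seen: set[tuple[str, str, int]] = set()
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            rec = SnpRecord(
                rs_id=row.rs_id,
                protein_ac=row.protein_ac,
                position=int(row.position),
                ref_aa=row.ref_aa,
                alt_aa=row.alt_aa,
                snp_class=row.snp_class,
                snp_window=_parse_window(getattr(row, "snp_window", "")),
            )
        except (ValueError, TypeError):
            n_rejected += 1
            continue
        key = (rec.rs_id, rec.protein_ac, rec.position)
        if key in seen:
            continue
        seen.add(key)
        records.append(rec)
    if n_rejected:
        log.warning("%s: rejected %d unparseable SNP rows", path, n_rejected)
    return records


def read_ptm_table(path: str | Path) -> list[PtmSite]:
    df = _read_tsv(path, ["protein_ac", "position", "residue", "ptm_type", "evidence"])
    records: list[PtmSite] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            records.append(
                PtmSite(
                    protein_ac=row.protein_ac,
                    position=int(row.position),
                    residue=row.residue,
                    ptm_type=row.ptm_type,
                    evidence=row.evidence,
                    ptm_window=_parse_window(getattr(row, "ptm_window", "")),
                )
            )
        except (ValueError, TypeError):
            n_rejected += 1
    if n_rejected:
        log.warning("%s: rejected %d unparseable PTM rows", path, n_rejected)
    return records


def read_disease_catalog(path: str | Path) -> list[DiseaseSnp]:
    """Read catalog.tsv.  The same rsID may appear under several traits —
    no collapsing happens across traits."""
    df = _read_tsv(path, ["rs_id", "trait", "p_value", "source"])
    records: list[DiseaseSnp] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            p = float(row.p_value) if str(row.p_value).strip() else None
            records.append(DiseaseSnp(row.rs_id, row.trait, p, row.source))
        except (ValueError, TypeError):
            n_rejected += 1
    if n_rejected:
        log.warning("%s: rejected %d unparseable catalog rows", path, n_rejected)
    return records


def read_id_map(path: str | Path) -> list[tuple[str, str]]:
    """Read the snp_db→ptm_db accession map (columns snp_ac, ptm_ac)."""
    df = _read_tsv(path, ["snp_ac", "ptm_ac"])
    return [(r.snp_ac, r.ptm_ac) for r in df.itertuples(index=False)]


def write_snp_table(records: Iterable[SnpRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "rs_id": r.rs_id,
                "protein_ac": r.protein_ac,
                "position": r.position,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "snp_class": r.snp_class,
                "snp_window": r.snp_window.residues if r.snp_window else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=["rs_id", "protein_ac", "position", "ref_aa", "alt_aa", "snp_class", "snp_window"],
    ).to_csv(path, sep="\t", index=False)


def write_ptm_table(records: Iterable[PtmSite], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "protein_ac": r.protein_ac,
                "position": r.position,
                "residue": r.residue,
                "ptm_type": r.ptm_type,
                "evidence": r.evidence,
                "ptm_window": r.ptm_window.residues if r.ptm_window else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=["protein_ac", "position", "residue", "ptm_type", "evidence", "ptm_window"],
    ).to_csv(path, sep="\t", index=False)


def write_disease_catalog(records: Iterable[DiseaseSnp], path: str | Path) -> None:
    rows = [
        {
            "rs_id": r.rs_id,
            "trait": r.trait,
            "p_value": "" if r.p_value is None else f"{r.p_value:.6E}",
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["rs_id", "trait", "p_value", "source"]).to_csv(
        path, sep="\t", index=False
    )


def write_id_map(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(list(pairs), columns=["snp_ac", "ptm_ac"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ratio formatting
# ---------------------------------------------------------------------------

def coverage_ratio(numer: int, denom: int, ndigits: int = 3) -> float:
    """Rounded coverage ratio, the convention of the site and trait tables."""
    if denom == 0:
        return 0.0
    return round(numer / denom, ndigits)


def truncate_ratio(numer: int, denom: int, ndigits: int = 5) -> float:
    """Truncated (floor) ratio, the convention of the functional-class table."""
    if denom == 0:
        return 0.0
    scale = 10 ** ndigits
    return math.floor(numer / denom * scale) / scale


def format_p(p: float, cap: float = 0.999) -> str:
    """Display form of a p-value: 3 decimals when >= 0.001, else scientific
    with a 2-decimal mantissa; values above ``cap`` display as the cap."""
    p = min(p, cap)
    if p >= 0.001:
        return f"{p:.3f}"
    return f"{p:.2E}"


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

HITS_COLUMNS = [
    "rs_id",
    "snp_protein_ac",
    "snp_position",
    "ptm_protein_ac",
    "ptm_position",
    "ptm_type",
    "evidence",
    "offset",
    "category",
    "method",
    "identities",
    "overlap",
    "truncates_site",
    "n_merged",
]


def write_hits_tsv(hits: Iterable, path: str | Path) -> None:
    """Write detected PTM-SNP hits, sorted by (rs_id, accessions, position)."""
    rows = [dataclasses.asdict(h) for h in hits]
    df = pd.DataFrame(rows, columns=HITS_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["rs_id", "snp_protein_ac", "ptm_protein_ac", "ptm_position", "ptm_type"],
            kind="mergesort",
        )
        df["truncates_site"] = df["truncates_site"].map(
            lambda v: "" if v is None else str(int(v))
        )
    df.to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list:
    from .detection import PtmSnpHit  # local import avoids a module cycle

    df = _read_tsv(path, HITS_COLUMNS)
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            PtmSnpHit(
                rs_id=row.rs_id,
                snp_protein_ac=row.snp_protein_ac,
                snp_position=int(row.snp_position),
                ptm_protein_ac=row.ptm_protein_ac,
                ptm_position=int(row.ptm_position),
                ptm_type=row.ptm_type,
                evidence=row.evidence,
                offset=int(row.offset),
                category=row.category,
                method=row.method,
                identities=int(row.identities),
                overlap=int(row.overlap),
                truncates_site=bool(int(row.truncates_site)) if str(row.truncates_site).strip() else None,
                n_merged=int(row.n_merged),
            )
        )
    return hits


ENRICHMENT_COLUMNS = ["label", "n_class", "k_class", "n_total", "k_total", "coverage", "p_value"]


def write_enrichment_tsv(rows: Iterable, path: str | Path, style: str = "functional") -> None:
    """Write enrichment rows.  ``style='functional'`` prints coverage truncated
    to 5 decimals (functional-class convention); ``style='ptm'`` rounds to 3."""
    out = []
    for r in rows:
        if style == "functional":
            cov = f"{truncate_ratio(r.k_class, r.n_class, 5):.5f}"
        else:
            cov = f"{coverage_ratio(r.k_class, r.n_class, 3):.3f}"
        out.append(
            {
                "label": r.label,
                "n_class": r.n_class,
                "k_class": r.k_class,
                "n_total": r.n_total,
                "k_total": r.k_total,
                "coverage": cov,
                "p_value": format_p(r.p_value),
            }
        )
    pd.DataFrame(out, columns=ENRICHMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_enrichment_tsv(path: str | Path) -> list:
    from .enrichment import EnrichmentRow

    df = _read_tsv(path, ENRICHMENT_COLUMNS)
    return [
        EnrichmentRow(
            label=r.label,
            n_class=int(r.n_class),
            k_class=int(r.k_class),
            n_total=int(r.n_total),
            k_total=int(r.k_total),
            coverage=float(r.coverage),
            p_value=float(r.p_value),
        )
        for r in df.itertuples(index=False)
    ]


SUMMARY_COLUMNS = ["trait", "n_disease_snps", "n_ptm_snps", "ratio"]


def write_disease_summary_tsv(rows: Iterable, path: str | Path) -> None:
    out = [
        {
            "trait": r.trait,
            "n_disease_snps": r.n_disease_snps,
            "n_ptm_snps": r.n_ptm_snps,
            "ratio": f"{r.ratio:.3f}",
        }
        for r in rows
    ]
    pd.DataFrame(out, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_disease_summary_tsv(path: str | Path) -> list:
    from .association import TraitSummary

    df = _read_tsv(path, SUMMARY_COLUMNS)
    return [
        TraitSummary(
            trait=r.trait,
            n_disease_snps=int(r.n_disease_snps),
            n_ptm_snps=int(r.n_ptm_snps),
            ratio=float(r.ratio),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# genotype tables (GWAS stage)
# ---------------------------------------------------------------------------

GENOTYPE_COUNT_COLUMNS = ["rs_id", "r0", "r1", "r2", "s0", "s1", "s2", "miss_case", "miss_ctrl"]


def read_genotype_counts(path: str | Path) -> pd.DataFrame:
    """Aggregate-mode genotype table: per-SNP case (r) / control (s) counts of
    0/1/2 copies of the counted allele plus missing-call counts."""
    df = _read_tsv(path, GENOTYPE_COUNT_COLUMNS)
    for col in GENOTYPE_COUNT_COLUMNS[1:]:
        df[col] = df[col].astype(int)
    return df


def write_genotype_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[GENOTYPE_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)
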