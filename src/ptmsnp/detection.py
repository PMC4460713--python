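"""PTM-SNP detection: pair nsSNPs with candidate PTM sites, resolve the
signed offset of each SNP relative to each site, classify, and de-duplicate.

A *PTM-SNP* is an nsSNP whose best window superposition places it on a PTM
site (offset 0) or within the ±7-residue flanking region.  Detection is
sliding-window identity matching; when repeats leave two superpositions tied
on identities, the case is routed to an affine-gap global alignment of the
full protein sequences.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .alignment import AlignParams, fallback_offset, slide_candidates
from .io_formats import (
    PAD,
    ProteinRecord,
    PtmSite,
    SnpRecord,
    coverage_ratio,
    extract_window,
)

log = logging.getLogger(__name__)

CATEGORIES = ("on_site", "flanking", "stopgain_affected")
METHODS = ("slide", "global_fallback")


@dataclass(frozen=True)
class ProteinIndex:
    """Lookup of full protein sequences in both source databases."""

    snp_db: Mapping[str, ProteinRecord]
    ptm_db: Mapping[str, ProteinRecord]

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord]) -> "ProteinIndex":
        snp_db: dict[str, ProteinRecord] = {}
        ptm_db: dict[str, ProteinRecord] = {}
        for rec in records:
            (snp_db if rec.db_tag == "snp_db" else ptm_db)[rec.accession] = rec
        return cls(snp_db, ptm_db)


@dataclass(frozen=True)
class PtmSnpHit:
    """A detected (nsSNP, PTM site) pair with its resolved signed offset."""

    rs_id: str
    snp_protein_ac: str
    snp_position: int
    ptm_protein_ac: str
    ptm_position: int
    ptm_type: str
    evidence: str
    offset: int
    category: str  # on_site | flanking | stopgain_affected
    method: str  # slide | global_fallback
    identities: int
    overlap: int
    truncates_site: bool | None = None  # stop-gain only: stop at/before the site
    n_merged: int = 1

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if self.method not in METHODS:
            raise ValueError(f"bad method {self.method!r}")
        if self.category == "on_site" and self.offset != 0:
            raise ValueError("on_site hits must have offset 0")
        if self.category == "flanking" and self.offset == 0:
            raise ValueError("flanking hits must have offset != 0")

    @property
    def dedup_key(self) -> tuple[str, str, int, str]:
        return (self.rs_id, self.ptm_protein_ac, self.ptm_position, self.ptm_type)


def classify(snp_class: str, offset: int, flank: int = 7) -> str:
    """Category of a resolved hit: missense at offset 0 is on-site, missense
    elsewhere in the window is flanking, any stop-gain in the window is
    stopgain_affected."""
    if abs(offset) > flank:
        raise ValueError(f"offset {offset} outside ±{flank}")
    if snp_class == "stopgain":
        return "stopgain_affected"
    if snp_class == "missense":
        return "on_site" if offset == 0 else "flanking"
    raise ValueError(f"bad snp_class {snp_class!r}")


def candidate_pairs(
    snps: Iterable[SnpRecord],
    ptms: Iterable[PtmSite],
    id_map: Iterable[tuple[str, str]] | Mapping[str, set[str]],
    flank: int = 7,
    slack: int = 10,
) -> list[tuple[SnpRecord, PtmSite]]:
    """All (SNP, PTM) pairs on mapped accessions whose raw coordinate
    difference is within flank + slack (slack absorbs cross-database
    coordinate drift)."""
    if isinstance(id_map, Mapping):
        mapping = {k: set(v) for k, v in id_map.items()}
    else:
        mapping = {}
        for snp_ac, ptm_ac in id_map:
            mapping.setdefault(snp_ac, set()).add(ptm_ac)
    by_ac: dict[str, list[PtmSite]] = {}
    for ptm in ptms:
        by_ac.setdefault(ptm.protein_ac, []).append(ptm)
    band = flank + slack
    pairs: list[tuple[SnpRecord, PtmSite]] = []
    for snp in snps:
        for ptm_ac in sorted(mapping.get(snp.protein_ac, ())):
            for ptm in by_ac.get(ptm_ac, ()):
                if abs(snp.position - ptm.position) <= band:
                    pairs.append((snp, ptm))
    return pairs


def _window_stats_at_offset(snp_window, ptm_window, k: int) -> tuple[int, int]:
    a, b = snp_window.residues, ptm_window.residues
    overlap = identities = 0
    for i in range(len(a)):
        j = i + k
        if not 0 <= j < len(b):
            continue
        if a[i] == PAD or b[j] == PAD:
            continue
        overlap += 1
        if a[i] == b[j] and a[i] != "X":
            identities += 1
    return overlap, identities


def resolve(
    snp: SnpRecord,
    ptm: PtmSite,
    proteins: ProteinIndex | None = None,
    align_params: AlignParams = AlignParams(),
    flank: int = 7,
    min_overlap: int = 8,
    max_mismatch: int = 1,
) -> PtmSnpHit | None:
    """Resolve one candidate pair to a hit, or None.

    Sliding-window matching produces offset candidates; a unique best
    (most identities) candidate is accepted directly.  A tie on identities —
    the signature of a sequence repeat — routes the pair to the global-
    alignment fallback.  Stop-gain SNPs are aligned with their
    reference-allele window (the variant peptide does not exist).
    """
    snp_window = snp.snp_window
    if snp_window is None:
        if proteins is None or snp.protein_ac not in proteins.snp_db:
            raise LookupError(f"no window or sequence for SNP {snp.rs_id}")
        snp_window = extract_window(
            proteins.snp_db[snp.protein_ac].sequence, snp.position, flank
        )
    ptm_window = ptm.ptm_window
    if ptm_window is None:
        if proteins is None or ptm.protein_ac not in proteins.ptm_db:
            raise LookupError(f"no window or sequence for PTM {ptm.site_key}")
        ptm_window = extract_window(
            proteins.ptm_db[ptm.protein_ac].sequence, ptm.position, flank
        )

    cands = slide_candidates(snp_window, ptm_window, min_overlap, max_mismatch)
    if not cands:
        return None
    tied = [c for c in cands if c.identities == cands[0].identities]
    if len(tied) == 1:
        best = tied[0]
        offset, overlap, identities = best.offset, best.overlap, best.identities
        method = "slide"
    else:
        snp_prot = proteins.snp_db.get(snp.protein_ac) if proteins else None
        ptm_prot = proteins.ptm_db.get(ptm.protein_ac) if proteins else None
        snp_for_fb = snp if snp.snp_window else dataclasses.replace(snp, snp_window=snp_window)
        ptm_for_fb = ptm if ptm.ptm_window else dataclasses.replace(ptm, ptm_window=ptm_window)
        offset = fallback_offset(snp_for_fb, ptm_for_fb, snp_prot, ptm_prot, align_params, flank)
        if offset is None:
            return None
        overlap, identities = _window_stats_at_offset(snp_window, ptm_window, offset)
        method = "global_fallback"

    aligned_col = ptm_window.center_index + offset
    if 0 <= aligned_col < len(ptm_window.residues):
        ptm_side_res = ptm_window.residues[aligned_col]
        if ptm_side_res not in (PAD, snp.ref_aa):
            log.debug(
                "%s: ref_aa %s disagrees with PTM-window residue %s at offset %+d",
                snp.rs_id, snp.ref_aa, ptm_side_res, offset,
            )

    category = classify(snp.snp_class, offset, flank)
    return PtmSnpHit(
        rs_id=snp.rs_id,
        snp_protein_ac=snp.protein_ac,
        snp_position=snp.position,
        ptm_protein_ac=ptm.protein_ac,
        ptm_position=ptm.position,
        ptm_type=ptm.ptm_type,
        evidence=ptm.evidence,
        offset=offset,
        category=category,
        method=method,
        identities=identities,
        overlap=overlap,
        truncates_site=(offset <= 0) if snp.snp_class == "stopgain" else None,
    )


def detect(
    snps: Iterable[SnpRecord],
    ptms: Iterable[PtmSite],
    id_map,
    proteins: ProteinIndex | None = None,
    align_params: AlignParams = AlignParams(),
    flank: int = 7,
    slack: int = 10,
    min_overlap: int = 8,
    max_mismatch: int = 1,
) -> list[PtmSnpHit]:
    """End-to-end detection: enumerate banded pairs, resolve, de-duplicate."""
    hits = []
    for snp, ptm in candidate_pairs(snps, ptms, id_map, flank, slack):
        hit = resolve(snp, ptm, proteins, align_params, flank, min_overlap, max_mismatch)
        if hit is not None:
            hits.append(hit)
    return deduplicate(hits)


_EVIDENCE_RANK = {"experimental": 0, "predicted": 1}
_METHOD_RANK = {"slide": 0, "global_fallback": 1}


def deduplicate(hits: Iterable[PtmSnpHit]) -> list[PtmSnpHit]:
    """One hit per (rs_id, ptm accession, ptm position, ptm type), preferring
    experimental evidence, then the sliding method, then more identities.
    The survivor's ``n_merged`` accumulates the merged records."""
    groups: dict[tuple, list[PtmSnpHit]] = {}
    order: list[tuple] = []
    for h in hits:
        key = h.dedup_key
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(h)
    out: list[PtmSnpHit] = []
    for key in order:
        group = groups[key]
        best = min(
            group,
            key=lambda h: (_EVIDENCE_RANK[h.evidence], _METHOD_RANK[h.method], -h.identities),
        )
        n = sum(h.n_merged for h in group)
        out.append(best if n == best.n_merged else dataclasses.replace(best, n_merged=n))
    return out


def site_coverage_from_counts(
    rows: Iterable[tuple[str, int, int]], total_label: str = "Total"
) -> pd.DataFrame:
    """Coverage table from (label, n_sites, n_sites_with_hit) triples, with a
    Total row aggregating all classes; ratios rounded to 3 decimals."""
    recs = [
        {"ptm_type": label, "n_sites": n, "n_sites_hit": c, "ratio": coverage_ratio(c, n)}
        for label, n, c in rows
    ]
    recs.sort(key=lambda r: (-r["ratio"], r["ptm_type"]))
    total_n = sum(r["n_sites"] for r in recs)
    total_c = sum(r["n_sites_hit"] for r in recs)
    recs.append(
        {
            "ptm_type": total_label,
            "n_sites": total_n,
            "n_sites_hit": total_c,
            "ratio": coverage_ratio(total_c, total_n),
        }
    )
    return pd.DataFrame(recs, columns=["ptm_type", "n_sites", "n_sites_hit", "ratio"])


def site_coverage(ptms: Iterable[PtmSite], hits: Iterable[PtmSnpHit]) -> pd.DataFrame:
    """Per-PTM-type site coverage: a site counts as covered when at least one
    distinct hit references it."""
    hit_keys = {(h.ptm_protein_ac, h.ptm_position, h.ptm_type) for h in hits}
    totals: dict[str, set] = {}
    covered: dict[str, set] = {}
    for ptm in ptms:
        totals.setdefault(ptm.ptm_type, set()).add(ptm.site_key)
        if ptm.site_key in hit_keys:
            covered.setdefault(ptm.ptm_type, set()).add(ptm.site_key)
    rows = [
        (ptm_type, len(sites), len(covered.get(ptm_type, ())))
        for ptm_type, sites in sorted(totals.items())
    ]
    return site_coverage_from_counts(rows)
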