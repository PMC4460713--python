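"""Join detected PTM-SNPs with disease-SNP catalogs and summarize per trait.

rsIDs are normalized (optional ``rs`` prefix stripped, compared numerically
when possible) before joining; trait terms are compared case-insensitively
after whitespace normalization, with no ontology mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .detection import PtmSnpHit
from .io_formats import DiseaseSnp, coverage_ratio


def normalize_rsid(rs_id: str) -> str:
    """Canonical form of an rsID: digits only when the ID is numeric under an
    optional 'rs' prefix, else the lower-cased string."""
    s = str(rs_id).strip().lower()
    if s.startswith("rs"):
        s = s[2:]
    if s.isdigit():
        return str(int(s))
    return s


def normalize_trait(trait: str) -> str:
    return " ".join(trait.split()).lower()


@dataclass(frozen=True)
class DiseasePtmSnp:
    """A PTM-SNP hit joined with one trait association from the catalogs."""

    hit: PtmSnpHit
    trait: str
    p_value: float | None
    source: str


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    n_disease_snps: int
    n_ptm_snps: int
    ratio: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_ptm_snps <= self.n_disease_snps:
            raise ValueError("require 0 <= n_ptm_snps <= n_disease_snps")


def match_disease(
    hits: Iterable[PtmSnpHit], catalog: Iterable[DiseaseSnp]
) -> list[DiseasePtmSnp]:
    """Equi-join on normalized rsID: one row per (distinct hit key, trait).

    When the same (rsID, trait) pair occurs in several catalog sources, the
    record with the smallest p-value (unscored last) represents the trait.
    """
    best: dict[tuple[str, str], DiseaseSnp] = {}
    for entry in catalog:
        key = (normalize_rsid(entry.rs_id), normalize_trait(entry.trait))
        prev = best.get(key)
        if prev is None:
            best[key] = entry
            continue
        prev_p = float("inf") if prev.p_value is None else prev.p_value
        cur_p = float("inf") if entry.p_value is None else entry.p_value
        if cur_p < prev_p:
            best[key] = entry

    by_rsid: dict[str, list[tuple[str, DiseaseSnp]]] = {}
    for (rsid, trait), entry in best.items():
        by_rsid.setdefault(rsid, []).append((trait, entry))

    out: list[DiseasePtmSnp] = []
    seen_hit_keys: set[tuple] = set()
    for hit in hits:
        if hit.dedup_key in seen_hit_keys:
            continue
        seen_hit_keys.add(hit.dedup_key)
        for trait, entry in sorted(
            by_rsid.get(normalize_rsid(hit.rs_id), ()), key=lambda t: t[0]
        ):
            out.append(DiseasePtmSnp(hit, entry.trait, entry.p_value, entry.source))
    return out


def trait_summary(
    catalog: Iterable[DiseaseSnp], hits: Iterable[PtmSnpHit]
) -> list[TraitSummary]:
    """Per-trait counts: distinct catalog rsIDs and how many are PTM-SNPs;
    ratio rounded to 3 decimals, sorted by ratio descending."""
    hit_rsids = {normalize_rsid(h.rs_id) for h in hits}
    per_trait: dict[str, dict] = {}
    for entry in catalog:
        t = normalize_trait(entry.trait)
        info = per_trait.setdefault(t, {"display": entry.trait, "rsids": set()})
        info["rsids"].add(normalize_rsid(entry.rs_id))
    rows = []
    for info in per_trait.values():
        n = len(info["rsids"])
        k = len(info["rsids"] & hit_rsids)
        rows.append(TraitSummary(info["display"], n, k, coverage_ratio(k, n)))
    rows.sort(key=lambda r: (-r.ratio, -r.n_disease_snps, r.trait.lower()))
    return rows


def trait_summary_from_counts(rows: Iterable[tuple[str, int, int]]) -> list[TraitSummary]:
    """Trait summaries from (trait, n_disease_snps, n_ptm_snps) triples."""
    out = [TraitSummary(t, n, k, coverage_ratio(k, n)) for t, n, k in rows]
    out.sort(key=lambda r: (-r.ratio, -r.n_disease_snps, r.trait.lower()))
    return out


def select_significant(
    catalog: Iterable[DiseaseSnp],
    threshold: float = 1e-5,
    keep_unscored: bool = False,
) -> list[DiseaseSnp]:
    """Keep catalog rows with p-value strictly below ``threshold``; rows
    without a p-value survive only with ``keep_unscored``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    out = []
    for entry in catalog:
        if entry.p_value is None:
            if keep_unscored:
                out.append(entry)
        elif entry.p_value < threshold:
            out.append(entry)
    return out
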