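"""Coverage ratios and one-sided Fisher's exact enrichment tests.

The test asks whether a class of SNPs (a functional class, a PTM type, any
user-defined partition) carries more disease-associated SNPs than expected
under hypergeometric sampling from the full SNP universe: the p-value is the
upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).  Tail sums are
accumulated in log space with log-gamma terms, so extreme tails (p ~ 1e-67
for the PTM-SNP class) are computed without underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

from .detection import PtmSnpHit


@dataclass(frozen=True)
class EnrichmentRow:
    """One class-vs-rest contingency comparison."""

    label: str
    n_class: int
    k_class: int
    n_total: int
    k_total: int
    coverage: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.k_class <= self.n_class <= self.n_total:
            raise ValueError(f"{self.label}: require k_class <= n_class <= n_total")
        if not self.k_class <= self.k_total <= self.n_total:
            raise ValueError(f"{self.label}: require k_class <= k_total <= n_total")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, sample n).

    Equivalent to the one-sided ("greater") Fisher exact test on the 2x2
    table (class vs rest) x (disease-associated vs not).  Computed as a
    log-space sum of log-gamma point masses; equals 1 when k == 0.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if N < 1 or n < 0 or K < 0 or n > N or K > N:
        raise ValueError(f"invalid population arguments n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1, dtype=np.float64)
    log_pmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, math.exp(logsumexp(log_pmf))))


def enrich_partition(
    rows: Iterable[tuple[str, int, int]], n_total: int, k_total: int
) -> list[EnrichmentRow]:
    """Enrichment rows from (label, n_class, k_class) triples against the
    population totals (classes may overlap and need not exhaust the
    population).  Sorted by p-value ascending."""
    out = []
    for label, n_class, k_class in rows:
        out.append(
            EnrichmentRow(
                label=label,
                n_class=n_class,
                k_class=k_class,
                n_total=n_total,
                k_total=k_total,
                coverage=k_class / n_class if n_class else 0.0,
                p_value=hypergeom_upper_tail(k_class, n_class, k_total, n_total),
            )
        )
    out.sort(key=lambda r: (r.p_value, r.label))
    return out


def enrich_ptm_types(
    hits: Iterable[PtmSnpHit], disease_hits: Iterable
) -> list[EnrichmentRow]:
    """Per-PTM-type enrichment of disease association among PTM-SNPs.

    The population is the distinct PTM-SNP rsIDs; successes are the distinct
    disease-associated ones.  ``disease_hits`` are the joined records from
    :func:`ptmsnp.association.match_disease`.
    """
    from .association import normalize_rsid

    all_rsids: set[str] = set()
    by_type: dict[str, set[str]] = {}
    for h in hits:
        rsid = normalize_rsid(h.rs_id)
        all_rsids.add(rsid)
        by_type.setdefault(h.ptm_type, set()).add(rsid)
    disease_rsids = {normalize_rsid(d.hit.rs_id) for d in disease_hits}
    disease_rsids &= all_rsids
    rows = [
        (ptm_type, len(rsids), len(rsids & disease_rsids))
        for ptm_type, rsids in sorted(by_type.items())
    ]
    return enrich_partition(rows, len(all_rsids), len(disease_rsids))


def fold_enrichment(row: EnrichmentRow, comparator: EnrichmentRow) -> float | None:
    """Ratio of the row's coverage to the comparator's; None (undefined) when
    the comparator coverage is zero."""
    if comparator.coverage == 0:
        return None
    return row.coverage / comparator.coverage
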