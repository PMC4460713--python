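"""Case/control association stage: QC filters, exact Hardy-Weinberg test,
Cochran-Armitage trend test, and significance selection.

The stage mirrors a standard SNP-array workflow: samples with a missing
genotype rate above 3% are dropped first, then SNPs with a missing rate
above 1%, SNPs out of Hardy-Weinberg equilibrium in controls (exact test,
p <= 1e-4), and SNPs with pooled minor allele frequency below 1%.  Surviving
SNPs are tested with the 1-df Cochran-Armitage trend test and those below
the significance threshold (default 1e-5) are emitted as a disease-SNP
catalog.  Linkage-disequilibrium pruning is intentionally absent so that
PTM-SNP candidates are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .io_formats import GENOTYPE_COUNT_COLUMNS, DiseaseSnp


@dataclass(frozen=True)
class QcThresholds:
    """QC cutoffs.  Removal semantics: missing rates strictly above the
    threshold, HWE p-value at or below, MAF strictly below."""

    sample_missing_max: float = 0.03
    snp_missing_max: float = 0.01
    hwe_p_min: float = 1e-4
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("sample_missing_max", "snp_missing_max", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class GenotypePanel:
    """Per-SNP case/control genotype data.

    Two representations: sample mode carries genotype matrices
    (samples x SNPs, values 0/1/2 copies of the counted allele, -1 missing),
    from which counts are derived; aggregate mode carries only the per-SNP
    count table (columns r0..r2 cases, s0..s2 controls, miss_case,
    miss_ctrl).  Sample-level QC needs sample mode.
    """

    rs_ids: list[str]
    case_geno: np.ndarray | None = None
    ctrl_geno: np.ndarray | None = None
    count_table: pd.DataFrame | None = None

    @property
    def sample_mode(self) -> bool:
        return self.case_geno is not None and self.ctrl_geno is not None

    @property
    def n_snps(self) -> int:
        return len(self.rs_ids)

    def counts(self) -> pd.DataFrame:
        if self.sample_mode:
            rows = []
            for j, rs in enumerate(self.rs_ids):
                ca = self.case_geno[:, j]
                co = self.ctrl_geno[:, j]
                rows.append(
                    {
                        "rs_id": rs,
                        "r0": int((ca == 0).sum()),
                        "r1": int((ca == 1).sum()),
                        "r2": int((ca == 2).sum()),
                        "s0": int((co == 0).sum()),
                        "s1": int((co == 1).sum()),
                        "s2": int((co == 2).sum()),
                        "miss_case": int((ca < 0).sum()),
                        "miss_ctrl": int((co < 0).sum()),
                    }
                )
            return pd.DataFrame(rows, columns=GENOTYPE_COUNT_COLUMNS)
        if self.count_table is None:
            raise ValueError("empty panel")
        return self.count_table.reset_index(drop=True)

    @classmethod
    def from_counts(cls, table: pd.DataFrame) -> "GenotypePanel":
        return cls(rs_ids=list(table["rs_id"]), count_table=table.reset_index(drop=True))

    def drop_snps(self, keep_mask: np.ndarray) -> "GenotypePanel":
        keep_idx = np.flatnonzero(keep_mask)
        rs = [self.rs_ids[i] for i in keep_idx]
        if self.sample_mode:
            return GenotypePanel(rs, self.case_geno[:, keep_idx], self.ctrl_geno[:, keep_idx])
        return GenotypePanel(rs, count_table=self.count_table.iloc[keep_idx].reset_index(drop=True))

    def drop_samples(self, keep_case: np.ndarray, keep_ctrl: np.ndarray) -> "GenotypePanel":
        if not self.sample_mode:
            raise ValueError("sample-level filtering needs sample-mode data")
        return GenotypePanel(list(self.rs_ids), self.case_geno[keep_case], self.ctrl_geno[keep_ctrl])


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count.  Log-factorial arithmetic; symmetric in the two
    homozygote labels.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype counts")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele count
    # heterozygote counts sharing the allele totals have n_minor's parity
    hets = np.arange(n_minor % 2, n_minor + 1, 2, dtype=np.float64)
    hom_minor = (n_minor - hets) / 2
    hom_major = n - hets - hom_minor
    log_w = (
        hets * math.log(2)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    log_total = logsumexp(log_w)
    log_p = log_w - log_total
    obs_idx = int((n_Aa - (n_minor % 2)) // 2)
    # include configurations as extreme as observed; the relative tolerance
    # guards against log-space rounding of mathematically equal masses
    sel = log_p <= log_p[obs_idx] + 1e-12
    return float(min(1.0, math.exp(logsumexp(log_p[sel]))))


@dataclass(frozen=True)
class CattResult:
    chi2: float
    p: float
    degenerate: bool = False


def catt(
    r0: int, r1: int, r2: int, s0: int, s1: int, s2: int,
    weights: tuple[float, float, float] = (0.0, 1.0, 2.0),
) -> CattResult:
    """Cochran-Armitage trend test on a 2x3 case/control genotype table.

    chi2 = N [N sum(w_i r_i) - R sum(w_i n_i)]^2
           / (R (N-R) [N sum(w_i^2 n_i) - (sum(w_i n_i))^2])

    with R cases, S controls, N = R + S, n_i = r_i + s_i.  A degenerate
    variance (all samples in one genotype) reports chi2 = 0, p = 1 with the
    degenerate flag set.
    """
    r = np.array([r0, r1, r2], dtype=np.float64)
    s = np.array([s0, s1, s2], dtype=np.float64)
    if r.min() < 0 or s.min() < 0:
        raise ValueError("counts must be non-negative")
    R, S = r.sum(), s.sum()
    if R == 0 or S == 0:
        raise ValueError("need at least one case and one control")
    N = R + S
    n = r + s
    w = np.asarray(weights, dtype=np.float64)
    num = N * (w @ r) - R * (w @ n)
    var_term = N * ((w**2) @ n) - (w @ n) ** 2
    denom = R * (N - R) * var_term
    if denom <= 0:
        return CattResult(0.0, 1.0, degenerate=True)
    stat = N * num**2 / denom
    return CattResult(float(stat), float(chi2.sf(stat, df=1)), degenerate=False)


def _maf_from_counts(row) -> float:
    n_called = row.r0 + row.r1 + row.r2 + row.s0 + row.s1 + row.s2
    if n_called == 0:
        return 0.0
    alt = row.r1 + row.s1 + 2 * (row.r2 + row.s2)
    freq = alt / (2 * n_called)
    return min(freq, 1 - freq)


def qc_filter(
    panel: GenotypePanel, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypePanel, dict[str, int]]:
    """Apply the QC cascade; returns the filtered panel and per-stage removal
    counts.

    Stages, in order: (1) drop samples with missing rate > sample_missing_max
    (sample mode only), (2) recompute counts, (3) drop SNPs with missing rate
    > snp_missing_max, (4) drop SNPs with control-only HWE exact p <=
    hwe_p_min, (5) drop SNPs with pooled MAF < maf_min.
    """
    removed = {"samples": 0, "snp_missing": 0, "hwe": 0, "maf": 0}

    if panel.sample_mode:
        miss_case = (panel.case_geno < 0).mean(axis=1)
        miss_ctrl = (panel.ctrl_geno < 0).mean(axis=1)
        keep_case = miss_case <= thresholds.sample_missing_max
        keep_ctrl = miss_ctrl <= thresholds.sample_missing_max
        removed["samples"] = int((~keep_case).sum() + (~keep_ctrl).sum())
        panel = panel.drop_samples(keep_case, keep_ctrl)

    counts = panel.counts()
    n_samples = (
        counts[["r0", "r1", "r2", "s0", "s1", "s2", "miss_case", "miss_ctrl"]]
        .sum(axis=1)
        .to_numpy(dtype=float)
    )
    miss = (counts["miss_case"] + counts["miss_ctrl"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        miss_rate = np.where(n_samples > 0, miss / n_samples, 1.0)
    keep = miss_rate <= thresholds.snp_missing_max
    removed["snp_missing"] = int((~keep).sum())
    panel = panel.drop_snps(keep)
    counts = counts[keep].reset_index(drop=True)

    hwe_p = np.array(
        [
            hwe_exact_p(int(row.s0), int(row.s1), int(row.s2))
            if (row.s0 + row.s1 + row.s2) > 0
            else 1.0
            for row in counts.itertuples(index=False)
        ]
    )
    keep = hwe_p > thresholds.hwe_p_min
    removed["hwe"] = int((~keep).sum())
    panel = panel.drop_snps(keep)
    counts = counts[keep].reset_index(drop=True)

    maf = np.array([_maf_from_counts(row) for row in counts.itertuples(index=False)])
    keep = maf >= thresholds.maf_min
    removed["maf"] = int((~keep).sum())
    panel = panel.drop_snps(keep)

    return panel, removed


def run_association(
    panel: GenotypePanel,
    alpha: float = 1e-5,
    trait: str = "study trait",
    source: str = "user",
) -> list[DiseaseSnp]:
    """Trend-test every SNP and emit those with p < alpha as catalog rows."""
    out: list[DiseaseSnp] = []
    for row in panel.counts().itertuples(index=False):
        res = catt(row.r0, row.r1, row.r2, row.s0, row.s1, row.s2)
        if res.p < alpha or alpha >= 1.0:
            out.append(DiseaseSnp(row.rs_id, trait, max(res.p, 1e-300), source))
    return out


def trend_p_values(panel: GenotypePanel) -> pd.DataFrame:
    """Per-SNP trend-test results as a table (rs_id, chi2, p, degenerate)."""
    rows = []
    for row in panel.counts().itertuples(index=False):
        res = catt(row.r0, row.r1, row.r2, row.s0, row.s1, row.s2)
        rows.append({"rs_id": row.rs_id, "chi2": res.chi2, "p": res.p, "degenerate": res.degenerate})
    return pd.DataFrame(rows, columns=["rs_id", "chi2", "p", "degenerate"])
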