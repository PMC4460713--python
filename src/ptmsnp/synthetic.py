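"""Seed-reproducible synthetic inputs with known ground truth.

The generator emulates the statistical structure of the real pipeline
inputs: two protein databases whose sequences disagree in controlled ways
(point substitutions inside PTM windows, N-terminal coordinate shifts,
tandem-repeat insertions), planted PTM sites and nsSNPs at known offsets,
a disease-SNP catalog with a planted enrichment effect at the SNP level,
and case/control genotype panels drawn from Hardy-Weinberg proportions with
additive allelic odds ratios.

Every output is a pure function of :class:`SimConfig`; each stage derives
its own random stream from the seed so stages can be rerun independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_stats import GenotypePanel
from .io_formats import DiseaseSnp, ProteinRecord, PtmSite, SnpRecord, extract_window

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PTM_VOCABULARY = [
    ("Phosphorylation", 0.55),
    ("Ubiquitination", 0.15),
    ("N-linked Glycosylation", 0.10),
    ("Acetylation", 0.08),
    ("O-linked Glycosylation", 0.06),
    ("Methylation", 0.03),
    ("Disulfide bond", 0.03),
]

TRAIT_VOCABULARY = [
    "Diabetes Mellitus, Type 2",
    "Coronary heart disease",
    "Stroke",
    "Macular Degeneration",
    "Lupus Erythematosus, Systemic",
    "Cholesterol, LDL",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Cross-database sequence discrepancy model.

    ``substitution_rate`` is the probability that a planted PTM window
    receives one point substitution in the PTM-database copy;
    ``coordinate_shift_max`` bounds the random N-terminal extension of the
    PTM-database sequence; tandem-repeat insertions (probability per
    protein, unit length) create the repeat ambiguities that exercise the
    global-alignment fallback.
    """

    substitution_rate: float = 0.0
    coordinate_shift_max: int = 0
    repeat_insertion_prob: float = 0.0
    repeat_unit_len: int = 5


@dataclass(frozen=True)
class DiseaseConfig:
    background_rate: float = 2e-4
    ptm_snp_odds_ratio: float = 4.4


@dataclass(frozen=True)
class GwasConfig:
    n_case: int = 2000
    n_ctrl: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_proteins: int = 1000
    protein_length: tuple[int, int] = (100, 400)
    n_ptm_sites: int = 2000
    n_snps: int = 5000
    frac_far: float = 0.2
    frac_stopgain: float = 0.03
    offset_weights: Sequence[float] | None = None  # over offsets -flank..+flank
    flank: int = 7
    far_min_distance: int = 18  # > flank + band slack (7 + 10)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    disease: DiseaseConfig = field(default_factory=DiseaseConfig)
    gwas: GwasConfig = field(default_factory=GwasConfig)


@dataclass(frozen=True)
class PtmCopyInfo:
    """How one protein's PTM-database copy was derived from the SNP-database
    sequence."""

    shift: int
    insertion_pos: int | None  # snp-db coordinate after which a unit repeats
    unit_len: int

    def map_position(self, q: int) -> int:
        """snp-db coordinate -> ptm-db coordinate."""
        p = q + self.shift
        if self.insertion_pos is not None and q > self.insertion_pos:
            p += self.unit_len
        return p


@dataclass
class SimProteome:
    snp_proteins: list[ProteinRecord]
    ptm_proteins: list[ProteinRecord]
    id_map: list[tuple[str, str]]
    copy_info: dict[str, PtmCopyInfo]  # keyed by snp-db accession


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def gen_proteome(config: SimConfig) -> SimProteome:
    """Generate the SNP-database proteome and its perturbed PTM-database copy."""
    rng = _stage_rng(config, 0)
    lo, hi = config.protein_length
    noise = config.noise
    snp_proteins: list[ProteinRecord] = []
    ptm_proteins: list[ProteinRecord] = []
    id_map: list[tuple[str, str]] = []
    copy_info: dict[str, PtmCopyInfo] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_peptide(rng, length)
        snp_ac = f"SNPP{i:05d}"
        ptm_ac = f"PTMP{i:05d}"
        shift = int(rng.integers(0, noise.coordinate_shift_max + 1)) if noise.coordinate_shift_max else 0
        ins_pos: int | None = None
        unit_len = noise.repeat_unit_len
        ptm_seq = seq
        if noise.repeat_insertion_prob and rng.random() < noise.repeat_insertion_prob:
            if length > 2 * unit_len:
                ins_pos = int(rng.integers(unit_len, length))
                ptm_seq = ptm_seq[:ins_pos] + ptm_seq[ins_pos - unit_len : ins_pos] + ptm_seq[ins_pos:]
        if shift:
            ptm_seq = _random_peptide(rng, shift) + ptm_seq
        snp_proteins.append(ProteinRecord(snp_ac, "snp_db", seq))
        ptm_proteins.append(ProteinRecord(ptm_ac, "ptm_db", ptm_seq))
        id_map.append((snp_ac, ptm_ac))
        copy_info[snp_ac] = PtmCopyInfo(shift, ins_pos, unit_len if ins_pos is not None else 0)
    return SimProteome(snp_proteins, ptm_proteins, id_map, copy_info)


GROUND_TRUTH_COLUMNS = [
    "rs_id",
    "is_ptm_snp",
    "true_offset",
    "ptm_protein_ac",
    "ptm_position",
    "ptm_type",
]


@dataclass
class SyntheticAnnotations:
    snps: list[SnpRecord]
    ptms: list[PtmSite]
    ground_truth: pd.DataFrame
    proteome: SimProteome  # PTM sequences may carry planted window noise


def plant_annotations(config: SimConfig, proteome: SimProteome) -> SyntheticAnnotations:
    """Place PTM sites and nsSNPs with known offsets.

    PTM sites go to interior positions (so default-config windows are
    pad-free); each planted SNP draws an offset in [-flank, +flank] from the
    configured distribution, "far" SNPs are placed more than
    ``far_min_distance`` residues from every site on their protein.
    """
    rng = _stage_rng(config, 1)
    flank = config.flank
    snp_by_ac = {p.accession: p for p in proteome.snp_proteins}
    ptm_ac_of = dict(proteome.id_map)
    ptm_seq_work = {p.accession: list(p.sequence) for p in proteome.ptm_proteins}

    type_names = [t for t, _ in PTM_VOCABULARY]
    type_probs = np.array([w for _, w in PTM_VOCABULARY])
    type_probs = type_probs / type_probs.sum()

    eligible = [p.accession for p in proteome.snp_proteins if len(p) >= 2 * flank + 2]
    if not eligible:
        raise ValueError("no proteins long enough to host PTM windows")

    # --- PTM sites ---------------------------------------------------------
    sites: list[dict] = []
    taken: set[tuple[str, int]] = set()
    attempts = 0
    while len(sites) < config.n_ptm_sites:
        attempts += 1
        if attempts > 50 * config.n_ptm_sites:
            raise ValueError("requested PTM sites exceed available positions")
        ac = eligible[int(rng.integers(len(eligible)))]
        seq = snp_by_ac[ac].sequence
        q = int(rng.integers(flank + 1, len(seq) - flank + 1))  # snp-db coords
        info = proteome.copy_info[ac]
        ptm_ac = ptm_ac_of[ac]
        ptm_pos = info.map_position(q)
        if (ptm_ac, ptm_pos) in taken:
            continue
        taken.add((ptm_ac, ptm_pos))
        ptm_type = type_names[int(rng.choice(len(type_names), p=type_probs))]
        evidence = "experimental" if rng.random() < 0.5 else "predicted"
        sites.append(
            {"snp_ac": ac, "q": q, "ptm_ac": ptm_ac, "ptm_pos": ptm_pos,
             "ptm_type": ptm_type, "evidence": evidence}
        )

    # window-noise pass: at most one substitution per planted window, so a
    # mutation column may not fall inside any *other* site's window
    if config.noise.substitution_rate:
        from collections import Counter

        col_claims: dict[str, Counter] = {}
        for s in sites:
            claims = col_claims.setdefault(s["ptm_ac"], Counter())
            claims.update(range(s["ptm_pos"] - flank, s["ptm_pos"] + flank + 1))
        for s in sites:
            if rng.random() >= config.noise.substitution_rate:
                continue
            work = ptm_seq_work[s["ptm_ac"]]
            claims = col_claims[s["ptm_ac"]]
            free = [
                c
                for c in range(s["ptm_pos"] - flank, s["ptm_pos"] + flank + 1)
                if 1 <= c <= len(work) and claims[c] == 1
            ]
            if not free:
                continue
            mut_pos = free[int(rng.integers(len(free)))]
            old = work[mut_pos - 1]
            choices = [a for a in AMINO_ACIDS if a != old]
            work[mut_pos - 1] = choices[int(rng.integers(len(choices)))]

    ptm_proteins = [
        ProteinRecord(p.accession, "ptm_db", "".join(ptm_seq_work[p.accession]))
        for p in proteome.ptm_proteins
    ]
    ptm_by_ac = {p.accession: p for p in ptm_proteins}
    proteome = dataclasses.replace(proteome, ptm_proteins=ptm_proteins)

    ptms = [
        PtmSite(
            protein_ac=s["ptm_ac"],
            position=s["ptm_pos"],
            residue=ptm_by_ac[s["ptm_ac"]].sequence[s["ptm_pos"] - 1],
            ptm_type=s["ptm_type"],
            evidence=s["evidence"],
            ptm_window=extract_window(ptm_by_ac[s["ptm_ac"]].sequence, s["ptm_pos"], flank),
        )
        for s in sites
    ]

    # --- SNPs --------------------------------------------------------------
    sites_by_protein: dict[str, list[int]] = {}
    for s in sites:
        sites_by_protein.setdefault(s["snp_ac"], []).append(s["q"])

    if config.offset_weights is None:
        offsets = np.arange(-flank, flank + 1)
        offset_probs = np.full(len(offsets), 1 / len(offsets))
    else:
        offsets = np.arange(-flank, flank + 1)
        offset_probs = np.asarray(config.offset_weights, dtype=float)
        if len(offset_probs) != len(offsets):
            raise ValueError("offset_weights must cover -flank..+flank")
        offset_probs = offset_probs / offset_probs.sum()

    n_far = int(round(config.frac_far * config.n_snps))
    n_planted = config.n_snps - n_far
    snps: list[SnpRecord] = []
    truth_rows: list[dict] = []

    for i in range(n_planted):
        site = sites[int(rng.integers(len(sites)))]
        k = int(offsets[int(rng.choice(len(offsets), p=offset_probs))])
        ac = site["snp_ac"]
        seq = snp_by_ac[ac].sequence
        pos = site["q"] + k
        ref = seq[pos - 1]
        rs_id = f"rs{i + 1}"
        if rng.random() < config.frac_stopgain:
            alt, snp_class = "*", "stopgain"
        else:
            choices = [a for a in AMINO_ACIDS if a != ref]
            alt, snp_class = choices[int(rng.integers(len(choices)))], "missense"
        snps.append(
            SnpRecord(rs_id, ac, pos, ref, alt, snp_class,
                      snp_window=extract_window(seq, pos, flank))
        )
        truth_rows.append(
            {"rs_id": rs_id, "is_ptm_snp": True, "true_offset": k,
             "ptm_protein_ac": site["ptm_ac"], "ptm_position": site["ptm_pos"],
             "ptm_type": site["ptm_type"]}
        )

    for i in range(n_far):
        rs_id = f"rs{n_planted + i + 1}"
        for _ in range(200):
            ac = eligible[int(rng.integers(len(eligible)))]
            seq = snp_by_ac[ac].sequence
            pos = int(rng.integers(flank + 1, len(seq) - flank + 1))
            site_qs = sites_by_protein.get(ac, ())
            if all(abs(pos - q) > config.far_min_distance for q in site_qs):
                break
        else:
            raise ValueError("could not place a 'far' SNP; too many sites per protein")
        ref = seq[pos - 1]
        choices = [a for a in AMINO_ACIDS if a != ref]
        alt = choices[int(rng.integers(len(choices)))]
        snps.append(
            SnpRecord(rs_id, ac, pos, ref, alt, "missense",
                      snp_window=extract_window(seq, pos, flank))
        )
        truth_rows.append(
            {"rs_id": rs_id, "is_ptm_snp": False, "true_offset": pd.NA,
             "ptm_protein_ac": "", "ptm_position": 0, "ptm_type": ""}
        )

    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return SyntheticAnnotations(snps, ptms, truth, proteome)


def draw_disease_status(
    rng: np.random.Generator, is_ptm_snp: np.ndarray, disease: DiseaseConfig
) -> np.ndarray:
    """Bernoulli disease status per SNP: background rate for ordinary SNPs,
    the rate implied by the configured odds ratio for PTM-SNPs."""
    p0 = disease.background_rate
    odds1 = disease.ptm_snp_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    probs = np.where(np.asarray(is_ptm_snp, dtype=bool), p1, p0)
    return rng.random(len(probs)) < probs


def gen_disease_catalog(
    config: SimConfig, ground_truth: pd.DataFrame
) -> tuple[list[DiseaseSnp], np.ndarray]:
    """Draw the disease catalog; returns (catalog, per-SNP disease status
    aligned with the ground-truth row order)."""
    rng = _stage_rng(config, 2)
    status = draw_disease_status(rng, ground_truth["is_ptm_snp"].to_numpy(dtype=bool),
                                 config.disease)
    catalog: list[DiseaseSnp] = []
    sources = ["nhgri", "gad", "dbgap"]
    for rs_id, diseased in zip(ground_truth["rs_id"], status):
        if not diseased:
            continue
        trait = TRAIT_VOCABULARY[int(rng.integers(len(TRAIT_VOCABULARY)))]
        p = float(10.0 ** rng.uniform(-12, -5))
        source = sources[int(rng.integers(len(sources)))]
        catalog.append(DiseaseSnp(rs_id, trait, p, source))
    return catalog, status


def genotype_probs(maf: float, odds_ratio: float) -> tuple[np.ndarray, np.ndarray]:
    """(control, case) genotype probabilities for 0/1/2 copies of the minor
    allele: controls at Hardy-Weinberg proportions, cases tilted by the
    additive allelic odds ratio."""
    hwe = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    case = hwe * odds_ratio ** np.arange(3)
    return hwe, case / case.sum()


def gen_genotype_panel(
    config: SimConfig,
    rs_ids: Sequence[str],
    odds_ratios: Sequence[float] | None = None,
    mafs: Sequence[float] | None = None,
    sample_mode: bool = False,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Case/control genotype panel; returns (panel, per-SNP truth table with
    the MAF and odds ratio used)."""
    rng = _stage_rng(config, 3)
    g = config.gwas
    n_snps = len(rs_ids)
    if odds_ratios is None:
        odds_ratios = np.ones(n_snps)
    if mafs is None:
        mafs = rng.uniform(g.maf_range[0], g.maf_range[1], size=n_snps)
    rows = []
    case_cols = []
    ctrl_cols = []
    for j, rs in enumerate(rs_ids):
        ctrl_p, case_p = genotype_probs(float(mafs[j]), float(odds_ratios[j]))
        if sample_mode:
            ca = rng.choice(3, size=g.n_case, p=case_p).astype(np.int8)
            co = rng.choice(3, size=g.n_ctrl, p=ctrl_p).astype(np.int8)
            if g.missing_rate:
                ca[rng.random(g.n_case) < g.missing_rate] = -1
                co[rng.random(g.n_ctrl) < g.missing_rate] = -1
            case_cols.append(ca)
            ctrl_cols.append(co)
        else:
            miss_case = int(rng.binomial(g.n_case, g.missing_rate)) if g.missing_rate else 0
            miss_ctrl = int(rng.binomial(g.n_ctrl, g.missing_rate)) if g.missing_rate else 0
            r = rng.multinomial(g.n_case - miss_case, case_p)
            s = rng.multinomial(g.n_ctrl - miss_ctrl, ctrl_p)
            rows.append(
                {"rs_id": rs, "r0": int(r[0]), "r1": int(r[1]), "r2": int(r[2]),
                 "s0": int(s[0]), "s1": int(s[1]), "s2": int(s[2]),
                 "miss_case": miss_case, "miss_ctrl": miss_ctrl}
            )
    truth = pd.DataFrame(
        {"rs_id": list(rs_ids), "maf": np.asarray(mafs, dtype=float),
         "odds_ratio": np.asarray(odds_ratios, dtype=float)}
    )
    if sample_mode:
        panel = GenotypePanel(
            list(rs_ids),
            np.column_stack(case_cols) if case_cols else np.empty((g.n_case, 0), np.int8),
            np.column_stack(ctrl_cols) if ctrl_cols else np.empty((g.n_ctrl, 0), np.int8),
        )
    else:
        panel = GenotypePanel.from_counts(pd.DataFrame(rows))
    return panel, truth


def plant_qc_violation_panel(
    n_clean: int = 100,
    n_bad_sample: int = 6,
    n_bad_snp_missing: int = 5,
    n_bad_hwe: int = 4,
    n_bad_maf: int = 3,
    n_case: int = 400,
    n_ctrl: int = 400,
) -> tuple[GenotypePanel, dict[str, int]]:
    """Deterministic sample-mode panel with planted violations of each QC
    threshold; returns (panel, expected per-stage removal counts).

    Clean SNPs sit at exact Hardy-Weinberg integer counts (MAF 0.25) with no
    missingness.  Bad samples (placed among cases, genotype 0 where called)
    miss 10% of SNPs; bad-missing SNPs miss 5% of the *good* samples so the
    violation survives sample removal; bad-HWE SNPs have controls split
    between the two homozygotes with no heterozygotes; bad-MAF SNPs carry a
    minor-allele frequency of 0.5%.
    """
    n_snps = n_clean + n_bad_snp_missing + n_bad_hwe + n_bad_maf
    case = np.zeros((n_case, n_snps), dtype=np.int8)
    ctrl = np.zeros((n_ctrl, n_snps), dtype=np.int8)

    def hwe_column(n: int) -> np.ndarray:
        # MAF 0.25 -> genotype fractions 9/16, 6/16, 1/16
        n2 = n // 16
        n1 = (6 * n) // 16
        col = np.zeros(n, dtype=np.int8)
        col[:n2] = 2
        col[n2 : n2 + n1] = 1
        return col

    j = 0
    for _ in range(n_clean):
        case[:, j] = hwe_column(n_case)
        ctrl[:, j] = hwe_column(n_ctrl)
        j += 1
    n_miss = int(0.05 * (n_case + n_ctrl))  # 5% of good samples, > 1%
    if n_bad_snp_missing * n_miss > n_ctrl:
        raise ValueError("too many bad-missing SNPs for the control pool")
    row_start = 0
    for _ in range(n_bad_snp_missing):
        case[:, j] = hwe_column(n_case)
        ctrl[:, j] = hwe_column(n_ctrl)
        # stagger missing calls across disjoint control rows so no single
        # good sample crosses the 3% sample-missing threshold
        ctrl[row_start : row_start + n_miss, j] = -1
        row_start += n_miss
        j += 1
    for _ in range(n_bad_hwe):
        case[:, j] = hwe_column(n_case)
        ctrl[: n_ctrl // 2, j] = 2  # homozygote split, zero heterozygotes
        ctrl[n_ctrl // 2 :, j] = 0
        j += 1
    for _ in range(n_bad_maf):
        # minor allele count = 1% of alleles / 2 -> MAF 0.5%
        n_het = max(1, (n_case + n_ctrl) // 100 // 2)
        ctrl[:n_het, j] = 1
        j += 1

    # bad samples: appended cases, genotype 0 where called, 10% missing
    bad_rows = np.zeros((n_bad_sample, n_snps), dtype=np.int8)
    n_miss_cols = max(int(0.10 * n_snps), int(0.04 * n_snps) + 1)
    bad_rows[:, :n_miss_cols] = -1
    case = np.vstack([case, bad_rows])

    rs_ids = [f"rs{j + 1}" for j in range(n_snps)]
    panel = GenotypePanel(rs_ids, case, ctrl)
    expected = {
        "samples": n_bad_sample,
        "snp_missing": n_bad_snp_missing,
        "hwe": n_bad_hwe,
        "maf": n_bad_maf,
    }
    return panel, expected


def detection_performance(ground_truth: pd.DataFrame, hits) -> dict[str, float]:
    """Recall and wrong-offset count of detection against the planted truth.

    A planted (SNP, site) pair is *recovered* when a hit exists for exactly
    that pair; a recovered pair whose offset differs from the planted offset
    counts as *wrong*.
    """
    hit_offsets = {
        (h.rs_id, h.ptm_protein_ac, h.ptm_position, h.ptm_type): h.offset for h in hits
    }
    planted = ground_truth[ground_truth["is_ptm_snp"].astype(bool)]
    n_recovered = n_wrong = 0
    for row in planted.itertuples(index=False):
        key = (row.rs_id, row.ptm_protein_ac, row.ptm_position, row.ptm_type)
        if key in hit_offsets:
            n_recovered += 1
            if hit_offsets[key] != row.true_offset:
                n_wrong += 1
    n_planted = len(planted)
    return {
        "n_planted": n_planted,
        "n_recovered": n_recovered,
        "n_wrong": n_wrong,
        "recall": n_recovered / n_planted if n_planted else float("nan"),
    }


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
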