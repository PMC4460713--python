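import numpy as np
import pytest

from ptmsnp.detection import ProteinIndex, detect
from ptmsnp.synthetic import (
    DiseaseConfig,
    NoiseConfig,
    SimConfig,
    detection_performance,
    draw_disease_status,
    gen_disease_catalog,
    gen_genotype_panel,
    gen_proteome,
    plant_annotations,
)
from ptmsnp.gwas_stats import qc_filter


def run_detection(ann):
    idx = ProteinIndex.from_records(ann.proteome.snp_proteins + ann.proteome.ptm_proteins)
    return detect(ann.snps, ann.ptms, ann.proteome.id_map, idx)


class TestGenProteome:
    def test_deterministic_per_seed(self):
        cfg = SimConfig(seed=3, n_proteins=20)
        a, b = gen_proteome(cfg), gen_proteome(cfg)
        assert a.snp_proteins == b.snp_proteins
        assert a.ptm_proteins == b.ptm_proteins
        assert a.id_map == b.id_map

    def test_different_seed_differs(self):
        a = gen_proteome(SimConfig(seed=3, n_proteins=20))
        b = gen_proteome(SimConfig(seed=4, n_proteins=20))
        assert a.snp_proteins != b.snp_proteins

    def test_zero_noise_copies_identical_up_to_tags(self):
        prot = gen_proteome(SimConfig(seed=3, n_proteins=20))
        for s, p in zip(prot.snp_proteins, prot.ptm_proteins):
            assert s.sequence == p.sequence
            assert s.db_tag == "snp_db" and p.db_tag == "ptm_db"

    def test_coordinate_shift_prepends_residues(self):
        cfg = SimConfig(seed=3, n_proteins=20,
                        noise=NoiseConfig(coordinate_shift_max=2))
        prot = gen_proteome(cfg)
        for s, p in zip(prot.snp_proteins, prot.ptm_proteins):
            shift = prot.copy_info[s.accession].shift
            assert 0 <= shift <= 2
            assert p.sequence[shift:] == s.sequence

    def test_repeat_insertion_lengthens_copy(self):
        cfg = SimConfig(seed=3, n_proteins=30,
                        noise=NoiseConfig(repeat_insertion_prob=1.0, repeat_unit_len=5))
        prot = gen_proteome(cfg)
        lengthened = [
            (s, p) for s, p in zip(prot.snp_proteins, prot.ptm_proteins)
            if prot.copy_info[s.accession].insertion_pos is not None
        ]
        assert lengthened
        for s, p in lengthened:
            assert len(p) == len(s) + 5


class TestPlantAnnotations:
    def test_residue_annotations_consistent(self):
        cfg = SimConfig(seed=9, n_proteins=20, n_ptm_sites=40, n_snps=100,
                        noise=NoiseConfig(substitution_rate=1.0))
        ann = plant_annotations(cfg, gen_proteome(cfg))
        ptm_by_ac = {p.accession: p for p in ann.proteome.ptm_proteins}
        snp_by_ac = {p.accession: p for p in ann.proteome.snp_proteins}
        for site in ann.ptms:
            assert ptm_by_ac[site.protein_ac].sequence[site.position - 1] == site.residue
        for snp in ann.snps:
            assert snp_by_ac[snp.protein_ac].sequence[snp.position - 1] == snp.ref_aa

    def test_point_mass_at_zero_yields_on_site_only(self):
        weights = [0.0] * 7 + [1.0] + [0.0] * 7
        cfg = SimConfig(seed=9, n_proteins=20, n_ptm_sites=40, n_snps=60,
                        frac_far=0.0, frac_stopgain=0.0, offset_weights=weights)
        ann = plant_annotations(cfg, gen_proteome(cfg))
        hits = run_detection(ann)
        by_key = {(h.rs_id, h.ptm_protein_ac, h.ptm_position, h.ptm_type): h for h in hits}
        planted = ann.ground_truth[ann.ground_truth.is_ptm_snp.astype(bool)]
        assert len(planted)
        for row in planted.itertuples(index=False):
            hit = by_key[(row.rs_id, row.ptm_protein_ac, row.ptm_position, row.ptm_type)]
            assert hit.category == "on_site"

    def test_all_far_yields_no_hits(self):
        cfg = SimConfig(seed=9, n_proteins=20, n_ptm_sites=30, n_snps=50, frac_far=1.0)
        ann = plant_annotations(cfg, gen_proteome(cfg))
        assert run_detection(ann) == []

    def test_offset_histogram_recovered_under_zero_noise(self, small_dataset):
        cfg, ann = small_dataset
        hits = run_detection(ann)
        truth = ann.ground_truth
        planted = truth[truth.is_ptm_snp.astype(bool)]
        planted_counts = planted.true_offset.value_counts()
        offsets = {}
        hit_by_key = {(h.rs_id, h.ptm_protein_ac, h.ptm_position, h.ptm_type): h for h in hits}
        for row in planted.itertuples(index=False):
            h = hit_by_key[(row.rs_id, row.ptm_protein_ac, row.ptm_position, row.ptm_type)]
            offsets[h.offset] = offsets.get(h.offset, 0) + 1
        assert offsets == {int(k): int(v) for k, v in planted_counts.items()}

    def test_recall_non_increasing_in_substitution_rate(self):
        recalls = []
        for rate in (0.0, 0.3, 1.0):
            cfg = SimConfig(seed=12, n_proteins=30, n_ptm_sites=60, n_snps=150,
                            noise=NoiseConfig(substitution_rate=rate))
            ann = plant_annotations(cfg, gen_proteome(cfg))
            perf = detection_performance(ann.ground_truth, run_detection(ann))
            recalls.append(perf["recall"])
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2] - 0.02  # small-sample wobble


class TestDiseaseCatalog:
    def test_null_odds_ratio_equalizes_rates(self):
        rng = np.random.default_rng(0)
        is_ptm = np.repeat([True, False], 50000)
        status = draw_disease_status(rng, is_ptm, DiseaseConfig(background_rate=0.01,
                                                                ptm_snp_odds_ratio=1.0))
        rate_ptm = status[is_ptm].mean()
        rate_other = status[~is_ptm].mean()
        assert rate_ptm == pytest.approx(rate_other, abs=3 * np.sqrt(2 * 0.01 / 50000))

    def test_zero_background_restricts_to_ptm_snps(self):
        cfg = SimConfig(seed=9, n_proteins=20, n_ptm_sites=40, n_snps=200,
                        disease=DiseaseConfig(background_rate=1e-9, ptm_snp_odds_ratio=1e9))
        ann = plant_annotations(cfg, gen_proteome(cfg))
        catalog, status = gen_disease_catalog(cfg, ann.ground_truth)
        truth_ptm = dict(zip(ann.ground_truth.rs_id, ann.ground_truth.is_ptm_snp))
        assert catalog and all(truth_ptm[c.rs_id] for c in catalog)

    def test_catalog_p_values_below_gwas_threshold(self):
        cfg = SimConfig(seed=9, n_proteins=20, n_ptm_sites=40, n_snps=200,
                        disease=DiseaseConfig(background_rate=0.05))
        ann = plant_annotations(cfg, gen_proteome(cfg))
        catalog, _ = gen_disease_catalog(cfg, ann.ground_truth)
        assert catalog and all(c.p_value < 1e-5 for c in catalog)


class TestGenotypePanel:
    def test_no_missingness_passes_early_qc_stages(self):
        cfg = SimConfig(seed=4)
        panel, _ = gen_genotype_panel(cfg, [f"rs{i}" for i in range(50)])
        _, removed = qc_filter(panel)
        assert removed["samples"] == 0 and removed["snp_missing"] == 0

    def test_sample_mode_counts_consistent(self):
        cfg = SimConfig(seed=4)
        panel, _ = gen_genotype_panel(cfg, ["rs1", "rs2"], sample_mode=True)
        counts = panel.counts()
        assert (counts[["r0", "r1", "r2"]].sum(axis=1) == cfg.gwas.n_case).all()
        assert (counts[["s0", "s1", "s2"]].sum(axis=1) == cfg.gwas.n_ctrl).all()

    def test_deterministic(self):
        cfg = SimConfig(seed=4)
        a, _ = gen_genotype_panel(cfg, ["rs1", "rs2"])
        b, _ = gen_genotype_panel(cfg, ["rs1", "rs2"])
        assert a.counts().equals(b.counts())
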