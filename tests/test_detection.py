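import numpy as np
import pytest

from ptmsnp.detection import (
    ProteinIndex,
    candidate_pairs,
    classify,
    deduplicate,
    detect,
    resolve,
    site_coverage,
    site_coverage_from_counts,
)
from ptmsnp.io_formats import ProteinRecord, PtmSite, SnpRecord, extract_window
from ptmsnp.synthetic import detection_performance

from conftest import make_hit


def snp_on(protein: ProteinRecord, position: int, snp_class="missense") -> SnpRecord:
    ref = protein.sequence[position - 1]
    if snp_class == "stopgain":
        alt = "*"
    else:
        alt = "L" if ref != "L" else "V"
    return SnpRecord("rs1", protein.accession, position, ref, alt, snp_class,
                     snp_window=extract_window(protein.sequence, position))


def ptm_on(protein: ProteinRecord, position: int, ptm_type="Phosphorylation",
           evidence="experimental") -> PtmSite:
    return PtmSite(protein.accession, position, protein.sequence[position - 1],
                   ptm_type, evidence,
                   ptm_window=extract_window(protein.sequence, position))


BASE = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
PROT_A = ProteinRecord("A", "snp_db", BASE)
PROT_B = ProteinRecord("B", "ptm_db", BASE)
INDEX = ProteinIndex.from_records([PROT_A, PROT_B])
ID_MAP = [("A", "B")]


class TestClassify:
    @pytest.mark.parametrize(
        "snp_class,offset,expected",
        [
            ("missense", 0, "on_site"),
            ("missense", -7, "flanking"),
            ("missense", 7, "flanking"),
            ("stopgain", 2, "stopgain_affected"),
            ("stopgain", 0, "stopgain_affected"),
        ],
    )
    def test_categories(self, snp_class, offset, expected):
        assert classify(snp_class, offset) == expected

    def test_offset_out_of_range(self):
        with pytest.raises(ValueError):
            classify("missense", 8)


class TestCandidatePairs:
    def test_band_filtering(self):
        snp = snp_on(PROT_A, 20)
        far_ptm = ptm_on(PROT_B, 50)  # |20-50| = 30 > 17
        near = [ptm_on(PROT_B, 15), ptm_on(PROT_B, 24)]
        pairs = candidate_pairs([snp], [far_ptm] + near, ID_MAP)
        assert [p.position for _, p in pairs] == [15, 24]

    def test_unmapped_accessions_excluded(self):
        pairs = candidate_pairs([snp_on(PROT_A, 20)], [ptm_on(PROT_B, 20)], [("A", "C")])
        assert pairs == []

    def test_count_matches_bruteforce_band_count(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 500))
        a = ProteinRecord("A", "snp_db", seq)
        b = ProteinRecord("B", "ptm_db", seq)
        snp_pos = rng.integers(1, 501, size=100)
        ptm_pos = rng.integers(1, 501, size=100)
        snps = [
            SnpRecord(f"rs{i}", "A", int(p), seq[p - 1], "*" if seq[p - 1] != "*" else "L",
                      "stopgain")
            for i, p in enumerate(snp_pos)
        ]
        ptms = [PtmSite("B", int(p), seq[p - 1], "Phosphorylation", "predicted")
                for p in ptm_pos]
        pairs = candidate_pairs(snps, ptms, ID_MAP, flank=7, slack=10)
        expected = sum(
            1 for sp in snp_pos for pp in ptm_pos if abs(int(sp) - int(pp)) <= 17
        )
        assert len(pairs) == expected


class TestResolve:
    def test_on_site(self):
        hit = resolve(snp_on(PROT_A, 20), ptm_on(PROT_B, 20), INDEX)
        assert hit.offset == 0 and hit.category == "on_site" and hit.method == "slide"

    def test_plus_three_flanking(self):
        hit = resolve(snp_on(PROT_A, 23), ptm_on(PROT_B, 20), INDEX)
        assert hit.offset == 3 and hit.category == "flanking"

    def test_stopgain_any_offset(self):
        hit = resolve(snp_on(PROT_A, 22, "stopgain"), ptm_on(PROT_B, 20), INDEX)
        assert hit.category == "stopgain_affected"
        assert hit.truncates_site is False  # offset +2, stop after the site
        hit2 = resolve(snp_on(PROT_A, 18, "stopgain"), ptm_on(PROT_B, 20), INDEX)
        assert hit2.truncates_site is True

    def test_no_candidate_returns_none(self):
        other = ProteinRecord("B", "ptm_db", "W" * 56)
        idx = ProteinIndex.from_records([PROT_A, other])
        assert resolve(snp_on(PROT_A, 20), ptm_on(other, 20), idx) is None

    def test_repeat_tie_routed_to_global_fallback(self):
        # SNP-db protein: lone K at 24; PTM-db copy also has K at 18.  The
        # sliding match ties at offsets ±3 and the full-protein alignment
        # must recover the true +3 (coordinate-difference oracle).
        snp_seq = list("A" * 41)
        snp_seq[23] = "K"
        ptm_seq = list(snp_seq)
        ptm_seq[17] = "K"
        a = ProteinRecord("A", "snp_db", "".join(snp_seq))
        b = ProteinRecord("B", "ptm_db", "".join(ptm_seq))
        idx = ProteinIndex.from_records([a, b])
        hit = resolve(snp_on(a, 24), ptm_on(b, 21), idx)
        assert hit.method == "global_fallback"
        assert hit.offset == 24 - 21

    def test_idempotent(self):
        snp, ptm = snp_on(PROT_A, 23), ptm_on(PROT_B, 20)
        assert resolve(snp, ptm, INDEX) == resolve(snp, ptm, INDEX)

    def test_windows_derived_from_proteins_when_absent(self):
        snp = SnpRecord("rs1", "A", 20, BASE[19], "L", "missense")
        ptm = PtmSite("B", 20, BASE[19], "Phosphorylation", "experimental")
        hit = resolve(snp, ptm, INDEX)
        assert hit.offset == 0


class TestDeduplicate:
    def test_experimental_preferred(self):
        a = make_hit(evidence="predicted", identities=15)
        b = make_hit(evidence="experimental", identities=12)
        (kept,) = deduplicate([a, b])
        assert kept.evidence == "experimental" and kept.n_merged == 2

    def test_slide_preferred_then_identities(self):
        a = make_hit(method="global_fallback", identities=15)
        b = make_hit(method="slide", identities=12)
        c = make_hit(method="slide", identities=14)
        (kept,) = deduplicate([a, b, c])
        assert kept.method == "slide" and kept.identities == 14

    def test_distinct_ptm_types_kept(self):
        hits = [make_hit(ptm_type="Phosphorylation"), make_hit(ptm_type="Ubiquitination")]
        assert len(deduplicate(hits)) == 2

    def test_never_increases_and_idempotent(self):
        hits = [make_hit(rs_id=f"rs{i % 3}") for i in range(10)]
        once = deduplicate(hits)
        assert len(once) <= len(hits)
        assert deduplicate(once) == once

    def test_empty(self):
        assert deduplicate([]) == []


class TestSiteCoverage:
    def test_from_counts_matches_hand_ratios(self):
        df = site_coverage_from_counts([("Disulfide bond", 1750, 1230), ("Other", 250, 0)])
        row = df[df.ptm_type == "Disulfide bond"].iloc[0]
        assert row.ratio == 0.703
        assert df[df.ptm_type == "Other"].iloc[0].ratio == 0.0
        total = df[df.ptm_type == "Total"].iloc[0]
        assert total.n_sites == 2000 and total.n_sites_hit == 1230

    def test_counts_sites_not_hits(self):
        ptms = [ptm_on(PROT_B, 20), ptm_on(PROT_B, 30)]
        hits = [
            make_hit(rs_id="rs1", ptm_protein_ac="B", ptm_position=20),
            make_hit(rs_id="rs2", ptm_protein_ac="B", ptm_position=20),
        ]
        df = site_coverage(ptms, hits)
        row = df[df.ptm_type == "Phosphorylation"].iloc[0]
        assert row.n_sites == 2 and row.n_sites_hit == 1 and row.ratio == 0.5


class TestEndToEnd:
    def test_zero_noise_offsets_equal_planted_difference(self, small_dataset):
        cfg, ann = small_dataset
        idx = ProteinIndex.from_records(ann.proteome.snp_proteins + ann.proteome.ptm_proteins)
        hits = detect(ann.snps, ann.ptms, ann.proteome.id_map, idx)
        perf = detection_performance(ann.ground_truth, hits)
        assert perf["recall"] == 1.0 and perf["n_wrong"] == 0
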