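import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """A small zero-noise synthetic dataset shared across tests."""
    from ptmsnp.synthetic import SimConfig, gen_proteome, plant_annotations

    cfg = SimConfig(seed=7, n_proteins=40, n_ptm_sites=80, n_snps=200)
    ann = plant_annotations(cfg, gen_proteome(cfg))
    return cfg, ann


def make_hit(**kwargs):
    """A PtmSnpHit with sensible defaults for table/round-trip tests."""
    from ptmsnp.detection import PtmSnpHit

    defaults = dict(
        rs_id="rs1",
        snp_protein_ac="SNPP00001",
        snp_position=20,
        ptm_protein_ac="PTMP00001",
        ptm_position=23,
        ptm_type="Phosphorylation",
        evidence="experimental",
        offset=-3,
        category="flanking",
        method="slide",
        identities=15,
        overlap=15,
        truncates_site=None,
        n_merged=1,
    )
    defaults.update(kwargs)
    return PtmSnpHit(**defaults)
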