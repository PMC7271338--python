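import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run():
    """One full default-scale pipeline run (13 sisters, 2 x 1 Mb, 140
    planted shared hotspot windows), shared by end-to-end tests."""
    import tetramosaic as tm

    cfg = tm.default_config(seed=11)
    ped = tm.simulate_pedigree(cfg)
    return cfg, ped


@pytest.fixture(scope="session")
def small_pedigree():
    """A small, fast pedigree: 3 sisters, 1 chromosome x 100 kb."""
    import tetramosaic as tm

    cfg = tm.SimConfig(
        n_chromosomes=1,
        chrom_length_bp=100_000,
        n_sisters=3,
        parental_variant_rate=1e-3,
        recomb_breakpoints_per_chrom=2,
        np_hotspots=[tm.Hotspot("chr01", 30_000, 40_000, 5)],
        private_novel_rate=2e-5,
        seed=5,
    )
    return cfg, tm.simulate_pedigree(cfg)
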