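import pytest
from hypothesis import HealthCheck, settings

from gliascan import pipeline, synthetic_data as sd

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A 200 kb chromosome with a bipartite tandem array (5 + 2 copies) at
    2% per-copy divergence — the standard discovery/clustering fixture."""
    cfg = sd.SimConfig(
        chromosomes={"chr6B": 200_000},
        loci=(sd.LocusSpec("chr6B", anchors_bp=(43_500, 120_000), copies=(5, 2)),),
        substitution_rate=0.02,
        pseudogene_prob=0.2,
        seed=7,
    )
    assembly, truth = sd.generate_assembly(cfg)
    return cfg, assembly, truth


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """One full pipeline run on the bundled toy synthetic accession."""
    out = tmp_path_factory.mktemp("toyrun")
    cfg = pipeline.toy_config(seed=11)
    manifest = pipeline.run_pipeline(cfg, out)
    return cfg, out, manifest
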