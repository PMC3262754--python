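import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from poolcall.panel import Contig, ReferencePanel, TargetRegion
from poolcall.pipeline import example_run_config, run_pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_panel(seq: str, targets=None, name: str = "chr1") -> ReferencePanel:
    """Small single-contig panel for unit tests."""
    panel = ReferencePanel(contigs={name: Contig(name, seq)})
    if targets:
        panel.targets = [TargetRegion(name, s, e, lbl) for s, e, lbl in targets]
    return panel


def random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def pool2_run(tmp_path_factory):
    """One full pipeline run of the N=7 pool scenario (indel failure modes)."""
    outdir = tmp_path_factory.mktemp("pool2")
    config = example_run_config("POOL2", seed=1)
    manifest = run_pipeline(config, outdir)
    return config, manifest, outdir
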