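import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonepool import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def wt_manifest():
    """Small CRISPRwt-only library: 40 genes x 4 sgRNAs, 40 NTC sgRNAs,
    8 barcodes per sgRNA."""
    return sim.demo_manifest(
        n_genes=40, sgrnas_per_gene=4, bcs_per_sgrna=8, ntc_sgrnas=40,
        systems=("crisprwt",), seed=11,
    )


@pytest.fixture(scope="session")
def wt_screen(wt_manifest):
    """Expected-mode screen on the small library with three spiked
    resistance genes, both CRISPRwt clones."""
    clones = sim.demo_clones(("crisprwt",))
    effects = sim.spike_effects(["G00001", "G00002", "G00003"], resistance=0.9)
    design = sim.ScreenDesign(read_depth=400_000)
    return sim.run_screen(wt_manifest, clones, effects, design, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
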