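import numpy as np
import pytest

from nrskit import simulate as sim
from nrskit.demo import small_config


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return sim.build_reference(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg, small_ref):
    return sim.simulate_population(small_ref, small_cfg)


@pytest.fixture(scope="session")
def small_assemblies(small_cfg, small_ref, small_truth):
    return {info.sample: sim.emit_assembly(small_ref, small_truth,
                                           small_cfg, info.sample)
            for info in small_truth.samples}


@pytest.fixture(scope="session")
def small_pipeline(small_cfg, tmp_path_factory):
    from nrskit.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(small_cfg, outdir)


def random_sequence(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(p))])
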