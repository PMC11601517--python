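import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cleavemap as cm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref10k() -> cm.ReferenceSequence:
    """10-kb circular random reference at 50% GC (plasmid-scale stand-in)."""
    return cm.generate_reference(10000, gc=0.5, topology="circular", seed=7)


@pytest.fixture(scope="session")
def gnatnc_model() -> cm.BiasModel:
    """Strong rotationally symmetric dyad bias (G-N-A|T-N-C, x10, strength 2)."""
    return cm.BiasModel.symmetric_gnatnc(favor=10.0, strength=2.0)


def _library(ref, model, n_events, prep, seed):
    events = cm.sample_cleavage_events(ref, model, n_events, prep, seed=seed)
    reads = cm.simulate_library(events, prep, len(ref), ref.topology, seed=seed + 1)
    smap = cm.build_strand_map(reads, ref)
    return {"events": events, "reads": reads, "map": smap, "prep": prep, "model": model}


@pytest.fixture(scope="session")
def biased_library(ref10k, gnatnc_model):
    """3,000 sequence-biased DSBs, clean fill-in, faint uniform background."""
    prep = cm.LibraryPrepParams(background_rate=0.001)
    return _library(ref10k, gnatnc_model, 3000, prep, seed=11)


@pytest.fixture(scope="session")
def uniform_library(ref10k):
    """1,000 unbiased DSBs with background at 1% of the per-position signal."""
    prep = cm.LibraryPrepParams(background_rate=0.001)
    return _library(ref10k, cm.BiasModel.uniform(3), 1000, prep, seed=23)


@pytest.fixture(scope="session")
def artifact_library(ref10k, gnatnc_model):
    """Biased DSB library with 30% incomplete fill-in misassignment."""
    prep = cm.LibraryPrepParams(f_partial=0.3, background_rate=0.001)
    return _library(ref10k, gnatnc_model, 3000, prep, seed=31)
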