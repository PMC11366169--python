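import numpy as np
import pytest

from imprintscan import classify, registry, synthetic


@pytest.fixture(scope="session")
def catalog():
    return registry.load_dmr_catalog()


@pytest.fixture(scope="session")
def demo_bundle():
    """A 300-tumour demo cohort shared across tests (seed 7)."""
    config = synthetic.demo_config(seed=7, n_tumours=300)
    return synthetic.generate_cohort(config)


@pytest.fixture(scope="session")
def demo_calls(demo_bundle, catalog):
    """Probe map, probe calls and region calls for the demo cohort."""
    probe_map, _ = registry.map_probes_to_dmrs(demo_bundle.manifest, catalog)
    ctrl = classify.build_control_reference(demo_bundle.betas, demo_bundle.control_ids)
    probe_calls = classify.classify_probes(
        demo_bundle.betas[demo_bundle.tumour_ids], probe_map, ctrl
    )
    region_calls = classify.aggregate_regions(probe_calls)
    return probe_map, probe_calls, region_calls


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def tiny_catalog(n_dmrs=1, length=1000, methylated_allele="M"):
    """A minimal synthetic catalog for fast simulations."""
    dmrs = []
    for i in range(n_dmrs):
        dmrs.append(
            registry.ImprintedDMR(
                name=f"DMR{i}",
                display_name=f"DMR{i}",
                chrom=f"chr{i + 1}",
                start=1000,
                end=1000 + length - 1,
                methylated_allele=methylated_allele,
            )
        )
    return tuple(dmrs)
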