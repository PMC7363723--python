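import pytest

from linkscan import (
    classify_linkers,
    generate_family,
    partition_domains,
    two_class_config,
)


@pytest.fixture(scope="session")
def small_family():
    """20+20 sequence two-class family with perfect p-loop coupling."""
    cfg = two_class_config(n_per_class=20, seed=11)
    return generate_family(cfg)


@pytest.fixture(scope="session")
def small_partition(small_family):
    fam, truth = small_family
    ref = fam.ids[0]
    return partition_domains(fam, ref, truth.ref_ntd_end, truth.ref_ctd_start(ref))


@pytest.fixture(scope="session")
def small_classing(small_partition):
    return classify_linkers(small_partition)
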