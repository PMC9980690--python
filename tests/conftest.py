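import pytest

from hairpinrcp import synthetic_data as sd


@pytest.fixture(scope="session")
def reference():
    """Synthetic ~100 bp amplicon with 5 CpG dyads."""
    return sd.make_reference(n_cpg=5, length=100, seed=7)


@pytest.fixture()
def clean_spec():
    """Error-free simulation spec: conversion perfect, no slippage."""
    return sd.SimSpec(
        n_individuals_per_group=2,
        molecules_per_individual=10,
        fail_rate=0.0,
        inappropriate_rate=0.0,
        slippage_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clock():
    return sd.make_synthetic_clock(n_probes=10)
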