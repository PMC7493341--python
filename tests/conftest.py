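"""Shared fixtures: one default synthetic experiment reused across tests."""

import pytest

from macetools.synth import (
    SynthConfig,
    generate_annotation,
    generate_counts,
    generate_genotypes,
    generate_go,
    generate_tags,
)


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def annotation(default_config):
    return generate_annotation(default_config)


@pytest.fixture(scope="session")
def models(annotation):
    return annotation[0]


@pytest.fixture(scope="session")
def tags(annotation, default_config):
    models, truth = annotation
    return generate_tags(models, truth, default_config)


@pytest.fixture(scope="session")
def count_bundle(annotation, default_config):
    models, truth = annotation
    return generate_counts(models, default_config, truth)


@pytest.fixture(scope="session")
def go_bundle(annotation, count_bundle, default_config):
    models, _ = annotation
    _, truth = count_bundle
    return generate_go(models, truth, default_config)


@pytest.fixture(scope="session")
def genotype_bundle(default_config):
    return generate_genotypes(default_config)
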