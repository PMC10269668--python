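"""Shared fixtures: a small synthetic genome world and a model trained on it.

The small world uses a 60-kb chromosome so unit tests stay fast; the chromosome
length filter is overridden accordingly when building its training set.  The
full-scale default conditions are exercised in the acceptance tests.
"""

import numpy as np
import pytest

import repliclass as rc
from repliclass.features import feature_table
from repliclass.markers import NaiveBackend
from repliclass.synthetic import SynthGenomeSpec, fragment_assembly, generate_genome
from repliclass.training import build_training_set, specs_up_to, train

SMALL_SEED = 7


@pytest.fixture(scope="session")
def small_genome():
    spec = SynthGenomeSpec(
        seed=SMALL_SEED,
        chromosome_length=60_000,
        n_plasmids=3,
        plasmid_length_range=(4_000, 12_000),
    )
    return generate_genome(spec)


@pytest.fixture(scope="session")
def small_dbs(small_genome):
    return rc.build_reference_databases([small_genome.chromosome], small_genome.plasmids)


@pytest.fixture(scope="session")
def backend():
    return NaiveBackend()


@pytest.fixture(scope="session")
def small_feature_table(small_genome, small_dbs, backend):
    windows = build_training_set(
        small_genome.labeled_replicons(),
        specs_up_to(2_000),
        chrom_min_len=50_000,
        seed=3,
    )
    table = feature_table(
        [(w.id, w.sequence) for w in windows],
        small_dbs,
        backend,
        small_genome.marker_db,
        labels=[w.label for w in windows],
    )
    return table


@pytest.fixture(scope="session")
def small_model(small_feature_table):
    return train(small_feature_table, small_feature_table["label"].tolist(), ntrees=200, seed=5)


@pytest.fixture(scope="session")
def small_fragments(small_genome):
    contigs, truth = fragment_assembly(small_genome.labeled_replicons(), 40, seed=9)
    return contigs, truth


@pytest.fixture(scope="session")
def toy_separable_features():
    """600 rows separated purely on r_k18 (1 for chromosomes, 0 for plasmids)."""
    rng = np.random.default_rng(42)
    n = 600
    X = np.zeros((n, len(rc.FEATURE_NAMES)))
    labels = np.array(["chromosome"] * (n // 2) + ["plasmid"] * (n // 2))
    X[:, rc.FEATURE_NAMES.index("r_k18")] = (labels == "chromosome").astype(float)
    X[:, rc.FEATURE_NAMES.index("rp")] = 0.5
    noise_col = rc.FEATURE_NAMES.index("ConjMaxScore")
    X[:, noise_col] = rng.random(n)
    return X, labels
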