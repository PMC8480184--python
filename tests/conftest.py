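import warnings

import numpy as np
import pandas as pd
import pytest

from tomoevo import spatial, synth
from tomoevo.io_formats import SectionCounts


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Generator/pipeline emit informational warnings; keep test output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_params():
    """Reduced synthetic experiment for fast integration tests."""
    return synth.SynthParams(n_genes=600, n_candidate_pairs=100, n_refprep_genes=30)


@pytest.fixture(scope="session")
def small_experiment(small_params):
    return synth.generate_experiment(small_params, seed=11)


def random_section_counts(rng, n_genes=30, n_sections=8, specimen="w"):
    counts = rng.poisson(5.0, size=(n_genes, n_sections)).astype(np.int64)
    return SectionCounts(specimen, [f"g{i}" for i in range(n_genes)],
                         [f"s{j}" for j in range(n_sections)], counts)


def make_zprofile(z_rows: dict, specimen="w"):
    """Build a ZProfile directly from per-gene z rows (for peak/segment tests)."""
    genes = list(z_rows)
    z = np.array([z_rows[g] for g in genes], dtype=float)
    n_sections = z.shape[1]
    norm = np.full_like(z, 1.0 / max(len(genes), 1))
    return spatial.ZProfile(specimen, genes, [f"s{j}" for j in range(n_sections)],
                            norm, z, np.ones(len(genes), dtype=bool))


def hit_frame(rows):
    """Rows of (query, target, qtax, ttax, evalue, bitscore[, qend])."""
    recs = []
    for row in rows:
        row = list(row) + [np.nan] * (7 - len(row))
        recs.append(dict(zip(["query_id", "target_id", "query_taxon",
                              "target_taxon", "evalue", "bitscore", "query_end"], row)))
    return pd.DataFrame(recs, columns=["query_id", "target_id", "query_taxon",
                                       "target_taxon", "evalue", "bitscore", "query_end"])
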