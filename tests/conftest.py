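import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from hypothesis import settings

import sasearch as ss
from sasearch.db import ALPHABET

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scheme():
    return ss.default_scheme()


def make_reference_aligner(scheme: ss.ScoringScheme) -> Align.PairwiseAligner:
    """Independent Smith-Waterman oracle: Biopython's C aligner configured
    to the exact same scoring convention as the package."""
    sub = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            sub[a, b] = scheme.matrix[i, j]
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@pytest.fixture(scope="session")
def reference_aligner(scheme):
    return make_reference_aligner(scheme)


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale seeded benchmark shared by unit tests."""
    spec = ss.BenchmarkSpec(
        n_decoys=120, homologs_per_bin=4, decoy_length=(60, 150), seed=7
    )
    bench = ss.generate_benchmark(spec)
    db = ss.build_database(bench.database)
    sa = ss.build_suffix_array(db)
    return bench, db, sa
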