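import numpy as np
import pytest

from txprofiler.genetics import ALL_CODONS
from txprofiler.io_formats import AlignmentHit
from txprofiler.synthetic_data import SyntheticSpec, generate_corpus, write_corpus


@pytest.fixture(scope="session")
def corpus():
    """Default desk-scale synthetic corpus, generated once per session."""
    return generate_corpus(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def corpus_dir(corpus, tmp_path_factory):
    """The same corpus written out as the text files the CLI consumes."""
    outdir = tmp_path_factory.mktemp("corpus")
    paths = write_corpus(corpus, outdir)
    return paths


def random_count_table(rng) -> dict[str, int]:
    """A random 64-codon count dict, with occasional all-zero families."""
    counts = {c: int(v) for c, v in zip(ALL_CODONS, rng.integers(0, 200, 64))}
    if rng.random() < 0.3:  # zero out a few random codons / whole families
        for c in rng.choice(ALL_CODONS, size=rng.integers(1, 20)):
            counts[str(c)] = 0
    return counts


def random_hit(rng, query_id: str, subject_id: str) -> AlignmentHit:
    subject_length = int(rng.integers(50, 500))
    s_start = int(rng.integers(1, subject_length + 1))
    s_end = int(rng.integers(1, subject_length + 1))
    span = abs(s_end - s_start) + 1
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=float(np.round(rng.uniform(20, 100), 2)),
        aln_length=span,
        mismatches=int(rng.integers(0, span + 1)),
        gap_opens=int(rng.integers(0, 5)),
        q_start=1,
        q_end=span,
        s_start=s_start,
        s_end=s_end,
        evalue=10.0 ** float(rng.uniform(-100, 0)),
        bitscore=float(rng.choice([50.0, 100.0, 150.0, 200.0, 250.0])),
        subject_length=subject_length,
    )


def random_hit_table(rng, n_queries=8, max_hits_per_query=4) -> list[AlignmentHit]:
    hits = []
    for qi in range(int(rng.integers(0, n_queries + 1))):
        for hi in range(int(rng.integers(1, max_hits_per_query + 1))):
            hits.append(random_hit(rng, f"q{qi}", f"s{qi}_{hi}"))
    return hits
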