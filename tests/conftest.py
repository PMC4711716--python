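import os

import numpy as np
import pytest

from blockalign import _kernels
from blockalign.fixtures import write_genome
from blockalign.reference_index import build_index


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    # compile the DP kernels once for the whole session
    _kernels.warmup()


@pytest.fixture(scope="session")
def genome_2kb(tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "genome2kb.fa"
    seq = write_genome(path, 2000, gc_content=0.5, seed=11)
    return str(path), seq


@pytest.fixture(scope="session")
def index_2kb(genome_2kb):
    path, _ = genome_2kb
    return build_index(path, k=13)


@pytest.fixture(scope="session")
def genome_100kb(tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "genome100kb.fa"
    seq = write_genome(path, 100_000, gc_content=0.5, seed=7)
    return str(path), seq


@pytest.fixture(scope="session")
def index_100kb(genome_100kb):
    path, _ = genome_100kb
    return build_index(path, k=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_fastq(path, records):
    """records: iterable of (id, seq) or (id, seq, qual)."""
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = rec[0], rec[1]
            qual = rec[2] if len(rec) > 2 else "I" * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return os.fspath(path)


@pytest.fixture()
def fastq_writer():
    return write_fastq
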