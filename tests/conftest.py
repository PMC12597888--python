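"""Shared fixtures: small deterministic synthetic references and fragment sets.

Everything is generated at test time; no data files ship with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from fragkit.fragio import Fragment, GenomicInterval
from fragkit.synth import simulate_fragments, simulate_reference


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    """10 kb uniform-ACGT reference, seed-fixed."""
    d = tmp_path_factory.mktemp("ref")
    path = d / "ref.fa"
    simulate_reference({"chr1": 10_000}, seed=7, out_fasta=path)
    return path


@pytest.fixture(scope="session")
def toy_fragments():
    """2000 clean synthetic fragments on a 50 kb contig."""
    return simulate_fragments(2000, {"chr1": 50_000}, seed=11)


@pytest.fixture(scope="session")
def toy_fragfile(tmp_path_factory, toy_fragments):
    d = tmp_path_factory.mktemp("frags")
    path = d / "toy.frag.gz"
    from fragkit.fragio import write_fragfile

    write_fragfile(toy_fragments, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_fragments(rng, n, contig="chr1", max_pos=2000, min_len=50, max_len=250):
    """Uniform random toy fragments for oracle comparisons."""
    frags = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(min_len, max_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frags.append(Fragment(contig, start, start + length, 60, strand))
    return frags
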