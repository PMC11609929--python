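import numpy as np
import pytest

from scfishhook.amplicon import DesignParams, build_fishhooks
from scfishhook.kras import default_reference, default_variants
from scfishhook.matcher import MatcherParams, build_seed_index


@pytest.fixture(scope="session")
def kras_ref():
    return default_reference()


@pytest.fixture(scope="session")
def kras_variants():
    return default_variants()


@pytest.fixture(scope="session")
def kras_hooks(kras_ref, kras_variants):
    return build_fishhooks(kras_ref, kras_variants, DesignParams())


@pytest.fixture(scope="session")
def kras_index(kras_hooks):
    return build_seed_index(kras_hooks, MatcherParams())


def write_fastq(path, records):
    """records: iterable of (read_id, sequence); qualities are constant."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def random_read(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
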