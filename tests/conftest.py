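import numpy as np
import pytest

from prokmethylome import MotifSpec
from prokmethylome.simulate import build_scenario


@pytest.fixture(scope="session")
def gatc():
    return MotifSpec.palindromic("GATC", 1, "m6A")


@pytest.fixture(scope="session")
def small_bundle():
    """Compact orphan-MTase scenario shared by fast tests."""
    return build_scenario(
        "orphan_regulatory", seed=11,
        genome_length=50_000, n_genes=40, n_instances=150, n_unmethylated=10,
    )


@pytest.fixture(scope="session")
def small_results(small_bundle):
    from prokmethylome.model import MethylomeModel

    return MethylomeModel.from_bundle(small_bundle).fit()


def naive_motif_scan(sequence, pattern):
    """Per-position IUPAC-expansion oracle: forward-strand match starts."""
    from prokmethylome.motifs import IUPAC

    hits = []
    L = len(pattern)
    for s in range(len(sequence) - L + 1):
        window = sequence[s: s + L]
        if all(b in IUPAC[sym] for b, sym in zip(window, pattern)):
            hits.append(s)
    return hits
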