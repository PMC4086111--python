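import numpy as np
import pytest

from srnatarget.fixtures import build_fixture, planted_spec
from srnatarget.scoring import scan_replicon

BASES = np.array(list("ACGU"))


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


@pytest.fixture(scope="session")
def planted_scans():
    """Scan results for the 20 seeded planted-target fixtures (200 genes,
    one perfect 20-nt complement each).  Shared between the recovery and
    co-expression acceptance checks, which look at the same replicons."""
    out = {}
    for seed in range(1, 21):
        fix = build_fixture(planted_spec(seed=seed, n_genes=200, with_de=True))
        out[seed] = (fix, scan_replicon(fix.srna, fix.replicon))
    return out
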