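import numpy as np
import pytest

from viralhist.io import DomainHit


@pytest.fixture
def make_hit():
    """Factory for DomainHit with sensible defaults."""

    def _make(family="H3", ali_from=1, ali_to=70, c_evalue=1e-10,
              bit_score=100.0, hmm_from=1, hmm_to=70, hmm_length=70,
              protein_id="p1"):
        return DomainHit(protein_id=protein_id, family=family,
                         ali_from=ali_from, ali_to=ali_to,
                         hmm_from=hmm_from, hmm_to=hmm_to,
                         hmm_length=hmm_length, c_evalue=c_evalue,
                         bit_score=bit_score)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_hits(rng, n, protein_len=400, families=("H2A", "H2B", "H3", "H4")):
    """Random hit set on one protein for oracle comparisons."""
    hits = []
    for _ in range(n):
        fam = families[rng.integers(len(families))]
        hmm_length = int(rng.integers(50, 90))
        start = int(rng.integers(1, protein_len - 30))
        length = int(rng.integers(10, 120))
        end = min(start + length - 1, protein_len)
        cov_len = int(rng.integers(5, hmm_length + 1))
        hfrom = int(rng.integers(1, hmm_length - cov_len + 2))
        hits.append(DomainHit(
            protein_id="p1", family=fam, ali_from=start, ali_to=end,
            hmm_from=hfrom, hmm_to=hfrom + cov_len - 1, hmm_length=hmm_length,
            c_evalue=float(10.0 ** rng.uniform(-30, 0)),
            bit_score=float(rng.uniform(10, 200)),
        ))
    return hits
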