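import numpy as np
import pandas as pd
import pytest

from decaykit import PredictorTable
from decaykit.sequence_features import SENSE_CODONS, relative_adaptiveness


@pytest.fixture(scope="session")
def flat_usage():
    """Usage table with equal counts: every codon has w = 1."""
    return relative_adaptiveness({c: 10.0 for c in SENSE_CODONS}, pseudo_count=0.5)


@pytest.fixture(scope="session")
def random_usage():
    """Seeded random codon counts for non-trivial CAI weights."""
    rng = np.random.default_rng(42)
    counts = {c: float(rng.integers(1, 1000)) for c in SENSE_CODONS}
    return relative_adaptiveness(counts, pseudo_count=0.5)


def make_linear_table(seed, n=300, p=5, n_true=2, beta=0.5, noise_sd=1.0):
    """Gaussian predictors, linear response on the first n_true of them."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    names = [f"x{j}" for j in range(p)]
    y = 1.0 + X[:, :n_true] @ np.full(n_true, beta) + rng.normal(0, noise_sd, n)
    y = y - y.min() + 0.01  # rate constants are positive
    genes = [f"g{i}" for i in range(n)]
    data = pd.DataFrame(X, columns=names, index=genes)
    return PredictorTable(data, pd.Series(y, index=genes, name="k_deg"))


def random_cds_seq(rng, n_codons):
    """Random sense-codon sequence (no stops) as a plain string."""
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))
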