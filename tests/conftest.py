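import numpy as np
import pytest

from mosaictk import CandidateSNV, GenomicSite, StrandCounts, sim_bulk_pileups


@pytest.fixture
def site():
    return GenomicSite("chr1", 100, "A", "T")


@pytest.fixture
def clean_mosaic_counts():
    # VAF 0.1 at depth 250, strand-balanced
    return StrandCounts(ref_fwd=113, ref_rev=112, alt_fwd=13, alt_rev=12)


@pytest.fixture(scope="session")
def bulk_cohort():
    """A simulated 250x candidate cohort with truth, shared across tests."""
    pileups, truth = sim_bulk_pileups(n_sites=300, seed=0)
    candidates = [CandidateSNV(site=s, counts=c) for s, c in pileups.items()]
    return candidates, truth


def exact_binom_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Minimum-likelihood two-sided binomial p-value by full enumeration.

    Sums P(X = j) over all j whose probability does not exceed that of the
    observed count (with a small relative tolerance for float ties).
    """
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(n + 1), n, p)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration over all
    tables with the observed margins."""
    from scipy.stats import hypergeom

    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())
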