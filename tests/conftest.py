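import numpy as np
import pytest

import mvgmdr as m


def make_panel(y, family="binomial", ids=None):
    """PhenotypePanel from a dense (n,) or (n,t) array; nan marks missing."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, t = y.shape
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    return m.PhenotypePanel(ids, [f"occ{j}" for j in range(t)], y, family,
                            np.isnan(y))


def make_genotypes(dosages, ids=None, loci=None):
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    n, p = d.shape
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    if loci is None:
        loci = [f"snp{j}" for j in range(p)]
    return m.GenotypeMatrix.from_dosages(ids, loci, d)


@pytest.fixture(scope="session")
def epi_dataset():
    """One shared-interaction dataset: pair (L000, L001) is causal."""
    cfg = m.default_epistasis_scenario(n=800, seed=7)
    return m.simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
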