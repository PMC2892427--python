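import numpy as np
import pytest

from famstage.pedigree import Individual, Pedigree
from famstage.simstudy import _PanelContext, default_panel


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree([
        Individual("f1", "dad", sex=1),
        Individual("f1", "mom", sex=2),
        Individual("f1", "kid", father_id="dad", mother_id="mom"),
    ])


@pytest.fixture
def sib_family() -> Pedigree:
    """Two parents, three full siblings."""
    return Pedigree([
        Individual("f1", "dad", sex=1),
        Individual("f1", "mom", sex=2),
        Individual("f1", "s1", "dad", "mom"),
        Individual("f1", "s2", "dad", "mom"),
        Individual("f1", "s3", "dad", "mom"),
    ])


@pytest.fixture
def cousin_pedigree() -> Pedigree:
    """Three generations; c1 and c2 are first cousins."""
    return Pedigree([
        Individual("f1", "gp1", sex=1),
        Individual("f1", "gp2", sex=2),
        Individual("f1", "p1", "gp1", "gp2", sex=1),
        Individual("f1", "p2", "gp1", "gp2", sex=2),
        Individual("f1", "s1", sex=2),
        Individual("f1", "s2", sex=1),
        Individual("f1", "c1", "p1", "s1"),
        Individual("f1", "c2", "s2", "p2"),
    ])


@pytest.fixture(scope="session")
def panel():
    """The 500-family study panel (trios / 2-child sibships / 3-generation)."""
    return default_panel(500)


@pytest.fixture(scope="session")
def panel_ctx(panel):
    """Panel plus precomputed kinship decompositions and FBAT layout."""
    return _PanelContext(panel)


def gene_drop_kinship_mc(ped: Pedigree, n_drops: int, seed: int) -> np.ndarray:
    """Monte-Carlo kinship oracle: probability that one random allele from i
    and one from j are identical by descent, estimated by dropping uniquely
    labelled founder alleles through the pedigree ``n_drops`` times.

    Independent of the tabular recursion under test.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    founders = np.flatnonzero(ped.founder_mask)
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    labels = np.arange(1, 2 * len(founders) + 1, dtype=np.int32)
    alleles[founders] = labels.reshape(len(founders), 2)[:, :, None]
    for child, father, mother in ped.transmission_levels:
        for arr, par in ((0, father), (1, mother)):
            pick = rng.integers(0, 2, size=(len(child), n_drops))
            src = alleles[par]  # (k, 2, R)
            alleles[child, arr] = np.take_along_axis(
                src, pick[:, None, :], axis=1
            )[:, 0, :]
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            same = sum(
                (alleles[i, a] == alleles[j, b]).mean()
                for a in range(2) for b in range(2)
            ) / 4.0
            phi[i, j] = phi[j, i] = same
    return phi
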