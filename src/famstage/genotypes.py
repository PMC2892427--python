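"""Biallelic genotype simulation on pedigrees.

Founders draw alleles under Hardy-Weinberg equilibrium; offspring receive one
uniformly chosen allele from each parent (gene dropping), so transmissions are
exactly Mendelian.  Two-locus pairs in linkage disequilibrium are dropped at
the haplotype level (no recombination within the pair), which preserves the
founder r-squared through the pedigree.  Subpopulation allele frequencies for
admixture designs follow the Balding-Nichols Beta model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import Pedigree

__all__ = [
    "GenotypeMatrix",
    "AdmixtureDesign",
    "LDPairDesign",
    "drop_genotypes",
    "balding_nichols_freqs",
    "drop_ld_pair",
    "drop_admixture_genotypes",
]

MISSING = -1  # internal missing code; IO uses "NA"


@dataclass
class GenotypeMatrix:
    """Minor-allele counts, individuals x SNPs, entries in {0, 1, 2, MISSING}."""

    counts: np.ndarray
    snp_ids: list[str]
    ids: list[tuple[str, str]]
    minor_allele_freq: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        if self.counts.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.ids)}, {len(self.snp_ids)})"
            )

    def column(self, snp: str | int) -> np.ndarray:
        j = snp if isinstance(snp, int) else self.snp_ids.index(snp)
        return self.counts[:, j]


@dataclass(frozen=True)
class AdmixtureDesign:
    """Two-subpopulation stratification: Balding-Nichols allele frequencies
    around ``base_freq`` at differentiation ``fst``, and a trait-mean offset
    ``delta`` added to subpopulation 2.  Whole families belong to one
    subpopulation."""

    base_freq: float
    fst: float
    delta: float = 0.25

    def __post_init__(self):
        if not 0.0 < self.base_freq < 1.0:
            raise ValueError(f"base_freq must be in (0,1), got {self.base_freq}")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0,1), got {self.fst}")


@dataclass(frozen=True)
class LDPairDesign:
    """A causal locus and a marker at target squared correlation ``r2``.

    Haplotype frequencies use D = +sqrt(r2 * pA(1-pA) * pB(1-pB)); the sign of
    D does not affect r2 or two-sided tests.
    """

    qtl_freq: float
    marker_freq: float
    r2: float

    def haplotype_freqs(self) -> np.ndarray:
        """Frequencies of haplotypes (ab, aB, Ab, AB); A/B = minor alleles."""
        pa, pb, r2 = self.qtl_freq, self.marker_freq, self.r2
        if not (0.0 < pa < 1.0 and 0.0 < pb < 1.0):
            raise ValueError("allele frequencies must be in (0,1)")
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        d = np.sqrt(r2 * pa * (1 - pa) * pb * (1 - pb))
        h = np.array(
            [
                (1 - pa) * (1 - pb) + d,  # ab
                (1 - pa) * pb - d,        # aB
                pa * (1 - pb) - d,        # Ab
                pa * pb + d,              # AB
            ]
        )
        names = ("ab", "aB", "Ab", "AB")
        for f, name in zip(h, names):
            if f < -1e-12 or f > 1 + 1e-12:
                raise ValueError(
                    f"infeasible LD design: haplotype {name} frequency {f:.4g} "
                    f"outside [0,1] for qtl_freq={pa}, marker_freq={pb}, r2={r2}"
                )
        return np.clip(h, 0.0, 1.0)


def _founder_indices(ped: Pedigree) -> np.ndarray:
    return np.flatnonzero(ped.founder_mask)


def _drop_alleles(ped: Pedigree, founder_alleles: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Propagate founder alleles down the pedigree.

    ``founder_alleles`` has shape (n_founders, 2, ...); returns (n, 2, ...)
    with each offspring receiving one uniformly chosen allele (or haplotype)
    from each parent.
    """
    n = len(ped)
    alleles = np.zeros((n, 2) + founder_alleles.shape[2:],
                       dtype=founder_alleles.dtype)
    alleles[_founder_indices(ped)] = founder_alleles
    for child, father, mother in ped.transmission_levels:
        pick_f = rng.integers(0, 2, size=len(child))
        pick_m = rng.integers(0, 2, size=len(child))
        alleles[child, 0] = alleles[father, pick_f]
        alleles[child, 1] = alleles[mother, pick_m]
    return alleles


def drop_genotypes(
    ped: Pedigree,
    maf: float,
    rng: np.random.Generator,
    snp_id: str = "snp1",
    founder_freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Gene-drop one SNP: HWE founders at ``maf``, Mendelian offspring.

    ``founder_freqs`` optionally gives a per-founder allele frequency
    (admixture designs); it overrides ``maf`` for the founder draw.
    """
    if founder_freqs is None:
        if not 0.0 < maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {maf}")
        p = maf
    else:
        p = np.asarray(founder_freqs)[:, None]
    fidx = _founder_indices(ped)
    founder_alleles = (rng.random((len(fidx), 2)) < p).astype(np.int8)
    alleles = _drop_alleles(ped, founder_alleles, rng)
    counts = alleles.sum(axis=1, dtype=np.int8)
    return GenotypeMatrix(counts, [snp_id], ped.ids,
                          minor_allele_freq=np.array([maf]))


def balding_nichols_freqs(
    p: float, fst: float, rng: np.random.Generator, size: int = 2
) -> np.ndarray:
    """Subpopulation allele frequencies: Beta with mean p, variance p(1-p)Fst.

    Shape parameters are p(1-Fst)/Fst and (1-p)(1-Fst)/Fst.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0,1), got {p}")
    if not 0.0 < fst < 1.0:
        raise ValueError(f"fst must be in (0,1), got {fst}")
    c = (1.0 - fst) / fst
    return rng.beta(p * c, (1.0 - p) * c, size=size)


def drop_ld_pair(
    ped: Pedigree,
    design: LDPairDesign,
    rng: np.random.Generator,
    snp_ids: tuple[str, str] = ("qtl", "marker"),
) -> GenotypeMatrix:
    """Gene-drop a QTL/marker pair in LD as two-locus haplotypes.

    Founder chromosomes are drawn from the four-haplotype distribution implied
    by the design; whole haplotypes are transmitted, so offspring r-squared
    matches the founder value in expectation.
    """
    h = design.haplotype_freqs()
    fidx = _founder_indices(ped)
    cats = rng.choice(4, size=(len(fidx), 2), p=h)
    # category -> (qtl allele, marker allele)
    table = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
    founder_haps = table[cats]  # (n_founders, 2, 2)
    haps = _drop_alleles(ped, founder_haps, rng)
    counts = haps.sum(axis=1, dtype=np.int8)  # (n, 2)
    return GenotypeMatrix(
        counts,
        list(snp_ids),
        ped.ids,
        minor_allele_freq=np.array([design.qtl_freq, design.marker_freq]),
    )


def subpop_assignment(ped: Pedigree) -> np.ndarray:
    """Per-individual subpopulation label (1 or 2), whole families alternating
    in family order so the two subpopulations have near-equal size."""
    labels = np.zeros(len(ped), dtype=np.int8)
    for k, fam in enumerate(ped.families.values()):
        labels[np.asarray(fam)] = 1 + (k % 2)
    return labels


def drop_admixture_genotypes(
    ped: Pedigree,
    design: AdmixtureDesign,
    n_snps: int,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate an admixture SNP panel plus per-individual subpopulation labels.

    Each SNP gets its own (p1, p2) Balding-Nichols pair; founders draw HWE
    genotypes at their subpopulation's frequency; offspring are gene-dropped.
    SNPs are mutually in linkage equilibrium.
    """
    labels = subpop_assignment(ped)
    fidx = _founder_indices(ped)
    founder_sub = labels[fidx]
    cols = np.empty((len(ped), n_snps), dtype=np.int8)
    for j in range(n_snps):
        p1, p2 = balding_nichols_freqs(design.base_freq, design.fst, rng)
        pf = np.where(founder_sub == 1, p1, p2)
        g = drop_genotypes(ped, design.base_freq, rng, snp_id=f"adm{j+1}",
                           founder_freqs=pf)
        cols[:, j] = g.counts[:, 0]
    gm = GenotypeMatrix(
        cols,
        [f"adm{j+1}" for j in range(n_snps)],
        ped.ids,
        minor_allele_freq=np.full(n_snps, design.base_freq),
    )
    return gm, labels
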