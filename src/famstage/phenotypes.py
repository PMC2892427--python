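"""Quantitative-trait simulation with QTL, polygenic and residual components.

The trait is Y = a * (X - 2p) + g + e on a standardised scale (mean 0, total
variance 1 by default):

* ``a = sqrt(q2 * total_var / (2 p (1 - p)))`` so an additive QTL at design
  frequency p explains fraction ``q2`` of the variance among HWE founders;
* ``g ~ MVN(0, h2 * total_var * 2*Phi)`` per family block — the polygenic
  correlation between relatives is twice their kinship coefficient;
* ``e ~ iid N(0, (1 - q2 - h2) * total_var)``.

Non-normal marginals (absolute-normal, chi-square(1), lognormal) are produced
by transforming the multivariate-normal draw element-wise, which preserves the
familial dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import KinshipMatrix, Pedigree

__all__ = [
    "TraitModel",
    "simulate_trait",
    "transform_trait",
    "apply_admixture_offset",
    "DISTRIBUTIONS",
]

DISTRIBUTIONS = ("normal", "abs_normal", "chisq1", "lognormal")


@dataclass(frozen=True)
class TraitModel:
    """Variance decomposition and marginal distribution of the trait.

    ``q2`` is the QTL variance fraction, ``polygenic_h2`` the polygenic
    heritability; the residual fraction 1 - q2 - h2 must be positive.
    ``qtl_allele_freq`` is the design frequency used to scale the additive
    effect (realised QTL variance fluctuates with the sampled genotypes).
    """

    q2: float = 0.0
    polygenic_h2: float = 0.0
    total_var: float = 1.0
    qtl_allele_freq: float = 0.1
    distribution: str = "normal"

    def __post_init__(self):
        if not 0.0 <= self.q2 < 1.0:
            raise ValueError(f"q2 must be in [0,1), got {self.q2}")
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ValueError(f"polygenic_h2 must be in [0,1), got {self.polygenic_h2}")
        if self.q2 + self.polygenic_h2 >= 1.0:
            raise ValueError("q2 + polygenic_h2 must be < 1")
        if self.total_var <= 0:
            raise ValueError("total_var must be positive")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; "
                f"choose from {DISTRIBUTIONS}"
            )

    @property
    def residual_var_fraction(self) -> float:
        return 1.0 - self.q2 - self.polygenic_h2

    @property
    def additive_effect(self) -> float:
        """Per-allele effect a with var(a*X) = q2*total_var under HWE."""
        p = self.qtl_allele_freq
        return float(np.sqrt(self.q2 * self.total_var / (2.0 * p * (1.0 - p))))


def simulate_trait(
    ped: Pedigree,
    kinship: KinshipMatrix,
    model: TraitModel,
    rng: np.random.Generator,
    qtl: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one trait vector aligned with ``ped.ids``.

    ``qtl`` is the allele-count column of the causal SNP; required iff
    ``model.q2 > 0``.  The genotype term is centred at its HWE mean 2p so the
    trait mean stays near 0.  The non-normal transform (if any) is applied to
    the standardised normal draw.
    """
    n = len(ped)
    if model.q2 > 0 and qtl is None:
        raise ValueError("model has q2 > 0 but no QTL genotypes were given")
    y = np.zeros(n)
    if model.q2 > 0:
        p = model.qtl_allele_freq
        y += model.additive_effect * (np.asarray(qtl, dtype=float) - 2.0 * p)
    if model.polygenic_h2 > 0:
        L = kinship.chol2phi  # L L' = 2*Phi, block diagonal
        z = rng.standard_normal(n)
        y += np.sqrt(model.polygenic_h2 * model.total_var) * (L @ z)
    sd_e = np.sqrt(model.residual_var_fraction * model.total_var)
    y += sd_e * rng.standard_normal(n)
    if model.distribution != "normal":
        y = transform_trait(y, model.distribution)
    return y


def transform_trait(values: np.ndarray, distribution: str) -> np.ndarray:
    """Element-wise marginal transform of a standardised normal trait."""
    values = np.asarray(values, dtype=float)
    if distribution == "normal":
        return values.copy()
    if distribution == "abs_normal":
        return np.abs(values)
    if distribution == "chisq1":
        return values**2
    if distribution == "lognormal":
        return np.exp(values)
    raise ValueError(
        f"unknown distribution {distribution!r}; choose from {DISTRIBUTIONS}"
    )


def apply_admixture_offset(
    values: np.ndarray, labels: np.ndarray, delta: float
) -> np.ndarray:
    """Add the stratification offset ``delta`` to subpopulation-2 phenotypes."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != values.shape:
        raise ValueError(
            f"labels shape {labels.shape} does not match trait shape {values.shape}"
        )
    return values + delta * (labels == 2)
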