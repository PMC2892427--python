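"""The three association engines: least squares, kinship LME, and FBAT.

* ``fit_lm`` — ordinary least squares of the trait on the allele count,
  ignoring familial correlation; two-sided t test.  Fast, but anti-conservative
  when phenotypes are correlated within families.
* ``fit_lme`` — Gaussian linear mixed model with a polygenic random effect
  whose within-family correlation is twice the kinship matrix,
  Y ~ N(b0 + b*X, sg2 * 2*Phi + se2 * I); maximum likelihood, Wald chi-square
  test (one degree of freedom, upper tail) on the genotype effect.
* ``fbat_test`` — quantitative family-based association test: offspring allele
  counts are compared with their Mendelian expectation conditional on parental
  genotypes, so the test is robust to population stratification.

All engines take numpy arrays aligned with a pedigree's individual order and
return :class:`AssocResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .genotypes import MISSING
from .pedigree import KinshipMatrix, NuclearFamily

__all__ = [
    "AssocResult",
    "VarianceComponents",
    "FbatLayout",
    "fit_lm",
    "fit_lme",
    "fbat_test",
]


@dataclass
class AssocResult:
    """Per-SNP association summary.

    ``statistic`` is the t statistic (LM), Wald chi-square (LME) or Z (FBAT).
    ``n_used`` counts individuals for LM/LME and informative families for
    FBAT.  A missing ``pvalue`` (None) flags a SNP that could not be tested
    (monomorphic, insufficient data, or FBAT non-informative); ``note`` says
    why.
    """

    snp_id: str
    method: str
    n_used: int
    beta: float | None = None
    se: float | None = None
    statistic: float | None = None
    pvalue: float | None = None
    converged: bool = True
    note: str = ""

    @property
    def tested(self) -> bool:
        return self.pvalue is not None


@dataclass(frozen=True)
class VarianceComponents:
    """ML estimates of the polygenic (sigma2_g) and residual (sigma2_e)
    variance components of the mixed model."""

    sigma2_g: float
    sigma2_e: float


def _clean_xy(trait: np.ndarray, geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = np.asarray(trait, dtype=float)
    g = np.asarray(geno)
    mask = np.isfinite(y) & (g != MISSING)
    return y[mask], g[mask].astype(float), mask


def fit_lm(
    trait: np.ndarray, geno: np.ndarray, snp_id: str = "snp"
) -> AssocResult:
    """OLS regression of trait on allele count; two-sided t test, n-2 df.

    Individuals with a missing trait or genotype are excluded listwise.
    """
    y, x, mask = _clean_xy(trait, geno)
    n = len(y)
    if n < 3:
        return AssocResult(snp_id, "LM", n, note="insufficient data (n < 3)")
    if np.ptp(x) == 0:
        return AssocResult(snp_id, "LM", n, note="monomorphic")
    fit = stats.linregress(x, y)
    return AssocResult(
        snp_id,
        "LM",
        n,
        beta=float(fit.slope),
        se=float(fit.stderr),
        statistic=float(fit.slope / fit.stderr),
        pvalue=float(fit.pvalue),
    )


def _profile_loglik(h: float, yt: np.ndarray, Xt: np.ndarray, d: np.ndarray):
    """Profile log-likelihood at heritability ratio h, with the GLS fixed
    effects and the total variance profiled out analytically.

    ``yt``/``Xt`` are the trait and design rotated into the eigenbasis of
    2*Phi with eigenvalues ``d``; marginal variances are sigma2*(1-h+h*d).
    """
    n = len(yt)
    v = 1.0 - h + h * d
    w = 1.0 / v
    Xw = Xt * w[:, None]
    xtx = Xt.T @ Xw
    xty = Xw.T @ yt
    beta = np.linalg.solve(xtx, xty)
    resid = yt - Xt @ beta
    rss = float(resid @ (w * resid))
    sigma2 = rss / n
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + np.log(v).sum())
    return ll, beta, sigma2, xtx


def fit_lme(
    trait: np.ndarray,
    geno: np.ndarray,
    kinship: KinshipMatrix,
    snp_id: str = "snp",
    xatol: float = 1e-8,
    maxiter: int = 200,
) -> tuple[AssocResult, VarianceComponents | None]:
    """Kinship linear mixed model by maximum likelihood.

    The covariance sg2 * 2*Phi + se2 * I is reparameterised as
    sigma2 * ((1-h) I + h * 2*Phi) with h = sg2/(sg2+se2) in [0, 1); the
    likelihood is profiled over (b0, b, sigma2) and maximised over h by
    bounded scalar search.  The boundary h = 0 (no polygenic variance) is
    checked explicitly.  The genotype effect is tested by Wald chi-square
    with one degree of freedom (upper tail), equivalent to a two-sided Z
    test on beta/SE.
    """
    y, x, mask = _clean_xy(trait, geno)
    n = len(y)
    if n < 3:
        return AssocResult(snp_id, "LME", n, note="insufficient data (n < 3)"), None
    if np.ptp(x) == 0:
        return AssocResult(snp_id, "LME", n, note="monomorphic"), None
    if mask.all():
        U, d = kinship.eigen2phi
    else:
        U, d = kinship.subset(np.flatnonzero(mask)).eigen2phi
    yt = U.T @ y
    Xt = U.T @ np.column_stack([np.ones(n), x])

    neg = lambda h: -_profile_loglik(h, yt, Xt, d)[0]
    opt = optimize.minimize_scalar(
        neg, bounds=(0.0, 1.0 - 1e-9), method="bounded",
        options={"xatol": xatol, "maxiter": maxiter},
    )
    h_hat, ll_hat = float(opt.x), -float(opt.fun)
    ll0 = _profile_loglik(0.0, yt, Xt, d)[0]
    if ll0 >= ll_hat:
        h_hat = 0.0
    ll, beta, sigma2, xtx = _profile_loglik(h_hat, yt, Xt, d)
    cov = sigma2 * np.linalg.inv(xtx)
    se = float(np.sqrt(cov[1, 1]))
    wald = float((beta[1] / se) ** 2)
    pval = float(stats.chi2.sf(wald, df=1))
    vc = VarianceComponents(sigma2_g=h_hat * sigma2, sigma2_e=(1.0 - h_hat) * sigma2)
    res = AssocResult(
        snp_id,
        "LME",
        n,
        beta=float(beta[1]),
        se=se,
        statistic=wald,
        pvalue=pval,
        converged=bool(opt.success or h_hat == 0.0),
    )
    return res, vc


class FbatLayout:
    """Flattened offspring/parent index arrays for fast repeated FBAT calls.

    Built once per (pedigree, nuclear-family decomposition); the per-SNP
    statistic is then fully vectorised.
    """

    def __init__(self, families: list[NuclearFamily]):
        off, fa, mo, fam = [], [], [], []
        for k, nf in enumerate(families):
            for c in nf.offspring:
                off.append(c)
                fa.append(nf.father)
                mo.append(nf.mother)
                fam.append(k)
        self.offspring = np.asarray(off, dtype=np.intp)
        self.father = np.asarray(fa, dtype=np.intp)
        self.mother = np.asarray(mo, dtype=np.intp)
        self.family = np.asarray(fam, dtype=np.intp)
        self.n_families = len(families)


def fbat_test(
    trait: np.ndarray,
    geno: np.ndarray,
    families: list[NuclearFamily] | FbatLayout,
    offset: float | str = "mean",
    snp_id: str = "snp",
) -> AssocResult:
    """Quantitative FBAT with additive coding.

    With T = trait - offset over genotyped, phenotyped offspring whose parents
    are both genotyped::

        S = sum T * (X - E[X | parents]),   E[X | P] = (x_f + x_m) / 2
        V = sum T^2 * Var(X | parents),     Var(X | P) = (het_f + het_m) / 4
        Z = S / sqrt(V),  two-sided normal p-value

    Under the null of no linkage and no association, transmissions are
    Mendelian conditional on parental genotypes, so E[S] = 0 and Var(S) = V
    regardless of population structure.  ``offset`` is a constant or
    ``"mean"`` (sample mean of the tested offspring phenotypes — the
    variance-reducing default).  ``n_used`` counts families contributing
    nonzero variance (informative families); parents' phenotypes are never
    used.
    """
    lay = families if isinstance(families, FbatLayout) else FbatLayout(families)
    y = np.asarray(trait, dtype=float)
    g = np.asarray(geno)
    ok = (
        np.isfinite(y[lay.offspring])
        & (g[lay.offspring] != MISSING)
        & (g[lay.father] != MISSING)
        & (g[lay.mother] != MISSING)
    )
    if not ok.any():
        return AssocResult(snp_id, "FBAT", 0, note="no usable offspring")
    yo = y[lay.offspring[ok]]
    xo = g[lay.offspring[ok]].astype(float)
    xf = g[lay.father[ok]].astype(float)
    xm = g[lay.mother[ok]].astype(float)
    fam = lay.family[ok]

    off_val = float(np.mean(yo)) if offset == "mean" else float(offset)
    t = yo - off_val
    e = 0.5 * (xf + xm)
    var = ((xf == 1).astype(float) + (xm == 1).astype(float)) / 4.0
    s = float(np.sum(t * (xo - e)))
    contrib = t * t * var
    v = float(np.sum(contrib))
    fam_v = np.bincount(fam, weights=contrib, minlength=lay.n_families)
    n_inf = int(np.count_nonzero(fam_v > 0))
    if v <= 0.0:
        return AssocResult(snp_id, "FBAT", n_inf, note="non-informative (V = 0)")
    z = s / np.sqrt(v)
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return AssocResult(snp_id, "FBAT", n_inf, statistic=float(z), pvalue=pval)
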