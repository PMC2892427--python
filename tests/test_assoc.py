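"""Association engines against independent oracles.

Each engine is checked against a second, independent route to the same
quantity: closed-form normal equations for least squares, dense generic /
profile-grid likelihood maximisation for the mixed model, and exhaustive
enumeration of Mendelian transmissions for FBAT.
"""

import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from famstage.assoc import FbatLayout, fbat_test, fit_lm, fit_lme
from famstage.genotypes import MISSING, drop_genotypes
from famstage.pedigree import (
    Individual,
    Pedigree,
    compute_kinship,
    extract_nuclear_families,
)
from famstage.phenotypes import TraitModel, simulate_trait
from famstage.simstudy import generate_pedigree_panel


# ---------------------------------------------------------------- LM ----


def ols_oracle(y, x):
    """Hand-rolled normal equations with the classical t test."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - 2)
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), df=len(y) - 2)
    return beta[1], se, p


class TestLM:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=200).astype(float)
        y = 0.3 * x + rng.standard_normal(200)
        res = fit_lm(y, x)
        b, se, p = ols_oracle(y, x)
        assert res.beta == pytest.approx(b, rel=1e-10)
        assert res.se == pytest.approx(se, rel=1e-10)
        assert res.pvalue == pytest.approx(p, rel=1e-10)

    def test_orthogonal_trait_gives_zero_beta_p_one(self):
        x = np.array([0.0, 1.0, 2.0] * 4)
        y = np.array([1.0, -2.0, 1.0] * 4)  # orthogonal to [1, x]
        res = fit_lm(y, x)
        assert res.beta == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_monomorphic_and_insufficient_flagged(self):
        res = fit_lm(np.arange(5.0), np.ones(5))
        assert res.pvalue is None and "monomorphic" in res.note
        res2 = fit_lm(np.array([1.0, 2.0]), np.array([0, 1]))
        assert res2.pvalue is None and "insufficient" in res2.note

    def test_missing_data_listwise_deletion(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 100).astype(np.int8)
        y = rng.standard_normal(100)
        xm = x.copy()
        xm[:10] = MISSING
        ym = y.copy()
        ym[90:] = np.nan
        res = fit_lm(ym, xm)
        ref = fit_lm(y[10:90], x[10:90])
        assert res.n_used == 80
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_nominal_rate_without_family_structure(self):
        """OLS is valid on unrelateds: ~5% rejections under the null."""
        ped = Pedigree([Individual(f"f{i}", "1") for i in range(300)])
        rng = np.random.default_rng(2)
        n_rej, reps = 0, 10_000
        for _ in range(reps):
            x = rng.binomial(2, 0.3, 300).astype(float)
            y = rng.standard_normal(300)
            if fit_lm(y, x).pvalue < 0.05:
                n_rej += 1
        rate = n_rej / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


# --------------------------------------------------------------- LME ----


def generic_ml_oracle(y, X, two_phi):
    """Nelder-Mead over (b0, b, log sg2, log se2) on the raw Gaussian
    likelihood with dense linear algebra."""
    n = len(y)

    def nll(th):
        b0, b, lsg, lse = th
        V = np.exp(lsg) * two_phi + np.exp(lse) * np.eye(n)
        r = y - X @ [b0, b]
        _, logdet = np.linalg.slogdet(V)
        return 0.5 * (logdet + r @ np.linalg.solve(V, r) + n * np.log(2 * np.pi))

    best = None
    for x0 in ([0, 0, -1, -1], [0, 0, -4, 0], [0, 0, 0, -4]):
        o = optimize.minimize(nll, x0, method="Nelder-Mead",
                              options={"xatol": 1e-11, "fatol": 1e-13,
                                       "maxiter": 8000})
        if best is None or o.fun < best.fun:
            best = o
    b0, b, lsg, lse = best.x
    V = np.exp(lsg) * two_phi + np.exp(lse) * np.eye(n)
    cov = np.linalg.inv(X.T @ np.linalg.solve(V, X))
    return b, float(np.sqrt(cov[1, 1])), np.exp(lsg), np.exp(lse)


def profile_grid_oracle(y, X, two_phi):
    """Iteratively refined grid over the heritability ratio with dense GLS."""
    n = len(y)
    eye = np.eye(n)

    def scan(grid):
        best = (-np.inf, None, None)
        for h in grid:
            V = (1 - h) * eye + h * two_phi
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ beta
            s2 = (r @ Vi @ r) / n
            _, logdet = np.linalg.slogdet(V)
            ll = -0.5 * (n * (np.log(2 * np.pi * s2) + 1) + logdet)
            if ll > best[0]:
                best = (ll, h, (beta[1], h * s2, (1 - h) * s2))
        return best

    lo, hi = 0.0, 0.9999
    for _ in range(5):
        grid = np.linspace(lo, hi, 401)
        _, h, out = scan(grid)
        step = grid[1] - grid[0]
        lo, hi = max(0.0, h - 2 * step), min(0.9999, h + 2 * step)
    return out


@pytest.fixture(scope="module")
def toy_fit():
    """A 21-individual mixed-template pedigree with a genuine polygenic
    signal, fitted once and reused across oracle comparisons."""
    ped = generate_pedigree_panel(5)
    kin = compute_kinship(ped)
    rng = np.random.default_rng(42)
    g = drop_genotypes(ped, 0.3, rng).counts[:, 0]
    y = simulate_trait(ped, kin, TraitModel(polygenic_h2=0.4), rng)
    res, vc = fit_lme(y, g, kin)
    X = np.column_stack([np.ones(len(y)), g.astype(float)])
    return y, g, X, 2 * kin.to_dense(), res, vc


class TestLME:
    def test_matches_generic_optimizer_oracle(self, toy_fit):
        y, g, X, two_phi, res, vc = toy_fit
        b, se, sg2, se2 = generic_ml_oracle(y, X, two_phi)
        assert res.beta == pytest.approx(b, rel=1e-5)
        assert res.se == pytest.approx(se, rel=1e-5)
        assert vc.sigma2_g == pytest.approx(sg2, rel=1e-4, abs=1e-8)
        assert vc.sigma2_e == pytest.approx(se2, rel=1e-4)

    def test_matches_profile_grid_oracle(self, toy_fit):
        y, g, X, two_phi, res, vc = toy_fit
        b, sg2, se2 = profile_grid_oracle(y, X, two_phi)
        assert res.beta == pytest.approx(b, rel=1e-4)
        assert vc.sigma2_g == pytest.approx(sg2, rel=1e-3, abs=1e-6)
        assert vc.sigma2_e == pytest.approx(se2, rel=1e-3)

    def test_singleton_families_reduce_to_ols(self):
        """With 2*Phi = I the mixed model collapses to least squares and the
        Wald p equals the generic ML oracle's to 6 significant digits."""
        ped = Pedigree([Individual(f"f{i}", "1") for i in range(80)])
        kin = compute_kinship(ped)
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, 80).astype(np.int8)
        y = rng.standard_normal(80)
        res, vc = fit_lme(y, g, kin)
        X = np.column_stack([np.ones(80), g.astype(float)])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert res.beta == pytest.approx(beta_ols, rel=1e-9)
        b, se, *_ = generic_ml_oracle(y, X, np.eye(80))
        p_oracle = stats.chi2.sf((b / se) ** 2, 1)
        assert res.pvalue == pytest.approx(p_oracle, rel=1e-6)

    def test_boundary_sigma_g_zero_allowed(self):
        """Independent data: the polygenic component may land on 0."""
        ped = generate_pedigree_panel(30, "sibship_2")
        kin = compute_kinship(ped)
        rng = np.random.default_rng(4)
        g = drop_genotypes(ped, 0.3, rng).counts[:, 0]
        y = rng.standard_normal(len(ped))  # iid: no familial correlation
        res, vc = fit_lme(y, g, kin)
        assert res.converged
        assert vc.sigma2_g >= 0.0
        assert vc.sigma2_e > 0.0

    def test_monomorphic_flagged(self, panel, panel_ctx):
        y = np.random.default_rng(5).standard_normal(len(panel))
        res, vc = fit_lme(y, np.zeros(len(panel), dtype=np.int8),
                          panel_ctx.kinship)
        assert res.pvalue is None and "monomorphic" in res.note

    def test_missing_genotypes_excluded(self, panel, panel_ctx):
        rng = np.random.default_rng(6)
        g = drop_genotypes(panel, 0.3, rng).counts[:, 0].copy()
        y = simulate_trait(panel, panel_ctx.kinship,
                           TraitModel(polygenic_h2=0.3), rng)
        g[:50] = MISSING
        res, _ = fit_lme(y, g, panel_ctx.kinship)
        assert res.n_used == len(panel) - 50
        assert res.pvalue is not None


# -------------------------------------------------------------- FBAT ----


def make_nuclear(genos_parents, n_kids_each):
    """Pedigree + genotype scaffold for explicit FBAT configurations."""
    inds, fams = [], []
    for k, _ in enumerate(genos_parents):
        fid = f"f{k}"
        inds.append(Individual(fid, "dad", sex=1))
        inds.append(Individual(fid, "mom", sex=2))
        for j in range(n_kids_each[k]):
            inds.append(Individual(fid, f"k{j}", "dad", "mom"))
    ped = Pedigree(inds)
    return ped, extract_nuclear_families(ped)


TRANSMIT = {0: [(0, 1.0)], 1: [(0, 0.5), (1, 0.5)], 2: [(1, 1.0)]}


def enumerate_s_distribution(parent_genos, kid_traits, offset=0.0):
    """Distribution of S over all Mendelian transmission outcomes.

    ``parent_genos[k] = (gf, gm)``; ``kid_traits[k]`` lists each child's
    phenotype.  Returns (values, probabilities) for S = sum T (X - E[X|P]).
    """
    per_kid = []
    for (gf, gm), traits in zip(parent_genos, kid_traits):
        e = (gf + gm) / 2.0
        for t in traits:
            opts = [
                (af + am, pf * pm)
                for af, pf in TRANSMIT[gf]
                for am, pm in TRANSMIT[gm]
            ]
            per_kid.append([( (t - offset) * (x - e), pr) for x, pr in opts])
    values, probs = [], []
    for combo in itertools.product(*per_kid):
        values.append(sum(c[0] for c in combo))
        probs.append(np.prod([c[1] for c in combo]))
    return np.array(values), np.array(probs)


class TestFBAT:
    def test_hand_worked_single_transmission(self):
        """Father Aa, mother aa, child Aa with T = 2: S = 1, V = 1, Z = 1."""
        ped, fams = make_nuclear([(1, 0)], [1])
        g = np.array([1, 0, 1], dtype=np.int8)
        y = np.array([np.nan, np.nan, 2.0])
        res = fbat_test(y, g, fams, offset=0.0)
        assert res.statistic == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(2 * stats.norm.sf(1.0), rel=1e-6)
        assert res.pvalue == pytest.approx(0.3173, abs=2e-4)
        assert res.n_used == 1

    def test_homozygous_parents_contribute_nothing(self):
        ped, fams = make_nuclear([(2, 0), (1, 1)], [1, 1])
        g = np.array([2, 0, 1, 1, 1, 2], dtype=np.int8)
        y = np.array([0, 0, 3.0, 0, 0, 1.5])
        res = fbat_test(y, g, fams, offset=0.0)
        # only the het x het family is informative
        assert res.n_used == 1
        v = 1.5**2 * 0.5  # T^2 * (1/4 + 1/4)
        s = 1.5 * (2 - 1.0)
        assert res.statistic == pytest.approx(s / np.sqrt(v))

    def test_null_moments_match_exhaustive_enumeration(self):
        """E[S] = 0 and Var[S] = V over every transmission outcome of four
        heterogeneous nuclear families."""
        parent_genos = [(1, 0), (1, 1), (2, 1), (1, 0)]
        kid_traits = [[1.2], [-0.7, 0.4], [2.1], [-1.5, 0.8]]
        ped, fams = make_nuclear(parent_genos, [len(t) for t in kid_traits])
        values, probs = enumerate_s_distribution(parent_genos, kid_traits)
        assert probs.sum() == pytest.approx(1.0)
        mean_s = values @ probs
        var_s = ((values - mean_s) ** 2) @ probs
        assert mean_s == pytest.approx(0.0, abs=1e-12)
        # realise one concrete outcome and recover V from the implementation
        rng = np.random.default_rng(7)
        geno = np.zeros(len(ped), dtype=np.int8)
        traits = np.full(len(ped), np.nan)
        i = 0
        s_obs = 0.0
        for (gf, gm), tr in zip(parent_genos, kid_traits):
            geno[i], geno[i + 1] = gf, gm
            e = (gf + gm) / 2
            for j, t in enumerate(tr):
                # options within TRANSMIT are equiprobable, so uniform choice
                af = TRANSMIT[gf][rng.integers(len(TRANSMIT[gf]))][0]
                am = TRANSMIT[gm][rng.integers(len(TRANSMIT[gm]))][0]
                x = af + am
                geno[i + 2 + j] = x
                traits[i + 2 + j] = t
                s_obs += t * (x - e)
            i += 2 + len(tr)
        res = fbat_test(traits, geno, fams, offset=0.0)
        v_impl = (s_obs / res.statistic) ** 2
        assert v_impl == pytest.approx(var_s, rel=1e-10)

    def test_allele_relabeling_flips_z(self, panel, panel_ctx):
        rng = np.random.default_rng(8)
        g = drop_genotypes(panel, 0.3, rng).counts[:, 0]
        y = simulate_trait(panel, panel_ctx.kinship,
                           TraitModel(polygenic_h2=0.3), rng)
        res = fbat_test(y, g, panel_ctx.layout)
        flipped = fbat_test(y, (2 - g).astype(np.int8), panel_ctx.layout)
        assert flipped.statistic == pytest.approx(-res.statistic)
        assert flipped.pvalue == pytest.approx(res.pvalue)

    def test_non_informative_when_all_parents_homozygous(self):
        ped, fams = make_nuclear([(0, 0), (2, 2)], [2, 1])
        g = np.array([0, 0, 0, 0, 2, 2, 2], dtype=np.int8)
        y = np.ones(len(ped))
        res = fbat_test(y, g, fams, offset=0.0)
        assert res.pvalue is None
        assert "non-informative" in res.note

    def test_offspring_with_missing_data_skipped_family_retained(self):
        ped, fams = make_nuclear([(1, 1)], [2])
        g = np.array([1, 1, 1, MISSING], dtype=np.int8)
        y = np.array([np.nan, np.nan, 1.0, 5.0])
        res = fbat_test(y, g, fams, offset=0.0)
        # second child excluded, first still informative
        assert res.n_used == 1
        assert res.statistic == pytest.approx(1.0 * (1 - 1.0) / np.sqrt(0.5))

    def test_mean_offset_default_centres_offspring(self, panel, panel_ctx):
        rng = np.random.default_rng(9)
        g = drop_genotypes(panel, 0.3, rng).counts[:, 0]
        y = simulate_trait(panel, panel_ctx.kinship, TraitModel(), rng)
        lay = panel_ctx.layout
        mean_off = float(np.mean(y[lay.offspring]))
        assert fbat_test(y, g, lay).statistic == pytest.approx(
            fbat_test(y, g, lay, offset=mean_off).statistic
        )
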