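"""Monte-Carlo drivers for type I error, power, and statistic-correlation
studies of the association engines and the staged pipelines.

The synthetic pedigree panel stands in for a large family cohort: a mixture
of trios, two-child nuclear families and three-generation families.  Rates
are always reported with their binomial standard errors, and every replicate
draws its generator from ``base_seed + replicate_index`` so runs are
reproducible and resumable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import FbatLayout, fbat_test, fit_lm, fit_lme
from .genotypes import (
    AdmixtureDesign,
    GenotypeMatrix,
    LDPairDesign,
    balding_nichols_freqs,
    drop_genotypes,
    drop_ld_pair,
    drop_admixture_genotypes,
    subpop_assignment,
    _drop_alleles,
    _founder_indices,
)
from .pedigree import (
    Individual,
    KinshipMatrix,
    Pedigree,
    compute_kinship,
    extract_nuclear_families,
)
from .phenotypes import TraitModel, apply_admixture_offset, simulate_trait
from .pipeline import StageConfig

__all__ = [
    "SimExperiment",
    "SimReport",
    "generate_pedigree_panel",
    "default_panel",
    "estimate_type1_error",
    "estimate_power",
    "fbat_lme_correlation",
    "estimate_admixture_rates",
]

DEFAULT_MIX = {"trio": 0.4, "sibship_2": 0.4, "three_gen": 0.2}


def _family(template: str, fam_id: str) -> list[Individual]:
    """One family's individuals for a structure template."""
    if template == "trio":
        template = "sibship_1"
    if template.startswith("sibship_"):
        k = int(template.split("_", 1)[1])
        if k < 1:
            raise ValueError(f"sibship size must be >= 1, got {k}")
        inds = [
            Individual(fam_id, "1", sex=1),
            Individual(fam_id, "2", sex=2),
        ]
        inds += [
            Individual(fam_id, str(3 + j), father_id="1", mother_id="2")
            for j in range(k)
        ]
        return inds
    if template == "three_gen":
        return [
            Individual(fam_id, "1", sex=1),                       # grandfather
            Individual(fam_id, "2", sex=2),                       # grandmother
            Individual(fam_id, "3", "1", "2", sex=1),             # father
            Individual(fam_id, "4", "1", "2", sex=2),             # aunt
            Individual(fam_id, "5", sex=2),                       # mother (married in)
            Individual(fam_id, "6", "3", "5"),                    # grandchild
            Individual(fam_id, "7", "3", "5"),                    # grandchild
        ]
    raise ValueError(
        f"unknown pedigree template {template!r}; "
        "use 'trio', 'sibship_<k>' or 'three_gen'"
    )


def generate_pedigree_panel(
    n_families: int,
    templates: str | dict[str, float] = DEFAULT_MIX,
    rng: np.random.Generator | None = None,
) -> Pedigree:
    """Deterministic pedigree collection from a template or template mixture.

    ``templates`` is one template name or a proportion mapping; family counts
    per template follow largest-remainder apportionment, so the panel is
    reproducible without randomness (``rng`` accepted for interface symmetry).
    Templates are interleaved across family order so downstream alternating
    subpopulation assignment stays balanced within each structure type.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if isinstance(templates, str):
        templates = {templates: 1.0}
    names = sorted(templates)
    props = np.array([templates[t] for t in names], dtype=float)
    if (props < 0).any() or props.sum() <= 0:
        raise ValueError("template proportions must be nonnegative, not all zero")
    props = props / props.sum()
    exact = props * n_families
    counts = np.floor(exact).astype(int)
    for k in np.argsort(-(exact - counts))[: n_families - counts.sum()]:
        counts[k] += 1
    # interleave: assign each family slot the template furthest behind quota
    inds: list[Individual] = []
    assigned = np.zeros(len(names), dtype=int)
    for i in range(n_families):
        deficit = counts * (i + 1) / n_families - assigned
        k = int(np.argmax(np.where(assigned < counts, deficit, -np.inf)))
        assigned[k] += 1
        inds.extend(_family(names[k], f"F{i + 1}"))
    return Pedigree(inds)


def default_panel(n_families: int = 500) -> Pedigree:
    """The study panel: 40% trios, 40% two-child sibships, 20% three-generation."""
    return generate_pedigree_panel(n_families, DEFAULT_MIX)


@dataclass
class SimExperiment:
    """A replicated simulation design on a fixed pedigree panel."""

    pedigree: Pedigree
    trait_model: TraitModel
    n_replicates: int
    maf: float = 0.1
    alpha: float = 0.05
    seed: int = 0

    def rng(self, replicate: int) -> np.random.Generator:
        return np.random.default_rng(self.seed + replicate)


@dataclass
class SimReport:
    """Rates with binomial standard errors plus raw per-replicate records."""

    table: pd.DataFrame
    n_replicates: int
    seed: int
    records: pd.DataFrame | None = None


def _rate_row(method: str, rejected: np.ndarray, tested: np.ndarray,
              alpha: float) -> dict:
    n = int(tested.sum())
    r = float(rejected[tested].mean()) if n else float("nan")
    se = float(np.sqrt(r * (1 - r) / n)) if n else float("nan")
    return {"method": method, "alpha": alpha, "rate": r, "se": se, "n": n}


class _PanelContext:
    """Everything reusable across replicates on one panel."""

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.kinship = compute_kinship(ped)
        self.kinship.eigen2phi  # warm caches
        self.kinship.chol2phi
        self.layout = FbatLayout(extract_nuclear_families(ped))


def estimate_type1_error(
    exp: SimExperiment,
    methods: tuple[str, ...] = ("LM", "LME", "FBAT", "two_stage"),
    alpha1: float = 0.1,
    qtl_maf: float | None = None,
    context: _PanelContext | None = None,
) -> SimReport:
    """Null rejection rates per method at ``exp.alpha``.

    The tested SNP is always null.  If ``exp.trait_model.q2 > 0`` an
    independent, unlinked QTL (MAF ``qtl_maf`` or the trait model's design
    frequency) feeds the trait, emulating unexplained major-locus variance.
    ``two_stage`` rejects when the LM screen at ``alpha1`` passes and the
    LME p-value falls below ``exp.alpha``.
    """
    ctx = context or _PanelContext(exp.pedigree)
    model = exp.trait_model
    need_lme = bool({"LME", "two_stage"} & set(methods))
    recs = []
    for i in range(exp.n_replicates):
        rng = exp.rng(i)
        g = drop_genotypes(ctx.ped, exp.maf, rng).counts[:, 0]
        qtl = None
        if model.q2 > 0:
            qmaf = qtl_maf if qtl_maf is not None else model.qtl_allele_freq
            qtl = drop_genotypes(ctx.ped, qmaf, rng).counts[:, 0]
        y = simulate_trait(ctx.ped, ctx.kinship, model, rng, qtl=qtl)
        rec = {"replicate": i}
        if "LM" in methods or need_lme:
            rec["lm_pvalue"] = fit_lm(y, g).pvalue
        if need_lme:
            rec["lme_pvalue"] = fit_lme(y, g, ctx.kinship)[0].pvalue
        if "FBAT" in methods:
            rec["fbat_pvalue"] = fbat_test(y, g, ctx.layout).pvalue
        recs.append(rec)
    records = pd.DataFrame(recs).astype(float)
    rows = []
    for m in methods:
        if m == "two_stage":
            lm = records["lm_pvalue"].to_numpy()
            lme = records["lme_pvalue"].to_numpy()
            tested = np.isfinite(lm)
            rej = np.isfinite(lm) & (lm < alpha1) & np.isfinite(lme) & (lme < exp.alpha)
        else:
            p = records[f"{m.lower()}_pvalue"].to_numpy()
            tested = np.isfinite(p)
            rej = tested & (p < exp.alpha)
        rows.append(_rate_row(m, rej, tested, exp.alpha))
    return SimReport(pd.DataFrame(rows), exp.n_replicates, exp.seed, records)


def estimate_power(
    exp: SimExperiment,
    r2_levels: tuple[float, ...] = (0.5, 0.8, 1.0),
    methods: tuple[str, ...] = ("LM", "LME", "FBAT", "two_stage"),
    marker_freq: float | None = None,
    alpha1: float = 0.1,
    context: _PanelContext | None = None,
) -> SimReport:
    """Power to detect a marker in LD with the causal QTL, per r-squared level.

    The QTL (trait model's design frequency, variance fraction q2) and marker
    (``marker_freq``, default the QTL frequency) are gene-dropped as
    haplotypes; each method tests the MARKER.
    """
    if exp.trait_model.q2 <= 0:
        raise ValueError("power study needs trait_model.q2 > 0")
    ctx = context or _PanelContext(exp.pedigree)
    model = exp.trait_model
    pb = marker_freq if marker_freq is not None else model.qtl_allele_freq
    rows, recs = [], []
    for r2 in r2_levels:
        design = LDPairDesign(model.qtl_allele_freq, pb, r2)
        rej = {m: [] for m in methods}
        for i in range(exp.n_replicates):
            rng = exp.rng(i)
            pair = drop_ld_pair(ctx.ped, design, rng)
            qtl, marker = pair.counts[:, 0], pair.counts[:, 1]
            y = simulate_trait(ctx.ped, ctx.kinship, model, rng, qtl=qtl)
            lm_p = fit_lm(y, marker).pvalue
            lme_p = (
                fit_lme(y, marker, ctx.kinship)[0].pvalue
                if {"LME", "two_stage"} & set(methods)
                else None
            )
            for m in methods:
                if m == "LM":
                    p, extra = lm_p, True
                elif m == "LME":
                    p, extra = lme_p, True
                elif m == "FBAT":
                    p, extra = fbat_test(y, marker, ctx.layout).pvalue, True
                elif m == "two_stage":
                    p = lme_p
                    extra = lm_p is not None and lm_p < alpha1
                rej[m].append(p is not None and extra and p < exp.alpha)
            recs.append({"r2": r2, "replicate": i, "lm_pvalue": lm_p,
                         "lme_pvalue": lme_p})
        for m in methods:
            v = np.asarray(rej[m], dtype=bool)
            row = _rate_row(m, v, np.ones_like(v, dtype=bool), exp.alpha)
            row["r2"] = r2
            rows.append(row)
    return SimReport(pd.DataFrame(rows), exp.n_replicates, exp.seed,
                     pd.DataFrame(recs))


DEFAULT_BINS = (0.01, 0.05, 0.1, 0.2, 0.3)


def fbat_lme_correlation(
    exp: SimExperiment,
    bin_edges: tuple[float, ...] = DEFAULT_BINS,
    min_bin: int = 10,
    context: _PanelContext | None = None,
) -> SimReport:
    """Correlation between signed FBAT and LME statistics under the null,
    within bins of the LME two-sided p-value.

    Per replicate the signed statistics are FBAT's Z and sign(beta) times the
    square root of the LME Wald chi-square; bins with fewer than ``min_bin``
    replicates are reported as NaN.
    """
    if exp.trait_model.q2 != 0:
        raise ValueError("correlation study is defined under the null (q2 = 0)")
    ctx = context or _PanelContext(exp.pedigree)
    recs = []
    for i in range(exp.n_replicates):
        rng = exp.rng(i)
        g = drop_genotypes(ctx.ped, exp.maf, rng).counts[:, 0]
        y = simulate_trait(ctx.ped, ctx.kinship, exp.trait_model, rng)
        lme, _ = fit_lme(y, g, ctx.kinship)
        fb = fbat_test(y, g, ctx.layout)
        if lme.pvalue is None or fb.pvalue is None:
            continue
        z_lme = np.sign(lme.beta) * np.sqrt(lme.statistic)
        recs.append({"replicate": i, "lme_pvalue": lme.pvalue,
                     "z_lme": z_lme, "z_fbat": fb.statistic})
    records = pd.DataFrame(recs)
    edges = (0.0, *bin_edges, 1.0000001)
    labels = [f"<{bin_edges[0]}"] + [
        f"[{a}-{b})" for a, b in zip(bin_edges[:-1], bin_edges[1:])
    ] + [f">{bin_edges[-1]}"]
    rows = []
    idx = np.digitize(records["lme_pvalue"], edges) - 1
    for k, lab in enumerate(labels):
        sel = records[idx == k]
        if len(sel) < min_bin:
            rows.append({"bin": lab, "correlation": float("nan"), "n": len(sel)})
        else:
            c = float(np.corrcoef(sel["z_fbat"], sel["z_lme"])[0, 1])
            rows.append({"bin": lab, "correlation": c, "n": len(sel)})
    return SimReport(pd.DataFrame(rows), exp.n_replicates, exp.seed, records)


def _drop_ld_pair_admixed(
    ped: Pedigree, r2: float, design: AdmixtureDesign,
    labels: np.ndarray, rng: np.random.Generator,
) -> GenotypeMatrix:
    """QTL/marker haplotype drop where each subpopulation's founders use their
    own Balding-Nichols frequency for both loci."""
    p1, p2 = balding_nichols_freqs(design.base_freq, design.fst, rng)
    fidx = _founder_indices(ped)
    founder_sub = labels[fidx]
    table = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
    cats = np.empty((len(fidx), 2), dtype=np.intp)
    for sub, p in ((1, p1), (2, p2)):
        h = LDPairDesign(p, p, r2).haplotype_freqs()
        m = founder_sub == sub
        cats[m] = rng.choice(4, size=(int(m.sum()), 2), p=h)
    haps = _drop_alleles(ped, table[cats], rng)
    return GenotypeMatrix(haps.sum(axis=1, dtype=np.int8), ["qtl", "marker"],
                          ped.ids)


def estimate_admixture_rates(
    exp: SimExperiment,
    design: AdmixtureDesign,
    n_snps: int = 100,
    r2: float | None = None,
    cfg: StageConfig = StageConfig(),
    context: _PanelContext | None = None,
) -> SimReport:
    """False-positive (q2 = 0) or power (q2 > 0 with an LD marker) rates under
    two-subpopulation stratification.

    Per replicate an ``n_snps`` admixture panel is simulated; with ``r2`` set
    and q2 > 0, a QTL/marker pair is appended and the marker is the detection
    target.  The trait receives the subpopulation offset ``design.delta``.
    Reported rates:

    * per-SNP pooled rejection rates for LM/LME/FBAT at ``exp.alpha`` over the
      null admixture SNPs (or the marker's rejection rate when ``r2`` is set);
    * by-replicate rates: any SNP significant under the three-stage pipeline
      (``cfg``), and any LM/LME/FBAT p-value below ``cfg.alpha2``.
    """
    ctx = context or _PanelContext(exp.pedigree)
    model = exp.trait_model
    if r2 is not None and model.q2 <= 0:
        raise ValueError("marker power run needs trait_model.q2 > 0")
    labels = subpop_assignment(ctx.ped)
    per_snp = {"LM": [], "LME": [], "FBAT": []}
    by_rep = {"LM": [], "LME": [], "FBAT": [], "two_stage": [], "three_stage": []}
    marker_sig = {"LM": [], "LME": [], "FBAT": [], "three_stage": []}
    for i in range(exp.n_replicates):
        rng = exp.rng(i)
        panel, _ = drop_admixture_genotypes(ctx.ped, design, n_snps, rng)
        cols = [panel.counts[:, j] for j in range(n_snps)]
        qtl = None
        if r2 is not None:
            pair = _drop_ld_pair_admixed(ctx.ped, r2, design, labels, rng)
            qtl = pair.counts[:, 0]
            cols.append(pair.counts[:, 1])
        y0 = simulate_trait(ctx.ped, ctx.kinship, model, rng, qtl=qtl)
        y = apply_admixture_offset(y0, labels, design.delta)
        lm_p, lme_p, fb_p = [], [], []
        for x in cols:
            pl = fit_lm(y, x).pvalue
            lm_p.append(np.nan if pl is None else pl)
            if pl is not None and pl < cfg.alpha1:
                pm = fit_lme(y, x, ctx.kinship)[0].pvalue
            else:
                pm = None
            lme_p.append(np.nan if pm is None else pm)
            pf = fbat_test(y, x, ctx.layout).pvalue
            fb_p.append(np.nan if pf is None else pf)
        lm_p, lme_p, fb_p = map(np.asarray, (lm_p, lme_p, fb_p))
        stage3 = np.isfinite(lme_p) & (lme_p < cfg.alpha2)
        n3 = int(stage3.sum())
        adj = np.where(stage3 & np.isfinite(fb_p),
                       np.minimum(1.0, n3 * fb_p), np.nan)
        sig3 = np.isfinite(adj) & (adj <= cfg.alpha3_family)
        null_slice = slice(0, n_snps)
        for name, p in (("LM", lm_p), ("LME", lme_p), ("FBAT", fb_p)):
            pn = p[null_slice]
            per_snp[name].extend((pn[np.isfinite(pn)] < exp.alpha).tolist())
            by_rep[name].append(bool(np.any(pn[np.isfinite(pn)] < cfg.alpha2)))
        by_rep["two_stage"].append(bool(np.any(
            np.isfinite(lme_p[null_slice]) & (lme_p[null_slice] < cfg.alpha2))))
        by_rep["three_stage"].append(bool(sig3[null_slice].any()))
        if r2 is not None:
            marker_sig["LM"].append(bool(np.isfinite(lm_p[-1]) and lm_p[-1] < cfg.alpha2))
            marker_sig["LME"].append(bool(np.isfinite(lme_p[-1]) and lme_p[-1] < cfg.alpha2))
            marker_sig["FBAT"].append(bool(np.isfinite(fb_p[-1]) and fb_p[-1] < cfg.alpha2))
            marker_sig["three_stage"].append(bool(sig3[-1]))
    rows = []
    for m, v in per_snp.items():
        v = np.asarray(v, dtype=bool)
        row = _rate_row(m, v, np.ones_like(v, dtype=bool), exp.alpha)
        row["scope"] = "per_snp"
        rows.append(row)
    for m, v in by_rep.items():
        v = np.asarray(v, dtype=bool)
        row = _rate_row(m, v, np.ones_like(v, dtype=bool), cfg.alpha2)
        row["scope"] = "by_replicate"
        rows.append(row)
    if r2 is not None:
        for m, v in marker_sig.items():
            v = np.asarray(v, dtype=bool)
            row = _rate_row(m, v, np.ones_like(v, dtype=bool), cfg.alpha2)
            row["scope"] = "marker_power"
            row["r2"] = r2
            rows.append(row)
    return SimReport(pd.DataFrame(rows), exp.n_replicates, exp.seed)
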