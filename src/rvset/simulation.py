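"""Synthetic rare-variant data and the type-I-error / power study harnesses.

The generator emulates exome-sequencing-like genotype matrices: independent
bi-allelic variants whose MAF spectrum is dominated by singletons and other
ultra-rare alleles, hard-call dosages drawn as Binomial(2, MAF), and
functional annotations (lof / missense / synonymous) assigned at configurable
proportions.  Binary phenotypes follow a logistic model whose intercept is
solved numerically so the marginal prevalence matches the target; causal
architectures are controlled by the causal proportion, a MAF-dependent
effect-size model and the fraction of positive effect signs.

Two harnesses mirror the standard evaluation designs: a null study measuring
empirical type I error, genomic-control lambda and Q-Q behaviour of each
pipeline, and a power study comparing pipelines across causal scenarios at a
configurable significance threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy import stats

from .aggregation import combine_gene
from .collapsing import WeightScheme
from .null_model import fit_null_glm
from .reporting import lambda_gc, qq_points
from .set_tests import run_gene
from .variant_io import Annotation, GeneVariantSet, MaskSpec, Variant

logger = logging.getLogger(__name__)

TEST_TYPES = ("burden", "skat", "skato")


@dataclass
class SimConfig:
    """Study conditions for one simulation scenario.

    Defaults are the desk-scale analogue of a biobank null study: 10,000
    samples, 200 variants per gene, a singleton-heavy ("wes_like") MAF
    spectrum and 10% phenotype prevalence.
    """

    n_samples: int = 10_000
    n_variants: int = 200
    maf_spectrum: str | float = "wes_like"
    prevalence: float = 0.1
    case_control_ratio: str | None = None  # "1:r" overrides prevalence
    causal_prop: float = 0.0
    effect_model: str = "maf_log"  # |beta| = effect_c * |log10 maf|
    effect_c: float = 0.0
    sign_mix: float = 1.0  # fraction of causal effects with positive sign
    n_replicates: int = 100
    seed: int = 0
    anno_props: tuple[float, float, float] = (0.1, 0.6, 0.3)  # lof/mis/syn
    causal_annotations: tuple[str, ...] | None = None
    causal_max_maf: float | None = None
    covariate_effect: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0,1)")
        for name in ("causal_prop", "sign_mix"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")
        if self.case_control_ratio is not None:
            one, r = self.case_control_ratio.split(":")
            if float(one) != 1:
                raise ValueError("case_control_ratio must be of the form '1:r'")
            self.prevalence = 1.0 / (1.0 + float(r))
        if abs(sum(self.anno_props) - 1.0) > 1e-9:
            raise ValueError("anno_props must sum to 1")

    def target_prevalence(self) -> float:
        return self.prevalence


@dataclass
class StudyReport:
    """Empirical rates, genomic-control lambda and Q-Q data per pipeline."""

    kind: str  # "type1" or "power"
    alphas: tuple[float, ...]
    n_tests: dict
    rates: dict  # pipeline -> test -> alpha(str) -> [rate, ci_lo, ci_hi]
    lambda_gc: dict  # pipeline -> test -> float
    qq: dict  # pipeline -> test -> [[expected...],[observed...]] (thinned)
    median_chisq: dict
    config: dict

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


@dataclass
class Pipeline:
    """One analysis configuration run inside a study."""

    name: str
    mac_threshold: float = 10.0
    scheme: WeightScheme = field(default_factory=WeightScheme)
    masks: list[MaskSpec] | None = None  # None -> use the study's mask list

    @classmethod
    def with_collapse(cls, masks=None) -> "Pipeline":
        return cls(name="with-collapse", mac_threshold=10.0, masks=masks)

    @classmethod
    def without_collapse(cls, masks=None) -> "Pipeline":
        # threshold 0 keeps every polymorphic variant as its own marker
        return cls(name="without-collapse", mac_threshold=0.0, masks=masks)


# ---------------------------------------------------------------------------
# generators


def _draw_mafs(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    n2 = 2.0 * cfg.n_samples
    if isinstance(cfg.maf_spectrum, (int, float)):
        return np.full(cfg.n_variants, float(cfg.maf_spectrum))
    if cfg.maf_spectrum == "wes_like":
        # 80% of mass in the ultra-rare range (expected MAC <= ~8),
        # the rest log-uniform up to 1%
        ultra = rng.random(cfg.n_variants) < 0.8
        lo, hi = 0.25 / n2, 8.0 / n2
        hi2 = max(0.01, 20.0 / n2)  # keep the range valid at tiny N
        maf = np.where(
            ultra,
            np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_variants)),
            np.exp(rng.uniform(np.log(10.0 / n2), np.log(hi2), cfg.n_variants)),
        )
        return np.minimum(maf, 0.5)
    if cfg.maf_spectrum == "uniform_log":
        return np.exp(rng.uniform(np.log(1.0 / n2), np.log(0.05), cfg.n_variants))
    raise ValueError(f"unknown maf_spectrum {cfg.maf_spectrum!r}")


def simulate_genotypes(cfg: SimConfig, seed=None, gene_id: str = "simgene") -> GeneVariantSet:
    """Draw one gene's hard-call genotype matrix.

    Variants are independent; dosages are Binomial(2, MAF).  Monomorphic
    draws are redrawn up to 10 times, then dropped.  Deterministic given
    (config, seed)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    maf = _draw_mafs(rng, cfg)
    n = cfg.n_samples
    # equivalent to per-sample Binomial(2, maf) draws, but sampled by allele
    # copy: the total count is Binomial(2n, maf) and the carrying chromosomes
    # are uniform without replacement — fast for the rare-variant regime
    dosage = np.zeros((n, cfg.n_variants))
    for j in range(cfg.n_variants):
        k = 0
        for _ in range(10):
            k = int(rng.binomial(2 * n, maf[j]))
            if k > 0:
                break
        if k == 0:
            continue
        slots = rng.choice(2 * n, size=min(k, 2 * n), replace=False)
        np.add.at(dosage[:, j], slots // 2, 1.0)
    keep = dosage.sum(axis=0) > 0
    if not keep.any():
        raise ValueError("all simulated variants monomorphic; config infeasible")
    dosage, maf = dosage[:, keep], maf[keep]
    m = dosage.shape[1]
    anno_classes = (Annotation.LOF, Annotation.MISSENSE, Annotation.SYNONYMOUS)
    annos = [anno_classes[i] for i in rng.choice(3, size=m, p=list(cfg.anno_props))]
    variants = [
        Variant(variant_id=f"1:{j + 1}:A:T", chrom="1", pos=j + 1, annotation=annos[j])
        for j in range(m)
    ]
    # flip any column drifting past 0.5 (possible for degenerate spectra)
    mac = dosage.sum(axis=0)
    flip = mac / (2 * n) > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]
    return GeneVariantSet(gene_id=gene_id, dosage=dosage, variants=variants,
                          sample_ids=[f"s{i}" for i in range(n)])


def _solve_intercept(fixed: np.ndarray, target: float) -> float:
    """Bisection for the logistic intercept giving marginal prevalence."""
    lo, hi = -30.0, 10.0
    if expit(lo + fixed).mean() > target or expit(hi + fixed).mean() < target:
        raise ValueError("target prevalence unattainable with these effects")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + fixed).mean() < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    a0 = 0.5 * (lo + hi)
    if abs(expit(a0 + fixed).mean() - target) > 1e-3:
        raise ValueError("prevalence solver did not reach the target within 0.001")
    return a0


def simulate_phenotype(gvs: GeneVariantSet, cfg: SimConfig, null: bool = True,
                       seed=None):
    """Binary phenotype and covariates for one replicate.

    ``logit P(y=1) = a0 + X g + sum_causal beta_j g_j`` with the intercept
    solved so the marginal prevalence hits the configured target within
    0.001.  ``null=True`` forces all genetic effects to zero.  Returns
    ``(y, X, causal_index)``."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = gvs.n_samples
    X = rng.standard_normal(n)
    fixed = cfg.covariate_effect * X
    causal = np.array([], dtype=int)
    if not null and cfg.causal_prop > 0 and cfg.effect_c != 0:
        qual = np.ones(gvs.n_variants, dtype=bool)
        if cfg.causal_annotations is not None:
            allowed = {Annotation(a) for a in cfg.causal_annotations}
            qual &= np.array([v.annotation in allowed for v in gvs.variants])
        if cfg.causal_max_maf is not None:
            qual &= gvs.maf <= cfg.causal_max_maf
        qual_idx = np.flatnonzero(qual)
        n_causal = int(round(cfg.causal_prop * qual_idx.size))
        if n_causal > 0:
            causal = rng.choice(qual_idx, size=n_causal, replace=False)
            if cfg.effect_model == "maf_log":
                beta = cfg.effect_c * np.abs(np.log10(gvs.maf[causal]))
            elif cfg.effect_model == "constant":
                beta = np.full(causal.size, cfg.effect_c)
            else:
                raise ValueError(f"unknown effect_model {cfg.effect_model!r}")
            sign = np.where(rng.random(causal.size) < cfg.sign_mix, 1.0, -1.0)
            fixed = fixed + gvs.dosage[:, causal] @ (beta * sign)
    a0 = _solve_intercept(fixed, cfg.target_prevalence())
    y = (rng.random(n) < expit(a0 + fixed)).astype(float)
    if y.sum() == 0 or y.sum() == n:
        # pathological draw at tiny N; flip one sample to keep the GLM defined
        y[int(rng.integers(n))] = 1.0 - y[int(rng.integers(n))]
    return y, X, causal


# ---------------------------------------------------------------------------
# study harnesses


def _binom_ci(k: int, n: int) -> tuple[float, float]:
    """Normal-approximation 95% binomial CI for a proportion."""
    if n == 0:
        return (0.0, 0.0)
    p = k / n
    half = 1.96 * np.sqrt(max(p * (1 - p), 1e-300) / n)
    return (max(p - half, 0.0), min(p + half, 1.0))


def _collect_report(kind, alphas, pvals, config) -> StudyReport:
    rates, lam, qq, med, n_tests = {}, {}, {}, {}, {}
    for pname, per_test in pvals.items():
        rates[pname], lam[pname], qq[pname], med[pname], n_tests[pname] = {}, {}, {}, {}, {}
        for tname, ps in per_test.items():
            ps = np.asarray(ps, dtype=float)
            n_tests[pname][tname] = int(ps.size)
            rates[pname][tname] = {}
            for a in alphas:
                k = int((ps < a).sum())
                lo, hi = _binom_ci(k, ps.size)
                rates[pname][tname][str(a)] = [k / ps.size if ps.size else 0.0, lo, hi]
            if ps.size:
                lam[pname][tname] = lambda_gc(np.clip(ps, 1e-300, 1.0))
                pts = qq_points(np.clip(ps, 1e-300, 1.0))
                step = max(1, len(pts) // 500)  # thin for the report
                thinned = pts[::step]
                qq[pname][tname] = [[e for e, _ in thinned], [o for _, o in thinned]]
                med[pname][tname] = float(np.median(stats.chi2.isf(np.clip(ps, 1e-300, 1), 1)))
    return StudyReport(kind=kind, alphas=tuple(alphas), n_tests=n_tests,
                       rates=rates, lambda_gc=lam, qq=qq, median_chisq=med,
                       config=config)


def _run_study(cfg: SimConfig, pipelines: Sequence[Pipeline], masks: list[MaskSpec],
               null: bool, genes_per_replicate: int, aggregate: bool):
    pvals = {p.name: {t: [] for t in TEST_TYPES} for p in pipelines}
    for rep in range(cfg.n_replicates):
        rep_ss = np.random.SeedSequence([cfg.seed, rep])
        gene_seeds = rep_ss.spawn(genes_per_replicate + 1)
        gvs0 = simulate_genotypes(cfg, seed=gene_seeds[0], gene_id=f"g{rep}_0")
        y, X, _ = simulate_phenotype(gvs0, cfg, null=null,
                                     seed=np.random.SeedSequence([cfg.seed, rep, 7]))
        fit = fit_null_glm(y, X, "binary")
        genes = [gvs0] + [
            simulate_genotypes(cfg, seed=gene_seeds[j], gene_id=f"g{rep}_{j}")
            for j in range(1, genes_per_replicate)
        ]
        for gvs in genes:
            for pipe in pipelines:
                pmasks = pipe.masks if pipe.masks is not None else masks
                cells = run_gene(fit, gvs, pmasks, pipe.scheme, pipe.mac_threshold)
                if not cells:
                    continue
                for t in TEST_TYPES:
                    if aggregate:
                        pvals[pipe.name][t].append(combine_gene(cells, t).p_combined)
                    else:
                        pvals[pipe.name][t].extend(getattr(c, f"p_{t}") for c in cells)
    return pvals


def run_type1_study(
    cfg: SimConfig,
    pipelines: Sequence[Pipeline],
    masks: list[MaskSpec] | None = None,
    genes_per_replicate: int = 20,
    alphas: Sequence[float] = (0.05, 0.01),
    aggregate: bool = False,
) -> StudyReport:
    """Null study: phenotypes with no genetic effect, many independent genes.

    Each replicate draws one phenotype and ``genes_per_replicate`` genes; all
    pipelines test the same data.  Reports per-pipeline empirical type I
    error with 95% binomial CIs, genomic-control lambda and Q-Q points."""
    if masks is None:
        masks = [MaskSpec(frozenset({Annotation.LOF, Annotation.MISSENSE,
                                     Annotation.SYNONYMOUS}), 0.0001)]
    names = {p.name for p in pipelines}
    if len(names) != len(list(pipelines)):
        raise ValueError("pipeline names must be unique")
    pvals = _run_study(cfg, pipelines, masks, null=True,
                       genes_per_replicate=genes_per_replicate, aggregate=aggregate)
    return _collect_report("type1", tuple(alphas), pvals, asdict(cfg))


def run_power_study(
    cfgs: Sequence[SimConfig],
    pipelines: Sequence[Pipeline],
    masks: list[MaskSpec] | None = None,
    alpha: float = 1e-3,
    aggregate: bool = True,
) -> list[StudyReport]:
    """Power study over causal scenarios.

    Each config is one scenario (causal proportion / effect size / sign mix);
    per replicate one gene is drawn, the phenotype depends on its causal
    variants, and each pipeline produces one gene-level p-value (Cauchy- or
    min-P-combined over its mask grid).  Power is the fraction below
    ``alpha``; the median chi-square statistic is reported alongside."""
    if masks is None:
        masks = [MaskSpec(frozenset({Annotation.LOF, Annotation.MISSENSE,
                                     Annotation.SYNONYMOUS}), 0.01)]
    reports = []
    for cfg in cfgs:
        pvals = _run_study(cfg, pipelines, masks, null=False,
                           genes_per_replicate=1, aggregate=aggregate)
        reports.append(_collect_report("power", (alpha,), pvals, asdict(cfg)))
    return reports
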