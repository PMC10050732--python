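"""Synthetic two-sample GWAS generator with known causal ground truth.

Two disjoint cohorts are simulated from the same LD structure: an exposure
cohort with a continuous, unit-variance exposure driven additively by the
SNPs (plus a shared confounder), and an outcome cohort whose binary status
arises from a liability-threshold (probit) model
``L = beta * X + G alpha + c U + e`` with the case threshold set by the
target prevalence.  Per-SNP GWAS fits (OLS for the exposure, logistic
regression for the outcome) then produce summary statistics in exactly the
format :mod:`mrkit.gwas_io` reads, so every estimator can be exercised
end-to-end against a known truth without any external download.

Genotypes come from a Gaussian copula: haplotype alleles are thresholded
correlated normals (AR(1) within blocks), dosage = sum of two independent
haplotypes.  This gives direct control of the LD matrix the estimators
consume; the *dosage-scale* LD implied by the latent correlation is
computed exactly (bivariate-normal orthant probabilities) and returned as
part of the truth.

Because the outcome GWAS is logistic while the causal effect acts on the
liability scale, the per-SNP log-odds the GWAS estimates is not the
liability coefficient itself.  The truth object therefore also carries the
*pseudo-true* per-SNP logistic slopes (the large-sample values of the
logistic fits) and their pooled IVW value — the quantity a consistent
summary-statistic MR estimator converges to — computed semi-analytically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .gwas_io import (
    LdMatrix,
    ValidationError,
    VariantAssociation,
    write_ld_matrix,
    write_summary_stats,
)

log = logging.getLogger(__name__)

# Non-palindromic allele pairs cycled over synthetic SNPs.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic two-sample MR study.

    Defaults emulate a cis-instrument MR of a cortisol-like exposure on a
    common binary disease at desk scale: three instruments in one AR(1) LD
    block, strong instruments (expected first-stage F well above 30), a
    moderate shared confounder, and a case fraction of 0.381.
    """

    seed: int = 0
    n_exposure_cohort: int = 12597
    n_outcome_cohort: int = 20000
    n_snps: int = 3
    block_size: int = 3
    rho_block: float = 0.35
    maf_range: tuple[float, float] = (0.2, 0.45)
    #: per-allele effect on the (unit-variance) exposure; a scalar applies
    #: to every SNP, a sequence gives per-SNP effects, None draws each
    #: effect uniformly from 0.08-0.16.
    gamma: float | Sequence[float] | None = 0.10
    causal_beta: float = 0.25
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    confounder_strength: float = 0.3
    outcome_prevalence: float = 0.381

    def __post_init__(self) -> None:
        if self.n_snps % self.block_size != 0:
            raise ValidationError("block_size must divide n_snps")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if not 0.0 < self.outcome_prevalence < 1.0:
            raise ValidationError("outcome_prevalence must lie in (0,1)")
        if not -1.0 < self.rho_block < 1.0:
            raise ValidationError("rho_block must lie in (-1,1)")


@dataclass(frozen=True)
class SimulationTruth:
    """Realized generating parameters and derived large-sample targets."""

    snp_ids: tuple[str, ...]
    mafs: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    causal_beta: float
    ld: LdMatrix  # true dosage-scale LD
    case_fraction: float
    variance_explained: np.ndarray  # per-SNP marginal r² on the exposure
    marginal_exposure_slopes: np.ndarray
    pseudo_true_outcome_slopes: np.ndarray
    pseudo_true_outcome_ses: np.ndarray
    pseudo_true_pooled_slope: float

    def __post_init__(self) -> None:
        k = len(self.snp_ids)
        for name in (
            "mafs",
            "gamma",
            "alpha",
            "variance_explained",
            "marginal_exposure_slopes",
            "pseudo_true_outcome_slopes",
            "pseudo_true_outcome_ses",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValidationError(f"truth field {name} has shape {arr.shape}, expected ({k},)")
            object.__setattr__(self, name, arr)
        if self.ld.n_snps != k:
            raise ValidationError("truth LD dimension mismatch")

    def to_dict(self) -> dict:
        return {
            "snp_ids": list(self.snp_ids),
            "mafs": self.mafs.tolist(),
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "causal_beta": self.causal_beta,
            "ld": self.ld.r.tolist(),
            "case_fraction": self.case_fraction,
            "variance_explained": self.variance_explained.tolist(),
            "marginal_exposure_slopes": self.marginal_exposure_slopes.tolist(),
            "pseudo_true_outcome_slopes": self.pseudo_true_outcome_slopes.tolist(),
            "pseudo_true_outcome_ses": self.pseudo_true_outcome_ses.tolist(),
            "pseudo_true_pooled_slope": self.pseudo_true_pooled_slope,
        }


def snp_labels(n_snps: int) -> tuple[tuple[str, ...], tuple[tuple[str, str], ...]]:
    """Deterministic rsID-style identifiers and non-palindromic allele pairs."""
    ids = tuple(f"rs{i + 1}" for i in range(n_snps))
    alleles = tuple(_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n_snps))
    return ids, alleles


def _latent_block(config: SimulationConfig) -> np.ndarray:
    """AR(1) latent correlation within one haplotype block."""
    idx = np.arange(config.block_size)
    return config.rho_block ** np.abs(idx[:, None] - idx[None, :])


def _draw_params(config: SimulationConfig, rng: np.random.Generator):
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    if config.gamma is None:
        gamma = rng.uniform(0.08, 0.16, size=config.n_snps)
    else:
        gamma = np.broadcast_to(np.asarray(config.gamma, dtype=float), (config.n_snps,)).copy()
    alpha = (
        config.pleiotropy_mean
        + config.pleiotropy_sd * rng.standard_normal(config.n_snps)
        if (config.pleiotropy_mean != 0.0 or config.pleiotropy_sd != 0.0)
        else np.zeros(config.n_snps)
    )
    return mafs, gamma, alpha


def _allele_corr(t_i: float, t_j: float, rho: float) -> float:
    """Pearson correlation of two thresholded-normal Bernoulli alleles."""
    if rho == 0.0:
        return 0.0
    p_i, p_j = stats.norm.cdf(t_i), stats.norm.cdf(t_j)
    p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf(
        [t_i, t_j]
    )
    denom = np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))
    return float((p11 - p_i * p_j) / denom)


def true_dosage_ld(config: SimulationConfig, mafs: np.ndarray) -> np.ndarray:
    """Exact dosage-scale correlation matrix implied by the Gaussian copula.

    Dosages are sums of two iid thresholded haplotypes, so their pairwise
    correlation equals the allele-level correlation, obtained from the
    bivariate-normal orthant probability at the per-SNP MAF thresholds.
    Only within-block pairs can be nonzero.
    """
    k = config.n_snps
    bs = config.block_size
    t = stats.norm.ppf(mafs)
    latent = _latent_block(config)
    r = np.eye(k)
    for b0 in range(0, k, bs):
        for i in range(bs):
            for j in range(i + 1, bs):
                gi, gj = b0 + i, b0 + j
                rij = _allele_corr(t[gi], t[gj], latent[i, j])
                r[gi, gj] = r[gj, gi] = rij
    return r


def simulate_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator,
    mafs: np.ndarray,
    n_individuals: int,
) -> np.ndarray:
    """Dosage matrix (individuals x SNPs) for one cohort.

    Each of the two haplotypes per individual is a vector of thresholded
    correlated normals (AR(1) within blocks); dosage is their sum.
    """
    k, bs = config.n_snps, config.block_size
    t = stats.norm.ppf(mafs)
    chol = np.linalg.cholesky(_latent_block(config))
    dosage = np.empty((n_individuals, k))
    for b0 in range(0, k, bs):
        z = rng.standard_normal((n_individuals, 2, bs)) @ chol.T
        alleles = z < t[b0 : b0 + bs]
        dosage[:, b0 : b0 + bs] = alleles.sum(axis=1)
    return dosage


def simulate_phenotypes(
    config: SimulationConfig,
    g_exposure: np.ndarray,
    g_outcome: np.ndarray,
    gamma: np.ndarray,
    alpha: np.ndarray,
    mafs: np.ndarray,
    dosage_cov: np.ndarray,
    rng_exposure: np.random.Generator,
    rng_outcome: np.random.Generator,
):
    """Continuous exposure (cohort 1) and liability-threshold case labels (cohort 2).

    The exposure is X = G'gamma + c U + e with the environmental variance
    chosen so Var(X) = 1 exactly in the population.  The outcome cohort's
    (unobserved) exposure X* follows the same rule; liability is
    L = causal_beta X* + G'alpha + c U + e', and case status is L above the
    population (1 - prevalence) quantile of the centered liability.

    Returns ``(exposure, cases, model)`` where ``model`` carries the
    analytic pieces (total genetic loading w, residual liability variance,
    case threshold) reused by the pseudo-true computations.
    """
    c = config.confounder_strength
    beta = config.causal_beta
    var_genetic = float(gamma @ dosage_cov @ gamma)
    var_env = 1.0 - var_genetic - c**2
    if var_env <= 0.0:
        raise ValidationError(
            f"instrument ({var_genetic:.3f}) + confounder ({c ** 2:.3f}) variance "
            "reaches or exceeds the unit exposure variance"
        )
    center = 2.0 * mafs

    gc_exp = g_exposure - center
    n1 = g_exposure.shape[0]
    x = (
        gc_exp @ gamma
        + c * rng_exposure.standard_normal(n1)
        + np.sqrt(var_env) * rng_exposure.standard_normal(n1)
    )

    gc_out = g_outcome - center
    n2 = g_outcome.shape[0]
    u2 = rng_outcome.standard_normal(n2)
    x_star = gc_out @ gamma + c * u2 + np.sqrt(var_env) * rng_outcome.standard_normal(n2)
    liability = beta * x_star + gc_out @ alpha + c * u2 + rng_outcome.standard_normal(n2)

    w = beta * gamma + alpha
    sigma_n2 = (c * (1.0 + beta)) ** 2 + beta**2 * var_env + 1.0
    sd_liability = np.sqrt(float(w @ dosage_cov @ w) + sigma_n2)
    threshold = sd_liability * stats.norm.ppf(1.0 - config.outcome_prevalence)
    cases = (liability > threshold).astype(float)
    model = {"w": w, "sigma_n2": sigma_n2, "threshold": threshold, "var_env": var_env}
    return x, cases, model


def _linear_fit_all(dosages: np.ndarray, y: np.ndarray):
    """Per-SNP simple linear regression, vectorized across SNPs."""
    n = dosages.shape[0]
    gc = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    if np.any(sxx == 0.0):
        j = int(np.argmax(sxx == 0.0))
        raise ValidationError(f"constant dosage column at SNP index {j}")
    beta = gc.T @ yc / sxx
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    sigma2 = rss / max(n - 2, 1)
    se = np.sqrt(sigma2 / sxx)
    return beta, se, np.ones(dosages.shape[1], dtype=bool)


def _logistic_fit_all(dosages: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-8):
    """Per-SNP logistic regression (intercept + dosage) by Newton scoring.

    All SNPs are updated simultaneously; each SNP has its own 2x2 observed
    information, inverted in closed form.  Non-convergence or runaway
    slopes (separation) are reported per SNP.
    """
    n, k = dosages.shape
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValidationError("outcome has no cases or no controls")
    a = np.full(k, np.log(ybar / (1.0 - ybar)))
    b = np.zeros(k)
    converged = np.zeros(k, dtype=bool)
    yv = y[:, None]
    for _ in range(max_iter):
        eta = a + dosages * b
        mu = 1.0 / (1.0 + np.exp(-eta))
        wv = mu * (1.0 - mu)
        s0 = (yv - mu).sum(axis=0)
        s1 = (dosages * (yv - mu)).sum(axis=0)
        i11 = wv.sum(axis=0)
        i12 = (wv * dosages).sum(axis=0)
        i22 = (wv * dosages**2).sum(axis=0)
        det = i11 * i22 - i12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (i22 * s0 - i12 * s1) / det
            db = (i11 * s1 - i12 * s0) / det
        bad = ~np.isfinite(da) | ~np.isfinite(db)
        da[bad] = 0.0
        db[bad] = 0.0
        a += da
        b += db
        converged = (np.abs(da) < tol) & (np.abs(db) < tol) & ~bad
        if converged.all():
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(i11 / det)
    ok = converged & np.isfinite(se) & (np.abs(b) < 15.0)
    return b, se, ok


def gwas_fit(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    binary: bool = False,
    snp_ids: Sequence[str] | None = None,
    alleles: Sequence[tuple[str, str]] | None = None,
) -> list[VariantAssociation]:
    """Per-SNP GWAS of a phenotype on dosages, in summary-statistic form.

    Continuous phenotypes get simple linear regression, binary ones
    maximum-likelihood logistic regression; the effect allele is the
    counted (dosage) allele.  SNPs whose logistic fit fails to converge
    (separation) are dropped with a warning.
    """
    dosages = np.asarray(dosages, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if dosages.shape[0] != phenotype.shape[0]:
        raise ValidationError("phenotype length does not match cohort size")
    n, k = dosages.shape
    if snp_ids is None or alleles is None:
        default_ids, default_alleles = snp_labels(k)
        snp_ids = snp_ids or default_ids
        alleles = alleles or default_alleles
    if binary:
        beta, se, ok = _logistic_fit_all(dosages, phenotype)
    else:
        beta, se, ok = _linear_fit_all(dosages, phenotype)
    eaf = dosages.mean(axis=0) / 2.0
    records = []
    for j in range(k):
        if not ok[j]:
            log.warning("SNP %s: logistic fit did not converge (separation?), dropped", snp_ids[j])
            continue
        se_j = max(float(se[j]), 5e-324)
        z = beta[j] / se_j if se_j > 0 else 0.0
        records.append(
            VariantAssociation(
                snp_id=str(snp_ids[j]),
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                eaf=float(eaf[j]),
                beta=float(beta[j]),
                se=se_j,
                pvalue=float(max(2.0 * stats.norm.sf(abs(z)), 5e-324)),
                n=float(n),
            )
        )
    return records


def _fractional_logistic(g: np.ndarray, q: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Logistic pseudo-MLE on a finite design: solve sum q (target - mu)(1,g) = 0."""
    pbar = float(q @ target)
    a, b = np.log(pbar / (1.0 - pbar)), 0.0
    for _ in range(100):
        mu = 1.0 / (1.0 + np.exp(-(a + b * g)))
        s = np.array([q @ (target - mu), q @ (g * (target - mu))])
        wv = q * mu * (1.0 - mu)
        info = np.array([[wv.sum(), wv @ g], [wv @ g, wv @ g**2]])
        step = np.linalg.solve(info, s)
        a += step[0]
        b += step[1]
        if np.max(np.abs(step)) < 1e-13:
            break
    return a, b


def pseudo_true_outcome_model(
    mafs: np.ndarray,
    dosage_cov: np.ndarray,
    w: np.ndarray,
    sigma_n2: float,
    threshold: float,
    n_outcome: int,
):
    """Large-sample per-SNP logistic slopes implied by the liability model.

    For each SNP the centered liability given its dosage is approximated as
    normal (exact for the dominant confounder/noise terms, near-exact for
    the small residual genetic part), giving case probabilities at dosages
    0/1/2; the pseudo-true logistic (intercept, slope) is the exact
    logistic pseudo-MLE on that three-point design.  Also returns the
    large-sample SE of each slope at the given cohort size (from the
    logistic Fisher information).
    """
    k = len(mafs)
    cw = dosage_cov @ w
    var_w = float(w @ cw)
    slopes = np.empty(k)
    ses = np.empty(k)
    for j in range(k):
        v = dosage_cov[j, j]
        b_lin = cw[j] / v
        var_cond = max(var_w - cw[j] ** 2 / v, 0.0) + sigma_n2
        sigma = np.sqrt(var_cond)
        p = mafs[j]
        g = np.array([0.0, 1.0, 2.0])
        q = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        pi = stats.norm.cdf((b_lin * (g - 2 * p) - threshold) / sigma)
        a_hat, b_hat = _fractional_logistic(g, q, pi)
        mu = 1.0 / (1.0 + np.exp(-(a_hat + b_hat * g)))
        wv = q * mu * (1.0 - mu)
        info = n_outcome * np.array([[wv.sum(), wv @ g], [wv @ g, wv @ g**2]])
        slopes[j] = b_hat
        ses[j] = np.sqrt(np.linalg.inv(info)[1, 1])
    return slopes, ses


def _pooled_pseudo_true(
    bx: np.ndarray, slopes: np.ndarray, ses: np.ndarray, r: np.ndarray
) -> float:
    """GLS pooling of the pseudo-true slope ratios under the true LD."""
    omega = np.outer(ses, ses) * r
    oi = np.linalg.solve(omega, np.column_stack([bx, slopes]))
    denom = float(bx @ oi[:, 0])
    if denom == 0.0:  # no instrument signal (global null): ratio undefined
        return float("nan")
    return float(bx @ oi[:, 1]) / denom


def simulate_dataset(config: SimulationConfig):
    """Generate one synthetic two-sample study entirely in memory.

    Returns ``(exposure_records, outcome_records, truth)``.  All
    randomness flows from ``config.seed`` through three independent
    streams (parameters, exposure cohort, outcome cohort), so outcome-side
    changes can never perturb exposure-side summaries.
    """
    master = np.random.default_rng(config.seed)
    rng_param, rng_exp, rng_out = master.spawn(3)
    mafs, gamma, alpha = _draw_params(config, rng_param)
    r_true = true_dosage_ld(config, mafs)
    variances = 2.0 * mafs * (1.0 - mafs)
    dosage_cov = r_true * np.sqrt(np.outer(variances, variances))

    g_exp = simulate_genotypes(config, rng_exp, mafs, config.n_exposure_cohort)
    g_out = simulate_genotypes(config, rng_out, mafs, config.n_outcome_cohort)
    x, cases, model = simulate_phenotypes(
        config, g_exp, g_out, gamma, alpha, mafs, dosage_cov, rng_exp, rng_out
    )
    snp_ids, alleles = snp_labels(config.n_snps)
    exposure_records = gwas_fit(g_exp, x, binary=False, snp_ids=snp_ids, alleles=alleles)
    outcome_records = gwas_fit(g_out, cases, binary=True, snp_ids=snp_ids, alleles=alleles)

    bx_true = dosage_cov @ gamma / variances  # marginal per-allele exposure slope
    slopes, ses = pseudo_true_outcome_model(
        mafs, dosage_cov, model["w"], model["sigma_n2"], model["threshold"],
        config.n_outcome_cohort,
    )
    truth = SimulationTruth(
        snp_ids=snp_ids,
        mafs=mafs,
        gamma=gamma,
        alpha=alpha,
        causal_beta=config.causal_beta,
        ld=LdMatrix(snp_ids, r_true),
        case_fraction=float(cases.mean()),
        variance_explained=bx_true**2 * variances,
        marginal_exposure_slopes=bx_true,
        pseudo_true_outcome_slopes=slopes,
        pseudo_true_outcome_ses=ses,
        pseudo_true_pooled_slope=_pooled_pseudo_true(bx_true, slopes, ses, r_true),
    )
    return exposure_records, outcome_records, truth


def simulate_study(config: SimulationConfig, out_dir) -> dict:
    """Generate a study and write its artifacts in the package dialects.

    Writes ``exposure.tsv``, ``outcome.tsv``, ``ld.tsv`` (the true dosage
    LD) and ``truth.json`` under ``out_dir``; identical seeds give
    byte-identical files.  Returns the paths plus the truth object.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure_records, outcome_records, truth = simulate_dataset(config)
    paths = {
        "exposure": out_dir / "exposure.tsv",
        "outcome": out_dir / "outcome.tsv",
        "ld": out_dir / "ld.tsv",
        "truth": out_dir / "truth.json",
    }
    write_summary_stats(exposure_records, paths["exposure"])
    write_summary_stats(outcome_records, paths["outcome"])
    write_ld_matrix(truth.ld, paths["ld"])
    payload = {"config": dataclasses.asdict(config), "truth": truth.to_dict()}
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return {"paths": paths, "truth": truth}
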