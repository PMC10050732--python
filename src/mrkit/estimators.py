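"""Two-sample MR estimators and pleiotropy/heterogeneity diagnostics.

Given K harmonized instruments with SNP-exposure effects bx_i (SE sx_i) and
SNP-outcome effects by_i (SE sy_i, log-odds scale), the suite implements:

* per-SNP Wald ratios by_i/bx_i with delta-method SEs,
* fixed-effect IVW for *correlated* instruments: generalized weighted least
  squares of by on bx through the origin with covariance
  Omega_ij = sy_i sy_j rho_ij (rho = signed LD), equivalent to pooling the
  Wald ratios with their correlation,
* classic independent-instrument IVW (fixed or multiplicative random
  effects),
* MR-Egger regression (weighted regression of by on bx with intercept; a
  nonzero intercept indicates directional horizontal pleiotropy),
* Cochran's Q / I² heterogeneity, leave-one-out, and a profile-likelihood
  RAPS estimator that accounts for exposure-side measurement error.

All causal estimates are on the log-odds-per-1-SD-exposure scale; every
:class:`MrEstimate` also carries the odds ratio exp(beta) with the
exp-transformed 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .gwas_io import HarmonizedDataset, ValidationError

log = logging.getLogger(__name__)

_TINY_P = 5e-324  # smallest positive float; keeps P-values in (0, 1]


class EstimationError(RuntimeError):
    """An estimator could not produce a numerically valid result."""


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate on the log-odds-per-1-SD-exposure scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    def __post_init__(self) -> None:
        if not self.ci_low < self.ci_high:
            raise ValidationError(f"{self.method}: CI [{self.ci_low}, {self.ci_high}] inverted")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"{self.method}: pvalue {self.pvalue} not in (0,1]")

    @property
    def odds_ratio(self) -> float:
        """Odds ratio per 1-SD exposure, exp(beta)."""
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))


def _make_estimate(
    method: str, beta: float, se: float, n_snps: int, df: int | None = None
) -> MrEstimate:
    """Normal-theory (or, with df, t-based) 95% CI and two-sided P from (beta, se)."""
    if not se > 0 or not np.isfinite(se):
        raise EstimationError(f"{method}: invalid standard error {se}")
    if df is None:
        crit = stats.norm.ppf(0.975)
        p = 2.0 * stats.norm.sf(abs(beta) / se)
    else:
        crit = stats.t.ppf(0.975, df)
        p = 2.0 * stats.t.sf(abs(beta) / se, df)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - crit * se),
        ci_high=float(beta + crit * se),
        pvalue=float(max(p, _TINY_P)),
        n_snps=n_snps,
    )


def wald_ratio(
    bx: float, sx: float, by: float, sy: float, second_order: bool = False
) -> MrEstimate:
    """Single-SNP Wald ratio by/bx.

    The default SE is the first-order delta method sy/|bx|; with
    ``second_order`` the exposure-side uncertainty is propagated too:
    sqrt(sy²/bx² + by²·sx²/bx⁴).
    """
    if bx == 0.0:
        raise EstimationError("Wald ratio undefined: SNP-exposure beta is 0")
    beta = by / bx
    if second_order:
        se = float(np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))
    else:
        se = sy / abs(bx)
    return _make_estimate("wald_ratio", beta, se, n_snps=1)


def ivw_correlated(data: HarmonizedDataset) -> MrEstimate:
    """Fixed-effect IVW for correlated instruments.

    GLS of outcome betas on exposure betas through the origin with
    covariance Omega_ij = sy_i sy_j rho_ij:
    beta = (bx' Omega⁻¹ bx)⁻¹ bx' Omega⁻¹ by, se = sqrt((bx' Omega⁻¹ bx)⁻¹).
    With K = 1 this reduces to the Wald ratio with first-order SE.
    """
    bx, by, sy = data.beta_exposure, data.beta_outcome, data.se_outcome
    omega = np.outer(sy, sy) * data.ld.r
    try:
        cho = linalg.cho_factor(omega)
        oi_bx = linalg.cho_solve(cho, bx)
        oi_by = linalg.cho_solve(cho, by)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(omega)
        raise EstimationError(
            f"IVW covariance is singular (condition number {cond:.3g})"
        ) from exc
    denom = float(bx @ oi_bx)
    if denom <= 0 or not np.isfinite(denom):
        raise EstimationError(
            f"IVW precision bx'Omega^-1 bx = {denom:.3g} is not positive "
            f"(condition number {np.linalg.cond(omega):.3g})"
        )
    beta = float(bx @ oi_by) / denom
    se = float(np.sqrt(1.0 / denom))
    return _make_estimate("ivw_correlated", beta, se, n_snps=data.n_snps)


def ivw_independent(data: HarmonizedDataset, model: str = "fixed") -> MrEstimate:
    """Classic IVW assuming independent instruments (weights 1/sy²).

    ``model='fixed'``: precision-weighted regression through the origin.
    ``model='multiplicative_random'``: the fixed-effect SE is inflated by
    max(1, sqrt(Q/(K-1))); requires K >= 2.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown model {model!r}")
    bx, by, sy = data.beta_exposure, data.beta_outcome, data.se_outcome
    k = data.n_snps
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = float(np.sqrt(1.0 / denom))
    method = "ivw_fixed"
    if model == "multiplicative_random":
        if k < 2:
            raise EstimationError("multiplicative random-effects IVW requires K >= 2")
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, np.sqrt(q / (k - 1)))
        method = "ivw_multiplicative_random"
    return _make_estimate(method, beta, se, n_snps=k)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (causal estimate) and intercept (pleiotropy test)."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float

    def __post_init__(self) -> None:
        if not 0.0 < self.intercept_pvalue <= 1.0:
            raise ValidationError(f"intercept pvalue {self.intercept_pvalue} not in (0,1]")


def mr_egger(data: HarmonizedDataset) -> EggerResult:
    """MR-Egger regression: weighted LS of by on bx with intercept, weights 1/sy².

    Instruments are first oriented so every bx_i > 0 (the fit is invariant
    to joint sign flips of (bx_i, by_i)).  Inference uses the estimated
    multiplicative residual scale with a t(K-2) reference, the convention
    of the field's reference implementations.
    """
    k = data.n_snps
    if k < 3:
        raise EstimationError(f"MR-Egger requires K >= 3 instruments, got {k}")
    sign = np.sign(data.beta_exposure)
    if np.any(sign == 0):
        raise EstimationError("MR-Egger undefined with a zero SNP-exposure beta")
    bx = data.beta_exposure * sign
    by = data.beta_outcome * sign
    sy = data.se_outcome
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(k), bx])
    xtwx = x.T * w @ x
    xtwy = x.T @ (w * by)
    try:
        coef = np.linalg.solve(xtwx, xtwy)
        cov_unit = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("MR-Egger design is singular (no spread in bx)") from exc
    resid = by - x @ coef
    scale2 = float(np.sum(w * resid**2)) / (k - 2)
    if scale2 <= 0.0:
        raise EstimationError("MR-Egger fit is degenerate (zero residual variance)")
    cov = cov_unit * scale2
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_inter = float(max(2.0 * stats.t.sf(abs(inter) / se_inter, k - 2), _TINY_P))
    return EggerResult(
        slope=_make_estimate("mr_egger", slope, se_slope, n_snps=k, df=k - 2),
        intercept=inter,
        intercept_se=se_inter,
        intercept_pvalue=p_inter,
    )


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran's Q heterogeneity of per-SNP estimates around the pooled slope."""

    q: float
    df: int
    pvalue: float
    i_squared: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValidationError("Q must be >= 0")
        if not 0.0 <= self.i_squared <= 1.0:
            raise ValidationError("I² must lie in [0,1]")


def heterogeneity(data: HarmonizedDataset, pooled: MrEstimate) -> HeterogeneityReport:
    """Cochran's Q = sum_i (by_i - beta·bx_i)²/sy_i² with K-1 df, and I²."""
    k = data.n_snps
    if k < 2:
        raise EstimationError("heterogeneity requires K >= 2 instruments")
    resid = data.beta_outcome - pooled.beta * data.beta_exposure
    q = float(np.sum((resid / data.se_outcome) ** 2))
    df = k - 1
    p = float(max(stats.chi2.sf(q, df), _TINY_P))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityReport(q=q, df=df, pvalue=p, i_squared=i2)


def leave_one_out(data: HarmonizedDataset) -> list[tuple[str, MrEstimate]]:
    """IVW re-estimated with each SNP omitted in turn.

    Uses the correlated-instrument estimator when the LD submatrix is not
    the identity, the classic fixed-effect IVW otherwise.
    """
    k = data.n_snps
    if k < 2:
        raise EstimationError("leave-one-out requires K >= 2 instruments")
    correlated = not data.ld.is_identity
    out = []
    for i in range(k):
        sub = data.subset([j for j in range(k) if j != i])
        est = ivw_correlated(sub) if correlated else ivw_independent(sub)
        out.append((data.snp_ids[i], est))
    return out


def _raps_negloglik(beta: float, tau2: float, data: HarmonizedDataset, with_log: bool) -> float:
    v = data.se_outcome**2 + beta**2 * data.se_exposure**2 + tau2
    resid = data.beta_outcome - beta * data.beta_exposure
    nll = 0.5 * float(np.sum(resid**2 / v))
    if with_log:
        nll += 0.5 * float(np.sum(np.log(v)))
    return nll


def raps(data: HarmonizedDataset, overdispersion: bool = False) -> MrEstimate:
    """Robust adjusted profile score (profile-likelihood) estimator.

    Maximizes the profile log-likelihood
    -1/2 sum_i (by_i - beta·bx_i)² / (sy_i² + beta²·sx_i² + tau²),
    which accounts for exposure-side measurement error; instruments are
    treated as independent.  With ``overdispersion`` a systematic
    pleiotropy variance tau² >= 0 is estimated jointly (the Gaussian
    log-variance term is then included, since tau² is otherwise
    unidentified).  The SE comes from the observed information at the
    optimum.
    """
    k = data.n_snps
    if k < 3:
        raise EstimationError(f"RAPS requires K >= 3 instruments, got {k}")
    start = ivw_independent(data).beta
    width = 10.0 * max(abs(start), 1.0)

    if not overdispersion:
        objective = lambda b: _raps_negloglik(b, 0.0, data, with_log=False)
        res = optimize.minimize_scalar(
            objective, bounds=(start - width, start + width), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise EstimationError(f"RAPS optimizer did not converge: {res}")
        beta_hat, tau2_hat = float(res.x), 0.0
        with_log = False
    else:
        def objective2(theta):
            b, log_tau2 = theta
            return _raps_negloglik(b, np.exp(log_tau2), data, with_log=True)

        best = None
        for log_tau2_0 in (-20.0, np.log(np.mean(data.se_outcome**2)) - 2.0):
            res = optimize.minimize(
                objective2, x0=[start, log_tau2_0], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not best.success:
            raise EstimationError(f"RAPS optimizer did not converge: {best}")
        beta_hat, tau2_hat = float(best.x[0]), float(np.exp(best.x[1]))
        # Degenerate overdispersion: treat tau2 below numerical floor as 0.
        if tau2_hat < 1e-12:
            tau2_hat = 0.0
        with_log = True

    # Observed information in beta via central second difference.
    h = 1e-5 * max(abs(beta_hat), 1.0)
    f0 = _raps_negloglik(beta_hat, tau2_hat, data, with_log)
    fp = _raps_negloglik(beta_hat + h, tau2_hat, data, with_log)
    fm = _raps_negloglik(beta_hat - h, tau2_hat, data, with_log)
    info = (fp - 2.0 * f0 + fm) / h**2
    if not np.isfinite(info) or info <= 0:
        raise EstimationError(f"RAPS observed information {info:.3g} is not positive")
    se = float(np.sqrt(1.0 / info))
    method = "raps_overdispersed" if overdispersion else "raps"
    return _make_estimate(method, beta_hat, se, n_snps=k)


def estimate_all(
    data: HarmonizedDataset, methods: Sequence[str] = ("wald", "ivw", "ivw-re", "egger", "raps")
) -> dict:
    """Run the requested estimator suite on one harmonized dataset.

    Returns a dict with per-method :class:`MrEstimate` objects plus the
    heterogeneity report and Egger intercept where applicable.  The 'ivw'
    entry uses the correlated-instrument form when the LD submatrix is not
    the identity.
    """
    results: dict = {"wald_ratios": [], "estimates": []}
    k = data.n_snps
    if "wald" in methods:
        for i, snp in enumerate(data.snp_ids):
            results["wald_ratios"].append(
                (
                    snp,
                    wald_ratio(
                        data.beta_exposure[i],
                        data.se_exposure[i],
                        data.beta_outcome[i],
                        data.se_outcome[i],
                    ),
                )
            )
    ivw_est = None
    if "ivw" in methods:
        ivw_est = ivw_correlated(data) if not data.ld.is_identity else ivw_independent(data)
        results["estimates"].append(ivw_est)
    if "ivw-re" in methods and k >= 2:
        results["estimates"].append(ivw_independent(data, model="multiplicative_random"))
    if "egger" in methods and k >= 3:
        try:
            egger = mr_egger(data)
            results["estimates"].append(egger.slope)
            results["egger_intercept"] = egger
        except EstimationError as exc:
            log.warning("MR-Egger skipped: %s", exc)
    if "raps" in methods and k >= 3:
        try:
            results["estimates"].append(raps(data))
        except EstimationError as exc:
            log.warning("RAPS skipped: %s", exc)
    if ivw_est is not None and k >= 2:
        results["heterogeneity"] = heterogeneity(data, ivw_est)
        results["leave_one_out"] = leave_one_out(data)
    return results
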