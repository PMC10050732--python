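"""Instrument selection (P-value filter + greedy LD clumping) and strength metrics.

Instrument strength is summarised by the first-stage F statistic
F = (beta/SE)^2 of each SNP-exposure association (values above ~10
conventionally indicate a non-weak instrument) and by the variance of the
exposure each SNP explains, 2p(1-p)beta^2 for a unit-variance trait.
Because the plain sum of per-SNP variances overstates the total when
instruments are in LD, an LD-adjusted total (quadratic form through the
generalized inverse of the LD matrix) is reported alongside the sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gwas_io import LdMatrix, ValidationError, VariantAssociation

log = logging.getLogger(__name__)


def f_statistic(beta: float, se: float) -> float:
    """First-stage F statistic of a single SNP-exposure association, (beta/se)^2."""
    if not se > 0:
        raise ValidationError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def variance_explained(eaf: float, beta: float) -> float:
    """Variance of a unit-variance trait explained by one SNP: 2p(1-p)beta^2."""
    if not 0.0 < eaf < 1.0:
        raise ValidationError(f"eaf must be in (0,1), got {eaf}")
    return 2.0 * eaf * (1.0 - eaf) * beta**2


def total_variance_explained(
    eafs: Sequence[float], betas: Sequence[float], ld: LdMatrix | None = None
) -> tuple[float, float]:
    """Total exposure variance explained by a SNP set: (plain sum, LD-adjusted).

    The LD-adjusted total is b' D R⁻ D b with D = diag(sqrt(2p(1-p))) and
    R⁻ the Moore-Penrose inverse of the LD matrix; it equals the plain sum
    when the instruments are uncorrelated.
    """
    p = np.asarray(eafs, dtype=float)
    b = np.asarray(betas, dtype=float)
    d = np.sqrt(2.0 * p * (1.0 - p))
    plain = float(np.sum((d * b) ** 2))
    if ld is None:
        return plain, plain
    db = d * b
    adjusted = float(db @ np.linalg.pinv(ld.r) @ db)
    return plain, adjusted


def select_instruments(
    records: Sequence[VariantAssociation],
    p_threshold: float,
    ld: LdMatrix,
    r2_threshold: float,
) -> list[str]:
    """Greedy LD clumping of P-filtered candidates.

    Candidates with ``pvalue < p_threshold`` are sorted by ascending P
    (ties broken by rsID for determinism); repeatedly the smallest-P
    candidate is kept and every remaining candidate with squared LD
    >= ``r2_threshold`` against it is removed.  Returns kept rsIDs in keep
    order; an empty candidate set yields an empty list with a warning.
    """
    candidates = [r for r in records if r.pvalue < p_threshold]
    if not candidates:
        log.warning("no SNP passes the P-value threshold %g", p_threshold)
        return []
    missing = [r.snp_id for r in candidates if r.snp_id not in ld.snp_ids]
    if missing:
        raise ValidationError(f"LD matrix does not cover candidate SNPs: {missing}")
    queue = sorted(candidates, key=lambda r: (r.pvalue, r.snp_id))
    kept: list[str] = []
    while queue:
        head = queue.pop(0)
        kept.append(head.snp_id)
        i = ld.index(head.snp_id)
        queue = [r for r in queue if ld.r[i, ld.index(r.snp_id)] ** 2 < r2_threshold]
    return kept


@dataclass(frozen=True)
class InstrumentReport:
    """Per-SNP and aggregate strength of a selected instrument set."""

    snp_ids: tuple[str, ...]
    f_statistics: tuple[float, ...]
    variance_explained: tuple[float, ...]
    total_variance_explained: float
    total_variance_explained_ld_adjusted: float
    min_f: float

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.f_statistics):
            raise ValidationError("negative F statistic")
        if self.f_statistics and abs(self.min_f - min(self.f_statistics)) > 1e-12:
            raise ValidationError("min_f does not equal the smallest per-SNP F")


def instrument_report(
    records: Sequence[VariantAssociation], ld: LdMatrix | None = None
) -> InstrumentReport:
    """Strength report (F statistics, variance explained) for an instrument set."""
    fs = tuple(f_statistic(r.beta, r.se) for r in records)
    r2s = tuple(variance_explained(r.eaf, r.beta) for r in records)
    plain, adjusted = total_variance_explained(
        [r.eaf for r in records], [r.beta for r in records], ld
    )
    return InstrumentReport(
        snp_ids=tuple(r.snp_id for r in records),
        f_statistics=fs,
        variance_explained=r2s,
        total_variance_explained=plain,
        total_variance_explained_ld_adjusted=adjusted,
        min_f=min(fs) if fs else float("nan"),
    )
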