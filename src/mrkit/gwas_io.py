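"""Reading, validation, writing and harmonization of GWAS summary statistics.

This module is the data backbone of the package. It defines the three
containers every estimator consumes:

* :class:`VariantAssociation` — one SNP's summary record (alleles, effect
  allele frequency, additive beta, SE, P, sample size),
* :class:`LdMatrix` — a signed pairwise allelic correlation matrix keyed by
  rsID (the r whose square is the usual LD r²),
* :class:`HarmonizedDataset` — allele-aligned parallel exposure/outcome
  arrays plus the matching LD submatrix, the unit all estimators operate on.

Files are plain tab-delimited text with a header row.  Column names are
configurable through a ``column_map``; the defaults (SNP/CHR/EA/OA/EAF/
BETA/SE/P/N) match common GWAS summary exports.  LD matrices are square
tab-delimited tables with rsIDs as both header row and first column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default file column names: rsID, chromosome, effect allele, other allele,
#: effect-allele frequency, beta, standard error, P-value, sample size.
DEFAULT_COLUMNS = {
    "snp_id": "SNP",
    "chromosome": "CHR",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

#: Columns that must be present in every summary-statistics file; CHR and N
#: are optional (all inputs are keyed by rsID alone).
REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue")

# Harmonization provenance flags.
KEPT = "kept-as-is"
FLIPPED = "outcome-flipped"
DROPPED_PALINDROMIC = "dropped-palindromic"
DROPPED_MISSING = "dropped-missing"
DROPPED_MISMATCH = "dropped-mismatch"


class FormatError(ValueError):
    """A file does not conform to the expected tab-delimited dialect."""


class ValidationError(ValueError):
    """A record or matrix violates its domain invariants."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's GWAS summary record.

    ``beta`` is the additive per-allele effect of ``effect_allele``: SD of
    the exposure per allele on the exposure side, log-odds per allele on the
    outcome side.  ``eaf`` is the effect-allele frequency.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    chromosome: str = ""
    n: float | None = None

    def __post_init__(self) -> None:
        def fail(field_name: str, msg: str) -> None:
            raise ValidationError(f"SNP {self.snp_id!r}, field {field_name!r}: {msg}")

        if self.effect_allele not in VALID_ALLELES:
            fail("effect_allele", f"{self.effect_allele!r} not one of A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            fail("other_allele", f"{self.other_allele!r} not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            fail("other_allele", "effect and other allele are identical")
        if not 0.0 < self.eaf < 1.0:
            fail("eaf", f"{self.eaf} not strictly in (0,1)")
        if not self.se > 0.0:
            fail("se", f"{self.se} is not > 0")
        if not 0.0 < self.pvalue <= 1.0:
            fail("pvalue", f"{self.pvalue} not in (0,1]")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G pairs, whose strand cannot be resolved from alleles."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "VariantAssociation":
        """Same association re-referenced to the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


def read_summary_stats(
    path, column_map: Mapping[str, str] | None = None
) -> list[VariantAssociation]:
    """Read a tab-delimited summary-statistics file into validated records.

    Parameters
    ----------
    path
        Tab-delimited UTF-8 file with a header row.
    column_map
        Field-name -> column-name overrides, merged over ``DEFAULT_COLUMNS``.

    Row order is preserved.  A missing mapped column raises
    :class:`FormatError` naming the column; an invariant violation raises
    :class:`ValidationError` naming the SNP and field.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = pd.read_csv(
        path, sep="\t", dtype={cols["snp_id"]: str}, float_precision="round_trip"
    )
    for field_name in REQUIRED_FIELDS:
        if cols[field_name] not in frame.columns:
            raise FormatError(
                f"column {cols[field_name]!r} (field {field_name!r}) missing from {path}"
            )
    has_chr = cols["chromosome"] in frame.columns
    has_n = cols["n"] in frame.columns
    records = []
    for row in frame.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(frame.columns, row))
        n_val = row.get(cols["n"]) if has_n else None
        if n_val is not None and pd.isna(n_val):
            n_val = None
        records.append(
            VariantAssociation(
                snp_id=str(row[cols["snp_id"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                eaf=float(row[cols["eaf"]]),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                pvalue=float(row[cols["pvalue"]]),
                chromosome=str(row[cols["chromosome"]]) if has_chr else "",
                n=float(n_val) if n_val is not None else None,
            )
        )
    return records


def write_summary_stats(
    records: Sequence[VariantAssociation], path, column_map: Mapping[str, str] | None = None
) -> None:
    """Write records as a tab-delimited file; the inverse of :func:`read_summary_stats`."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    data = {
        cols["snp_id"]: [r.snp_id for r in records],
        cols["chromosome"]: [r.chromosome for r in records],
        cols["effect_allele"]: [r.effect_allele for r in records],
        cols["other_allele"]: [r.other_allele for r in records],
        cols["eaf"]: [r.eaf for r in records],
        cols["beta"]: [r.beta for r in records],
        cols["se"]: [r.se for r in records],
        cols["pvalue"]: [r.pvalue for r in records],
    }
    if any(r.n is not None for r in records):
        data[cols["n"]] = [r.n for r in records]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LdMatrix:
    """Signed pairwise allelic correlation matrix among instrument SNPs.

    The entries are signed r (so the clumping threshold applies to r²,
    while the correlated-IVW covariance uses r itself), referenced to the
    effect alleles of the study the matrix was estimated against.
    Validated symmetric with unit diagonal; indefinite matrices (possible
    from small reference panels) are repaired by a minimal ridge with a
    logged warning.
    """

    snp_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.snp_ids)
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] != len(ids):
            raise ValidationError(
                f"LD matrix shape {r.shape} does not match {len(ids)} SNP identifiers"
            )
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNP identifiers in LD matrix")
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValidationError("LD matrix is not symmetric within 1e-10")
        r = 0.5 * (r + r.T)
        if not np.allclose(np.diag(r), 1.0, atol=1e-10):
            raise ValidationError("LD matrix diagonal is not 1")
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise ValidationError("LD matrix has |r| > 1")
        lam_min = float(np.linalg.eigvalsh(r)[0])
        if lam_min < -1e-8:
            # Minimal ridge repair followed by rescaling back to unit diagonal.
            delta = abs(lam_min) + 1e-8
            log.warning(
                "LD matrix not positive semi-definite (min eigenvalue %.3g); "
                "adding ridge %.3g",
                lam_min,
                delta,
            )
            r = (r + delta * np.eye(len(ids))) / (1.0 + delta)
        object.__setattr__(self, "snp_ids", ids)
        object.__setattr__(self, "r", r)

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LdMatrix":
        return cls(tuple(snp_ids), np.eye(len(snp_ids)))

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.r, np.eye(self.n_snps), atol=1e-12))

    def index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def subset(self, snp_ids: Sequence[str]) -> "LdMatrix":
        """Submatrix restricted (and reordered) to ``snp_ids``."""
        idx = [self.index(s) for s in snp_ids]
        return LdMatrix(tuple(snp_ids), self.r[np.ix_(idx, idx)])


def read_ld_matrix(path) -> LdMatrix:
    """Read a square tab-delimited LD matrix with rsID header row and column."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(frame.index) != list(frame.columns):
        raise FormatError(f"LD matrix {path}: row and column identifiers differ")
    return LdMatrix(tuple(str(s) for s in frame.columns), frame.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(sep="\t", path_or_buf=path)


def ld_from_dosages(dosage_matrix, snp_ids: Sequence[str]) -> LdMatrix:
    """Pearson correlation of dosage columns (individuals x SNPs, counts in [0,2])."""
    dosages = np.asarray(dosage_matrix, dtype=float)
    if dosages.ndim != 2 or dosages.shape[0] < 2:
        raise ValidationError("dosage matrix must be 2-D with at least 2 individuals")
    if dosages.shape[1] != len(snp_ids):
        raise ValidationError("dosage matrix column count does not match SNP identifiers")
    sd = dosages.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0.0:
            raise ValidationError(f"SNP {snp_ids[j]!r}: constant dosage column")
    r = np.corrcoef(dosages, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(tuple(snp_ids), r)


@dataclass(frozen=True)
class HarmonizedDataset:
    """Allele-aligned exposure/outcome summary arrays, the unit of estimation.

    After harmonization the effect allele of every retained SNP is identical
    across the two studies; ``provenance`` records the fate of every input
    SNP (kept, outcome-flipped, or a drop reason).
    """

    snp_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    other_alleles: tuple[str, ...]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    eaf: np.ndarray
    ld: LdMatrix
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.snp_ids)
        if k < 1:
            raise ValidationError("harmonized dataset must retain at least one SNP")
        arrays = {}
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome", "eaf"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (k,):
                raise ValidationError(f"{name} length {a.shape} != number of SNPs {k}")
            arrays[name] = a
        for name, a in arrays.items():
            object.__setattr__(self, name, a)
        if self.ld.snp_ids != tuple(self.snp_ids):
            raise ValidationError("LD submatrix identifiers do not match retained SNPs")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, indices: Sequence[int]) -> "HarmonizedDataset":
        idx = list(indices)
        ids = tuple(self.snp_ids[i] for i in idx)
        return HarmonizedDataset(
            snp_ids=ids,
            effect_alleles=tuple(self.effect_alleles[i] for i in idx),
            other_alleles=tuple(self.other_alleles[i] for i in idx),
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            eaf=self.eaf[idx],
            ld=self.ld.subset(ids),
            provenance={s: self.provenance.get(s, KEPT) for s in ids},
        )

    def to_record_lists(self) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
        """Exposure and outcome records of the retained SNPs (already aligned)."""
        exp, out = [], []
        for i, snp in enumerate(self.snp_ids):
            common = dict(
                snp_id=snp,
                effect_allele=self.effect_alleles[i],
                other_allele=self.other_alleles[i],
                eaf=float(self.eaf[i]),
            )
            for lst, b, s in (
                (exp, float(self.beta_exposure[i]), float(self.se_exposure[i])),
                (out, float(self.beta_outcome[i]), float(self.se_outcome[i])),
            ):
                p = 2.0 * stats.norm.sf(abs(b) / s) if s > 0 else 1.0
                lst.append(VariantAssociation(pvalue=max(p, 5e-324), beta=b, se=s, **common))
        return exp, out


def _unique_index(records: Sequence[VariantAssociation], label: str):
    index = {}
    for r in records:
        if r.snp_id in index:
            raise ValidationError(f"duplicate SNP {r.snp_id!r} in {label} records")
        index[r.snp_id] = r
    return index


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    ld: LdMatrix | None = None,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedDataset:
    """Align outcome records to the exposure effect alleles.

    Rules, applied per SNP of the exposure/outcome intersection (exposure
    row order preserved):

    * same allele pair -> kept as is;
    * swapped pair (outcome EA == exposure OA) -> outcome beta sign-flipped,
      eaf replaced by 1-eaf;
    * strand-complement pairs resolved the same way;
    * palindromic SNPs (A/T, C/G) with eaf within ``palindromic_eaf_window``
      of 0.5 in either study are dropped; the remainder are aligned by
      frequency (minor allele matched across studies);
    * any other allele configuration is dropped with a warning.

    The LD matrix (identity if ``ld`` is None) must cover the intersection;
    its submatrix is reordered to the retained SNPs.  Exposure records are
    never re-referenced, so LD signs are preserved as supplied.
    """
    exp_index = _unique_index(exposure, "exposure")
    out_index = _unique_index(outcome, "outcome")
    provenance: dict[str, str] = {}
    shared = [r.snp_id for r in exposure if r.snp_id in out_index]
    if not shared:
        raise ValidationError("exposure and outcome records share no SNPs")
    for r in exposure:
        if r.snp_id not in out_index:
            provenance[r.snp_id] = DROPPED_MISSING
    for r in outcome:
        if r.snp_id not in exp_index:
            provenance[r.snp_id] = DROPPED_MISSING
    if ld is not None:
        missing = [s for s in shared if s not in ld.snp_ids]
        if missing:
            raise ValidationError(f"LD matrix does not cover shared SNPs: {missing}")

    kept: list[tuple[VariantAssociation, VariantAssociation]] = []
    for snp in shared:
        e, o = exp_index[snp], out_index[snp]
        if e.is_palindromic:
            if {o.effect_allele, o.other_allele} != {e.effect_allele, e.other_allele}:
                provenance[snp] = DROPPED_MISMATCH
                log.warning("SNP %s: unresolvable allele pair, dropped", snp)
                continue
            near_half = (
                abs(e.eaf - 0.5) < palindromic_eaf_window
                or abs(o.eaf - 0.5) < palindromic_eaf_window
            )
            if near_half:
                provenance[snp] = DROPPED_PALINDROMIC
                log.warning("SNP %s: palindromic with ambiguous frequency, dropped", snp)
                continue
            # Alleles alone cannot orient a palindromic SNP; align by which
            # side of 0.5 the effect-allele frequency falls on.
            if (e.eaf - 0.5) * (o.eaf - 0.5) >= 0.0:
                provenance[snp] = KEPT
                kept.append((e, o))
            else:
                provenance[snp] = FLIPPED
                kept.append((e, o.flipped()))
            continue
        o_pairs = {
            (o.effect_allele, o.other_allele): o,
            (COMPLEMENT[o.effect_allele], COMPLEMENT[o.other_allele]): o,
        }
        if (e.effect_allele, e.other_allele) in o_pairs:
            provenance[snp] = KEPT
            kept.append((e, o))
        elif (e.other_allele, e.effect_allele) in o_pairs:
            provenance[snp] = FLIPPED
            kept.append((e, o.flipped()))
        else:
            provenance[snp] = DROPPED_MISMATCH
            log.warning(
                "SNP %s: allele pair %s/%s vs %s/%s unresolvable, dropped",
                snp,
                e.effect_allele,
                e.other_allele,
                o.effect_allele,
                o.other_allele,
            )
    if not kept:
        raise ValidationError("no SNPs retained after harmonization")

    ids = tuple(e.snp_id for e, _ in kept)
    sub_ld = ld.subset(ids) if ld is not None else LdMatrix.identity(ids)
    return HarmonizedDataset(
        snp_ids=ids,
        effect_alleles=tuple(e.effect_allele for e, _ in kept),
        other_alleles=tuple(e.other_allele for e, _ in kept),
        beta_exposure=np.array([e.beta for e, _ in kept]),
        se_exposure=np.array([e.se for e, _ in kept]),
        beta_outcome=np.array([o.beta for _, o in kept]),
        se_outcome=np.array([o.se for _, o in kept]),
        eaf=np.array([e.eaf for e, _ in kept]),
        ld=sub_ld,
        provenance=provenance,
    )
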