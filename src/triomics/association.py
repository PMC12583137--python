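"""Single-omics linear association scans.

Three model roles, each an OLS fit with intercept and covariates (age, sex,
cohort by default), classical homoskedastic variance, and two-sided p from
the Student-t distribution with n - k degrees of freedom:

* ``snp_transcript``: transcript expression ~ SNP dosage + covariates (P_SNP)
* ``transcript_bmi``: transcript expression ~ BMI + covariates (P_BMI) —
  note the transcript is the outcome and BMI the predictor, not the reverse
* ``snp_bmi``: BMI ~ SNP dosage + covariates (the nominal screen)

Complete-case analysis per pair; n is recorded per result.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenotypeMatrix, PhenotypeTable
from .exceptions import (
    DegenerateInputError,
    IdLookupError,
    InsufficientDataError,
    ValidationError,
)

ROLES = ("snp_transcript", "transcript_bmi", "snp_bmi")
DEFAULT_COVARIATES = ("age", "sex", "cohort")
_TINY_P = 5e-324  # smallest subnormal double; p-values are floored here
_VAR_TOL = 1e-12


@dataclass
class AssociationResult:
    outcome_id: str
    predictor_id: str
    beta: float
    se: float
    t_stat: float
    p_two_sided: float
    n: int
    model_role: str


def fit_linear(
    outcome,
    predictor,
    covariates=None,
    *,
    outcome_id: str = "outcome",
    predictor_id: str = "predictor",
    model_role: str = "snp_transcript",
) -> AssociationResult:
    """OLS of ``outcome`` on intercept + covariates + ``predictor``.

    Returns beta/se/t/p for the predictor term only. Rows with any missing
    value are dropped (complete cases). The predictor must retain variance
    after projection on the intercept and covariates, and covariates must be
    of full rank (constant or duplicated covariates are rejected).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if covariates is None:
        C = np.empty((len(y), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    if len(x) != len(y) or len(C) != len(y):
        raise ValidationError("fit_linear: outcome, predictor, covariates lengths differ")

    keep = np.isfinite(y) & np.isfinite(x)
    if C.shape[1]:
        keep &= np.isfinite(C).all(axis=1)
    y, x, C = y[keep], x[keep], C[keep]
    n = len(y)
    k = 2 + C.shape[1]  # intercept + covariates + predictor
    if n <= k:
        raise InsufficientDataError(f"fit_linear: n={n} <= number of parameters k={k}")

    Xc = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise DegenerateInputError(
            "fit_linear: covariate matrix is rank-deficient (constant or duplicated column)"
        )
    # project predictor on [1, covariates] to check residual variance
    coef, *_ = np.linalg.lstsq(Xc, x, rcond=None)
    x_resid = x - Xc @ coef
    if (x_resid @ x_resid) / n < _VAR_TOL:
        raise DegenerateInputError(
            f"fit_linear: predictor {predictor_id!r} is constant after covariate projection"
        )

    X = np.column_stack([Xc, x])
    Q, R = np.linalg.qr(X)
    beta_all = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta_all
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df if rss > 0 else 0.0
    Rinv = np.linalg.inv(R)
    xtx_inv_diag = (Rinv @ Rinv.T)[-1, -1]
    beta = float(beta_all[-1])
    se = float(np.sqrt(max(sigma2 * xtx_inv_diag, 0.0)))
    if se == 0.0:
        # perfect fit: t diverges, p underflows to the smallest positive double
        t_stat = np.sign(beta) * np.inf if beta != 0 else 0.0
        p = _TINY_P if beta != 0 else 1.0
        se = float(np.sqrt(_TINY_P))
    else:
        t_stat = beta / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
        p = min(max(p, _TINY_P), 1.0)
    return AssociationResult(
        outcome_id=outcome_id,
        predictor_id=predictor_id,
        beta=beta,
        se=se,
        t_stat=float(t_stat),
        p_two_sided=p,
        n=n,
        model_role=model_role,
    )


@dataclass
class ScanTable:
    """Collection of AssociationResults for one model role."""

    results: pd.DataFrame  # columns: role, outcome_id, predictor_id, beta, se, t, p, n
    role: str
    covariates: tuple
    timestamp: str = ""

    COLUMNS = ("role", "outcome_id", "predictor_id", "beta", "se", "t", "p", "n")

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"ScanTable.role must be one of {ROLES}, got {self.role!r}")
        missing = [c for c in self.COLUMNS if c not in self.results.columns]
        if missing:
            raise ValidationError(f"ScanTable missing columns {missing}")
        if self.results.duplicated(subset=["outcome_id", "predictor_id"]).any():
            raise ValidationError("ScanTable: (outcome_id, predictor_id) must be unique")

    @classmethod
    def from_results(cls, results: Sequence[AssociationResult], role: str, covariates):
        df = pd.DataFrame(
            [
                (r.model_role, r.outcome_id, r.predictor_id, r.beta, r.se, r.t_stat,
                 r.p_two_sided, r.n)
                for r in results
            ],
            columns=list(cls.COLUMNS),
        )
        return cls(
            results=df,
            role=role,
            covariates=tuple(covariates),
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )


def run_scan(
    role: str,
    genotypes: GenotypeMatrix | None,
    expression: ExpressionMatrix | None,
    phenotypes: PhenotypeTable,
    pair_list: Sequence,
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
) -> ScanTable:
    """Fit one association per pair.

    ``pair_list`` entries: (snp_id, transcript_id) for ``snp_transcript``;
    transcript_id for ``transcript_bmi``; snp_id for ``snp_bmi``.
    """
    if role not in ROLES:
        raise ValidationError(f"unknown scan role {role!r}")
    if len(pair_list) == 0:
        raise ValidationError("pair_list must be non-empty")
    pairs = list(pair_list)
    if len(set(map(tuple, pairs)) if isinstance(pairs[0], (tuple, list)) else set(pairs)) != len(pairs):
        raise ValidationError("pair_list contains duplicates")

    from .datatypes import check_sample_alignment

    to_align = [phenotypes] + [o for o in (genotypes, expression) if o is not None]
    check_sample_alignment(*to_align)

    pheno = phenotypes.table
    covars = pheno[list(covariate_names)].to_numpy(dtype=float) if covariate_names else None
    bmi = pheno["bmi"].to_numpy(dtype=float)

    # resolve ids up front so unknown ids are reported together
    def _check(ids, table_cols, kind):
        missing = sorted(set(ids) - set(table_cols))
        if missing:
            raise IdLookupError(kind, missing)

    results = []
    if role == "snp_transcript":
        _check([p[0] for p in pairs], genotypes.dosages.columns, "snp")
        _check([p[1] for p in pairs], expression.values.columns, "transcript")
        for snp_id, tx_id in pairs:
            results.append(
                fit_linear(
                    expression.values[tx_id].to_numpy(dtype=float),
                    genotypes.dosages[snp_id].to_numpy(dtype=float),
                    covars,
                    outcome_id=tx_id,
                    predictor_id=snp_id,
                    model_role=role,
                )
            )
    elif role == "transcript_bmi":
        _check(pairs, expression.values.columns, "transcript")
        for tx_id in pairs:
            results.append(
                fit_linear(
                    expression.values[tx_id].to_numpy(dtype=float),
                    bmi,
                    covars,
                    outcome_id=tx_id,
                    predictor_id="BMI",
                    model_role=role,
                )
            )
    else:  # snp_bmi
        _check(pairs, genotypes.dosages.columns, "snp")
        for snp_id in pairs:
            results.append(
                fit_linear(
                    bmi,
                    genotypes.dosages[snp_id].to_numpy(dtype=float),
                    covars,
                    outcome_id="BMI",
                    predictor_id=snp_id,
                    model_role=role,
                )
            )
    return ScanTable.from_results(results, role, covariate_names)
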