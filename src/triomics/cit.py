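"""Causal inference test (CIT) for mediation.

Tests whether a mediator G (a transcript) transmits the effect of a genetic
instrument L (a SNP dosage) to an outcome T (the trait), via four component
tests combined as an intersection-union test: the omnibus null is that at
least one component null holds, so p_omnibus = max(p1, p2, p3, p4) and the
test rejects only if every component rejects.

Components (all conditional on covariates, which are projected out of
L, G, T once up front — exact for p1-p3 by Frisch-Waugh with degrees of
freedom carried over; an approximation only for the permutation component):

    p1: L associated with T              (F-test of L in T ~ L)
    p2: L associated with G given T      (F-test of L in G ~ L + T)
    p3: G associated with T given L      (F-test of G in T ~ G + L)
    p4: equivalence-style conditional-independence component: the observed
        F for L in T ~ L + G is compared against a permutation null that
        preserves the L-G relation while severing the G-T relation — the
        mediator is reconstructed as G* = fitted(G ~ L) + permuted
        residuals, and F is recomputed per permutation;
        p4 = (1 + #{F_perm <= F_obs}) / (n_perm + 1), small when the
        residual L-T association is small relative to that null.

An alternative ``scheme="strata"`` permutes L within quantile bins of G
(preserving the L-G relation approximately); note that under true mediation
its permutation null matches the observed distribution, so it has little
power — it is retained for comparison only.

The reverse direction (trait mediates the SNP's effect on the transcript)
is the same machinery with G and T swapped.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import DEFAULT_COVARIATES
from .datatypes import ExpressionMatrix, GenotypeMatrix, PhenotypeTable
from .exceptions import DegenerateInputError, ValidationError
from .prioritize import pick_top_snp

_TINY_P = 5e-324


@dataclass
class CITResult:
    snp_id: str
    mediator_id: str
    outcome_id: str
    direction: str  # forward (transcript mediates) or reverse (trait mediates)
    p_cond1: float
    p_cond2: float
    p_cond3: float
    p_cond4: float
    p_omnibus: float
    n_perm: int
    seed: int


def _residualize(v: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    if C is None or C.shape[1] == 0:
        return v - v.mean()
    X = np.column_stack([np.ones(len(v)), C])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


def _f_last(y: np.ndarray, cols: list[np.ndarray], df_loss: int):
    """F statistic and p for the last column of the design [1, *cols]."""
    n = len(y)
    X = np.column_stack([np.ones(n)] + cols)
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    X0 = X[:, :-1]
    Q0, R0 = np.linalg.qr(X0)
    b0 = np.linalg.solve(R0, Q0.T @ y)
    r0 = y - X0 @ b0
    rss0 = float(r0 @ r0)
    df = n - X.shape[1] - df_loss
    if df <= 0:
        raise ValidationError("cit: insufficient degrees of freedom")
    if rss1 <= 0:
        return np.inf, _TINY_P
    F = (rss0 - rss1) / (rss1 / df)
    p = float(stats.f.sf(F, 1, df))
    return F, min(max(p, _TINY_P), 1.0)


def _perm_f_variable_g(Lc, Tc, Gmat, n_params_df):
    """Vectorized F for L in T ~ 1 + G + L with G varying across columns of
    Gmat (n x n_perm). All inputs centered, so the intercept is implicit."""
    Gc = Gmat - Gmat.mean(axis=0)
    a = float(Lc @ Lc)
    u = float(Lc @ Tc)
    tt = float(Tc @ Tc)
    b = Lc @ Gc
    c = np.einsum("ij,ij->j", Gc, Gc)
    v = Tc @ Gc
    det = a * c - b * b
    bL = (c * u - b * v) / det
    bG = (a * v - b * u) / det
    rss = tt - bL * u - bG * v
    df = len(Lc) - 3 - n_params_df
    F = bL * bL * det / c / np.maximum(rss / df, 1e-300)
    return F


def _perm_f_variable_l(Lmat, Tc, Gc, n_params_df):
    """Vectorized F for L in T ~ 1 + G + L with L varying across columns."""
    Lc = Lmat - Lmat.mean(axis=0)
    c = float(Gc @ Gc)
    v = float(Tc @ Gc)
    tt = float(Tc @ Tc)
    a = np.einsum("ij,ij->j", Lc, Lc)
    b = Gc @ Lc
    u = Tc @ Lc
    det = a * c - b * b
    bL = (c * u - b * v) / det
    bG = (a * v - b * u) / det
    rss = tt - bL * u - bG * v
    df = Lmat.shape[0] - 3 - n_params_df
    F = bL * bL * det / c / np.maximum(rss / df, 1e-300)
    return F


def cit_test(
    L,
    G,
    T,
    covariates=None,
    n_perm: int = 1000,
    seed: int = 0,
    n_bins: int = 10,
    scheme: str = "residual",
    direction: str = "forward",
    snp_id: str = "L",
    mediator_id: str = "G",
    outcome_id: str = "T",
) -> CITResult:
    """Run the four-component CIT on aligned complete-case vectors."""
    if n_perm < 100:
        raise ValidationError(f"cit_test: n_perm must be >= 100, got {n_perm}")
    if scheme not in ("residual", "strata"):
        raise ValidationError("cit_test: scheme must be 'residual' or 'strata'")
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (len(L) == len(G) == len(T)):
        raise ValidationError("cit_test: L, G, T must have equal length")
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = np.isfinite(L) & np.isfinite(G) & np.isfinite(T)
    if C is not None:
        keep &= np.isfinite(C).all(axis=1)
        C = C[keep]
    L, G, T = L[keep], G[keep], T[keep]
    n = len(L)
    if n < 30:
        raise ValidationError(f"cit_test: need n >= 30 complete cases, got {n}")
    if np.ptp(L) == 0.0 or np.ptp(G) == 0.0:
        raise DegenerateInputError("cit_test: constant L or G")

    n_cov = 0 if C is None else C.shape[1]
    Lr = _residualize(L, C)
    Gr = _residualize(G, C)
    Tr = _residualize(T, C)

    _, p1 = _f_last(Tr, [Lr], n_cov)
    _, p2 = _f_last(Gr, [Tr, Lr], n_cov)
    _, p3 = _f_last(Tr, [Lr, Gr], n_cov)
    F_obs, _ = _f_last(Tr, [Gr, Lr], n_cov)

    rng = np.random.default_rng(seed)
    if scheme == "residual":
        X = np.column_stack([np.ones(n), Lr])
        coef, *_ = np.linalg.lstsq(X, Gr, rcond=None)
        ghat = X @ coef
        r = Gr - ghat
        R = rng.permuted(np.broadcast_to(r, (n_perm, n)).copy(), axis=1).T
        Gstar = ghat[:, None] + R
        F_perm = _perm_f_variable_g(Lr, Tr, Gstar, n_cov)
    else:
        qs = np.quantile(Gr, np.linspace(0.0, 1.0, n_bins + 1))
        bins = np.clip(np.searchsorted(qs, Gr, side="right") - 1, 0, n_bins - 1)
        Lmat = np.empty((n, n_perm))
        for j in range(n_perm):
            Lp = Lr.copy()
            for bidx in range(n_bins):
                sel = np.where(bins == bidx)[0]
                Lp[sel] = Lr[sel][rng.permutation(len(sel))]
            Lmat[:, j] = Lp
        F_perm = _perm_f_variable_l(Lmat, Tr, Gr, n_cov)

    p4 = (1.0 + float(np.sum(F_perm <= F_obs))) / (n_perm + 1.0)
    p_omni = max(p1, p2, p3, p4)
    return CITResult(
        snp_id=snp_id, mediator_id=mediator_id, outcome_id=outcome_id,
        direction=direction, p_cond1=p1, p_cond2=p2, p_cond3=p3, p_cond4=p4,
        p_omnibus=p_omni, n_perm=n_perm, seed=seed,
    )


def derive_seed(master_seed: int, *key_parts) -> int:
    """Stable per-test seed below 2**31 from the master seed and a pair key."""
    h = hashlib.blake2b(
        ("|".join([str(master_seed), *map(str, key_parts)])).encode(), digest_size=8
    )
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def cit_for_prioritized(
    triplets: pd.DataFrame,
    snp_scan,
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    covariate_names=DEFAULT_COVARIATES,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "residual",
) -> list[CITResult]:
    """Forward and reverse CIT for every prioritized transcript.

    For each transcript passing the five-criterion screen, the most
    significant SNP from its SNP-transcript associations is used (avoiding
    multicollinearity among LD proxies). Per-test seeds are derived
    deterministically from the master seed and the pair key.
    """
    passed = triplets[triplets["passed"]] if "passed" in triplets.columns else triplets
    if passed.empty:
        raise ValidationError("cit_for_prioritized: no prioritized triplets")
    covars = (
        phenotypes.table[list(covariate_names)].to_numpy(dtype=float)
        if covariate_names else None
    )
    bmi = phenotypes.table["bmi"].to_numpy(dtype=float)
    results = []
    for tx in sorted(passed["transcript_id"].unique()):
        snp = pick_top_snp(tx, snp_scan, genotypes.snp_meta)
        dose = genotypes.dosages[snp].to_numpy(dtype=float)
        expr = expression.values[tx].to_numpy(dtype=float)
        results.append(
            cit_test(
                dose, expr, bmi, covars, n_perm=n_perm,
                seed=derive_seed(seed, snp, tx, "forward"), scheme=scheme,
                direction="forward", snp_id=snp, mediator_id=tx, outcome_id="BMI",
            )
        )
        results.append(
            cit_test(
                dose, bmi, expr, covars, n_perm=n_perm,
                seed=derive_seed(seed, snp, tx, "reverse"), scheme=scheme,
                direction="reverse", snp_id=snp, mediator_id="BMI", outcome_id=tx,
            )
        )
    return results


def cit_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.snp_id, r.mediator_id, r.outcome_id, r.direction, r.p_cond1,
             r.p_cond2, r.p_cond3, r.p_cond4, r.p_omnibus, r.n_perm, r.seed)
            for r in results
        ],
        columns=["snp_id", "mediator_id", "outcome_id", "direction", "p1", "p2",
                 "p3", "p4", "p_omnibus", "n_perm", "seed"],
    )
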