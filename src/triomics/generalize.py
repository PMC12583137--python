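"""Fisher's-method generalization of discovery signals.

Generalization cohorts and tissues provide sparser, independently computed
SNP-transcript and transcript-BMI p-values. These are combined with the
traditional (independence-assuming) Fisher's method rather than the
correlated meta-analysis — with two studies, X^2 = -2(ln p1 + ln p2) is
chi-squared with 4 degrees of freedom — and a record generalizes when

    P_meta < 0.05  and  P_meta < P_SNP  and  P_meta < P_BMI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from .exceptions import ValidationError

FISHER_DF = 4  # two combined p-values -> 2k = 4 degrees of freedom


@dataclass
class FisherResult:
    x2: float
    df: int
    p_meta: float


def fisher_meta(p1: float, p2: float) -> FisherResult:
    """Combine two independent p-values: X^2 = -2(ln p1 + ln p2) ~ chi2(4).

    p = 1 is accepted (no evidence); p = 0 is a domain error (log diverges).
    Accurate for inputs down to ~1e-300 via the chi-squared survival function.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"fisher_meta: {name} must be in (0, 1], got {p}")
    x2 = -2.0 * (math.log(p1) + math.log(p2))
    p_meta = float(stats.chi2.sf(x2, FISHER_DF))
    return FisherResult(x2=x2, df=FISHER_DF, p_meta=min(max(p_meta, 5e-324), 1.0))


def generalization_filter(p_meta: float, p_snp: float, p_bmi: float,
                          alpha: float = 0.05) -> bool:
    """Strict three-way conjunction: P_meta < alpha & P_meta < P_SNP & P_meta < P_BMI."""
    for name, p in (("p_meta", p_meta), ("p_snp", p_snp), ("p_bmi", p_bmi)):
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"generalization_filter: {name} must be in (0, 1], got {p}")
    return (p_meta < alpha) and (p_meta < p_snp) and (p_meta < p_bmi)


def run_generalization(
    triplets: pd.DataFrame,
    tissue_tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher combination + significance filter per discovery triplet and tissue.

    Each tissue table must carry columns snp_id, transcript_id, p_snp, p_bmi
    (either p may be missing/NaN, mirroring sparse generalization data).
    Records with a missing component are emitted with significant = False and
    missing_flag = True.
    """
    discovery = triplets[triplets["passed"]] if "passed" in triplets.columns else triplets
    rows = []
    for tissue, table in tissue_tables.items():
        lookup = table.set_index(["snp_id", "transcript_id"])
        for _, trip in discovery.iterrows():
            key = (trip["snp_id"], trip["transcript_id"])
            p_snp = p_bmi = float("nan")
            if key in lookup.index:
                rec = lookup.loc[key]
                p_snp = float(rec["p_snp"])
                p_bmi = float(rec["p_bmi"])
            missing = not (p_snp == p_snp and p_bmi == p_bmi)  # NaN check
            if missing:
                x2, p_meta, sig = float("nan"), float("nan"), False
            else:
                fr = fisher_meta(p_bmi, p_snp)
                x2, p_meta = fr.x2, fr.p_meta
                sig = generalization_filter(p_meta, p_snp, p_bmi, alpha)
            rows.append(
                (tissue, trip["snp_id"], trip["transcript_id"], p_bmi, p_snp,
                 x2, p_meta, sig, missing)
            )
    return pd.DataFrame(
        rows,
        columns=["tissue", "snp_id", "transcript_id", "p_bmi", "p_snp", "x2",
                 "p_meta", "significant", "missing_flag"],
    )
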