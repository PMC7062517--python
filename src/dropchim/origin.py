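"""Per-cell sex assignment from XIST/RPS4Y1 and donor/recipient chimerism.

A cell is called female if XIST > 0 and RPS4Y1 == 0, male in the mirrored
case; double-positives are "both" (ambiguous) and double-negatives "neither"
(unassigned). Sample metadata (recipient vs donor sex) maps sex calls to
origin; per-sample summaries report category percentages over all cells and
the donor/recipient split among assignable cells only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .types import FEMALE, MALE, SEX_GENES, CountMatrix, SampleMeta

BOTH = "both"
NEITHER = "neither"

MARKER_GENES = ("CD68", "MARCO")


@dataclass(frozen=True)
class OriginCall:
    origin: str  # recipient | donor | ambiguous | unassigned
    sex_call: str  # female | male | both | neither

    def __post_init__(self) -> None:
        if (self.origin == "ambiguous") != (self.sex_call == BOTH):
            raise ValueError("ambiguous iff sex call is 'both'")
        if (self.origin == "unassigned") != (self.sex_call == NEITHER):
            raise ValueError("unassigned iff sex call is 'neither'")


@dataclass
class ChimerismSummary:
    sample_id: str
    n_cells: int
    pct_xist_pos: float  # % of all cells called female-only
    pct_rps4y1_pos: float  # % of all cells called male-only
    pct_ambiguous: float
    pct_unassigned: float
    n_recipient: int
    n_donor: int
    pct_recipient: float | None  # among assignable; None if none assignable
    pct_donor: float | None

    @property
    def n_assignable(self) -> int:
        return self.n_recipient + self.n_donor


def assign_sex(xist_count: int, rps4y1_count: int) -> str:
    if xist_count < 0 or rps4y1_count < 0:
        raise ValueError("counts must be nonnegative")
    if xist_count > 0 and rps4y1_count > 0:
        return BOTH
    if xist_count > 0:
        return FEMALE
    if rps4y1_count > 0:
        return MALE
    return NEITHER


def map_origin(sex_call: str, meta: SampleMeta) -> OriginCall:
    if not meta.sex_mismatched:
        raise ValueError("origin not identifiable: recipient and donor share one sex")
    if sex_call == BOTH:
        return OriginCall("ambiguous", BOTH)
    if sex_call == NEITHER:
        return OriginCall("unassigned", NEITHER)
    origin = "recipient" if sex_call == meta.recipient_sex else "donor"
    return OriginCall(origin, sex_call)


def gate_macrophages(
    matrix: CountMatrix,
    markers: Sequence[str] = MARKER_GENES,
    mode: str = "off",
) -> np.ndarray:
    """Per-cell boolean mask from marker positivity (count > 0)."""
    if mode not in ("off", "any_positive", "all_positive"):
        raise ValueError(f"unknown gating mode {mode!r}")
    if mode == "off":
        return np.ones(matrix.n_barcodes, dtype=bool)
    missing = [m for m in markers if m not in matrix.genes]
    if missing:
        raise ValueError(f"marker genes missing from panel: {missing}")
    positive = np.vstack([matrix.gene_counts(m) > 0 for m in markers])
    return positive.any(axis=0) if mode == "any_positive" else positive.all(axis=0)


def call_cells_origin(
    matrix: CountMatrix, meta: SampleMeta, gate_mode: str = "off"
) -> pd.DataFrame:
    """Sex + origin call per barcode of a QC-passing raw count matrix.

    Operates on raw counts (the > 0 rule is normalization-invariant). Cells
    failing the optional macrophage gate are excluded from the output.
    """
    xist = matrix.gene_counts("XIST") if "XIST" in matrix.genes else np.zeros(matrix.n_barcodes, dtype=int)
    rps = matrix.gene_counts("RPS4Y1") if "RPS4Y1" in matrix.genes else np.zeros(matrix.n_barcodes, dtype=int)
    mask = gate_macrophages(matrix, mode=gate_mode)
    rows = []
    for i, bc in enumerate(matrix.barcodes):
        if not mask[i]:
            continue
        call = map_origin(assign_sex(int(xist[i]), int(rps[i])), meta)
        rows.append((bc, call.sex_call, call.origin))
    return pd.DataFrame(rows, columns=["barcode", "sex_call", "origin"])


def summarize_chimerism(
    calls: Sequence[OriginCall] | pd.DataFrame, meta: SampleMeta
) -> ChimerismSummary:
    """Table-style per-sample summary of origin calls.

    Percentages of female-only / male-only / ambiguous / unassigned cells are
    over all input cells (they total 100); the recipient/donor split is over
    assignable cells only, undefined (None) when no cell is assignable.
    """
    if isinstance(calls, pd.DataFrame):
        origins = calls["origin"].tolist()
        sexes = calls["sex_call"].tolist()
    else:
        origins = [c.origin for c in calls]
        sexes = [c.sex_call for c in calls]
    n = len(origins)
    if n == 0:
        raise ValueError("summarize_chimerism requires at least one cell")
    n_female = sexes.count(FEMALE)
    n_male = sexes.count(MALE)
    n_both = sexes.count(BOTH)
    n_neither = sexes.count(NEITHER)
    n_recipient = origins.count("recipient")
    n_donor = origins.count("donor")
    n_assign = n_recipient + n_donor
    return ChimerismSummary(
        sample_id=meta.sample_id,
        n_cells=n,
        pct_xist_pos=100.0 * n_female / n,
        pct_rps4y1_pos=100.0 * n_male / n,
        pct_ambiguous=100.0 * n_both / n,
        pct_unassigned=100.0 * n_neither / n,
        n_recipient=n_recipient,
        n_donor=n_donor,
        pct_recipient=100.0 * n_recipient / n_assign if n_assign else None,
        pct_donor=100.0 * n_donor / n_assign if n_assign else None,
    )


def estimate_chimerism_fraction(
    summary: ChimerismSummary,
    lambda_recipient: float,
    lambda_donor: float,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Dropout-corrected recipient-fraction estimate with a Wilson interval.

    With detection probabilities d = 1 - exp(-lambda), the estimator solves
    f_hat = (p_R/d_R) / (p_R/d_R + p_D/d_D) where p are the observed
    exclusive-positive fractions. The Wilson interval for the assignable-cell
    recipient proportion is mapped through the same (monotone) transform.
    """
    if lambda_recipient <= 0 or lambda_donor <= 0:
        raise ValueError("detection rates require positive lambdas")
    d_r = 1.0 - math.exp(-lambda_recipient)
    d_d = 1.0 - math.exp(-lambda_donor)
    n_assign = summary.n_assignable
    if n_assign == 0:
        raise ValueError("undefined: no assignable cells")

    def invert(q: float) -> float:
        if q <= 0.0:
            return 0.0
        if q >= 1.0:
            return 1.0
        a = q / d_r
        b = (1.0 - q) / d_d
        return a / (a + b)

    q_hat = summary.n_recipient / n_assign
    lo, hi = proportion_confint(summary.n_recipient, n_assign, alpha=alpha, method="wilson")
    return invert(q_hat), (invert(float(lo)), invert(float(hi)))
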