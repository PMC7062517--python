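"""Cell calling from the per-barcode total-UMI distribution.

A robust maximum is taken as the nearest-rank 99th percentile of the top
``expected_cells`` barcode totals; every barcode within an order of
magnitude of it (total >= robust_max / 10) is called as a cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

DEFAULT_EXPECTED_CELLS = 10_000
PERCENTILE = 99.0


@dataclass
class CellCallResult:
    barcodes: list[str]
    robust_max: float
    threshold: float

    def __contains__(self, barcode: str) -> bool:
        return barcode in set(self.barcodes)


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Inclusive nearest-rank percentile: the ceil(pct/100 * n)-th smallest."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("empty input")
    rank = max(1, math.ceil(pct / 100.0 * v.size))
    return float(v[rank - 1])


def call_cells(
    barcode_totals: Mapping[str, int],
    expected_cells: int = DEFAULT_EXPECTED_CELLS,
) -> CellCallResult:
    if expected_cells < 1:
        raise ValueError("expected_cells must be >= 1")
    items = [(b, t) for b, t in barcode_totals.items() if t > 0]
    if not items:
        raise ValueError("no candidate cells: all barcode totals are zero")
    items.sort(key=lambda bt: (-bt[1], bt[0]))
    totals = np.array([t for _, t in items], dtype=float)
    top = totals[: min(expected_cells, len(totals))]
    robust_max = nearest_rank_percentile(top, PERCENTILE)
    threshold = robust_max / 10.0
    called = [b for b, t in items if t >= threshold]
    return CellCallResult(barcodes=called, robust_max=robust_max, threshold=threshold)
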