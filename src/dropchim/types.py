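"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

FEMALE = "female"
MALE = "male"

SEX_GENES = {FEMALE: "XIST", MALE: "RPS4Y1"}

#: Genes that must never be removed by family-based discards: the sex
#: transcripts used for origin calling and the macrophage identity markers.
PROTECTED_GENES = frozenset({"XIST", "RPS4Y1", "CD68", "MARCO"})

PHRED_OFFSET = 33


def phred_decode(quals: str) -> np.ndarray:
    """ASCII (offset-33) quality string -> integer Phred scores."""
    return np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET


def phred_encode(scores: Sequence[int]) -> str:
    arr = np.asarray(scores, dtype=np.uint8) + PHRED_OFFSET
    return arr.tobytes().decode("ascii")


@dataclass
class CountMatrix:
    """Sparse genes x barcodes matrix of UMI counts with identifier sidecars."""

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def gene_counts(self, gene: str) -> np.ndarray:
        """Per-barcode counts for one gene (dense vector)."""
        try:
            i = self.genes.index(gene)
        except ValueError as exc:
            raise KeyError(f"gene {gene!r} not in panel") from exc
        return np.asarray(self.matrix[i].todense()).ravel()

    def subset_genes(self, keep: Sequence[int]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(self.matrix[keep, :], [self.genes[i] for i in keep], list(self.barcodes))

    def subset_barcodes(self, keep: Sequence[int]) -> "CountMatrix":
        keep = list(keep)
        return CountMatrix(
            self.matrix[:, keep], list(self.genes), [self.barcodes[i] for i in keep]
        )

    def select_barcodes(self, barcodes: Sequence[str]) -> "CountMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        return self.subset_barcodes([index[b] for b in barcodes])

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.barcodes == other.barcodes
            and (self.matrix != other.matrix).nnz == 0
        )


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced molecule: observed barcode/UMI with per-base qualities."""

    barcode_observed: str
    barcode_quals: str
    umi_observed: str
    umi_quals: str
    gene: str

    def __post_init__(self) -> None:
        if len(self.barcode_observed) != len(self.barcode_quals):
            raise ValueError("barcode quality length mismatch")
        if len(self.umi_observed) != len(self.umi_quals):
            raise ValueError("UMI quality length mismatch")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample transplant metadata driving sex -> origin mapping."""

    sample_id: str
    recipient_sex: str
    donor_sex: str
    months_post_transplant: float = 0.0

    def __post_init__(self) -> None:
        for sex in (self.recipient_sex, self.donor_sex):
            if sex not in (FEMALE, MALE):
                raise ValueError(f"invalid sex {sex!r}")
        if self.months_post_transplant < 0:
            raise ValueError("months_post_transplant must be nonnegative")

    @property
    def sex_mismatched(self) -> bool:
        return self.recipient_sex != self.donor_sex


@dataclass
class StageLog:
    """Provenance entry for one pipeline stage."""

    stage: str
    n_in: int
    n_out: int
    params: dict = field(default_factory=dict)
    sample_id: str | None = None
    config_hash: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError(f"stage {self.stage}: items out ({self.n_out}) > items in ({self.n_in})")

    @property
    def retention(self) -> float:
        return self.n_out / self.n_in if self.n_in else 1.0
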