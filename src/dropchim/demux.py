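"""Barcode retention/correction and UMI filtering/correction.

Reads are kept only if their cell barcode is on (or correctable onto) the
whitelist, their UMI is a non-homopolymer with all base qualities above 10,
and — after within-gene UMI merging — their (barcode, UMI) pair maps to a
single gene. Each surviving distinct (barcode, UMI, gene) molecule
contributes exactly one count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import CountMatrix, ReadRecord, phred_decode

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: Minimum normalized posterior for accepting a Hamming-1 barcode correction.
POSTERIOR_THRESHOLD = 0.975


@dataclass
class Whitelist:
    """Known valid cell barcodes with observed read support per member."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        lengths = {len(b) for b in self.counts}
        if len(lengths) > 1:
            raise ValueError("whitelist members must share one length")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("abundances must be nonnegative")
        self.length = lengths.pop() if lengths else 0

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def abundance(self, barcode: str) -> int:
        return self.counts[barcode]

    @property
    def members(self) -> set[str]:
        return set(self.counts)


@dataclass(frozen=True)
class MoleculeKey:
    """A deduplicated molecule: corrected barcode + UMI + gene + read support."""

    barcode: str
    umi: str
    gene: str
    reads: int

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError("read count must be >= 1")


def _hamming1_variants(seq: str):
    for i, base in enumerate(seq):
        for alt in BASES:
            if alt != base:
                yield i, seq[:i] + alt + seq[i + 1 :]


def correct_barcode(
    observed: str,
    quals: str | Sequence[int],
    whitelist: Whitelist,
    threshold: float = POSTERIOR_THRESHOLD,
) -> str | None:
    """Return the retained barcode for one read, or None to discard.

    Exact whitelist hits pass through unchanged. Otherwise every whitelist
    member at Hamming distance exactly 1 is scored by
    ``abundance * P(sequencing error | Phred at the mismatched base)`` with
    ``P(error | q) = 10**(-q/10)``; the argmax is returned only when its
    normalized posterior reaches ``threshold``.
    """
    if len(observed) != whitelist.length:
        raise ValueError(
            f"observed barcode length {len(observed)} != whitelist length {whitelist.length}"
        )
    if observed in whitelist:
        return observed
    q = phred_decode(quals) if isinstance(quals, str) else np.asarray(quals)
    if len(q) != len(observed):
        raise ValueError("quality length mismatch")
    candidates: list[tuple[str, float]] = []
    for pos, variant in _hamming1_variants(observed):
        if variant in whitelist:
            p_err = 10.0 ** (-q[pos] / 10.0)
            candidates.append((variant, whitelist.abundance(variant) * p_err))
    if not candidates:
        return None
    total = sum(w for _, w in candidates)
    if total <= 0:
        return None
    best, weight = max(candidates, key=lambda c: c[1])
    return best if weight / total >= threshold else None


def filter_umi(umi: str, quals: str | Sequence[int]) -> bool:
    """True iff the UMI is not a homopolymer and every base has Phred > 10."""
    if not umi:
        raise ValueError("empty UMI")
    q = phred_decode(quals) if isinstance(quals, str) else np.asarray(quals)
    if len(q) != len(umi):
        raise ValueError("quality length mismatch")
    return len(set(umi)) > 1 and int(q.min()) > 10


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def correct_umis(molecules: Iterable[MoleculeKey]) -> set[MoleculeKey]:
    """Merge each UMI into a strictly more prolific Hamming-1 UMI of the
    same barcode and gene.

    Single pass in descending read-support order (ties broken
    lexicographically); the comparison uses pre-merge read counts so the
    result does not depend on merge order. Total read count is conserved.
    """
    mols = list(molecules)
    barcodes = {m.barcode for m in mols}
    if len(barcodes) > 1:
        raise ValueError("correct_umis expects molecules of a single barcode")
    out: set[MoleculeKey] = set()
    by_gene: dict[str, list[MoleculeKey]] = {}
    for m in mols:
        by_gene.setdefault(m.gene, []).append(m)
    for gene, group in by_gene.items():
        original = {m.umi: m.reads for m in group}
        if len(original) != len(group):
            raise ValueError(f"duplicate UMI keys for gene {gene}")
        order = sorted(original, key=lambda u: (-original[u], u))
        merged = dict(original)
        absorbed: set[str] = set()
        for i, u in enumerate(order):
            if u in absorbed:
                continue
            for v in order[i + 1 :]:
                if v in absorbed:
                    continue
                if original[v] < original[u] and _hamming(u, v) == 1:
                    merged[u] += merged[v]
                    del merged[v]
                    absorbed.add(v)
        barcode = group[0].barcode
        for u, reads in merged.items():
            out.add(MoleculeKey(barcode, u, gene, reads))
    return out


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        (r.barcode_observed, r.barcode_quals, r.umi_observed, r.umi_quals, r.gene)
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["barcode", "barcode_quals", "umi", "umi_quals", "gene"]
    )


def build_count_matrix(
    records,
    whitelist: Whitelist,
    genes: Sequence[str] | None = None,
    barcodes: Sequence[str] | None = None,
) -> CountMatrix:
    """Demultiplex read records into a deduplicated genes x barcodes matrix.

    Parameters
    ----------
    records
        Sequence of :class:`ReadRecord` or a DataFrame with columns
        barcode, barcode_quals, umi, umi_quals, gene.
    genes, barcodes
        Optional fixed axis orderings; defaults to the sorted identifiers
        observed after filtering (barcodes restricted to those retaining at
        least one molecule).
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no read records supplied")

    # Barcode correction: exact members pass; each unique (observed, quals)
    # miss is adjudicated once.
    members = whitelist.members
    exact = df["barcode"].isin(members)
    corrected = df["barcode"].copy()
    misses = df.loc[~exact, ["barcode", "barcode_quals"]].drop_duplicates()
    if not misses.empty:
        mapping = {
            (b, q): correct_barcode(b, q, whitelist)
            for b, q in misses.itertuples(index=False)
        }
        keys = list(zip(df.loc[~exact, "barcode"], df.loc[~exact, "barcode_quals"]))
        corrected.loc[~exact] = [mapping[k] for k in keys]
    df = df.assign(barcode=corrected)
    df = df[df["barcode"].notna()]

    # UMI retention: non-homopolymer, min Phred > 10. ASCII comparison works
    # because offset-33 encoding is monotone; Phred 10 encodes as '+'.
    if not df.empty:
        ok_qual = df["umi_quals"].map(min) > chr(10 + 33)
        not_homopolymer = df["umi"].map(lambda u: len(set(u)) > 1)
        df = df[ok_qual & not_homopolymer]

    if df.empty:
        warnings.warn("all reads rejected; returning empty count matrix")
        return CountMatrix(
            sp.csr_matrix((len(genes or []), len(barcodes or [])), dtype=np.int64),
            list(genes or []),
            list(barcodes or []),
        )

    reads = (
        df.groupby(["barcode", "gene", "umi"], sort=True).size().rename("reads").reset_index()
    )

    # Within-gene UMI merging, per barcode. A merge needs strictly unequal
    # read support within a (barcode, gene) group, so groups whose support is
    # uniform (the overwhelming majority) are skipped wholesale.
    grp_sizes = reads.groupby(["barcode", "gene"])["reads"].transform("size")
    grp_min = reads.groupby(["barcode", "gene"])["reads"].transform("min")
    grp_max = reads.groupby(["barcode", "gene"])["reads"].transform("max")
    needs_merge = (grp_sizes > 1) & (grp_min != grp_max)
    merged_parts = [reads[~needs_merge]]
    for (bc, gene), grp in reads[needs_merge].groupby(["barcode", "gene"], sort=False):
        mols = [MoleculeKey(bc, u, gene, int(r)) for u, r in zip(grp["umi"], grp["reads"])]
        out = correct_umis(mols)
        merged_parts.append(
            pd.DataFrame(
                {
                    "barcode": bc,
                    "gene": gene,
                    "umi": [m.umi for m in out],
                    "reads": [m.reads for m in out],
                }
            )
        )
    mol = pd.concat(merged_parts, ignore_index=True)

    # Multi-gene (barcode, UMI) collisions: keep the gene with most reads,
    # drop the pair entirely on a tie.
    def _resolve(grp: pd.DataFrame) -> pd.DataFrame:
        top = grp["reads"].max()
        best = grp[grp["reads"] == top]
        return best if len(best) == 1 else best.iloc[0:0]

    collide = mol.duplicated(["barcode", "umi"], keep=False)
    if collide.any():
        resolved = (
            mol[collide]
            .groupby(["barcode", "umi"], group_keys=False, sort=False)[mol.columns]
            .apply(_resolve)
        )
        mol = pd.concat([mol[~collide], resolved], ignore_index=True)

    counts = mol.groupby(["barcode", "gene"], sort=True).size()
    if counts.empty:
        warnings.warn("all reads rejected; returning empty count matrix")
        return CountMatrix(
            sp.csr_matrix((len(genes or []), len(barcodes or [])), dtype=np.int64),
            list(genes or []),
            list(barcodes or []),
        )

    gene_list = list(genes) if genes is not None else sorted(counts.index.get_level_values("gene").unique())
    bc_list = (
        list(barcodes)
        if barcodes is not None
        else sorted(counts.index.get_level_values("barcode").unique())
    )
    gene_idx = {g: i for i, g in enumerate(gene_list)}
    bc_idx = {b: i for i, b in enumerate(bc_list)}
    rows = [gene_idx[g] for _, g in counts.index]
    cols = [bc_idx[b] for b, _ in counts.index]
    mat = sp.coo_matrix(
        (counts.to_numpy(dtype=np.int64), (rows, cols)),
        shape=(len(gene_list), len(bc_list)),
    ).tocsr()
    logger.info("demultiplexed %d reads into %d molecules", len(df), int(mat.sum()))
    return CountMatrix(mat, gene_list, bc_list)
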