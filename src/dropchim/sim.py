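"""Synthetic chimeric droplet experiments with known ground truth.

Generates count-level and read-level data for a two-sex cell mixture
(recipient vs donor origin) plus ambient/empty droplets. Sex-exclusive
transcripts (XIST in female cells, RPS4Y1 in male cells) are Poisson with
configurable rates, giving closed-form dropout probabilities that serve as
analytic oracles for the downstream assignment logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .demux import Whitelist
from .types import FEMALE, MALE, SEX_GENES, CountMatrix, phred_encode

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: 13 mitochondrially encoded genes (standard human "MT-" nomenclature).
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

#: 20 ribosomal-protein genes ("RPS"/"RPL" prefixes; RPS4Y1 is deliberately
#: absent — as a sex marker it is handled separately and never discarded).
RIBO_GENES = (
    "RPS2", "RPS3", "RPS6", "RPS8", "RPS12", "RPS18", "RPS24", "RPS27",
    "RPS29", "RPL3", "RPL5", "RPL7", "RPL10", "RPL11", "RPL13", "RPL15",
    "RPL23", "RPL26", "RPL30", "RPL37",
)

SPECIAL_GENES = ("XIST", "RPS4Y1", "CD68", "MARCO") + MITO_GENES + RIBO_GENES


def default_gene_panel(n_genes: int = 200) -> list[str]:
    """Gene panel: sex transcripts, macrophage markers, mito and ribosomal
    families, padded with numbered background genes to ``n_genes``."""
    if n_genes < len(SPECIAL_GENES) + 1:
        raise ValueError(f"n_genes must be >= {len(SPECIAL_GENES) + 1}")
    n_bg = n_genes - len(SPECIAL_GENES)
    return list(SPECIAL_GENES) + [f"BG{i:04d}" for i in range(1, n_bg + 1)]


@dataclass
class SimConfig:
    n_cells: int = 500
    chimerism_fraction: float = 0.8
    recipient_sex: str = FEMALE
    donor_sex: str = MALE
    n_genes: int = 200
    n_ambient_droplets: int = 0
    mean_cell_umis: float = 1000.0
    mean_ambient_umis: float = 10.0
    lambda_xist: float = 1.2
    lambda_rps4y1: float = 1.2
    marker_lambdas: Mapping[str, float] = field(
        default_factory=lambda: {"CD68": 3.0, "MARCO": 2.0}
    )
    macrophage_fraction: float = 0.85
    pct_mito_mean: float = 5.0
    pct_ribo_mean: float = 20.0
    library_sigma: float = 0.35
    barcode_length: int = 16
    umi_length: int = 10
    barcode_error_rate: float = 0.0
    umi_error_rate: float = 0.0
    mean_reads_per_molecule: float = 1.0
    ambient_sex_contamination: float = 0.0
    barcode_min_distance: int = 3
    dispersion: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if not 0.0 <= self.chimerism_fraction <= 1.0:
            raise ValueError("chimerism_fraction must be in [0, 1]")
        for sex in (self.recipient_sex, self.donor_sex):
            if sex not in (FEMALE, MALE):
                raise ValueError(f"invalid sex {sex!r}")
        if (
            self.recipient_sex == self.donor_sex
            and self.chimerism_fraction not in (0.0, 1.0)
        ):
            raise ValueError(
                "sex-matched configuration: chimerism requires recipient_sex != donor_sex"
            )
        if self.n_ambient_droplets < 0:
            raise ValueError("n_ambient_droplets must be nonnegative")
        rates = [
            self.lambda_xist, self.lambda_rps4y1, self.mean_cell_umis,
            self.mean_ambient_umis, self.barcode_error_rate, self.umi_error_rate,
            self.ambient_sex_contamination, *self.marker_lambdas.values(),
        ]
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be >= 0")
        if self.mean_cell_umis <= 0:
            raise ValueError("mean_cell_umis must be positive")
        if self.barcode_length <= 0 or self.umi_length <= 0:
            raise ValueError("barcode_length and umi_length must be positive")
        if not 0.0 <= self.macrophage_fraction <= 1.0:
            raise ValueError("macrophage_fraction must be in [0, 1]")
        if self.pct_mito_mean + self.pct_ribo_mean >= 100:
            raise ValueError("pct_mito_mean + pct_ribo_mean must be < 100")
        if self.mean_reads_per_molecule < 1:
            raise ValueError("mean_reads_per_molecule must be >= 1")

    def gene_panel(self) -> list[str]:
        return default_gene_panel(self.n_genes)


@dataclass
class GroundTruth:
    """Per-droplet truth channel for parameter-recovery tests.

    ``table`` has one row per droplet: barcode, is_cell, origin
    (recipient/donor/ambient), sex (female/male, or "" for ambient) and
    population (macrophage/other, "" for ambient). ``counts`` holds the true
    per-gene molecule counts, columns ordered as ``table``.
    """

    table: pd.DataFrame
    counts: CountMatrix


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tags))


def random_barcodes(
    rng: np.random.Generator, n: int, length: int, min_distance: int = 3
) -> list[str]:
    """Distinct random barcodes with pairwise Hamming distance >= min_distance,
    so that Hamming-1 correction onto the whitelist is unambiguous."""
    accepted = np.empty((0, length), dtype=np.uint8)
    out: list[str] = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(max(64, n - len(out)), length), dtype=np.uint8)
        for cand in batch:
            if len(out) == n:
                break
            if accepted.size:
                if int((accepted != cand).sum(axis=1).min()) < min_distance:
                    continue
            accepted = np.vstack([accepted, cand])
            out.append(_BASE_BYTES[cand].tobytes().decode("ascii"))
    return out


def _lognormal_sizes(rng, mean: float, sigma: float, n: int) -> np.ndarray:
    # mean-preserving parameterization; at least one molecule per droplet
    mu = math.log(mean) - sigma**2 / 2.0
    return np.maximum(rng.lognormal(mu, sigma, size=n).round().astype(np.int64), 1)


def _poisson_counts(rng, lam: float, n: int, dispersion: float | None) -> np.ndarray:
    """Poisson, or gamma-Poisson (negative binomial) when dispersion is set."""
    if lam == 0:
        return np.zeros(n, dtype=np.int64)
    if dispersion:
        lam = rng.gamma(1.0 / dispersion, lam * dispersion, size=n)
    return rng.poisson(lam, size=n)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate true molecule counts for cells and ambient droplets.

    Deterministic for a fixed config (including seed). Column sums of the
    returned matrix equal the realized per-droplet library sizes recorded
    in the ground-truth table.
    """
    config.validate()
    rng = _substream(config.seed, 0)
    genes = config.gene_panel()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_cells, n_amb = config.n_cells, config.n_ambient_droplets
    n_drop = n_cells + n_amb

    origin = np.where(
        rng.random(n_cells) < config.chimerism_fraction, "recipient", "donor"
    )
    sex = np.where(origin == "recipient", config.recipient_sex, config.donor_sex)
    population = np.where(
        rng.random(n_cells) < config.macrophage_fraction, "macrophage", "other"
    )

    counts = np.zeros((n_drop, config.n_genes), dtype=np.int64)

    # cells: per-family budgets drawn against a lognormal target library size
    L = _lognormal_sizes(rng, config.mean_cell_umis, config.library_sigma, n_cells)
    pm = config.pct_mito_mean / 100.0
    pr = config.pct_ribo_mean / 100.0
    mito_idx = [gene_idx[g] for g in MITO_GENES]
    ribo_idx = [gene_idx[g] for g in RIBO_GENES]
    bg_idx = [i for g, i in gene_idx.items() if g not in SPECIAL_GENES]
    # mildly uneven background composition shared by cells and ambient
    bg_w = 1.0 / (np.arange(len(bg_idx)) + 10.0)
    bg_w /= bg_w.sum()

    counts[:n_cells, mito_idx] = rng.multinomial(
        rng.poisson(L * pm), np.full(len(mito_idx), 1.0 / len(mito_idx))
    )
    counts[:n_cells, ribo_idx] = rng.multinomial(
        rng.poisson(L * pr), np.full(len(ribo_idx), 1.0 / len(ribo_idx))
    )
    counts[:n_cells, bg_idx] = rng.multinomial(rng.poisson(L * (1 - pm - pr)), bg_w)

    for s, gene, lam in (
        (FEMALE, "XIST", config.lambda_xist),
        (MALE, "RPS4Y1", config.lambda_rps4y1),
    ):
        mask = sex == s
        counts[:n_cells, gene_idx[gene]][mask] = 0  # sex exclusivity
        vals = _poisson_counts(rng, lam, int(mask.sum()), config.dispersion)
        col = counts[:n_cells, gene_idx[gene]]
        col[mask] = vals
        counts[:n_cells, gene_idx[gene]] = col
    for gene, lam in config.marker_lambdas.items():
        mask = population == "macrophage"
        vals = _poisson_counts(rng, lam, int(mask.sum()), config.dispersion)
        col = counts[:n_cells, gene_idx[gene]]
        col[mask] = vals
        counts[:n_cells, gene_idx[gene]] = col

    if n_amb:
        La = _lognormal_sizes(rng, config.mean_ambient_umis, config.library_sigma, n_amb)
        counts[n_cells:, bg_idx] = rng.multinomial(La, bg_w)
        if config.ambient_sex_contamination > 0:
            for gene in ("XIST", "RPS4Y1"):
                counts[n_cells:, gene_idx[gene]] = rng.poisson(
                    config.ambient_sex_contamination, size=n_amb
                )

    barcodes = random_barcodes(
        _substream(config.seed, 1), n_drop, config.barcode_length,
        config.barcode_min_distance,
    )
    table = pd.DataFrame(
        {
            "barcode": barcodes,
            "is_cell": [True] * n_cells + [False] * n_amb,
            "origin": list(origin) + ["ambient"] * n_amb,
            "sex": list(sex) + [""] * n_amb,
            "population": list(population) + [""] * n_amb,
            "library_size": counts.sum(axis=1),
        }
    )
    cm = CountMatrix(sp.csr_matrix(counts.T), genes, barcodes)
    truth = GroundTruth(table=table, counts=cm)
    return CountMatrix(cm.matrix.copy(), list(genes), list(barcodes)), truth


def _codes_to_strings(codes: np.ndarray) -> np.ndarray:
    """(n, L) base-index matrix -> array of n nucleotide strings."""
    return (
        np.ascontiguousarray(_BASE_BYTES[codes])
        .view(f"S{codes.shape[1]}")
        .ravel()
        .astype(str)
    )


def _quals_to_strings(quals: np.ndarray) -> np.ndarray:
    return (
        np.ascontiguousarray(quals.astype(np.uint8) + 33)
        .view(f"S{quals.shape[1]}")
        .ravel()
        .astype(str)
    )


def simulate_reads(
    config: SimConfig,
) -> tuple[pd.DataFrame, Whitelist, GroundTruth]:
    """Expand simulated molecule counts into read records.

    Each true molecule gets a UMI unique within its barcode (never a
    homopolymer, so lossless recovery is exact) and >= 1 read. Substitution
    errors hit barcode/UMI bases at the configured per-base rates; the
    erroneous base's Phred score is lowered into the 4..20 range.

    Returns a DataFrame of reads (columns barcode, barcode_quals, umi,
    umi_quals, gene), the true-barcode whitelist with per-barcode read
    support, and the ground truth.
    """
    config.validate()
    _, truth = simulate_counts(config)
    rng = _substream(config.seed, 2)
    genes = np.asarray(truth.counts.genes)
    coo = truth.counts.matrix.tocoo()

    # one row per molecule
    reps = coo.data.astype(np.int64)
    mol_gene = np.repeat(coo.row, reps)
    mol_col = np.repeat(coo.col, reps)
    order = np.argsort(mol_col, kind="stable")
    mol_gene, mol_col = mol_gene[order], mol_col[order]
    n_mol = len(mol_col)

    # UMIs unique within each barcode, homopolymers excluded
    umi_codes = np.empty((n_mol, config.umi_length), dtype=np.uint8)
    start = 0
    for col, size in zip(*np.unique(mol_col, return_counts=True)):
        block = _unique_umis(rng, int(size), config.umi_length)
        umi_codes[start : start + size] = block
        start += size

    reads_per_mol = (
        1 + rng.poisson(config.mean_reads_per_molecule - 1.0, size=n_mol)
        if config.mean_reads_per_molecule > 1
        else np.ones(n_mol, dtype=np.int64)
    )
    read_mol = np.repeat(np.arange(n_mol), reads_per_mol)
    n_reads = len(read_mol)

    bc_strings = np.asarray(truth.counts.barcodes)
    rev = {b: i for i, b in enumerate("ACGT")}
    bc_codes_all = np.array(
        [[rev[c] for c in b] for b in bc_strings], dtype=np.uint8
    )
    bc_codes = bc_codes_all[mol_col[read_mol]]
    umi_read_codes = umi_codes[read_mol].copy()

    bc_quals = rng.integers(30, 41, size=bc_codes.shape, dtype=np.int64)
    umi_quals = rng.integers(30, 41, size=umi_read_codes.shape, dtype=np.int64)

    bc_codes = bc_codes.copy()
    for codes, quals, rate in (
        (bc_codes, bc_quals, config.barcode_error_rate),
        (umi_read_codes, umi_quals, config.umi_error_rate),
    ):
        if rate <= 0:
            continue
        err = rng.random(codes.shape) < rate
        n_err = int(err.sum())
        if n_err:
            codes[err] = (codes[err] + rng.integers(1, 4, size=n_err)) % 4
            quals[err] = rng.integers(4, 21, size=n_err)

    reads = pd.DataFrame(
        {
            "barcode": _codes_to_strings(bc_codes),
            "barcode_quals": _quals_to_strings(bc_quals),
            "umi": _codes_to_strings(umi_read_codes),
            "umi_quals": _quals_to_strings(umi_quals),
            "gene": genes[mol_gene[read_mol]],
        }
    )
    support = np.zeros(len(bc_strings), dtype=np.int64)
    np.add.at(support, mol_col[read_mol], 1)
    whitelist = Whitelist({b: int(s) for b, s in zip(bc_strings, support)})
    return reads, whitelist, truth


def _unique_umis(rng, n: int, length: int) -> np.ndarray:
    """n distinct non-homopolymer UMIs as an (n, length) base-index matrix."""
    if n > 4**length // 2:
        raise ValueError("UMI space too small for requested molecule count")
    seen: set[bytes] = set()
    rows = np.empty((n, length), dtype=np.uint8)
    filled = 0
    while filled < n:
        batch = rng.integers(0, 4, size=(n - filled + 8, length), dtype=np.uint8)
        for row in batch:
            if filled == n:
                break
            key = row.tobytes()
            if key in seen or (row == row[0]).all():
                continue
            seen.add(key)
            rows[filled] = row
            filled += 1
    return rows


def expected_assignable_fraction(config: SimConfig) -> float:
    """Closed-form probability that a cell's own sex transcript is detected:
    ``f * (1 - exp(-lam_R)) + (1 - f) * (1 - exp(-lam_D))`` under the Poisson
    expression model."""
    config.validate()
    lam = {FEMALE: config.lambda_xist, MALE: config.lambda_rps4y1}
    f = config.chimerism_fraction
    lam_r = lam[config.recipient_sex]
    lam_d = lam[config.donor_sex]
    return f * (1.0 - math.exp(-lam_r)) + (1.0 - f) * (1.0 - math.exp(-lam_d))
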