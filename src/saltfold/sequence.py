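"""Sequence net charge, ortholog charge statistics, and alignment
covariation.

The charge model is the simple integer count used for comparing charged
protein surfaces at neutral pH: +1 per Lys/Arg, -1 per Asp/Glu, His and
termini neutral.  Covariation between alignment columns is scored by mutual
information (in bits, gaps treated as a 21st symbol) with the average
product correction (APC) that removes phylogenetic/entropy background,

    MI_apc(i, j) = MI(i, j) - MI(i, .) * MI(., j) / <MI>,

significance by a permutation null (columns shuffled independently within
themselves, which preserves column compositions while destroying any
covariation) and Benjamini-Hochberg control of the false discovery rate
across all column pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SequenceRecord",
    "Alignment",
    "ChargeProfile",
    "CovariationResult",
    "net_charge",
    "alignment_charge_stats",
    "covariation_mi",
    "read_fasta",
    "read_alignment",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE = set("KR")
NEGATIVE = set("DE")
GAP_CHARS = set("-.")


@dataclass
class SequenceRecord:
    """One amino-acid sequence (one-letter code; X allowed, gaps only in
    alignments)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - AMINO_ACIDS - {"X"} - GAP_CHARS
        if bad:
            raise ValueError(f"invalid characters in sequence {self.id!r}: {bad}")


@dataclass
class Alignment:
    """Equal-length gapped sequences."""

    rows: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        L = len(self.rows[0].sequence)
        if any(len(r.sequence) != L for r in self.rows):
            raise ValueError("alignment rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].sequence)

    def to_array(self) -> np.ndarray:
        """(n_rows, n_cols) array of single characters."""
        return np.array([list(r.sequence) for r in self.rows])


@dataclass
class ChargeProfile:
    """Charge composition of one sequence (or region)."""

    id: str
    n_D: int
    n_E: int
    n_K: int
    n_R: int
    net_charge: int


@dataclass
class CovariationResult:
    """MI covariation scan over all column pairs."""

    table: pd.DataFrame  # pos_i, pos_j, mi, mi_apc, p_value, q_value
    significant: pd.DataFrame  # rows with q_value < alpha
    alpha: float
    n_permutations: int


def net_charge(seq: SequenceRecord | str, region: tuple[int, int] | None = None
               ) -> ChargeProfile:
    """Integer net charge (+1 K/R, -1 D/E, His neutral) over a region.

    ``region`` is a half-open ``(start, stop)`` position range (0-based);
    the whole sequence when absent.  Gap characters are ignored.
    """
    if isinstance(seq, str):
        seq = SequenceRecord(id="", sequence=seq)
    s = seq.sequence
    if region is not None:
        start, stop = region
        if not (0 <= start <= stop <= len(s)):
            raise ValueError(f"region {region} outside sequence of length {len(s)}")
        s = s[start:stop]
    counts = {aa: s.count(aa) for aa in "DEKR"}
    return ChargeProfile(
        id=seq.id,
        n_D=counts["D"], n_E=counts["E"], n_K=counts["K"], n_R=counts["R"],
        net_charge=(counts["K"] + counts["R"]) - (counts["D"] + counts["E"]),
    )


def alignment_charge_stats(aln: Alignment, region: tuple[int, int] | None = None):
    """Mean per-row net charge with a normal-approximation 95% CI.

    Gaps never contribute to the counts.  Returns
    ``(mean, ci_halfwidth, per_row_charges)``.
    """
    if region is not None and not (0 <= region[0] <= region[1] <= aln.n_cols):
        raise ValueError(f"region {region} outside alignment of width {aln.n_cols}")
    charges = np.array(
        [net_charge(row, region).net_charge for row in aln.rows], dtype=float
    )
    mean = float(charges.mean())
    n = len(charges)
    sd = float(charges.std(ddof=1)) if n > 1 else 0.0
    ci = 1.96 * sd / math.sqrt(n)
    return mean, ci, charges


def _encode(aln: Alignment) -> tuple[np.ndarray, int]:
    """Integer-encode over the observed alphabet (gap as its own symbol)."""
    arr = aln.to_array()
    arr[np.isin(arr, list(GAP_CHARS))] = "-"
    symbols = np.unique(arr)
    lut = {s: i for i, s in enumerate(symbols)}
    enc = np.vectorize(lut.get)(arr).astype(np.int64)
    return enc, len(symbols)


def _mi_all_pairs(enc: np.ndarray, n_sym: int) -> np.ndarray:
    """MI (bits) for every column pair, via one one-hot Gram matrix."""
    n, L = enc.shape
    onehot = np.zeros((n, L * n_sym), dtype=np.float64)
    onehot[np.arange(n)[:, None], np.arange(L) * n_sym + enc] = 1.0
    joint = (onehot.T @ onehot).reshape(L, n_sym, L, n_sym).transpose(0, 2, 1, 3)
    p = joint / n  # (L, L, A, A)
    pi = p.sum(axis=3)  # marginal of column i within pair (L, L, A)
    pj = p.sum(axis=2)
    hi = -xlogy(pi, pi).sum(axis=2)
    hj = -xlogy(pj, pj).sum(axis=2)
    hij = -xlogy(p, p).sum(axis=(2, 3))
    mi = (hi + hj - hij) / math.log(2.0)
    np.fill_diagonal(mi, 0.0)
    return np.clip(mi, 0.0, None)


def _apc(mi: np.ndarray) -> np.ndarray:
    L = mi.shape[0]
    col_mean = mi.sum(axis=1) / (L - 1)
    overall = mi.sum() / (L * (L - 1))
    if overall == 0:
        return mi.copy()
    apc = mi - np.outer(col_mean, col_mean) / overall
    np.fill_diagonal(apc, 0.0)
    return apc


def covariation_mi(aln: Alignment, n_permutations: int = 1000,
                   seed: int | None = None, alpha: float = 0.05
                   ) -> CovariationResult:
    """APC-corrected mutual-information covariation scan with FDR control.

    The permutation null shuffles every column independently within itself
    ``n_permutations`` times; APC-corrected MI values from all pairs of all
    shuffled alignments are pooled into one null sample, giving p-value
    resolution of about 1/(n_permutations * n_pairs) so that a genuinely
    covarying pair can remain significant after Benjamini-Hochberg
    correction across all pairs.
    """
    if aln.n_cols < 2:
        raise ValueError("alignment must have at least 2 columns")
    if aln.n_rows < 20:
        raise ValueError("need >= 20 rows for a meaningful permutation null")
    rng = np.random.default_rng(seed)
    enc, n_sym = _encode(aln)
    n, L = enc.shape

    mi = _mi_all_pairs(enc, n_sym)
    apc = _apc(mi)
    iu, ju = np.triu_indices(L, k=1)
    obs = apc[iu, ju]

    null = np.empty((n_permutations, len(obs)))
    perm = enc.copy()
    for b in range(n_permutations):
        for col in range(L):
            perm[:, col] = perm[rng.permutation(n), col]
        null[b] = _apc(_mi_all_pairs(perm, n_sym))[iu, ju]
    null_flat = np.sort(null.ravel())
    # p = (1 + #null >= obs) / (1 + N_null)
    n_ge = len(null_flat) - np.searchsorted(null_flat, obs, side="left")
    pvals = (1.0 + n_ge) / (1.0 + len(null_flat))

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "pos_i": iu, "pos_j": ju,
            "mi": mi[iu, ju], "mi_apc": obs,
            "p_value": pvals, "q_value": qvals,
        }
    ).sort_values("q_value", kind="stable").reset_index(drop=True)
    return CovariationResult(
        table=table,
        significant=table[table["q_value"] < alpha].reset_index(drop=True),
        alpha=alpha,
        n_permutations=n_permutations,
    )


def read_fasta(path) -> list[SequenceRecord]:
    """Read plain FASTA into SequenceRecords (Biopython reader)."""
    return [
        SequenceRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file into an Alignment (Biopython reader)."""
    msa = AlignIO.read(str(path), "fasta")
    return Alignment(
        rows=[SequenceRecord(id=rec.id, sequence=str(rec.seq)) for rec in msa]
    )
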