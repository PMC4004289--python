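"""Codon-usage tables and codon-pair context matrices.

The central object is the 61x61 codon context matrix: for an ordered
pair of adjacent codons (c1, c2), entry (c1, c2) holds the conditional
probability of observing c2 given that the first codon of the pair is
c1 *and* the second amino acid is aa(c2).  Conditioning on the second
amino acid is what makes the columns for Met (ATG) and Trp (TGG) —
amino acids with a single codon — identically 1 wherever the context
was observed.  The three stop codons are excluded throughout: trailing
stops are stripped before counting and internal stops are invalid, so
no stop codon ever contributes a pair.

Rows and columns are labelled by the 61 sense codons in alphabetical
order; that canonical order is also the tie-break/inversion order used
by the probabilistic designer, making designs reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from codoncontext.seq_core import (
    STANDARD_CODE,
    CodingSequence,
    GeneticCode,
    codons_of,
)

__all__ = [
    "CodonUsageTable",
    "CodonContextMatrix",
    "count_codon_pairs",
    "build_usage_table",
    "build_context_matrix",
    "write_matrix",
    "read_matrix",
    "write_usage_table",
    "read_usage_table",
]

N_SENSE = 61


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts and within-synonym-group relative frequencies.

    ``rel_freq`` for a codon is its count divided by the total count of
    its synonym group (0 when the group was never observed), the
    quantity a usage-table optimizer maximizes.  ``per_thousand`` is
    occurrences per 1000 sense codons, the CUTG-style presentation.
    Stop-codon counts are reported separately for completeness but take
    no part in relative frequencies.
    """

    counts: dict[str, int]
    stop_counts: dict[str, int]
    n_codons_total: int
    source_label: str = ""
    code: GeneticCode = field(default=STANDARD_CODE, repr=False, compare=False)

    @property
    def rel_freq(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for aa, group in self.code.synonym_groups.items():
            total = sum(self.counts.get(c, 0) for c in group)
            for c in group:
                out[c] = self.counts.get(c, 0) / total if total else 0.0
        return out

    @property
    def per_thousand(self) -> dict[str, float]:
        if self.n_codons_total == 0:
            return {c: 0.0 for c in self.code.sense_codons}
        return {
            c: 1000.0 * self.counts.get(c, 0) / self.n_codons_total
            for c in self.code.sense_codons
        }

    def argmax_codon(self, aa: str) -> str:
        """Most frequent codon for an amino acid; alphabetical tie-break."""
        group = self.code.synonym_groups[aa]
        counts = [self.counts.get(c, 0) for c in group]
        if sum(counts) == 0:
            raise ValueError(f"amino acid {aa!r} has no observed codons")
        best = max(counts)
        return next(c for c, k in zip(group, counts) if k == best)


@dataclass(frozen=True)
class CodonContextMatrix:
    """61x61 conditional codon-pair probabilities.

    ``P[i, j]`` = probability of sense codon ``labels[j]`` as the second
    codon of a pair, given that the first codon is ``labels[i]`` and the
    second amino acid is ``aa(labels[j])``.  ``pair_counts`` holds the
    raw pooled pair counts the probabilities were estimated from (all
    zeros for analytically constructed generator matrices).

    A (first codon, second amino acid) *context* is observed when either
    its pair counts or its probabilities have positive mass; unobserved
    contexts are all-zero in ``P`` so design-time fallback is an
    explicit, separate policy.
    """

    labels: tuple[str, ...]
    P: np.ndarray
    pair_counts: np.ndarray
    n_genes: int = 0
    source_label: str = ""
    code: GeneticCode = field(default=STANDARD_CODE, repr=False, compare=False)

    def __post_init__(self) -> None:
        if tuple(self.labels) != self.code.sense_codons:
            raise ValueError("labels must be the 61 sense codons in canonical order")
        P = np.asarray(self.P, dtype=float)
        counts = np.asarray(self.pair_counts)
        if P.shape != (N_SENSE, N_SENSE) or counts.shape != (N_SENSE, N_SENSE):
            raise ValueError(f"matrix must be {N_SENSE}x{N_SENSE}")
        if (P < 0).any() or (P > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if (counts < 0).any():
            raise ValueError("pair counts must be non-negative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "pair_counts", counts.astype(np.int64))

    def index(self, codon: str) -> int:
        return self.labels.index(codon)

    def group_indices(self, aa: str) -> list[int]:
        return [self.index(c) for c in self.code.synonym_groups[aa]]

    def context_observed(self, first_codon: str, second_aa: str) -> bool:
        i = self.index(first_codon)
        cols = self.group_indices(second_aa)
        return bool(
            self.pair_counts[i, cols].sum() > 0 or self.P[i, cols].sum() > 0
        )

    def context_distribution(self, first_codon: str, second_aa: str) -> np.ndarray:
        """P(second codon | first codon, second aa) over the synonym
        group in canonical order; raises if the context is unobserved."""
        if not self.context_observed(first_codon, second_aa):
            raise KeyError(f"context ({first_codon}, {second_aa}) unobserved")
        i = self.index(first_codon)
        cols = self.group_indices(second_aa)
        probs = self.P[i, cols]
        total = probs.sum()
        if total <= 0:  # counts present but P zeroed: renormalize counts
            counts = self.pair_counts[i, cols].astype(float)
            return counts / counts.sum()
        return probs / total

    def aa_marginal(self, aa: str) -> np.ndarray:
        """Marginal codon distribution for an amino acid from the
        training pair counts (second-codon occurrences).

        For matrices without counts (analytic generators) the rows of P
        are averaged over observed contexts instead.  Raises KeyError
        when the amino acid was never observed at all.
        """
        cols = self.group_indices(aa)
        col_counts = self.pair_counts[:, cols].sum(axis=0).astype(float)
        if col_counts.sum() > 0:
            return col_counts / col_counts.sum()
        mass = self.P[:, cols]
        row_totals = mass.sum(axis=1)
        observed_rows = row_totals > 0
        if not observed_rows.any():
            raise KeyError(f"amino acid {aa!r} unobserved in matrix")
        avg = mass[observed_rows].mean(axis=0)
        return avg / avg.sum()


def count_codon_pairs(
    seqs: Sequence[CodingSequence], code: GeneticCode = STANDARD_CODE
) -> tuple[np.ndarray, dict[str, int]]:
    """Count adjacent codon pairs and codon occurrences, pooled over genes.

    Each gene of L codons contributes its L-1 overlapping adjacent
    pairs; pairs never span two genes.  Sequences must be strict-valid
    (trailing stops are stripped), so stops cannot appear in any pair.

    Returns the 61x61 integer pair-count array (rows = first codon,
    canonical order) and the per-codon count dict.
    """
    if not seqs:
        raise ValueError("no sequences")
    idx = {c: i for i, c in enumerate(code.sense_codons)}
    pair_counts = np.zeros((N_SENSE, N_SENSE), dtype=np.int64)
    codon_counts: dict[str, int] = {}
    for seq in seqs:
        codons = codons_of(seq, code)
        for c in codons:
            codon_counts[c] = codon_counts.get(c, 0) + 1
        for c1, c2 in zip(codons, codons[1:]):
            pair_counts[idx[c1], idx[c2]] += 1
    return pair_counts, codon_counts


def build_usage_table(
    seqs: Sequence[CodingSequence],
    source_label: str = "",
    code: GeneticCode = STANDARD_CODE,
) -> CodonUsageTable:
    """Pool codon counts over a gene set into a usage table."""
    if not seqs:
        raise ValueError("no sequences")
    _, codon_counts = count_codon_pairs(seqs, code)
    counts = {c: codon_counts.get(c, 0) for c in code.sense_codons}
    # Trailing stops are excluded from sense statistics but tallied so the
    # CUTG-style table can report all 64 codons.
    stop_counts = {c: 0 for c in code.stop_codons}
    for seq in seqs:
        last = seq.dna[-3:]
        if code.codon_to_aa.get(last) == "*":
            stop_counts[last] += 1
    return CodonUsageTable(
        counts=counts,
        stop_counts=stop_counts,
        n_codons_total=sum(counts.values()),
        source_label=source_label,
        code=code,
    )


def build_context_matrix(
    seqs: Sequence[CodingSequence],
    source_label: str = "",
    code: GeneticCode = STANDARD_CODE,
) -> CodonContextMatrix:
    """Build the 61x61 codon context matrix from a gene set.

    P(c1, c2) = pair_counts(c1, c2) / sum of pair_counts(c1, c2') over
    c2' synonymous with c2, whenever that denominator is positive;
    unobserved contexts stay zero.
    """
    pair_counts, _ = count_codon_pairs(seqs, code)
    if pair_counts.sum() == 0:
        raise ValueError("no codon pairs (all genes single-codon)")
    P = np.zeros((N_SENSE, N_SENSE), dtype=float)
    for aa, group in code.synonym_groups.items():
        cols = [code.sense_codons.index(c) for c in group]
        denom = pair_counts[:, cols].sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            block = np.where(denom > 0, pair_counts[:, cols] / denom, 0.0)
        P[:, cols] = block
    return CodonContextMatrix(
        labels=code.sense_codons,
        P=P,
        pair_counts=pair_counts,
        n_genes=len(seqs),
        source_label=source_label,
        code=code,
    )


# ---------------------------------------------------------------------------
# TSV persistence.  Matrix file: '#'-metadata lines, then a header row of the
# 61 codon labels and one labelled row per first codon, probabilities at 17
# significant digits (lossless for float64).  A companion '<stem>.counts.tsv'
# stores the integer pair counts in the same layout.

def _counts_path(path) -> str:
    path = str(path)
    stem = path[:-4] if path.endswith(".tsv") else path
    return stem + ".counts.tsv"


def write_matrix(m: CodonContextMatrix, path) -> None:
    """Write a context matrix and its pair counts, losslessly."""
    labels = list(m.labels)
    with open(path, "w") as fh:
        fh.write(f"# n_genes={m.n_genes}\n")
        fh.write(f"# source_label={m.source_label}\n")
        fh.write("codon\t" + "\t".join(labels) + "\n")
        for i, c1 in enumerate(labels):
            row = "\t".join(format(v, ".17g") for v in m.P[i])
            fh.write(f"{c1}\t{row}\n")
    counts_df = pd.DataFrame(m.pair_counts, index=labels, columns=labels)
    counts_df.to_csv(_counts_path(path), sep="\t", index_label="codon")


class MatrixFormatError(ValueError):
    """Raised when a matrix file does not round-trip as a valid 61x61
    context matrix."""


def read_matrix(path, code: GeneticCode = STANDARD_CODE) -> CodonContextMatrix:
    """Read a context matrix written by :func:`write_matrix`.

    The companion counts file is optional; without it the matrix carries
    zero counts (a probability-only matrix).
    """
    n_genes = 0
    source_label = ""
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line[1:].strip().partition("=")
        if key.strip() == "n_genes":
            n_genes = int(value)
        elif key.strip() == "source_label":
            source_label = value

    import io

    df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
    labels = tuple(df.columns)
    if labels != code.sense_codons or tuple(df.index) != code.sense_codons:
        raise MatrixFormatError(
            f"{path}: labels are not the 61 sense codons in canonical order"
        )
    P = df.to_numpy(dtype=float)
    if (P < 0).any() or (P > 1 + 1e-12).any():
        raise MatrixFormatError(f"{path}: probabilities outside [0, 1]")

    counts = np.zeros((N_SENSE, N_SENSE), dtype=np.int64)
    counts_file = _counts_path(path)
    import os

    if os.path.exists(counts_file):
        cdf = pd.read_csv(counts_file, sep="\t", index_col=0)
        if tuple(cdf.columns) != code.sense_codons:
            raise MatrixFormatError(f"{counts_file}: bad labels")
        counts = cdf.to_numpy(dtype=np.int64)

    return CodonContextMatrix(
        labels=code.sense_codons,
        P=P,
        pair_counts=counts,
        n_genes=n_genes,
        source_label=source_label,
        code=code,
    )


def write_usage_table(t: CodonUsageTable, path) -> None:
    rel = t.rel_freq
    per_k = t.per_thousand
    with open(path, "w") as fh:
        fh.write(f"# n_codons_total={t.n_codons_total}\n")
        fh.write(f"# source_label={t.source_label}\n")
        fh.write("codon\taa\tcount\trel_freq\tper_thousand\n")
        for codon in t.code.sense_codons:
            aa = t.code.aa_of(codon)
            fh.write(
                f"{codon}\t{aa}\t{t.counts.get(codon, 0)}\t"
                f"{format(rel[codon], '.17g')}\t{format(per_k[codon], '.17g')}\n"
            )
        for codon in t.code.stop_codons:
            fh.write(f"{codon}\t*\t{t.stop_counts.get(codon, 0)}\t0\t0\n")


def read_usage_table(path, code: GeneticCode = STANDARD_CODE) -> CodonUsageTable:
    n_total = 0
    source_label = ""
    rows: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                if key.strip() == "n_codons_total":
                    n_total = int(value)
                elif key.strip() == "source_label":
                    source_label = value
                continue
            if line.startswith("codon\t") or not line:
                continue
            parts = line.split("\t")
            rows.append((parts[0], parts[1], int(parts[2])))
    counts = {c: k for c, aa, k in rows if aa != "*"}
    stop_counts = {c: k for c, aa, k in rows if aa == "*"}
    return CodonUsageTable(
        counts=counts,
        stop_counts=stop_counts,
        n_codons_total=n_total or sum(counts.values()),
        source_label=source_label,
        code=code,
    )
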