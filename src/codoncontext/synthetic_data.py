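"""Synthetic genomes, expression tables, and proteins with known
codon-pair structure.

Real inputs for this workflow are a genome's coding sequences plus a
condition's expression summary — for yeast, a 6,666-gene control set, a
top-100 high-expression set, a top-50 stationary-phase set.  The
generators here emulate those inputs with a known ground truth so every
pipeline stage is testable end to end: genes are first-order Markov
chains of codons drawn from a generator context matrix, a configurable
fraction of "biased" genes is drawn from a second matrix (a highly
expressed subset with genuinely distinct codon usage), and expression
tables give those biased genes stochastically higher values and
up-regulated log-fold changes.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from codoncontext.codon_stats import N_SENSE, CodonContextMatrix
from codoncontext.expression_select import ExpressionRecord
from codoncontext.seq_core import STANDARD_CODE, CodingSequence, GeneticCode, ProteinSequence

__all__ = [
    "SyntheticGenomeSpec",
    "random_context_matrix",
    "sample_genome",
    "sample_expression_table",
    "random_protein",
]

# Log-mean shift (natural-log units) separating biased from background
# expression values; strong enough that a top-N selection recovers most
# biased genes without being deterministic.
EXPRESSION_LOG_SHIFT = 2.0
# Log-scale spread of expression values within each group.
EXPRESSION_LOG_SD = 0.6

AMINO_ACIDS = tuple(sorted(STANDARD_CODE.synonym_groups))


def random_context_matrix(
    seed: int,
    concentration: float = 1.0,
    code: GeneticCode = STANDARD_CODE,
    source_label: str = "generator",
) -> CodonContextMatrix:
    """A random but valid generator matrix: every (first codon, second
    amino acid) context gets an independent Dirichlet draw over the
    synonym group.  Lower ``concentration`` yields more extreme codon
    preferences."""
    rng = np.random.default_rng(seed)
    P = np.zeros((N_SENSE, N_SENSE))
    for aa in AMINO_ACIDS:
        cols = [code.sense_codons.index(c) for c in code.synonym_groups[aa]]
        P[:, cols] = rng.dirichlet([concentration] * len(cols), size=N_SENSE)
    return CodonContextMatrix(
        labels=code.sense_codons,
        P=P,
        pair_counts=np.zeros((N_SENSE, N_SENSE), dtype=np.int64),
        n_genes=0,
        source_label=source_label,
        code=code,
    )


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic genome.

    ``codons_per_gene`` is either a fixed length or an inclusive
    (min, max) range; every gene has at least 2 codons so it
    contributes codon pairs.  ``bias_matrix``/``bias_fraction`` route a
    known fraction of genes through a second generator, creating a
    flagged subset with distinct codon usage.
    """

    n_genes: int
    codons_per_gene: int | tuple[int, int]
    generator_matrix: CodonContextMatrix
    seed: int
    bias_matrix: CodonContextMatrix | None = None
    bias_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo = (
            self.codons_per_gene
            if isinstance(self.codons_per_gene, int)
            else self.codons_per_gene[0]
        )
        if lo < 2:
            raise ValueError("codons_per_gene must be >= 2")
        if not (0.0 <= self.bias_fraction <= 1.0):
            raise ValueError("bias_fraction must be in [0, 1]")
        if self.bias_fraction > 0 and self.bias_matrix is None:
            raise ValueError("bias_fraction > 0 requires a bias_matrix")


def _sample_gene(
    m: CodonContextMatrix, n_codons: int, rng: np.random.Generator
) -> str:
    """One gene as a codon Markov chain under a uniformly random
    amino-acid path, codons drawn from the generator's conditionals."""
    code = m.code
    codons: list[str] = []
    prev: str | None = None
    for _ in range(n_codons):
        aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        group = code.synonym_groups[aa]
        if prev is None or not m.context_observed(prev, aa):
            probs = m.aa_marginal(aa)
        else:
            probs = m.context_distribution(prev, aa)
        codon = group[rng.choice(len(group), p=probs)] if len(group) > 1 else group[0]
        codons.append(codon)
        prev = codon
    return "".join(codons)


def sample_genome(spec: SyntheticGenomeSpec) -> tuple[list[CodingSequence], list[str]]:
    """Sample a synthetic genome.

    Returns the gene list (ids g000001, g000002, ...) and the ids of
    the genes drawn from the bias matrix (empty when no bias mixture is
    configured).  Deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_biased = int(round(spec.bias_fraction * spec.n_genes))
    biased_idx = set(
        rng.choice(spec.n_genes, size=n_biased, replace=False).tolist()
    ) if n_biased else set()
    genes: list[CodingSequence] = []
    biased_ids: list[str] = []
    for i in range(spec.n_genes):
        if isinstance(spec.codons_per_gene, int):
            n_codons = spec.codons_per_gene
        else:
            lo, hi = spec.codons_per_gene
            n_codons = int(rng.integers(lo, hi + 1))
        gene_id = f"g{i + 1:06d}"
        source = spec.bias_matrix if i in biased_idx else spec.generator_matrix
        genes.append(CodingSequence(id=gene_id, dna=_sample_gene(source, n_codons, rng)))
        if i in biased_idx:
            biased_ids.append(gene_id)
    return genes, biased_ids


def sample_expression_table(
    genome_ids: Sequence[str],
    biased_ids: Sequence[str],
    seed: int,
    log_shift: float = EXPRESSION_LOG_SHIFT,
    log_sd: float = EXPRESSION_LOG_SD,
) -> list[ExpressionRecord]:
    """Synthetic expression summary with biased genes up-shifted.

    Expression values are log-normal: background exp(N(0, log_sd)),
    biased exp(N(log_shift, log_sd)), so a top-N selection
    preferentially recovers the biased subset.  Log-fold changes are N(0, 0.3) for background
    and N(log_shift, 0.5) for biased genes; adjusted p-values are
    uniform for background and small (uniform on [0, 0.01]) for biased
    genes, mimicking a differential-expression contrast in which the
    biased subset is up-regulated.
    """
    biased = set(biased_ids)
    if not biased.issubset(set(genome_ids)):
        raise ValueError("biased_ids must be a subset of genome_ids")
    rng = np.random.default_rng(seed)
    records: list[ExpressionRecord] = []
    for gene_id in genome_ids:
        if gene_id in biased:
            value = float(np.exp(rng.normal(log_shift, log_sd)))
            logfc = float(rng.normal(log_shift, 0.5))
            adj_p = float(rng.uniform(0.0, 0.01))
        else:
            value = float(np.exp(rng.normal(0.0, log_sd)))
            logfc = float(rng.normal(0.0, 0.3))
            adj_p = float(rng.uniform(0.0, 1.0))
        records.append(
            ExpressionRecord(gene_id=gene_id, value=value, logfc=logfc, adj_p=adj_p)
        )
    return records


def write_expression_table(records: Sequence[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\tlogfc\tadj_p\n")
        for r in records:
            value = "" if r.value is None else format(r.value, ".17g")
            logfc = "" if r.logfc is None else format(r.logfc, ".17g")
            adj_p = "" if r.adj_p is None else format(r.adj_p, ".17g")
            fh.write(f"{r.gene_id}\t{value}\t{logfc}\t{adj_p}\n")


def random_protein(length: int, seed: int) -> ProteinSequence:
    """Uniform i.i.d. amino-acid sequence with a forced Met start."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    rest = "".join(
        AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length - 1)
    )
    return ProteinSequence(id=f"protein_{seed}", aa="M" + rest)
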