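"""Back-translation of proteins into codon-optimized DNA.

Two design modes:

* probabilistic — walk the protein left to right, drawing each codon
  from the context matrix's conditional distribution given the previous
  codon and the current amino acid.  If 60% of observed Met-Cys pairs
  were ATGTGT and 40% ATGTGC, the designer emits ATGTGT for a Met-Cys
  step 60% of the time.  Each run yields one variant; independent seeds
  yield a family of variants sharing the condition's codon-pair
  statistics rather than a single argmax sequence.

* table argmax — classic usage-table optimization: every amino acid is
  mapped to its most frequent codon, deterministically.

RNG contract (probabilistic mode): a single seeded NumPy generator,
exactly one uniform draw per designed codon position consumed left to
right (including forced positions such as Met/Trp), and the codon is
chosen by cumulative-probability inversion over the amino acid's
synonym group in canonical (alphabetical) codon order.  This makes a
design a pure function of (protein, matrix, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from codoncontext.codon_stats import CodonContextMatrix, CodonUsageTable
from codoncontext.seq_core import ProteinSequence

__all__ = [
    "DesignResult",
    "design_probabilistic",
    "design_variants",
    "design_table",
    "pair_frequency_audit",
]


@dataclass(frozen=True)
class DesignResult:
    """A designed coding sequence for a target protein.

    ``fallback_events`` counts positions where the (previous codon,
    amino acid) context was absent from the matrix and the designer
    backed off to the amino acid's marginal codon distribution (or a
    uniform draw if the amino acid was never observed).
    """

    protein_id: str
    dna: str
    method: str  # "matrix_probabilistic" | "table_argmax"
    source_label: str = ""
    seed: int | None = None
    fallback_events: int = 0

    def fasta_header(self) -> str:
        parts = [self.protein_id, f"method={self.method}"]
        if self.source_label:
            parts.append(f"source={self.source_label}")
        if self.seed is not None:
            parts.append(f"seed={self.seed}")
        parts.append(f"fallback_events={self.fallback_events}")
        return " ".join(parts)


def _draw(group: Sequence[str], probs: np.ndarray, u: float) -> str:
    """Cumulative-probability inversion over a synonym group in
    canonical order."""
    cum = 0.0
    for codon, p in zip(group, probs):
        cum += p
        if u < cum:
            return codon
    return group[-1]  # guard against float round-off at u ~ 1


def design_probabilistic(
    protein: ProteinSequence, m: CodonContextMatrix, seed: int
) -> DesignResult:
    """Design one DNA variant by sampling codons from the context matrix.

    The first codon (no left context) is drawn from the matrix's
    training marginal for the first amino acid — which is necessarily
    ATG for the universal Met start.  Every subsequent codon is drawn
    from P(previous codon, .) restricted to the current amino acid's
    synonym group, with the documented marginal/uniform fallback for
    unseen contexts.
    """
    rng = np.random.default_rng(seed)
    code = m.code
    codons: list[str] = []
    fallbacks = 0
    prev: str | None = None
    for aa in protein.aa:
        group = code.synonym_groups[aa]
        u = float(rng.random())  # one draw per position, always
        if len(group) == 1:  # Met/Trp: forced, no lookup, no fallback
            codon = group[0]
        else:
            if prev is None:
                probs, fell = _initial_distribution(m, aa)
            else:
                probs, fell = _conditional_distribution(m, prev, aa)
            fallbacks += fell
            codon = _draw(group, probs, u)
        codons.append(codon)
        prev = codon
    return DesignResult(
        protein_id=protein.id,
        dna="".join(codons),
        method="matrix_probabilistic",
        source_label=m.source_label,
        seed=seed,
        fallback_events=fallbacks,
    )


def _initial_distribution(m: CodonContextMatrix, aa: str) -> tuple[np.ndarray, int]:
    group = m.code.synonym_groups[aa]
    try:
        return m.aa_marginal(aa), 0
    except KeyError:
        return np.full(len(group), 1.0 / len(group)), 1


def _conditional_distribution(
    m: CodonContextMatrix, prev: str, aa: str
) -> tuple[np.ndarray, int]:
    if m.context_observed(prev, aa):
        return m.context_distribution(prev, aa), 0
    return _fallback_marginal(m, aa)


def _fallback_marginal(m: CodonContextMatrix, aa: str) -> tuple[np.ndarray, int]:
    group = m.code.synonym_groups[aa]
    try:
        return m.aa_marginal(aa), 1
    except KeyError:
        return np.full(len(group), 1.0 / len(group)), 1


def design_variants(
    protein: ProteinSequence, m: CodonContextMatrix, n: int, seed: int
) -> list[DesignResult]:
    """n independent probabilistic designs from derived seeds
    seed, seed+1, ....  Duplicates are permitted — variants are
    independent draws, not a de-duplicated set."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return [design_probabilistic(protein, m, seed + k) for k in range(n)]


def design_table(protein: ProteinSequence, t: CodonUsageTable) -> DesignResult:
    """Deterministic argmax design from a usage table.

    Each amino acid maps to its highest-relative-frequency codon; ties
    break to the alphabetically smallest codon.
    """
    codons = [t.argmax_codon(aa) for aa in protein.aa]
    return DesignResult(
        protein_id=protein.id,
        dna="".join(codons),
        method="table_argmax",
        source_label=t.source_label,
        seed=None,
        fallback_events=0,
    )


def pair_frequency_audit(
    designs: Sequence[DesignResult], m: CodonContextMatrix
) -> pd.DataFrame:
    """Compare empirical codon-pair selection in designs with the model.

    For every (first codon, second amino acid) context observed across
    the designed sequences, reports the empirical fraction of each
    second codon next to the matrix probability and their absolute
    deviation.  The designer is well calibrated when max deviation
    shrinks as the number of designs grows (O(1/sqrt(n))).
    """
    if not designs:
        raise ValueError("no designs to audit")
    code = m.code
    context_counts: dict[tuple[str, str], dict[str, int]] = {}
    for d in designs:
        codons = [d.dna[i : i + 3] for i in range(0, len(d.dna), 3)]
        for c1, c2 in zip(codons, codons[1:]):
            key = (c1, code.aa_of(c2))
            context_counts.setdefault(key, {})[c2] = (
                context_counts.setdefault(key, {}).get(c2, 0) + 1
            )
    rows = []
    for (c1, aa), counts in sorted(context_counts.items()):
        group = code.synonym_groups[aa]
        total = sum(counts.values())
        if m.context_observed(c1, aa):
            model = dict(zip(group, m.context_distribution(c1, aa)))
        else:
            model = {c: float("nan") for c in group}
        for c2 in group:
            emp = counts.get(c2, 0) / total
            p = model[c2]
            rows.append(
                {
                    "first_codon": c1,
                    "second_aa": aa,
                    "second_codon": c2,
                    "n_observed": counts.get(c2, 0),
                    "empirical": emp,
                    "model_p": p,
                    "abs_deviation": abs(emp - p) if p == p else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "first_codon",
            "second_aa",
            "second_codon",
            "n_observed",
            "empirical",
            "model_p",
            "abs_deviation",
        ],
    )
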