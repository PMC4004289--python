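"""Genetic-code services, FASTA I/O, CDS validation, and translation.

The standard nuclear genetic code is the only code supported: the
intended host is *S. cerevisiae* nuclear expression.  Codons are written
as DNA triplets (``ATG``, not ``AUG``); ``U`` is mapped to ``T`` on
input.  Stop codons never enter downstream statistics — a trailing stop
is stripped during validation, and an internal stop is a hard error in
strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "CodingSequence",
    "ProteinSequence",
    "ValidationReport",
    "read_fasta",
    "read_protein_fasta",
    "write_fasta",
    "validate_cds",
    "translate",
    "codons_of",
]

STOP_SYMBOL = "*"


@dataclass(frozen=True)
class GeneticCode:
    """The standard nuclear genetic code over DNA triplets.

    Attributes
    ----------
    codon_to_aa
        Map from each of the 64 DNA triplets to an amino-acid letter, or
        ``*`` for the three stops.
    sense_codons
        The 61 non-stop codons in canonical (alphabetical) order.  This
        order fixes the row/column labelling of every context matrix.
    synonym_groups
        Amino-acid letter -> alphabetically ordered list of its codons.
    """

    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)
    synonym_groups: dict[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        sense = tuple(
            c for c in sorted(self.codon_to_aa) if self.codon_to_aa[c] != STOP_SYMBOL
        )
        stops = tuple(
            c for c in sorted(self.codon_to_aa) if self.codon_to_aa[c] == STOP_SYMBOL
        )
        groups: dict[str, list[str]] = {}
        for codon in sense:
            groups.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(
            self, "synonym_groups", {aa: tuple(cs) for aa, cs in groups.items()}
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[1]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP_SYMBOL
        # CodonTable leaves stops out of forward_table; everything else is
        # covered, giving the expected 61 + 3 split.
        assert len(mapping) == 64
        return cls(codon_to_aa=mapping)

    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def codon_index(self, codon: str) -> int:
        return self.sense_codons.index(codon)


STANDARD_CODE = GeneticCode.standard()

_VALID_DNA = frozenset("ACGT")
_DNA_WITH_N = frozenset("ACGTN")
_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _normalize_dna(raw: str) -> str:
    return raw.upper().replace("U", "T")


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence with an identifier.

    ``dna`` is stored uppercase over ``{A,C,G,T}`` (optionally ``N``);
    validity (frame, internal stops) is checked by :func:`validate_cds`,
    not at construction time, so partially broken records read from disk
    can still be reported on.
    """

    id: str
    dna: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "dna", _normalize_dna(self.dna))

    def codons(self) -> list[str]:
        return [self.dna[i : i + 3] for i in range(0, len(self.dna) - len(self.dna) % 3, 3)]


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence over the 20 standard letters."""

    id: str
    aa: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "aa", self.aa.upper())
        if not self.aa:
            raise ValueError(f"protein {self.id!r} is empty")
        bad = set(self.aa) - _AA_LETTERS
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains invalid letters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.aa)


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


def _check_fasta_shape(path) -> None:
    # Bio.SeqIO silently yields nothing for a headerless file; surface
    # that as a parse error naming the offending line instead.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            return


def read_fasta(path) -> list[CodingSequence]:
    """Read a multi-FASTA file of coding DNA sequences.

    Record ids are the header up to the first whitespace; sequences are
    uppercased with ``U`` mapped to ``T``; record order is preserved.
    An empty file yields an empty list.
    """
    _check_fasta_shape(path)
    return [
        CodingSequence(id=rec.id, dna=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def read_protein_fasta(path) -> list[ProteinSequence]:
    """Read a multi-FASTA file of protein sequences."""
    _check_fasta_shape(path)
    return [
        ProteinSequence(id=rec.id, aa=str(rec.seq).upper().rstrip(STOP_SYMBOL))
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(records: Iterable, path, line_width: int = 60) -> None:
    """Write CodingSequence/ProteinSequence records (or (id, seq, desc)
    triples) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, CodingSequence):
                header, seq = rec.id, rec.dna
            elif isinstance(rec, ProteinSequence):
                header, seq = rec.id, rec.aa
            else:
                header, seq = rec[0], rec[1]
                if len(rec) > 2 and rec[2]:
                    header = f"{header} {rec[2]}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of CDS validation.

    ``stripped`` is the sequence with any single trailing stop codon
    removed — the form every statistics routine consumes, so stop codons
    never enter codon or pair counts.
    """

    id: str
    accepted: bool
    reasons: tuple[str, ...]
    stripped: CodingSequence | None
    trailing_stop_removed: bool = False
    n_skipped_codons: int = 0


def validate_cds(
    seq: CodingSequence, mode: str = "strict", code: GeneticCode = STANDARD_CODE
) -> ValidationReport:
    """Validate a coding sequence.

    Strict mode rejects length not a multiple of 3, characters outside
    ``{A,C,G,T}``, and internal stop codons.  Lenient mode accepts but
    flags; codons containing ``N`` are counted so downstream statistics
    can skip them.  A single trailing stop codon is accepted in both
    modes and stripped.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown validation mode {mode!r}")
    reasons: list[str] = []
    dna = seq.dna
    if not dna or len(dna) % 3 != 0:
        reasons.append("length-not-multiple-of-3")
    alphabet = _VALID_DNA if mode == "strict" else _DNA_WITH_N
    bad_chars = set(dna) - alphabet
    if bad_chars:
        reasons.append("invalid-characters:" + "".join(sorted(bad_chars)))

    trailing_removed = False
    n_skipped = 0
    stripped_dna = dna
    if not reasons:
        codons = seq.codons()
        if codons and code.codon_to_aa.get(codons[-1]) == STOP_SYMBOL:
            codons = codons[:-1]
            trailing_removed = True
        internal_stop = any(
            code.codon_to_aa.get(c) == STOP_SYMBOL for c in codons if "N" not in c
        )
        if internal_stop:
            reasons.append("internal-stop")
        n_skipped = sum(1 for c in codons if "N" in c)
        if n_skipped and mode == "strict":
            reasons.append("ambiguous-codon")
        stripped_dna = "".join(codons)

    if mode == "strict":
        accepted = not reasons
    else:
        accepted = "length-not-multiple-of-3" not in reasons and not any(
            r.startswith("invalid-characters") for r in reasons
        )
    stripped = CodingSequence(seq.id, stripped_dna) if accepted else None
    return ValidationReport(
        id=seq.id,
        accepted=accepted,
        reasons=tuple(reasons),
        stripped=stripped,
        trailing_stop_removed=trailing_removed,
        n_skipped_codons=n_skipped,
    )


def write_validation_reports(reports: Iterable[ValidationReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\taccepted\treasons\n")
        for r in reports:
            fh.write(f"{r.id}\t{str(r.accepted).lower()}\t{';'.join(r.reasons)}\n")


def translate(
    seq: CodingSequence, mode: str = "strict", code: GeneticCode = STANDARD_CODE
) -> ProteinSequence:
    """Translate a CDS under the standard code.

    The sequence must pass validation in the given mode; a trailing stop
    is stripped first.  In lenient mode codons containing ``N`` are
    skipped (the protein is correspondingly shorter).
    """
    report = validate_cds(seq, mode=mode, code=code)
    if not report.accepted or report.stripped is None:
        raise ValueError(
            f"cannot translate {seq.id!r}: {', '.join(report.reasons) or 'invalid'}"
        )
    codons = [c for c in report.stripped.codons() if "N" not in c]
    aa = str(Seq("".join(codons)).translate(table=1))
    return ProteinSequence(id=seq.id, aa=aa)


def codons_of(seq: CodingSequence, code: GeneticCode = STANDARD_CODE) -> list[str]:
    """Sense-codon list of a strict-valid CDS after trailing-stop strip."""
    report = validate_cds(seq, mode="strict", code=code)
    if not report.accepted or report.stripped is None:
        raise ValueError(f"invalid CDS {seq.id!r}: {', '.join(report.reasons)}")
    return report.stripped.codons()
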