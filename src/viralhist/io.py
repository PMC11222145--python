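"""Readers and writers for proteome FASTA files and HMMER domain tables.

Coordinates are 1-based inclusive throughout, following the HMMER
convention.  Domain tables use the per-domain tabular layout produced by
``hmmsearch --domtblout`` (whitespace-delimited columns, ``#`` comments);
the conditional E-value column (not the independent one) is the
significance measure carried downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Histone family labels, one per query HMM.  ``ARCH`` is the archaeal
#: single-fold histone family; ``Hx`` (ambiguous) is produced downstream
#: and never appears in a raw hit table.
FAMILIES = ("H1", "H2A", "H2B", "H3", "H4", "ARCH")

#: Core nucleosomal families making up a full complement.
CORE_FAMILIES = frozenset({"H2A", "H2B", "H3", "H4"})

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein.

    ``is_complete`` mirrors the upstream gene-calling annotation (a start
    and a stop codon present); incomplete proteins are parsed but excluded
    from architecture statistics by default.
    """

    protein_id: str
    genome_id: str
    sequence: str
    is_complete: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        if not _AA_RE.match(self.sequence.upper()):
            bad = sorted(set(self.sequence.upper()) - set("ACDEFGHIKLMNPQRSTVWYX"))
            raise ValueError(
                f"protein {self.protein_id}: non-amino-acid characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One HMM match on one protein (one row of a domain table)."""

    protein_id: str
    family: str
    ali_from: int
    ali_to: int
    hmm_from: int
    hmm_to: int
    hmm_length: int
    c_evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; accepted families: "
                f"{', '.join(FAMILIES)}"
            )
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(
                f"hit on {self.protein_id}: invalid alignment coordinates "
                f"{self.ali_from}..{self.ali_to}"
            )
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"hit on {self.protein_id}: invalid HMM coordinates "
                f"{self.hmm_from}..{self.hmm_to} (length {self.hmm_length})"
            )
        if self.c_evalue < 0:
            raise ValueError(f"hit on {self.protein_id}: negative c-Evalue")

    @property
    def coverage(self) -> float:
        """Fraction of the profile HMM matched by this hit, in (0, 1]."""
        return (self.hmm_to - self.hmm_from + 1) / self.hmm_length

    @property
    def ali_length(self) -> int:
        return self.ali_to - self.ali_from + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, delimiter: str = "|") -> list[ProteinRecord]:
    """Read proteins from FASTA with ``genomeID<delim>proteinID`` headers.

    A ``complete=0`` token in the description marks a protein lacking a
    start or stop codon; everything else is treated as complete.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if delimiter not in rec.id:
            raise ValueError(
                f"FASTA header {rec.id!r} lacks the {delimiter!r} "
                "genome/protein delimiter"
            )
        genome_id, protein_id = rec.id.split(delimiter, 1)
        is_complete = "complete=0" not in rec.description
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                genome_id=genome_id,
                sequence=str(rec.seq).upper(),
                is_complete=is_complete,
            )
        )
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids in FASTA: {dup}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                delimiter: str = "|") -> None:
    seq_records = []
    for r in records:
        desc = "" if r.is_complete else "complete=0"
        seq_records.append(
            SeqRecord(Seq(r.sequence), id=f"{r.genome_id}{delimiter}{r.protein_id}",
                      description=desc)
        )
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# HMMER domain tables
# ---------------------------------------------------------------------------

# domtblout columns (0-based):
#  0 target name   3 query name    5 qlen          11 c-Evalue
# 13 dom score    15 hmm from     16 hmm to        17 ali from    18 ali to
_N_DOMTBL_COLS = 23


def parse_domtblout(path: str | Path,
                    families: Sequence[str] = FAMILIES) -> list[DomainHit]:
    """Parse a HMMER ``--domtblout`` table into :class:`DomainHit` rows.

    The target is the protein, the query is the family HMM.  Raises
    ``ValueError`` naming the offending line on malformed rows, and
    listing the accepted families on an unknown query name.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _N_DOMTBL_COLS - 1:  # description may be empty
                raise ValueError(
                    f"{path}:{lineno}: expected ≥{_N_DOMTBL_COLS - 1} columns, "
                    f"got {len(cols)}"
                )
            family = cols[3]
            if family not in families:
                raise ValueError(
                    f"{path}:{lineno}: unknown query name {family!r}; "
                    f"accepted families: {', '.join(families)}"
                )
            try:
                hit = DomainHit(
                    protein_id=cols[0],
                    family=family,
                    hmm_length=int(cols[5]),
                    c_evalue=float(cols[11]),
                    bit_score=float(cols[13]),
                    hmm_from=int(cols[15]),
                    hmm_to=int(cols[16]),
                    ali_from=int(cols[17]),
                    ali_to=int(cols[18]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


_DOMTBL_HEADER = (
    "#{:<19s} {:>10s} {:>5s} {:<20s} {:>10s} {:>5s} {:>9s} {:>6s} {:>5s} "
    "{:>3s} {:>3s} {:>9s} {:>9s} {:>6s} {:>5s} {:>5s} {:>5s} {:>5s} {:>5s} "
    "{:>5s} {:>5s} {:>4s} {:s}".format(
        "target name", "accession", "tlen", "query name", "accession", "qlen",
        "E-value", "score", "bias", "#", "of", "c-Evalue", "i-Evalue",
        "score", "bias", "from", "to", "from", "to", "from", "to", "acc",
        "description of target")
)


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the ``--domtblout`` dialect read by :func:`parse_domtblout`.

    Fields not carried by :class:`DomainHit` (target length, full-sequence
    statistics, envelope coordinates) are filled with placeholders; the
    envelope is set equal to the alignment.
    """
    hits = list(hits)
    # number domains within each protein for the '# of' bookkeeping columns
    per_protein: dict[str, int] = {}
    for h in hits:
        per_protein[h.protein_id] = per_protein.get(h.protein_id, 0) + 1
    seen: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER + "\n")
        for h in hits:
            seen[h.protein_id] = seen.get(h.protein_id, 0) + 1
            fh.write(
                f"{h.protein_id:<20s} {'-':>10s} {h.ali_to:>5d} "
                f"{h.family:<20s} {'-':>10s} {h.hmm_length:>5d} "
                f"{h.c_evalue:>9.5g} {h.bit_score:>6.1f} {0.0:>5.1f} "
                f"{seen[h.protein_id]:>3d} {per_protein[h.protein_id]:>3d} "
                f"{h.c_evalue:.17g} {h.c_evalue:>9.5g} "
                f"{h.bit_score:.17g} {0.0:>5.1f} "
                f"{h.hmm_from:>5d} {h.hmm_to:>5d} "
                f"{h.ali_from:>5d} {h.ali_to:>5d} "
                f"{h.ali_from:>5d} {h.ali_to:>5d} {0.90:>4.2f} -\n"
            )
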