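"""Overlap resolution, family assignment and repeat classification.

A protein carrying several histone-fold matches is reduced to a tiling of
non-conflicting domains: hits covering less than ``min_coverage`` of their
profile HMM are discarded, and among the survivors domains are accepted
greedily in order of increasing conditional E-value, rejecting any
candidate that overlaps an already-accepted domain by more than
``overlap_threshold`` of the shorter interval.  The family of each
accepted region is taken from the best-scoring hit on it, demoted to the
ambiguous label ``Hx`` when a competing family scores within
``ambiguity_ratio`` of the winner.

The ordered N-to-C family string then defines the histone type
(e.g. ``"H2B-H2A-H3-H4"``), its repeat class (singlet/doublet/triplet/
quadruplet) and, for full-complement quadruplets, a configuration label
(HQA/HQB/HQC) looked up in a user-overridable order table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CORE_FAMILIES, DomainHit, ProteinRecord

AMBIGUOUS_FAMILY = "Hx"

_REPEAT_CLASSES = {1: "singlet", 2: "doublet", 3: "triplet", 4: "quadruplet"}

#: Default mapping from quadruplet domain order to configuration label.
#: The three orders keep H2A/H2B and H3/H4 in series, as observed for the
#: natural quadruplets; the exact order→label correspondence is
#: PROVISIONAL and should be overridden when the true table is known.
DEFAULT_QUADRUPLET_TABLE: Mapping[str, str] = {
    "H2B-H2A-H3-H4": "HQA",
    "H2A-H2B-H4-H3": "HQB",
    "H4-H3-H2B-H2A": "HQC",
}


@dataclass(frozen=True)
class ResolutionConfig:
    """Thresholds governing hit filtering and conflict resolution."""

    overlap_threshold: float = 0.50
    min_coverage: float = 0.25
    ambiguity_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.ambiguity_ratio < 1:
            raise ValueError("ambiguity_ratio must be ≥ 1")


@dataclass(frozen=True)
class ResolvedDomain:
    """One accepted domain region on a protein."""

    family: str
    start: int
    end: int
    c_evalue: float
    source_hit: DomainHit

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Architecture:
    """The ordered histone-domain content of one protein."""

    protein_id: str
    genome_id: str
    domain_families: tuple[str, ...]
    type_label: str
    repeat_class: str
    quadruplet_config: str | None = None


@dataclass(frozen=True)
class LinkerSet:
    """Inter-domain linkers and terminal extensions of one protein."""

    protein_id: str
    linkers: tuple[tuple[str, int, int], ...]  # (sequence, start, end)
    n_tail: str
    c_tail: str


@dataclass(frozen=True)
class GenomeComplement:
    """Which core histone families and types a genome encodes."""

    genome_id: str
    families_present: frozenset[str]
    types_present: frozenset[str]

    @property
    def is_full_complement(self) -> bool:
        return self.families_present == CORE_FAMILIES


# ---------------------------------------------------------------------------
# overlap resolution
# ---------------------------------------------------------------------------

def overlap_fraction(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Shared residues divided by the length of the shorter interval."""
    shared = min(a_end, b_end) - max(a_start, b_start) + 1
    if shared <= 0:
        return 0.0
    shorter = min(a_end - a_start + 1, b_end - b_start + 1)
    return shared / shorter


def _priority(h: DomainHit):
    # deterministic greedy order: best E-value, then higher bit score,
    # then longer interval, then lower start, then family name
    return (h.c_evalue, -h.bit_score, -h.ali_length, h.ali_from, h.family)


def assign_family(hits_for_region: Sequence[DomainHit],
                  cfg: ResolutionConfig = ResolutionConfig()) -> str:
    """Family of the best conditional E-value, or ``Hx`` when ambiguous.

    ``Hx`` is returned when the best competing *other* family scores
    within ``ambiguity_ratio`` times the winning E-value — a score-ratio
    surrogate for an unresolvable branching position.
    """
    if not hits_for_region:
        raise ValueError("assign_family: empty hit list")
    best = min(hits_for_region, key=_priority)
    rivals = [h for h in hits_for_region if h.family != best.family]
    if not rivals:
        return best.family
    second = min(rivals, key=_priority)
    if second.c_evalue <= cfg.ambiguity_ratio * best.c_evalue:
        return AMBIGUOUS_FAMILY
    return best.family


def resolve_overlaps(hits: Sequence[DomainHit],
                     cfg: ResolutionConfig = ResolutionConfig()
                     ) -> list[ResolvedDomain]:
    """Resolve a protein's hits into a conflict-free, sorted domain tiling.

    Hits below ``min_coverage`` HMM coverage are dropped, the rest are
    accepted greedily by ascending conditional E-value, and each accepted
    region's family is decided by :func:`assign_family` over the accepted
    hit together with the hits it displaced.
    """
    if not hits:
        return []
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(
            f"resolve_overlaps expects hits from one protein, got {sorted(proteins)}"
        )

    survivors = [h for h in hits if h.coverage >= cfg.min_coverage]
    accepted: list[DomainHit] = []
    competitors: dict[int, list[DomainHit]] = {}
    for h in sorted(survivors, key=_priority):
        clash = None
        for i, a in enumerate(accepted):
            if overlap_fraction(h.ali_from, h.ali_to, a.ali_from, a.ali_to) \
                    > cfg.overlap_threshold:
                clash = i
                break
        if clash is None:
            competitors[len(accepted)] = []
            accepted.append(h)
        else:
            competitors[clash].append(h)

    resolved = [
        ResolvedDomain(
            family=assign_family([a] + competitors[i], cfg),
            start=a.ali_from,
            end=a.ali_to,
            c_evalue=a.c_evalue,
            source_hit=a,
        )
        for i, a in enumerate(accepted)
    ]
    return sorted(resolved, key=lambda d: (d.start, d.end))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_architecture(domains: Sequence[ResolvedDomain],
                          genome_id: str = "",
                          quadruplet_table: Mapping[str, str] | None = None,
                          ) -> Architecture:
    """Classify a resolved domain tiling into a histone type.

    The type label is the hyphen-joined N-to-C family order; the repeat
    class follows the domain count; quadruplets whose four domains are
    exactly the four core families get a configuration label from
    ``quadruplet_table`` (``"unassigned"`` if the order is not listed).
    """
    if not domains:
        raise ValueError("no histone domains")
    starts = [d.start for d in domains]
    if starts != sorted(starts):
        raise ValueError("domains must be sorted by start")
    table = DEFAULT_QUADRUPLET_TABLE if quadruplet_table is None else quadruplet_table
    families = tuple(d.family for d in domains)
    label = "-".join(families)
    repeat_class = _REPEAT_CLASSES.get(len(families), "other")
    quad_config = None
    if repeat_class == "quadruplet":
        quad_config = (
            table.get(label, "unassigned")
            if sorted(families) == sorted(CORE_FAMILIES)
            else "unassigned"
        )
    protein_id = domains[0].source_hit.protein_id
    return Architecture(
        protein_id=protein_id,
        genome_id=genome_id,
        domain_families=families,
        type_label=label,
        repeat_class=repeat_class,
        quadruplet_config=quad_config,
    )


def filter_recurrent_types(architectures: Iterable[Architecture],
                           min_genomes: int = 2) -> set[str]:
    """Type labels observed in at least ``min_genomes`` distinct genomes.

    Guards against single-genome prediction artefacts: repeated
    observations within one genome count once.
    """
    if min_genomes < 1:
        raise ValueError("min_genomes must be ≥ 1")
    genomes_per_type: dict[str, set[str]] = {}
    for a in architectures:
        genomes_per_type.setdefault(a.type_label, set()).add(a.genome_id)
    return {t for t, g in genomes_per_type.items() if len(g) >= min_genomes}


def extract_linkers(protein: ProteinRecord,
                    domains: Sequence[ResolvedDomain]) -> LinkerSet:
    """Inter-domain linker segments plus N/C terminal extensions.

    Linker *i* is the substring strictly between domain *i*'s end and
    domain *i+1*'s start (possibly empty); coordinates are 1-based
    inclusive on the protein.
    """
    if not domains:
        raise ValueError("no domains to extract linkers between")
    n = len(protein.sequence)
    prev_end = 0
    for d in domains:
        if d.source_hit.protein_id != protein.protein_id:
            raise ValueError(
                f"domain on {d.source_hit.protein_id} does not belong to "
                f"protein {protein.protein_id}"
            )
        if not (1 <= d.start <= d.end <= n):
            raise ValueError(
                f"domain {d.start}..{d.end} out of range for protein of length {n}"
            )
        if d.start <= prev_end:
            raise ValueError("domains must be sorted and non-overlapping")
        prev_end = d.end
    seq = protein.sequence
    linkers = []
    for left, right in zip(domains, domains[1:]):
        linkers.append((seq[left.end:right.start - 1], left.end + 1, right.start - 1))
    return LinkerSet(
        protein_id=protein.protein_id,
        linkers=tuple(linkers),
        n_tail=seq[: domains[0].start - 1],
        c_tail=seq[domains[-1].end:],
    )


def linker_length_summary(linker_sets: Iterable[LinkerSet],
                          type_by_protein: Mapping[str, str]) -> pd.DataFrame:
    """Per-position linker-length median ± SD across proteins of each type.

    Returns a tidy frame with columns ``type_label``, ``position``
    (1-based junction index), ``median``, ``sd`` and ``n``.
    """
    rows = []
    by_type: dict[str, list[LinkerSet]] = {}
    for ls in linker_sets:
        by_type.setdefault(type_by_protein[ls.protein_id], []).append(ls)
    for label, sets in sorted(by_type.items()):
        n_link = {len(s.linkers) for s in sets}
        if len(n_link) != 1:
            warnings.warn(f"type {label}: inconsistent linker counts {n_link}")
        for pos in range(min(n_link)):
            lengths = np.array([len(s.linkers[pos][0]) for s in sets], dtype=float)
            rows.append({
                "type_label": label,
                "position": pos + 1,
                "median": float(np.median(lengths)),
                "sd": float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0,
                "n": len(lengths),
            })
    return pd.DataFrame(rows, columns=["type_label", "position", "median", "sd", "n"])


def genome_complement(genome_id: str,
                      architectures: Iterable[Architecture]) -> GenomeComplement:
    """Union of core families and types over one genome's histone proteins."""
    fams: set[str] = set()
    types: set[str] = set()
    for a in architectures:
        if a.genome_id and a.genome_id != genome_id:
            raise ValueError(
                f"architecture from genome {a.genome_id!r} passed to "
                f"complement of {genome_id!r}"
            )
        fams.update(a.domain_families)
        types.add(a.type_label)
    return GenomeComplement(
        genome_id=genome_id,
        families_present=frozenset(fams & CORE_FAMILIES),
        types_present=frozenset(types),
    )


def genome_complements(architectures: Iterable[Architecture]
                       ) -> list[GenomeComplement]:
    """Per-genome complements for a mixed architecture list."""
    by_genome: dict[str, list[Architecture]] = {}
    for a in architectures:
        by_genome.setdefault(a.genome_id, []).append(a)
    return [genome_complement(g, archs) for g, archs in sorted(by_genome.items())]


# ---------------------------------------------------------------------------
# end-to-end annotation
# ---------------------------------------------------------------------------

def annotate_proteome(proteins: Sequence[ProteinRecord],
                      hits: Sequence[DomainHit],
                      cfg: ResolutionConfig = ResolutionConfig(),
                      quadruplet_table: Mapping[str, str] | None = None,
                      include_incomplete: bool = False,
                      ) -> tuple[list[Architecture], dict[str, list[ResolvedDomain]]]:
    """Resolve and classify every hit-bearing protein of a proteome.

    Incomplete proteins (no start/stop codon) are skipped unless
    ``include_incomplete`` is set.  Returns the architectures and the
    resolved domains keyed by protein id.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    genome_of = {p.protein_id: p.genome_id for p in proteins}
    complete = {p.protein_id: p.is_complete for p in proteins}

    architectures: list[Architecture] = []
    resolved_map: dict[str, list[ResolvedDomain]] = {}
    for pid in sorted(by_protein):
        if pid not in genome_of:
            raise ValueError(f"hit table references unknown protein {pid!r}")
        if not complete[pid] and not include_incomplete:
            continue
        resolved = resolve_overlaps(by_protein[pid], cfg)
        if not resolved:
            continue
        resolved_map[pid] = resolved
        architectures.append(
            classify_architecture(resolved, genome_id=genome_of[pid],
                                  quadruplet_table=quadruplet_table)
        )
    return architectures, resolved_map
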