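"""Alignment-level transforms and statistics.

Covers the data-hygiene steps applied to histone alignments before
phylogenetic analysis — gap trimming, sparse-sequence removal,
compositional χ² screening and reduced-alphabet (Dayhoff 4-state)
recoding — plus per-column Shannon entropy and the one-way ANOVA used to
contrast protein length between groups.  Tree inference itself is out of
scope; these are the transforms and the statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default 4-bin amino-acid reduction (a standard Dayhoff-style grouping).
#: Each bin is represented by one of its own members so recoding is
#: idempotent.  The exact binning is configurable; see the methods note.
DAYHOFF4: Mapping[str, str] = {
    **{aa: "A" for aa in "AGNPST"},
    **{aa: "C" for aa in "CHWY"},
    **{aa: "D" for aa in "DEKQR"},
    **{aa: "F" for aa in "FILMV"},
}


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment as equal-length gapped rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(widths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    @classmethod
    def from_rows(cls, ids: Iterable[str], rows: Iterable[str]) -> "Alignment":
        return cls(tuple(ids), tuple(str(r).upper() for r in rows))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"no sequences in {path}")
        return cls.from_rows([r.id for r in recs], [str(r.seq) for r in recs])

    def to_fasta(self, path: str | Path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(r), id=i, description="")
             for i, r in zip(self.ids, self.rows)],
            str(path), "fasta",
        )


@dataclass(frozen=True)
class ColumnEntropy:
    """Per-column Shannon entropy (NaN where a column is all gaps)."""

    entropy: np.ndarray
    frequencies: pd.DataFrame  # columns × residues


@dataclass(frozen=True)
class LengthAnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def trim_alignment(aln: Alignment, gap_threshold: float = 0.20,
                   min_site_fraction: float = 0.50) -> Alignment:
    """Drop gappy columns, then sparse sequences.

    Columns whose non-gap fraction falls below ``gap_threshold`` are
    removed first (the trimAl ``-gt`` convention); sequences retaining
    fewer than ``min_site_fraction`` non-gap characters over the kept
    columns are then removed.  Removing sequences can push further
    columns below threshold, so the two filters are repeated to a fixed
    point — the result satisfies both criteria simultaneously, making
    the operation idempotent.
    """
    arr = aln.to_array()
    ids = list(aln.ids)
    while True:
        col_keep = (arr != GAP).mean(axis=0) >= gap_threshold
        if not col_keep.any():
            raise ValueError("empty alignment after trimming")
        arr = arr[:, col_keep]
        row_keep = (arr != GAP).mean(axis=1) >= min_site_fraction
        if not row_keep.any():
            raise ValueError("empty alignment after trimming")
        if col_keep.all() and row_keep.all():
            break
        arr = arr[row_keep]
        ids = [i for i, k in zip(ids, row_keep) if k]
    return Alignment(tuple(ids), tuple("".join(r) for r in arr))


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def column_entropy(aln: Alignment, base: float = 2.0,
                   include_gaps: bool = False) -> ColumnEntropy:
    """Shannon entropy per column, in bits by default.

    Gaps are excluded from the counts unless ``include_gaps`` is set (then
    the gap acts as a 21st state).  All-gap columns have no defined
    distribution and are reported as NaN.
    """
    arr = aln.to_array()
    states = AMINO_ACIDS + (GAP if include_gaps else "")
    counts = np.stack([(arr == s).sum(axis=0) for s in states], axis=1).astype(float)
    totals = counts.sum(axis=1)
    H = np.full(aln.n_columns, np.nan)
    ok = totals > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts[ok] / totals[ok, None]
        terms = np.where(p > 0, p * np.log(p), 0.0)
    H[ok] = -terms.sum(axis=1) / np.log(base)
    H[ok] = np.maximum(H[ok], 0.0)  # clip -0.0 from constant columns
    freq = pd.DataFrame(
        np.divide(counts, totals[:, None], out=np.zeros_like(counts),
                  where=totals[:, None] > 0),
        columns=list(states),
    )
    freq.index.name = "column"
    return ColumnEntropy(entropy=H, frequencies=freq)


# ---------------------------------------------------------------------------
# compositional bias
# ---------------------------------------------------------------------------

def composition_chisq(aln: Alignment, alpha: float = 0.05) -> pd.DataFrame:
    """Per-sequence χ² test of residue composition against the pooled one.

    Each sequence's non-gap residue counts are compared with the counts
    expected under the alignment-wide residue frequencies; residue
    categories with zero expected count are dropped from the degrees of
    freedom (df = non-empty categories − 1).  Returns a frame with
    columns ``id``, ``chisq``, ``df``, ``p_value``, ``flagged``.
    """
    if aln.n_sequences < 2:
        raise ValueError("composition test needs ≥2 sequences")
    arr = aln.to_array()
    counts = np.stack([(arr == aa).sum(axis=1) for aa in AMINO_ACIDS], axis=1)
    counts = counts.astype(float)
    row_tot = counts.sum(axis=1)
    if (row_tot == 0).any():
        empty = [aln.ids[i] for i in np.where(row_tot == 0)[0]]
        raise ValueError(f"sequences with zero non-gap residues: {empty}")
    pooled = counts.sum(axis=0)
    pooled_freq = pooled / pooled.sum()
    rows = []
    for i, seq_id in enumerate(aln.ids):
        expected = pooled_freq * row_tot[i]
        mask = expected > 0
        chisq = float(((counts[i, mask] - expected[mask]) ** 2
                       / expected[mask]).sum())
        df = int(mask.sum()) - 1
        p = float(stats.chi2.sf(chisq, df))
        rows.append({"id": seq_id, "chisq": chisq, "df": df,
                     "p_value": p, "flagged": p < alpha})
    return pd.DataFrame(rows, columns=["id", "chisq", "df", "p_value", "flagged"])


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------

def dayhoff_recode(aln: Alignment,
                   scheme: Mapping[str, str] | None = None) -> Alignment:
    """Collapse the amino-acid alphabet into exchange-group bins.

    Gaps are preserved.  Raises ``ValueError`` naming any residue not
    covered by the scheme.
    """
    scheme = DAYHOFF4 if scheme is None else scheme
    table = dict(scheme)
    for sym in set(table.values()):
        table.setdefault(sym, sym)  # bin symbols map to themselves
    table[GAP] = GAP
    recoded = []
    for seq_id, row in zip(aln.ids, aln.rows):
        missing = sorted(set(row) - set(table))
        if missing:
            raise ValueError(
                f"sequence {seq_id}: residues {missing} missing from the "
                "recoding scheme"
            )
        recoded.append("".join(table[c] for c in row))
    return Alignment(aln.ids, tuple(recoded))


# ---------------------------------------------------------------------------
# length contrast
# ---------------------------------------------------------------------------

def length_anova(groups: Mapping[str, Sequence[float]]) -> LengthAnovaResult:
    """One-way ANOVA contrasting group lengths (two groups ⇒ F = t²)."""
    if len(groups) < 2:
        raise ValueError("length_anova needs ≥2 groups")
    for label, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    F, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    return LengthAnovaResult(
        F=float(F),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        group_means={lab: float(np.mean(v)) for lab, v in groups.items()},
    )
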