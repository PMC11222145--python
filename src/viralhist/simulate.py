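"""Seeded generators for synthetic inputs with known ground truth.

Each generator is a pure function of (seed, parameters): the random
stream is derived from the master seed together with a per-scenario
label, so adding scenarios never shifts existing outputs.  Defaults
emulate the study conditions of the analyses they feed — planted histone
architectures with decoy hits, Gompertz-shaped OD curves, Gaussian-comb
digestion ladders, and condensed versus dispersed nucleoid transects.
Ground truth is returned alongside (and serialised as JSON next to) every
generated artifact.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GROWTH_COLUMNS, gompertz_model
from .io import DomainHit, ProteinRecord, write_domtblout, write_fasta
from .ladder import Electropherogram
from .nucleoid import TRANSECT_COLUMNS, NucleoidTransect

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Profile lengths for the synthetic family HMMs (single histone folds
#: are ~65–80 aa; the H1 linker histone HMM is longer).
HMM_LENGTHS: Mapping[str, int] = {
    "H2A": 70, "H2B": 68, "H3": 78, "H4": 66, "H1": 80, "ARCH": 60,
}

#: Default histone-type mix: quadruplets, the two core doublets, and
#: singlets, echoing the repeat classes seen across viral genomes.
DEFAULT_TYPE_FREQUENCIES: Mapping[str, float] = {
    "H2B-H2A-H3-H4": 0.20,
    "H4-H3": 0.20,
    "H2B-H2A": 0.20,
    "H3": 0.10,
    "H4": 0.10,
    "H2A": 0.10,
    "H2B": 0.10,
}


def scenario_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for one (seed, scenario) pair."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def _random_protein_segment(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(AA20, size=n)) if n > 0 else ""


# ---------------------------------------------------------------------------
# proteome with planted architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteomeTruth:
    """Planted architecture of one synthetic protein."""

    protein_id: str
    genome_id: str
    type_label: str
    domains: tuple[tuple[str, int, int], ...]  # (family, start, end)
    linker_lengths: tuple[int, ...]


def synth_proteome(n_proteins: int = 500, n_genomes: int = 50,
                   type_frequencies: Mapping[str, float] | None = None,
                   linker_length_means: Sequence[float] = (12.0, 56.0, 16.0),
                   decoy_rate: float = 0.3, jitter: int = 2,
                   seed: int = 0, out_dir: str | Path | None = None,
                   ) -> tuple[list[ProteinRecord], list[DomainHit],
                              list[ProteomeTruth]]:
    """Proteins with planted histone-domain architectures plus a hit table.

    Proteins are concatenations of family segments joined by linkers of
    Poisson lengths around ``linker_length_means`` (cycled per junction).
    The hit table holds one true hit per planted domain (coordinates
    jittered by ≤ ``jitter`` residues, conditional E-values log-uniform
    in [1e-30, 1e-8]) plus decoys at rate ``decoy_rate`` per domain:
    half are sub-threshold fragments (HMM coverage < 0.25), half are
    cross-family hits on a true domain with E-values 10–10⁶ × worse.
    """
    freqs = dict(DEFAULT_TYPE_FREQUENCIES if type_frequencies is None
                 else type_frequencies)
    total = sum(freqs.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"type frequencies must sum to 1 (got {total})")
    rng = scenario_rng(seed, "proteome")
    labels = list(freqs)
    probs = np.array([freqs[t] for t in labels])

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truths: list[ProteomeTruth] = []
    for i in range(n_proteins):
        pid = f"prot{i:05d}"
        genome = f"genome{rng.integers(n_genomes):04d}"
        type_label = labels[rng.choice(len(labels), p=probs)]
        families = type_label.split("-")

        n_tail = int(rng.poisson(8))
        c_tail = int(rng.poisson(10))
        linker_lengths = tuple(
            int(rng.poisson(linker_length_means[j % len(linker_length_means)]))
            for j in range(len(families) - 1)
        )
        seq_parts = [_random_protein_segment(rng, n_tail)]
        domains: list[tuple[str, int, int]] = []
        pos = n_tail
        for j, fam in enumerate(families):
            dlen = HMM_LENGTHS[fam]
            domains.append((fam, pos + 1, pos + dlen))
            seq_parts.append(_random_protein_segment(rng, dlen))
            pos += dlen
            if j < len(families) - 1:
                seq_parts.append(_random_protein_segment(rng, linker_lengths[j]))
                pos += linker_lengths[j]
        seq_parts.append(_random_protein_segment(rng, c_tail))
        sequence = "".join(seq_parts)
        proteins.append(ProteinRecord(pid, genome, sequence))
        truths.append(ProteomeTruth(pid, genome, type_label,
                                    tuple(domains), linker_lengths))

        n = len(sequence)
        for fam, start, end in domains:
            hlen = HMM_LENGTHS[fam]
            d_from = int(np.clip(start + rng.integers(-jitter, jitter + 1), 1, n))
            d_to = int(np.clip(end + rng.integers(-jitter, jitter + 1), d_from, n))
            h_off = abs(d_from - start) + abs(d_to - end)
            true_ce = float(10.0 ** rng.uniform(-30, -8))
            hits.append(DomainHit(
                protein_id=pid, family=fam,
                ali_from=d_from, ali_to=d_to,
                hmm_from=1 + min(h_off, hlen - 2),
                hmm_to=hlen, hmm_length=hlen,
                c_evalue=true_ce,
                bit_score=float(-2.0 * np.log10(true_ce) + rng.normal(0, 3)),
            ))
            if rng.random() >= decoy_rate:
                continue
            other = [f for f in HMM_LENGTHS if f != fam]
            if rng.random() < 0.5:
                # sub-threshold fragment anywhere on the protein
                dfam = other[rng.integers(len(other))]
                dhlen = HMM_LENGTHS[dfam]
                cov = rng.uniform(0.05, 0.24)
                span = max(1, int(round(cov * dhlen)))
                a0 = int(rng.integers(1, max(2, n - span)))
                h0 = int(rng.integers(1, dhlen - span + 1))
                decoy_ce = float(10.0 ** rng.uniform(-6, -1))
                hits.append(DomainHit(
                    protein_id=pid, family=dfam,
                    ali_from=a0, ali_to=a0 + span - 1,
                    hmm_from=h0, hmm_to=h0 + span - 1, hmm_length=dhlen,
                    c_evalue=decoy_ce,
                    bit_score=float(-2.0 * np.log10(decoy_ce) + rng.normal(0, 3)),
                ))
            else:
                # cross-family hit on the true domain, clearly worse
                dfam = other[rng.integers(len(other))]
                dhlen = HMM_LENGTHS[dfam]
                a0 = int(np.clip(start + rng.integers(-jitter, jitter + 1), 1, n))
                a1 = int(np.clip(a0 + dhlen - 1, a0, n))
                decoy_ce = float(true_ce * 10.0 ** rng.uniform(1.01, 6))
                hits.append(DomainHit(
                    protein_id=pid, family=dfam,
                    ali_from=a0, ali_to=a1,
                    hmm_from=1, hmm_to=dhlen, hmm_length=dhlen,
                    c_evalue=decoy_ce,
                    bit_score=float(-2.0 * np.log10(decoy_ce) + rng.normal(0, 3)),
                ))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(proteins, out / "proteome.fasta")
        write_domtblout(hits, out / "hits.domtblout")
        _write_truth(out / "proteome.truth.json",
                     [asdict(t) for t in truths], seed, "proteome")
    return proteins, hits, truths


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def synth_growth(groups: Mapping[str, tuple[float, float, float]] | None = None,
                 n_replicates: int = 3, noise_sd: float = 0.01,
                 blank_level: float = 0.04,
                 times: np.ndarray | None = None, seed: int = 0,
                 out_dir: str | Path | None = None,
                 ) -> tuple[pd.DataFrame, dict[str, tuple[float, float, float]]]:
    """Gompertz-shaped OD curves with Gaussian noise and a media blank.

    ``groups`` maps a strain label to its true (A, µ, λ); defaults
    contrast an uninduced-like strain with a long-lag induced-like one.
    OD readings every 30 min over 24 h (the plate-reader schedule) are
    ``model + blank + N(0, noise_sd)`` clipped at zero.
    """
    if groups is None:
        groups = {"control": (1.0, 0.2, 5.0), "induced": (0.95, 0.18, 9.0)}
    for label, (A, mu, lam) in groups.items():
        if A <= 0 or mu <= 0:
            raise ValueError(f"group {label!r}: A and µ must be positive")
    if times is None:
        times = np.arange(0.0, 24.0 + 1e-9, 0.5)
    rng = scenario_rng(seed, "growth")
    rows = []
    for label in groups:
        A, mu, lam = groups[label]
        clean = gompertz_model(times, A, mu, lam)
        for rep in range(1, n_replicates + 1):
            noisy = np.clip(
                clean + blank_level + rng.normal(0, noise_sd, times.size)
                if noise_sd > 0 else clean + blank_level,
                0.0, None)
            for t, od in zip(times, noisy):
                rows.append({"strain": label, "condition": "standard",
                             "replicate": rep, "time_h": float(t),
                             "od600": float(od),
                             "blank_od600": blank_level})
    df = pd.DataFrame(rows, columns=GROWTH_COLUMNS)
    truth = dict(groups)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "growth.csv", index=False)
        _write_truth(out / "growth.truth.json",
                     {k: list(v) for k, v in truth.items()}, seed, "growth")
    return df, truth


# ---------------------------------------------------------------------------
# digestion ladders
# ---------------------------------------------------------------------------

def synth_ladder(primary_bp: float = 148.0, step_fraction: float = 0.90,
                 n_orders: int = 3, peak_sd: float = 5.0, snr: float = 10.0,
                 height_decay: float = 0.7,
                 sizes: np.ndarray | None = None, seed: int = 0,
                 out_dir: str | Path | None = None,
                 ) -> tuple[Electropherogram, dict[str, float]]:
    """Gaussian-mixture ladder trace with a planted primary and step.

    Peak k (k = 0 … n_orders−1) sits at ``primary_bp·(1 + k·step_fraction)``
    with height ``height_decay**k``; white noise is added at amplitude
    ``max_signal / snr`` and the trace is clipped at zero.
    """
    if primary_bp <= 0:
        raise ValueError("primary_bp must be positive")
    if not (0 < step_fraction <= 1.5):
        raise ValueError("step_fraction must be in (0, 1.5]")
    if sizes is None:
        sizes = np.arange(20.0, 700.0, 1.0)
    rng = scenario_rng(seed, "ladder")
    signal = np.zeros_like(sizes)
    for k in range(n_orders):
        center = primary_bp * (1.0 + k * step_fraction)
        signal += height_decay ** k * np.exp(
            -0.5 * ((sizes - center) / peak_sd) ** 2)
    noise_sd = float(signal.max()) / snr if snr > 0 else 0.0
    trace = np.clip(signal + rng.normal(0, noise_sd, sizes.size), 0.0, None)
    eg = Electropherogram(sizes, trace, label=f"ladder_seed{seed}")
    truth = {"primary_bp": float(primary_bp),
             "step_fraction": float(step_fraction),
             "n_orders": int(n_orders), "peak_sd": float(peak_sd),
             "snr": float(snr)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"size_bp": sizes, "intensity": trace}).to_csv(
            out / "ladder.csv", index=False)
        _write_truth(out / "ladder.truth.json", truth, seed, "ladder")
    return eg, truth


# ---------------------------------------------------------------------------
# nucleoid transects
# ---------------------------------------------------------------------------

def synth_transects(n_cells: int = 50, condensed: bool = True,
                    strain: str | None = None, bump_center: float = 0.5,
                    bump_sd_rel: float = 0.1,
                    length_range: tuple[float, float] = (1.5, 4.5),
                    n_points: int = 60, baseline: float = 0.15,
                    noise_sd: float = 0.05, seed: int = 0,
                    out_dir: str | Path | None = None,
                    ) -> tuple[list[NucleoidTransect], dict[str, object]]:
    """Condensed (central Gaussian bump) or dispersed (near-flat) cells.

    Lengths are uniform over ``length_range`` (default 1.5–4.5 µm so the
    2–4 µm analysis filter is exercised); intensities are positive with
    additive Gaussian noise, clipped at a small floor.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be ≥ 1")
    label = strain or ("condensed" if condensed else "dispersed")
    rng = scenario_rng(seed, f"transects:{label}")
    cells = []
    for i in range(n_cells):
        length = float(rng.uniform(*length_range))
        pos = np.linspace(0.0, length, n_points)
        rel = pos / length
        if condensed:
            profile = baseline + np.exp(
                -0.5 * ((rel - bump_center) / bump_sd_rel) ** 2)
        else:
            profile = np.full(n_points, 1.0)
        noisy = np.clip(profile + rng.normal(0, noise_sd, n_points), 1e-3, None)
        cells.append(NucleoidTransect(
            cell_id=f"{label}_{i:04d}", strain=label,
            cell_length=length, positions=pos, intensities=noisy,
        ))
    truth = {"strain": label, "condensed": condensed, "n_cells": n_cells,
             "bump_center": bump_center, "bump_sd_rel": bump_sd_rel,
             "length_range": list(length_range)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for c in cells:
            for p, y in zip(c.positions, c.intensities):
                rows.append({"cell_id": c.cell_id, "strain": c.strain,
                             "cell_length_um": c.cell_length,
                             "position_um": float(p), "intensity": float(y)})
        pd.DataFrame(rows, columns=TRANSECT_COLUMNS).to_csv(
            out / f"transects_{label}.csv", index=False)
        _write_truth(out / f"transects_{label}.truth.json", truth, seed,
                     f"transects:{label}")
    return cells, truth


# ---------------------------------------------------------------------------

def _write_truth(path: Path, payload, seed: int, scenario: str) -> None:
    doc = {"scenario": scenario, "seed": seed, "truth": payload}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
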