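from itertools import permutations

import numpy as np
import pytest

from conftest import random_hits
from oracles import exhaustive_resolution
from viralhist.domains import (DEFAULT_QUADRUPLET_TABLE, Architecture,
                               ResolutionConfig, ResolvedDomain,
                               assign_family, classify_architecture,
                               extract_linkers, filter_recurrent_types,
                               genome_complement, linker_length_summary,
                               overlap_fraction, resolve_overlaps)
from viralhist.io import ProteinRecord


def _domain(hit):
    return ResolvedDomain(hit.family, hit.ali_from, hit.ali_to,
                          hit.c_evalue, hit)


# ---------------------------------------------------------------------------
# resolve_overlaps
# ---------------------------------------------------------------------------

class TestResolveOverlaps:
    def test_better_evalue_wins_contested_region(self, make_hit):
        # 60% overlap of the shorter interval > 50% threshold
        hits = [make_hit("H3", 1, 100, 1e-10),
                make_hit("H4", 41, 140, 1e-5)]
        out = resolve_overlaps(hits)
        assert [(d.start, d.end) for d in out] == [(1, 100)]

    def test_low_coverage_excluded(self, make_hit):
        hit = make_hit(hmm_from=1, hmm_to=24, hmm_length=100, ali_to=24)
        assert resolve_overlaps([hit]) == []

    def test_empty_input_is_empty_output(self):
        assert resolve_overlaps([]) == []

    def test_mixed_proteins_rejected(self, make_hit):
        with pytest.raises(ValueError, match="one protein"):
            resolve_overlaps([make_hit(protein_id="p1"),
                              make_hit(protein_id="p2")])

    def test_matches_exhaustive_oracle(self, rng):
        cfg = ResolutionConfig()
        for _ in range(200):
            hits = random_hits(rng, int(rng.integers(0, 13)))
            got = resolve_overlaps(hits, cfg)
            expected = exhaustive_resolution(hits, cfg)
            assert [d.source_hit for d in got] == expected

    def test_output_conflict_free(self, rng):
        cfg = ResolutionConfig()
        for _ in range(50):
            out = resolve_overlaps(random_hits(rng, 12), cfg)
            for i, a in enumerate(out):
                for b in out[i + 1:]:
                    assert overlap_fraction(a.start, a.end, b.start, b.end) \
                        <= cfg.overlap_threshold

    def test_raising_min_coverage_never_adds_domains(self, rng):
        for _ in range(30):
            hits = random_hits(rng, 10)
            counts = [
                len(resolve_overlaps(hits, ResolutionConfig(min_coverage=c)))
                for c in (0.1, 0.25, 0.5, 0.9)
            ]
            assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# assign_family
# ---------------------------------------------------------------------------

class TestAssignFamily:
    def test_clear_winner(self, make_hit):
        hits = [make_hit("H3", c_evalue=1e-20), make_hit("H4", c_evalue=1e-4)]
        assert assign_family(hits) == "H3"

    def test_ambiguous_is_hx(self, make_hit):
        hits = [make_hit("H2A", c_evalue=1e-6), make_hit("H2B", c_evalue=5e-6)]
        assert assign_family(hits) == "Hx"

    def test_single_family_never_ambiguous(self, make_hit):
        assert assign_family([make_hit("H2A", c_evalue=0.9)]) == "H2A"
        # two hits, same family: still unambiguous
        hits = [make_hit("H3", c_evalue=1e-6), make_hit("H3", c_evalue=2e-6)]
        assert assign_family(hits) == "H3"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            assign_family([])


# ---------------------------------------------------------------------------
# classify_architecture
# ---------------------------------------------------------------------------

class TestClassify:
    def test_doublet_and_triplet_labels(self, make_hit):
        doms = [_domain(make_hit("H4", 1, 66)),
                _domain(make_hit("H3", 80, 150))]
        arch = classify_architecture(doms, "g1")
        assert (arch.type_label, arch.repeat_class) == ("H4-H3", "doublet")

        doms = [_domain(make_hit("H2B", 1, 68)),
                _domain(make_hit("H2A", 80, 150)),
                _domain(make_hit("H3", 160, 230))]
        arch = classify_architecture(doms, "g1")
        assert (arch.type_label, arch.repeat_class) == \
            ("H2B-H2A-H3", "triplet")

    def test_all_quadruplet_permutations_against_table(self, make_hit):
        for perm in permutations(["H2A", "H2B", "H3", "H4"]):
            doms = [_domain(make_hit(f, 1 + 80 * i, 70 + 80 * i))
                    for i, f in enumerate(perm)]
            arch = classify_architecture(doms, "g1")
            label = "-".join(perm)
            expected = DEFAULT_QUADRUPLET_TABLE.get(label, "unassigned")
            assert arch.repeat_class == "quadruplet"
            assert arch.quadruplet_config == expected
        configs = set(DEFAULT_QUADRUPLET_TABLE.values())
        assert configs == {"HQA", "HQB", "HQC"}

    def test_quadruplet_with_repeated_family_unassigned(self, make_hit):
        doms = [_domain(make_hit(f, 1 + 80 * i, 70 + 80 * i))
                for i, f in enumerate(["H3", "H3", "H2A", "H2B"])]
        assert classify_architecture(doms).quadruplet_config == "unassigned"

    def test_five_domains_is_other(self, make_hit):
        doms = [_domain(make_hit("H3", 1 + 80 * i, 70 + 80 * i))
                for i in range(5)]
        assert classify_architecture(doms).repeat_class == "other"

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no histone domains"):
            classify_architecture([])


# ---------------------------------------------------------------------------
# recurrence filter
# ---------------------------------------------------------------------------

def _arch(type_label, genome_id, protein_id="p"):
    fams = tuple(type_label.split("-"))
    return Architecture(protein_id, genome_id, fams, type_label,
                        {1: "singlet", 2: "doublet", 3: "triplet",
                         4: "quadruplet"}.get(len(fams), "other"))


class TestRecurrence:
    def test_same_genome_twice_excluded(self):
        archs = [_arch("H4-H3", "g1", "p1"), _arch("H4-H3", "g1", "p2")]
        assert filter_recurrent_types(archs) == set()

    def test_two_genomes_included(self):
        archs = [_arch("H4-H3", "g1"), _arch("H4-H3", "g2")]
        assert filter_recurrent_types(archs) == {"H4-H3"}

    def test_matches_counting_oracle(self, rng):
        types = ["H3", "H4", "H4-H3", "H2B-H2A"]
        archs = [_arch(types[rng.integers(4)], f"g{rng.integers(6)}")
                 for _ in range(80)]
        got = filter_recurrent_types(archs, min_genomes=3)
        expected = set()
        for t in types:
            genomes = {a.genome_id for a in archs if a.type_label == t}
            if len(genomes) >= 3:
                expected.add(t)
        assert got == expected

    def test_min_genomes_validation(self):
        with pytest.raises(ValueError):
            filter_recurrent_types([], min_genomes=0)


# ---------------------------------------------------------------------------
# linkers
# ---------------------------------------------------------------------------

class TestLinkers:
    def test_adjacent_domains_zero_length_linker(self, make_hit):
        protein = ProteinRecord("p1", "g1", "A" * 220)
        doms = [_domain(make_hit("H3", 1, 100)),
                _domain(make_hit("H4", 101, 200))]
        ls = extract_linkers(protein, doms)
        assert ls.linkers == (("", 101, 100),)
        assert len(ls.c_tail) == 20

    def test_single_domain_has_two_tails(self, make_hit):
        protein = ProteinRecord("p1", "g1", "M" * 100)
        ls = extract_linkers(protein, [_domain(make_hit("H3", 11, 80))])
        assert ls.linkers == ()
        assert (len(ls.n_tail), len(ls.c_tail)) == (10, 20)

    def test_length_conservation(self, rng, make_hit):
        # domains + linkers + tails partition the protein exactly
        for _ in range(20):
            n = int(rng.integers(150, 400))
            protein = ProteinRecord("p1", "g1", "K" * n)
            a_end = int(rng.integers(20, n // 2))
            b_start = int(rng.integers(a_end + 1, n - 10))
            doms = [_domain(make_hit("H3", 5, a_end)),
                    _domain(make_hit("H4", b_start, n - 5))]
            ls = extract_linkers(protein, doms)
            total = sum(d.length for d in doms) \
                + sum(len(s) for s, _, _ in ls.linkers) \
                + len(ls.n_tail) + len(ls.c_tail)
            assert total == n

    def test_out_of_range_domain_errors(self, make_hit):
        protein = ProteinRecord("p1", "g1", "A" * 50)
        with pytest.raises(ValueError, match="out of range"):
            extract_linkers(protein, [_domain(make_hit("H3", 10, 80))])

    def test_planted_linker_medians_recovered(self):
        from viralhist.simulate import synth_proteome
        from viralhist.domains import annotate_proteome
        proteins, hits, truth = synth_proteome(
            n_proteins=50, decoy_rate=0.0, jitter=0, seed=42,
            type_frequencies={"H2B-H2A-H3-H4": 1.0})
        archs, resolved = annotate_proteome(proteins, hits)
        by_pid = {p.protein_id: p for p in proteins}
        linker_sets = [extract_linkers(by_pid[pid], doms)
                       for pid, doms in resolved.items()]
        summary = linker_length_summary(
            linker_sets, {a.protein_id: a.type_label for a in archs})
        medians = summary.sort_values("position")["median"].tolist()
        assert medians == pytest.approx([12, 56, 16], abs=2)


# ---------------------------------------------------------------------------
# complements
# ---------------------------------------------------------------------------

class TestComplement:
    def test_triplet_plus_singlet_is_full(self):
        archs = [_arch("H2B-H2A-H3", "g1"), _arch("H4", "g1")]
        comp = genome_complement("g1", archs)
        assert comp.is_full_complement

    def test_quadruplet_alone_is_full(self):
        comp = genome_complement("g1", [_arch("H2B-H2A-H3-H4", "g1")])
        assert comp.is_full_complement

    def test_single_family_not_full(self):
        comp = genome_complement("g1", [_arch("H2A", "g1")])
        assert comp.families_present == frozenset({"H2A"})
        assert not comp.is_full_complement

    def test_no_histones_empty(self):
        comp = genome_complement("g1", [])
        assert comp.families_present == frozenset()
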