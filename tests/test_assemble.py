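"""Greedy path extraction, path filtering, locus assembly, condense, GTF."""
import io

import numpy as np
import pytest

from endguide.assemble import (
    assemble,
    assemble_locus,
    condense,
    filter_paths,
    greedy_paths,
    write_gtf,
)
from endguide.elr import sort_key
from endguide.graph import build_overlap_graph, resolve_containment, synthetic_membership
from endguide.gtfio import gtf_to_read_models
from endguide.model import ELRHeader, NO_LABEL
from endguide.params import AssemblyParams
from endguide.simulate import (
    make_fixture_suite,
    make_tandem_fixture,
    make_two_isoform_locus,
    random_locus,
    simulate_reads,
)


def assemble_sorted(reads, params, n_samples):
    return list(assemble(sorted(reads, key=sort_key), params,
                         n_samples=n_samples))


def chains(models):
    return {(m.strand, tuple(m.exons)) for m in models}


def truth_chains(locus):
    return {(iso.strand, tuple(iso.exons)) for iso in locus.isoforms}


class TestGreedyPaths:
    def test_linear_graph_single_path_carries_total_weight(self):
        matrix = synthetic_membership([
            (4.0, [{0: 1, 1: 1, "S": 1}, {1: 1, 2: 1}, {2: 1, 3: 1, "E": 1}]),
        ])
        graph = resolve_containment(build_overlap_graph(matrix))
        paths = greedy_paths(graph, end_fraction=0.02)
        assert len(paths) == 1
        assert paths[0].complete
        assert paths[0].weight == pytest.approx(4.0)

    def test_two_chain_fork_extracts_both(self):
        matrix = synthetic_membership([
            (6.0, [{0: 1, 1: 1, "S": 1}]),
            (6.0, [{1: 1, 2: 1, "E": 1}]),
            (3.0, [{1: 1, 3: 1, 4: -1}, {3: 1, 4: 1, "E": 1}]),
        ])
        graph = resolve_containment(build_overlap_graph(matrix))
        paths = greedy_paths(graph, end_fraction=0.02)
        complete = [p for p in paths if p.complete]
        assert len(complete) == 2

    def test_assigned_plus_remaining_conserved(self, rng):
        loc = random_locus(rng, 3, n_samples=2)
        reads, _ = simulate_reads(loc, rng=rng, n_samples=2)
        reads.sort(key=sort_key)
        from endguide.assemble import _GreedyState
        from endguide.cluster import (build_partition, cluster_locus_tags,
                                      collect_tags, filter_locus_junctions,
                                      snap_read_labels)
        from endguide.graph import build_membership, collapse_linear_chains
        p = AssemblyParams()
        cl = cluster_locus_tags(collect_tags(reads), p.max_gap,
                                p.min_proportion, p.cap_bonus, p.cap_filter)
        snapped = [snap_read_labels(r, cl) for r in reads]
        jn = filter_locus_junctions(snapped, p.min_overhang, p.min_proportion)
        part = build_partition(cl, jn, (min(r.start for r in snapped),
                                        max(r.end for r in snapped)))
        matrix = collapse_linear_chains(
            build_membership(snapped, part, p.min_overhang, 2))
        graph = resolve_containment(build_overlap_graph(matrix))
        total_before = sum(e.weight * e.length
                           for e in graph.free_elements())
        state = _GreedyState(graph)
        paths = greedy_paths(graph, 0.02)
        # re-walk the assignment: sum of drained weight plus remaining
        # equals the starting total exactly
        state2 = _GreedyState(graph)
        drained = 0.0
        for path in paths:
            cov = {}
            for i in path.element_indices:
                e = state2.elements[i]
            for i in path.element_indices:
                before = state2.remaining[i]
                state2.remaining[i] = max(0.0, before - path.weight)
                drained += (before - state2.remaining[i]) * \
                    state2.elements[i].length
        remaining = sum(state2.remaining[i] * state2.elements[i].length
                        for i in state2.elements)
        assert drained + remaining == pytest.approx(total_before, rel=1e-9)


class TestFilters:
    def _models(self, rng, **overrides):
        loc = make_two_isoform_locus(rng, "tss")
        reads, _ = simulate_reads(loc, seed=123, n_samples=2)
        return assemble_sorted(reads, AssemblyParams(**overrides), 2)

    def test_min_cov_boundary_pair(self, rng):
        models = self._models(rng)
        weakest = min(m.abundance for m in models)
        passing = self._models(rng, min_cov=weakest - 0.01)
        failing = self._models(rng, min_cov=weakest + 0.01)
        assert len(passing) == len(models)
        assert len(failing) == len(models) - 1

    def test_min_len_boundary_pair(self, rng):
        models = self._models(rng)
        longest = max(m.length for m in models)
        kept = self._models(rng, min_len=longest)
        dropped = self._models(rng, min_len=longest + 1)
        assert any(m.length == longest for m in kept)
        assert all(m.length != longest for m in dropped)

    def test_min_proportion_boundary_pair(self, rng):
        loc = make_two_isoform_locus(rng, "tss")
        reads, _ = simulate_reads(loc, seed=123, n_samples=2)
        reads = sorted(reads, key=sort_key)
        total = sum(r.weight * r.aligned_bases for r in reads)
        models = assemble_sorted(reads, AssemblyParams(), 2)
        shares = sorted(m.abundance * m.length / total for m in models)
        midpoint = (shares[0] + shares[1]) / 2
        low = assemble_sorted(
            reads, AssemblyParams(min_proportion=shares[0] * 0.5), 2)
        high = assemble_sorted(
            reads, AssemblyParams(min_proportion=midpoint), 2)
        assert len(low) == len(models)
        assert len(high) < len(models)

    def test_discard_incomplete_default(self, rng):
        loc = make_two_isoform_locus(rng, "pas")
        reads, _ = simulate_reads(loc, rng=rng, n_samples=2,
                                  label_rate_5=0.0)  # no 5' evidence
        models = assemble_sorted(reads, AssemblyParams(), 2)
        assert models == []
        kept = assemble_sorted(
            reads, AssemblyParams(discard_incomplete=False), 2)
        assert kept and all(not m.complete for m in kept)


class TestAssembleLocus:
    def test_alternative_tss_locus_recovers_both_isoforms(self, rng):
        loc = make_two_isoform_locus(rng, "tss")
        reads, _ = simulate_reads(loc, rng=rng, n_samples=2)
        models = assemble_sorted(reads, AssemblyParams(), 2)
        assert chains(models) == truth_chains(loc)
        truth_tss = {iso.tss for iso in loc.isoforms}
        assert {m.tss_summit for m in models} == truth_tss

    def test_alternative_pas_locus_recovers_both_isoforms(self, rng):
        loc = make_two_isoform_locus(rng, "pas")
        reads, _ = simulate_reads(loc, rng=rng, n_samples=2)
        models = assemble_sorted(reads, AssemblyParams(), 2)
        assert chains(models) == truth_chains(loc)
        assert {m.pas_summit for m in models} == {i.pas for i in loc.isoforms}

    def test_tandem_genes_stay_separate_with_labels(self):
        fx = make_tandem_fixture(np.random.default_rng(12))
        models = assemble_sorted(fx.reads, AssemblyParams(), 2)
        assert len(models) == 2
        assert chains(models) == truth_chains(fx.locus)

    def test_tandem_genes_fuse_or_fragment_without_labels(self):
        fx = make_tandem_fixture(np.random.default_rng(12))
        stripped = [r.copy(left_label=NO_LABEL, right_label=NO_LABEL)
                    for r in fx.reads]
        models = assemble_sorted(
            stripped, AssemblyParams(discard_incomplete=False), 2)
        assert len(models) != 2

    def test_antisense_pair_resolved_by_strand(self):
        from endguide.simulate import make_antisense_fixture
        fx = make_antisense_fixture(np.random.default_rng(13))
        models = assemble_sorted(fx.reads, AssemblyParams(), 1)
        assert chains(models) == truth_chains(fx.locus)

    def test_unstranded_fragments_not_reported(self, rng):
        loc = make_two_isoform_locus(rng, "tss")
        reads, _ = simulate_reads(loc, rng=rng, label_rate_5=0.0,
                                  label_rate_3=0.0)
        models = assemble_sorted(
            reads, AssemblyParams(discard_incomplete=False), 1)
        assert models == []   # all evidence is unstranded


class TestCondense:
    def test_complete_and_incomplete_paths_reencoded(self, rng):
        loc = make_two_isoform_locus(rng, "tss")
        reads, _ = simulate_reads(loc, rng=rng, n_samples=1)
        out = condense(sorted(reads, key=sort_key), AssemblyParams())
        assert out
        complete = [r for r in out
                    if r.left_label != "." and r.right_label != "."]
        assert complete, "complete paths keep labels at both ends"
        for r in out:
            r.validate()

    def test_three_prime_only_path_keeps_only_end_label(self, rng):
        loc = make_two_isoform_locus(rng, "pas")
        reads, _ = simulate_reads(loc, rng=rng, label_rate_5=0.0)
        out = condense(sorted(reads, key=sort_key), AssemblyParams())
        assert out
        assert all(r.left_label == "." for r in out)   # plus strand: no TSS
        assert any(r.right_label == "E" for r in out)


class TestGtfOutput:
    def test_round_trip_preserves_exon_chains(self, rng):
        loc = make_two_isoform_locus(rng, "tss")
        reads, _ = simulate_reads(loc, rng=rng, n_samples=2)
        models = assemble_sorted(reads, AssemblyParams(), 2)
        header = ELRHeader([("chrSim", loc.length)], ["a", "b"])
        buf = io.StringIO()
        write_gtf(models, header, buf)
        back = list(gtf_to_read_models(io.StringIO(buf.getvalue()), header))
        assert {tuple(r.blocks) for r in back} == \
            {tuple(m.exons) for m in models}

    def test_repeated_runs_byte_identical(self, rng):
        loc = make_two_isoform_locus(rng, "pas")
        reads, _ = simulate_reads(loc, seed=77, n_samples=2)
        reads.sort(key=sort_key)
        header = ELRHeader([("chrSim", loc.length)], ["a", "b"])
        texts = []
        for _ in range(2):
            buf = io.StringIO()
            write_gtf(list(assemble(reads, AssemblyParams(), n_samples=2)),
                      header, buf)
            texts.append(buf.getvalue())
        assert texts[0] == texts[1]

    def test_one_based_inclusive_coordinates(self):
        from endguide.gtfio import format_gtf_transcript
        text = format_gtf_transcript("chr1", "t1", "g1", "+",
                                     [(99, 199), (299, 350)])
        lines = text.strip().split("\n")
        exon1 = lines[1].split("\t")
        assert (exon1[3], exon1[4]) == ("100", "199")


class TestFixtureSuite:
    def test_noise_free_fixtures_assemble_to_truth(self):
        suite = make_fixture_suite(1)
        for name in ("alt_tss", "alt_pas", "tandem", "antisense",
                     "truncated"):
            fx = suite[name]
            n_samples = max((r.sample for r in fx.reads), default=0) + 1
            models = assemble_sorted(fx.reads, AssemblyParams(), n_samples)
            assert chains(models) == truth_chains(fx.locus), name


class TestAnnotationPseudoReads:
    def test_single_annotation_round_trips_through_assembly(self, rng):
        """A weighted annotation pseudo-read assembles back to itself."""
        from endguide.gtfio import format_gtf_transcript
        header = ELRHeader([("chr1", 5000)], ["ann"])
        text = format_gtf_transcript(
            "chr1", "t1", "g1", "+", [(100, 400), (600, 900)],
            {"weight": "5"})
        reads = list(gtf_to_read_models(
            io.StringIO(text), header, weight_source="score"))
        assert len(reads) == 1
        assert reads[0].weight == 5.0
        assert (reads[0].left_label, reads[0].right_label) == ("C", "E")
        models = assemble_sorted(reads, AssemblyParams(), 1)
        assert len(models) == 1
        assert models[0].exons == [(100, 400), (600, 900)]
        assert models[0].complete and models[0].capped
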