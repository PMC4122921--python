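"""Simulator: genome construction, divergence, collapse, and fragment tiling."""

import pytest

from tedepth.simulate import (
    FamilySpec,
    SimulationConfig,
    apply_divergence,
    collapse_assembly,
    copy_pair_identity,
    depth_profile,
    simulate_alignments,
    simulate_genome,
)


def _config(**kw):
    base = dict(background_length=50_000, coverage=10.0, fragment_length=50,
                tiling_mode="exact", seed=3, n_genes=10, gene_span_range=(1000, 1500))
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateGenome:
    def test_no_families_means_no_te(self):
        sim = simulate_genome(_config(families=()))
        assert sim.truth.te_fraction == 0.0
        assert sim.te_annotations == []
        assert sim.length == 50_000

    def test_genome_length_and_fraction_are_config_arithmetic(self):
        fam = FamilySpec("f1", "Gypsy", copy_number=10, divergence=0.0, consensus_length=5000)
        sim = simulate_genome(_config(background_length=95_000, families=(fam,)))
        assert sim.length == 145_000
        assert sim.truth.te_fraction == pytest.approx(50_000 / 145_000)

    def test_truth_copy_numbers_and_annotation_count(self):
        fams = (
            FamilySpec("f1", "Gypsy", copy_number=3, divergence=0.01, consensus_length=2000),
            FamilySpec("f2", "LINE", copy_number=7, divergence=0.01, consensus_length=2000),
        )
        sim = simulate_genome(_config(families=fams))
        assert sim.truth.copy_number == {"f1": 3, "f2": 7}
        assert len(sim.te_annotations) == 10

    def test_gene_models_are_multiexon_and_clear_of_tes(self):
        fam = FamilySpec("f1", "Gypsy", copy_number=5, divergence=0.0, consensus_length=3000)
        sim = simulate_genome(_config(background_length=120_000, families=(fam,), n_genes=50))
        assert len(sim.gene_models) >= 50
        te_loci = [(c.start, c.end) for c in sim.copies]
        for g in sim.gene_models:
            assert len(g.exons) >= 2
            s, e = g.span
            assert all(e <= ts or s >= te for ts, te in te_loci)

    def test_overfull_background_raises(self):
        fam = FamilySpec("f1", "Gypsy", copy_number=100, divergence=0.0, consensus_length=5000)
        with pytest.raises(ValueError, match="genome overfull"):
            simulate_genome(_config(background_length=5_000, families=(fam,), n_genes=50))


class TestApplyDivergence:
    def test_zero_divergence_is_identity(self):
        seq = "ACGT" * 100
        assert apply_divergence(seq, 0.0, seed=1) == seq

    def test_mutation_rate_matches_divergence(self):
        seq = "ACGT" * 2500
        out = apply_divergence(seq, 0.1, seed=7)
        mismatches = sum(a != b for a, b in zip(seq, out))
        assert len(out) == len(seq)
        assert abs(mismatches / len(seq) - 0.1) < 0.01

    def test_different_seeds_differ(self):
        seq = "ACGT" * 100
        assert apply_divergence(seq, 0.5, seed=1) != apply_divergence(seq, 0.5, seed=2)

    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError):
            apply_divergence("ACGT", 0.6, seed=0)


class TestCollapse:
    def test_threshold_one_with_distinct_copies_is_noop(self):
        fam = FamilySpec("f1", "Gypsy", copy_number=6, divergence=0.03, consensus_length=2000)
        sim = simulate_genome(_config(families=(fam,)))
        asm = collapse_assembly(sim, threshold=1.0)
        assert len(asm.te_annotations) == len(sim.te_annotations)
        assert asm.te_bp == sum(a.length for a in sim.te_annotations)

    def test_identical_copies_collapse_to_one(self, tiny_config):
        sim = simulate_genome(tiny_config)
        asm = collapse_assembly(sim)
        assert len(asm.te_annotations) == 1
        assert len(asm.collapse_map) == 10
        reps = set(asm.collapse_map.values())
        assert len(reps) == 1
        rep = reps.pop()
        assert asm.collapse_map[rep] == rep  # representative maps to itself

    def test_pairwise_identity_below_threshold_keeps_both(self):
        # divergence 0.05 per copy -> pairwise identity ~0.90, below 0.97
        fam = FamilySpec("f1", "Gypsy", copy_number=2, divergence=0.05, consensus_length=4000)
        sim = simulate_genome(_config(families=(fam,)))
        ident = copy_pair_identity(sim.copies[0], sim.copies[1], 4000)
        assert 0.85 < ident < 0.95
        asm = collapse_assembly(sim, threshold=0.97)
        assert len(asm.te_annotations) == 2

    def test_collapse_map_is_total_and_reps_self_map(self, tiny_config):
        sim = simulate_genome(tiny_config)
        asm = collapse_assembly(sim)
        assert set(asm.collapse_map) == {c.copy_id for c in sim.copies}
        for rep in set(asm.collapse_map.values()):
            assert asm.collapse_map[rep] == rep

    def test_lower_threshold_never_increases_assembled_bp(self):
        fams = tuple(
            FamilySpec(f"f{i}", "Gypsy", copy_number=5, divergence=d, consensus_length=2000)
            for i, d in enumerate([0.0, 0.01, 0.05])
        )
        sim = simulate_genome(_config(families=fams))
        bps = [collapse_assembly(sim, threshold=t).te_bp for t in (1.0, 0.99, 0.97, 0.9, 0.5)]
        assert bps == sorted(bps, reverse=True)

    def test_deleted_loci_split_scaffolds(self, tiny_config):
        sim = simulate_genome(tiny_config)
        asm = collapse_assembly(sim)
        # 9 deletions split the sequence into 10 scaffolds
        assert len(asm.scaffolds) == 10
        assert asm.size == sim.length - 9 * 5000


class TestSimulateAlignments:
    def test_exact_tiling_fragment_count_and_uniform_depth(self):
        config = _config(background_length=1000, families=(), coverage=10.0,
                         fragment_length=100, n_genes=0)
        sim = simulate_genome(config)
        asm = collapse_assembly(sim)
        aln = simulate_alignments(sim, asm)
        assert len(aln) == 100
        assert aln.n_aligned == 100
        depth = depth_profile(aln, asm.scaffold_names[0], 1000, circular=True)
        assert (depth == 10).all()

    def test_collapsed_representative_depth_is_copy_number_fold(self, tiny_config):
        sim = simulate_genome(tiny_config)
        asm = collapse_assembly(sim)
        aln = simulate_alignments(sim, asm)
        ann = asm.te_annotations[0]
        idx = asm.scaffold_names.index(ann.scaffold)
        depth = depth_profile(aln, ann.scaffold, len(asm.scaffolds[ann.scaffold]))
        te_depth = depth[ann.start + 50 : ann.end - 50].mean()
        g = asm.gene_models[0]
        gene_depth = depth_profile(aln, g.scaffold, len(asm.scaffolds[g.scaffold]))[
            g.span[0] : g.span[1]
        ].mean()
        assert te_depth / gene_depth == pytest.approx(10.0, rel=0.02)

    def test_hemizygous_te_depth_is_half_gene_depth(self):
        fam = FamilySpec("f1", "Gypsy", copy_number=4, divergence=0.03, consensus_length=3000)
        config = _config(families=(fam,), heterozygosity_mode="hemizygous_te",
                         coverage=20.0, fragment_length=20)
        sim = simulate_genome(config)
        asm = collapse_assembly(sim)
        aln = simulate_alignments(sim, asm)
        name = asm.scaffold_names[0]
        depth = depth_profile(aln, name, len(asm.scaffolds[name]))
        ann = asm.te_annotations[0]
        g = asm.gene_models[0]
        ratio = depth[ann.start + 30 : ann.end - 30].mean() / depth[g.span[0] : g.span[1]].mean()
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_fragment_conservation(self, tiny_config):
        sim = simulate_genome(tiny_config)
        asm = collapse_assembly(sim)
        aln = simulate_alignments(sim, asm)
        n_plan = round(tiny_config.coverage * sim.length / tiny_config.fragment_length)
        assert len(aln) == n_plan
        assert aln.n_aligned + int((~aln.is_aligned).sum()) == n_plan
        ids = [r.fragment_id for r in aln.records()]
        assert len(ids) == len(set(ids))

    def test_breakpoint_spanning_fragments_are_unaligned(self, tiny_config):
        sim = simulate_genome(tiny_config)
        asm = collapse_assembly(sim)
        aln = simulate_alignments(sim, asm)
        # 9 deleted copies x 2 breakpoints x (L-1) straddling starts, plus the
        # origin-wrapping fragments (L-1) on a multi-scaffold assembly
        L = tiny_config.fragment_length
        assert int((~aln.is_aligned).sum()) == 9 * 2 * (L - 1) + (L - 1)

    def test_sampled_tiling_is_seeded(self):
        config = _config(tiling_mode="sampled", families=())
        sim = simulate_genome(config)
        asm = collapse_assembly(sim)
        a1 = simulate_alignments(sim, asm)
        a2 = simulate_alignments(sim, asm)
        assert (a1.start == a2.start).all()
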