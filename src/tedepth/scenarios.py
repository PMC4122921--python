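"""Reference simulation scenarios.

Each scenario fixes one study condition the estimator must handle:

* ``calibration``       — no collapse, no heterozygosity, deterministic tiling:
                          the null in which every S_t must be 1 and corrected
                          content must equal assembled content.
* ``collapsed_decade``  — ten identical 5 kb copies collapsing onto a single
                          representative: a worked example whose truth
                          (TE fraction 50/145 ~ 34.5%) is recoverable by hand.
* ``stochastic``        — a 5 Mb genome at 35% TE across three superfamilies
                          with 5/8 of copies young enough to collapse, sampled
                          30x coverage: the realistic parameter-recovery case.
* ``hemizygous``        — every TE copy present on one haplotype only, mapped
                          against a one-haplotype assembly: the half-coverage
                          pattern of heterozygous dikaryons (pre-floor S_t
                          around 0.5, log2 relative coverage around -1).

The scenario parameters are study conditions, not tuning knobs; tests and the
acceptance script consume them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import PipelineResult, quantify_te_content
from .simulate import (
    Assembly,
    FamilySpec,
    SimulatedGenome,
    SimulationConfig,
    collapse_assembly,
    simulate_alignments,
)


def calibration_config(seed: int = 0) -> SimulationConfig:
    """~2 Mb genome, 3 superfamilies, copies mutually well below 97% identity
    (divergence 0.03 -> pairwise identity ~0.94), exact tiling at 30x."""
    families = tuple(
        FamilySpec(f"{sf}_fam1", sf, copy_number=40, divergence=0.03, consensus_length=5000)
        for sf in ("Gypsy", "Copia", "LINE")
    )
    return SimulationConfig(
        background_length=1_400_000,
        families=families,
        coverage=30.0,
        fragment_length=30,
        tiling_mode="exact",
        seed=seed,
    )


def collapsed_decade_config(seed: int = 0) -> SimulationConfig:
    """95 kb background + one family of 10 identical 5 kb copies (divergence 0)
    collapsing to a single representative under the 0.97 threshold."""
    return SimulationConfig(
        background_length=95_000,
        families=(FamilySpec("Gypsy_fam1", "Gypsy", copy_number=10, divergence=0.0, consensus_length=5000),),
        coverage=10.0,
        fragment_length=10,
        tiling_mode="exact",
        seed=seed,
        n_genes=50,
        gene_span_range=(1200, 1500),
        min_gap=100,
    )


def stochastic_config(seed: int = 0) -> SimulationConfig:
    """5 Mb genome, true TE fraction ~35% over 3 superfamilies; each superfamily
    has a young family (divergence 0.004, collapsible at 0.97) and an old one
    (divergence 0.05, too diverged to collapse); 5/8 of copies are young."""
    families = []
    for sf in ("Gypsy", "Copia", "LINE"):
        families.append(FamilySpec(f"{sf}_young", sf, copy_number=73, divergence=0.004, consensus_length=5000))
        families.append(FamilySpec(f"{sf}_old", sf, copy_number=44, divergence=0.05, consensus_length=5000))
    return SimulationConfig(
        background_length=3_250_000,
        families=tuple(families),
        coverage=30.0,
        fragment_length=100,
        tiling_mode="sampled",
        seed=seed,
    )


def hemizygous_config(seed: int = 0) -> SimulationConfig:
    """All TE copies hemizygous (one haplotype), genes on both haplotypes
    assembled once: TE loci sequenced at half the per-base rate of genes."""
    families = tuple(
        FamilySpec(f"{sf}_fam1", sf, copy_number=20, divergence=0.03, consensus_length=5000)
        for sf in ("Gypsy", "LINE")
    )
    return SimulationConfig(
        background_length=500_000,
        families=families,
        coverage=30.0,
        fragment_length=30,
        tiling_mode="exact",
        heterozygosity_mode="hemizygous_te",
        hemizygous_fraction=1.0,
        seed=seed,
    )


@dataclass
class ScenarioRun:
    sim: SimulatedGenome
    assembly: Assembly
    result: PipelineResult


def run_scenario(config: SimulationConfig, mode: str = "length_weighted",
                 floor_at_one: bool = True) -> ScenarioRun:
    """Simulate, collapse, map, and quantify one scenario end to end."""
    from .simulate import simulate_genome

    sim = simulate_genome(config)
    assembly = collapse_assembly(sim)
    alignments = simulate_alignments(sim, assembly)
    result = quantify_te_content(
        assembly.te_annotations,
        assembly.gene_models,
        alignments,
        assembly_size=assembly.size,
        mode=mode,
        floor_at_one=floor_at_one,
        scaffolds=assembly.scaffold_names,
    )
    return ScenarioRun(sim, assembly, result)
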