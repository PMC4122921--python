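"""End-to-end composition: dedup -> count -> FPKM -> S_t -> corrected content."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotate import deduplicate_annotations
from .model import GeneModel, TEAnnotation
from .quantify import (
    CountTable,
    FeatureSet,
    FPKMTable,
    GenomeSummary,
    SuperfamilySummary,
    compute_fpkm,
    corrected_content,
    count_fragments,
    coverage_table,
    scaling_factors,
    te_read_fraction,
)


@dataclass
class PipelineResult:
    features: FeatureSet
    counts: CountTable
    fpkm: FPKMTable
    scaling: pd.DataFrame
    summaries: list[SuperfamilySummary]
    genome: GenomeSummary
    te_read_fraction: float
    coverage: pd.DataFrame

    def s_t(self, superfamily: str) -> float:
        return float(self.scaling.loc[superfamily, "s_t"])

    def s_t_prefloor(self, superfamily: str) -> float:
        return float(self.scaling.loc[superfamily, "s_t_prefloor"])


def quantify_te_content(
    te_annotations: Iterable[TEAnnotation],
    gene_models: Iterable[GeneModel],
    alignments,
    assembly_size: int,
    mode: str = "length_weighted",
    floor_at_one: bool = True,
    dedup: bool = True,
    min_remainder: int = 80,
    trim: bool = True,
    scaffolds: Iterable[str] = (),
) -> PipelineResult:
    """Run the full coverage-based estimator against one assembly.

    ``assembly_size`` is the total assembled bp; the non-TE portion of it forms
    the fixed part of the corrected genome size.
    """
    te_annotations = list(te_annotations)
    if dedup:
        te_annotations = deduplicate_annotations(te_annotations, min_remainder=min_remainder, trim=trim)
    features = FeatureSet.from_annotations(te_annotations, gene_models, scaffolds=scaffolds)
    counts = count_fragments(alignments, features)
    fpkm = compute_fpkm(counts, features)
    scaling = scaling_factors(fpkm, mode=mode, floor_at_one=floor_at_one)
    assembled_bp = features.assembled_bp_by_superfamily()
    non_te_bp = assembly_size - sum(assembled_bp.values())
    summaries, genome = corrected_content(assembled_bp, non_te_bp, scaling, mode=mode)
    fraction = te_read_fraction(counts, features.te_ids())
    cov = coverage_table(fpkm)
    return PipelineResult(features, counts, fpkm, scaling, summaries, genome, fraction, cov)
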