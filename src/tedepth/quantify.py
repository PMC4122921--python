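"""Coverage-based TE quantification.

The estimator compares the sequencing depth of repeat features against the
depth of single-copy housekeeping (CEGMA-like) genes.  Fragments are counted
per feature (a repeat ID consolidates every genomic copy of a consensus, on any
scaffold; a gene's counting span runs first-exon start to last-exon end,
introns included), converted to FPKM (fragments per kilobase of feature per
million aligned fragments), and each superfamily receives a scaling factor

    S_t = superfamily TE FPKM / median FPKM of the housekeeping genes,

which multiplies the assembled TE base pairs into a corrected content estimate.
Collapsed repeats show S_t > 1; hemizygous repeats in a diploid mapped against
a one-haplotype assembly show S_t around 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import GeneModel, TEAnnotation
from .simulate import Alignments

logger = logging.getLogger(__name__)

TE_KIND = "te"
GENE_KIND = "gene"


class FeatureSet:
    """Counting features: TE repeat IDs (possibly many intervals across
    scaffolds) and genes (one counting span each)."""

    def __init__(self) -> None:
        self.intervals: dict[str, list[tuple[str, int, int]]] = {}
        self.kind: dict[str, str] = {}
        self.superfamily: dict[str, str] = {}
        self.known_scaffolds: set[str] = set()
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None
        self._overlapping = False

    @classmethod
    def from_annotations(
        cls,
        te_annotations: Iterable[TEAnnotation] = (),
        gene_models: Iterable[GeneModel] = (),
        scaffolds: Iterable[str] = (),
    ) -> "FeatureSet":
        fs = cls()
        for a in te_annotations:
            fs.add_te_interval(a.repeat_id, a.scaffold, a.start, a.end, a.superfamily)
        for g in gene_models:
            s, e = g.span
            fs.add_gene(g.gene_id, g.scaffold, s, e)
        fs.known_scaffolds.update(scaffolds)
        return fs

    def add_te_interval(self, repeat_id: str, scaffold: str, start: int, end: int,
                        superfamily: str = "Unknown") -> None:
        if start >= end:
            raise ValueError(f"invalid interval [{start}, {end}) for {repeat_id}")
        self.intervals.setdefault(repeat_id, []).append((scaffold, start, end))
        self.kind[repeat_id] = TE_KIND
        self.superfamily[repeat_id] = superfamily
        self._index = None

    def add_gene(self, gene_id: str, scaffold: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"invalid span [{start}, {end}) for {gene_id}")
        self.intervals.setdefault(gene_id, []).append((scaffold, start, end))
        self.kind[gene_id] = GENE_KIND
        self._index = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intervals)

    def te_ids(self) -> list[str]:
        return [f for f, k in self.kind.items() if k == TE_KIND]

    def gene_ids(self) -> list[str]:
        return [f for f, k in self.kind.items() if k == GENE_KIND]

    def length(self, feature_id: str) -> int:
        return sum(e - s for _, s, e in self.intervals[feature_id])

    def assembled_bp_by_superfamily(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.te_ids():
            sf = self.superfamily[f]
            out[sf] = out.get(sf, 0) + self.length(f)
        return out

    # -- interval index ----------------------------------------------------
    def _build_index(self) -> None:
        ids = {f: i for i, f in enumerate(self.intervals)}
        per_scaffold: dict[str, list[tuple[int, int, int]]] = {}
        for f, ivs in self.intervals.items():
            for scf, s, e in ivs:
                per_scaffold.setdefault(scf, []).append((s, e, ids[f]))
        index = {}
        overlapping = False
        for scf, ivs in per_scaffold.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            fids = np.array([i for _, _, i in ivs], dtype=np.int64)
            if np.any(ends[:-1] > starts[1:]):
                overlapping = True
            index[scf] = (starts, ends, fids)
        self._index = index
        self._overlapping = overlapping

    def index(self):
        if self._index is None:
            self._build_index()
        return self._index, self._overlapping


@dataclass
class CountTable:
    """Per-feature fragment counts with conservation totals.

    assigned + ambiguous + no_feature + unaligned == total_fragments always.
    """

    counts: dict[str, int]
    assigned: int
    ambiguous: int
    no_feature: int
    unaligned: int
    total_fragments: int

    def __post_init__(self) -> None:
        if self.assigned + self.ambiguous + self.no_feature + self.unaligned != self.total_fragments:
            raise ValueError("fragment conservation violated")
        if min((self.assigned, self.ambiguous, self.no_feature, self.unaligned), default=0) < 0:
            raise ValueError("negative totals")

    @property
    def total_aligned(self) -> int:
        return self.assigned + self.ambiguous + self.no_feature


@dataclass
class FPKMTable:
    """Per-feature FPKM values; carries the counts and lengths it was built
    from so pooled (length-weighted) superfamily FPKMs can be recomputed."""

    table: pd.DataFrame  # index feature_id; columns kind, superfamily, length_bp, count, fpkm
    total_aligned: int

    def fpkm(self, feature_id: str) -> float:
        return float(self.table.loc[feature_id, "fpkm"])

    def cegma_median(self) -> float:
        genes = self.table[self.table["kind"] == GENE_KIND]
        if genes.empty or not (genes["fpkm"] > 0).any():
            raise ValueError("need at least one housekeeping gene with FPKM > 0")
        return float(genes["fpkm"].median())


@dataclass
class SuperfamilySummary:
    superfamily: str
    assembled_bp: int
    assembled_fraction: float
    s_t: float
    corrected_bp: float
    corrected_fraction: float
    mode: str = "length_weighted"
    floor_applied: bool = False
    s_t_prefloor: float = float("nan")


@dataclass
class GenomeSummary:
    assembly_bp: int
    assembled_te_bp: int
    assembled_te_fraction: float
    corrected_genome_bp: float
    corrected_te_bp: float
    corrected_te_fraction: float


def _as_arrays(alignments) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, int]:
    if not isinstance(alignments, Alignments):
        alignments = Alignments.from_records(list(alignments))
    return (
        alignments.scaffold_names,
        alignments.scaffold_idx,
        alignments.start,
        alignments.end,
        len(alignments),
    )


def count_fragments(alignments, features: FeatureSet) -> CountTable:
    """Count aligned fragments per feature.

    A fragment overlapping (>= 1 bp) intervals of exactly one feature is
    assigned to it (several intervals of one repeat ID count once); overlapping
    two or more distinct features makes it ambiguous and it is discarded from
    feature counts; overlapping none is no_feature.  Fragments on scaffolds
    unknown to the feature set are no_feature (with a warning).
    """
    names, sidx, astart, aend, n = _as_arrays(alignments)
    index, overlapping = features.index()
    fid_names = list(features.intervals)

    counts = np.zeros(len(fid_names), dtype=np.int64)
    assigned = ambiguous = no_feature = 0
    unaligned = int((sidx < 0).sum())

    warned: set[str] = set()
    for scf_i, name in enumerate(names):
        mask = sidx == scf_i
        m = int(mask.sum())
        if m == 0:
            continue
        if name not in index:
            if name not in warned and name not in features.known_scaffolds:
                logger.warning("scaffold %s unknown to the feature set; fragments counted as no_feature", name)
                warned.add(name)
            no_feature += m
            continue
        starts, ends, fids = index[name]
        a = astart[mask]
        b = aend[mask]
        if not overlapping:
            lo = np.searchsorted(ends, a, side="right")
            hi = np.searchsorted(starts, b, side="left")
            n_olap = hi - lo
            no_feature += int((n_olap <= 0).sum())
            one = n_olap == 1
            hits = fids[lo[one]]
            counts += np.bincount(hits, minlength=len(fid_names))
            assigned += int(one.sum())
            multi = np.flatnonzero(n_olap >= 2)
            for k in multi:
                distinct = np.unique(fids[lo[k]:hi[k]])
                if len(distinct) == 1:
                    counts[distinct[0]] += 1
                    assigned += 1
                else:
                    ambiguous += 1
        else:
            # rare general case: overlapping features within one scaffold
            from intervaltree import IntervalTree

            tree = IntervalTree()
            for s, e, f in zip(starts, ends, fids):
                tree.addi(int(s), int(e), int(f))
            for s, e in zip(a, b):
                hits = {iv.data for iv in tree.overlap(int(s), int(e))}
                if not hits:
                    no_feature += 1
                elif len(hits) == 1:
                    counts[hits.pop()] += 1
                    assigned += 1
                else:
                    ambiguous += 1
    return CountTable(
        counts=dict(zip(fid_names, (int(c) for c in counts))),
        assigned=assigned,
        ambiguous=ambiguous,
        no_feature=no_feature,
        unaligned=unaligned,
        total_fragments=n,
    )


def compute_fpkm(counts: CountTable, features: FeatureSet, total_aligned: int | None = None) -> FPKMTable:
    """FPKM(f) = count(f) / (length_bp(f)/1000) / (total_aligned/1e6)."""
    if total_aligned is None:
        total_aligned = counts.total_aligned
    if total_aligned <= 0:
        raise ValueError("no aligned fragments")
    rows = []
    for f in features.feature_ids:
        length = features.length(f)
        if length <= 0:
            raise ValueError(f"feature {f} has non-positive length")
        c = counts.counts.get(f, 0)
        fpkm = c / (length / 1000.0) / (total_aligned / 1e6)
        rows.append((f, features.kind[f], features.superfamily.get(f, ""), length, c, fpkm))
    table = pd.DataFrame(
        rows, columns=["feature_id", "kind", "superfamily", "length_bp", "count", "fpkm"]
    ).set_index("feature_id")
    return FPKMTable(table, total_aligned)


def scaling_factors(
    fpkm: FPKMTable,
    mode: str = "length_weighted",
    floor_at_one: bool = True,
) -> pd.DataFrame:
    """Per-superfamily scaling factor S_t.

    Denominator: median FPKM of the housekeeping genes.  Numerator —
    ``length_weighted`` (default): pooled superfamily FPKM,
    (sum of counts / sum of length in kb) / (aligned fragments / 1e6), the
    copy-number-consistent estimator; ``literal_sum``: the plain sum of the
    per-repeat-ID FPKMs.  With ``floor_at_one`` (default) S_t is floored at 1:
    assembled copies are a lower bound on true content.
    """
    if mode not in ("length_weighted", "literal_sum"):
        raise ValueError(f"unknown mode {mode!r}")
    denom = fpkm.cegma_median()
    te = fpkm.table[fpkm.table["kind"] == TE_KIND]
    rows = []
    for sf, grp in te.groupby("superfamily", sort=True):
        total_len = int(grp["length_bp"].sum())
        if total_len == 0:  # zero assembled length: S_t undefined, reported missing
            rows.append((sf, math.nan, math.nan, False))
            continue
        if mode == "literal_sum":
            numerator = float(grp["fpkm"].sum())
        else:
            numerator = (grp["count"].sum() / (total_len / 1000.0)) / (fpkm.total_aligned / 1e6)
        pre = numerator / denom
        floored = bool(floor_at_one and pre < 1.0)
        rows.append((sf, max(pre, 1.0) if floor_at_one else pre, pre, floored))
    return pd.DataFrame(rows, columns=["superfamily", "s_t", "s_t_prefloor", "floor_applied"]).set_index(
        "superfamily"
    )


def corrected_content(
    assembled_bp: Mapping[str, int],
    non_te_bp: int,
    s_t: Mapping[str, float] | pd.DataFrame,
    mode: str = "length_weighted",
    floor_info: Mapping[str, bool] | None = None,
) -> tuple[list[SuperfamilySummary], GenomeSummary]:
    """Scale assembled TE bp per superfamily into corrected content.

    corrected_bp(s) = assembled_bp(s) * S_t(s); the corrected genome size is
    the non-TE assembled bp plus the summed corrected TE bp, and fractions are
    taken against it.
    """
    if non_te_bp < 0 or any(v < 0 for v in assembled_bp.values()):
        raise ValueError("negative input sizes")
    if isinstance(s_t, pd.DataFrame):
        floor_info = {sf: bool(row["floor_applied"]) for sf, row in s_t.iterrows()}
        prefloor = {sf: float(row["s_t_prefloor"]) for sf, row in s_t.iterrows()}
        s_t = {sf: float(row["s_t"]) for sf, row in s_t.iterrows()}
    else:
        prefloor = dict(s_t)
    missing = [sf for sf, bp in assembled_bp.items() if bp > 0 and sf not in s_t]
    if missing:
        raise ValueError(f"no scaling factor for superfamilies: {missing}")
    assembly_size = non_te_bp + sum(assembled_bp.values())
    corrected = {sf: assembled_bp[sf] * s_t.get(sf, math.nan) for sf in assembled_bp}
    corrected_genome = non_te_bp + sum(corrected.values())
    summaries = [
        SuperfamilySummary(
            superfamily=sf,
            assembled_bp=int(assembled_bp[sf]),
            assembled_fraction=assembled_bp[sf] / assembly_size,
            s_t=float(s_t.get(sf, math.nan)),
            corrected_bp=float(corrected[sf]),
            corrected_fraction=corrected[sf] / corrected_genome,
            mode=mode,
            floor_applied=bool((floor_info or {}).get(sf, False)),
            s_t_prefloor=float(prefloor.get(sf, math.nan)),
        )
        for sf in sorted(assembled_bp)
    ]
    genome = GenomeSummary(
        assembly_bp=assembly_size,
        assembled_te_bp=int(sum(assembled_bp.values())),
        assembled_te_fraction=sum(assembled_bp.values()) / assembly_size,
        corrected_genome_bp=float(corrected_genome),
        corrected_te_bp=float(sum(corrected.values())),
        corrected_te_fraction=sum(corrected.values()) / corrected_genome,
    )
    return summaries, genome


def te_read_fraction(counts: CountTable, te_ids: Sequence[str]) -> float:
    """Fraction of aligned fragments assigned to TE features.

    Ambiguous and no-feature fragments stay in the denominator (they are
    aligned reads); unaligned fragments do not.
    """
    aligned = counts.total_aligned
    if aligned == 0:
        raise ValueError("no aligned fragments")
    return sum(counts.counts.get(f, 0) for f in te_ids) / aligned


def coverage_table(fpkm: FPKMTable, cegma_median: float | None = None) -> pd.DataFrame:
    """Per-feature relative coverage, log2(FPKM / housekeeping median), for QC.

    Zero-count features are flagged rather than log-transformed.
    """
    if cegma_median is None:
        cegma_median = fpkm.cegma_median()
    if cegma_median <= 0:
        raise ValueError("cegma median must be > 0")
    df = fpkm.table.copy()
    zero = df["count"] == 0
    with np.errstate(divide="ignore"):
        df["log2_ratio"] = np.where(zero, np.nan, np.log2(df["fpkm"] / cegma_median))
    df["zero_count"] = zero
    return df[["kind", "superfamily", "length_bp", "count", "fpkm", "log2_ratio", "zero_count"]]
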