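"""Synthetic genomes with transposable-element insertions of known copy number.

The generator produces (i) a "true" genome in which every TE copy is present at
its real copy number, (ii) an emulated draft assembly in which near-identical
copies of a family have been collapsed onto a single representative locus, and
(iii) a set of best-hit fragment placements with approximately even coverage.
Ground truth (copy numbers, per-superfamily content, the collapse map) is
recorded so that every downstream estimator can be checked by parameter
recovery.

The collapse model operates at the annotation level: copies of a family are
grouped by single-linkage on pairwise identity at a threshold (default 0.97),
one representative per group is retained, and the loci of the other members are
deleted, splitting the sequence into separate scaffolds at each deletion
breakpoint — the depth-of-coverage signature of collapsed repeats without
running an assembler.

For fragment generation the genome is treated as circular, which makes the
even-coverage assumption exact under deterministic tiling (no edge ramp).
Fragments that wrap the origin are clipped at the scaffold end in the emitted
record, or unaligned when the assembly has more than one scaffold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import AlignmentRecord, GeneModel, TEAnnotation

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[_b] = _i

GENOME_SCAFFOLD = "chr1"

#: default classification paths by superfamily label (general -> specific)
_DEFAULT_PATHS = {
    "Gypsy": ("ClassI", "LTR", "Gypsy"),
    "Copia": ("ClassI", "LTR", "Copia"),
    "LINE": ("ClassI", "LINE", "LINE"),
    "Tc1-Mariner": ("ClassII", "TIR", "Tc1-Mariner"),
    "hAT": ("ClassII", "TIR", "hAT"),
}

_STREAMS = ("consensus", "placement", "background", "mutation", "hemizygous", "fragments")


def seq_to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def str_to_seq(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8).copy()


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named RNG streams derived from one master seed (stream-splitting scheme)."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


@dataclass(frozen=True)
class FamilySpec:
    """One TE family: a consensus plus ``copy_number`` diverged genomic copies.

    ``divergence`` is the expected substitutions per site per copy relative to
    the consensus (a proxy for copy age), in [0, 0.5].  The default consensus
    length is the median length of a complete fungal LTR element (6,583 bp).
    """

    family_id: str
    superfamily: str
    copy_number: int
    divergence: float = 0.0
    consensus_length: int = 6583
    classification_path: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.consensus_length < 80:
            raise ValueError("consensus_length must be >= 80 bp (family-rule floor)")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must lie in [0, 0.5]")

    @property
    def path(self) -> tuple[str, ...]:
        if self.classification_path is not None:
            return self.classification_path
        return _DEFAULT_PATHS.get(self.superfamily, ("Unknown", self.superfamily))


@dataclass(frozen=True)
class SimulationConfig:
    background_length: int
    families: tuple[FamilySpec, ...] = ()
    coverage: float = 30.0
    fragment_length: int = 100
    collapse_identity_threshold: float = 0.97
    heterozygosity_mode: str = "off"  # "off" | "hemizygous_te"
    hemizygous_fraction: float = 1.0
    tiling_mode: str = "exact"  # "exact" | "sampled"
    seed: int = 0
    n_genes: int = 50
    gene_span_range: tuple[int, int] = (1500, 3000)
    min_gap: int = 200

    def __post_init__(self) -> None:
        if self.background_length <= 0:
            raise ValueError("background_length must be > 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be >= 1")
        if not 0.0 <= self.collapse_identity_threshold <= 1.0:
            raise ValueError("collapse_identity_threshold must lie in [0, 1]")
        if self.heterozygosity_mode not in ("off", "hemizygous_te"):
            raise ValueError(f"unknown heterozygosity_mode {self.heterozygosity_mode!r}")
        if self.tiling_mode not in ("exact", "sampled"):
            raise ValueError(f"unknown tiling_mode {self.tiling_mode!r}")
        if not 0.0 <= self.hemizygous_fraction <= 1.0:
            raise ValueError("hemizygous_fraction must lie in [0, 1]")
        object.__setattr__(self, "families", tuple(self.families))


@dataclass
class TECopy:
    """One genomic instance of a family, with its substitution record."""

    copy_id: str
    family_id: str
    superfamily: str
    start: int
    end: int
    hemizygous: bool = False
    mut_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mut_bases: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint8))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def pct_identity(self) -> float:
        return 100.0 * (1.0 - len(self.mut_positions) / self.length)


@dataclass
class SyntheticTruth:
    """Ground truth for parameter recovery."""

    copy_number: dict[str, int]
    superfamily_bp: dict[str, int]
    superfamily_fraction: dict[str, float]
    te_bp: int
    genome_length: int
    te_fraction: float
    collapse_map: dict[str, str] | None = None  # copy_id -> representative copy_id

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "copy_number": self.copy_number,
                    "superfamily_bp": self.superfamily_bp,
                    "superfamily_fraction": self.superfamily_fraction,
                    "te_bp": self.te_bp,
                    "genome_length": self.genome_length,
                    "te_fraction": self.te_fraction,
                    "collapse_map": self.collapse_map,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    sequence: np.ndarray  # uint8 ASCII, single scaffold GENOME_SCAFFOLD
    consensus: dict[str, np.ndarray]
    copies: list[TECopy]
    te_annotations: list[TEAnnotation]
    gene_models: list[GeneModel]
    truth: SyntheticTruth

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def scaffolds(self) -> dict[str, np.ndarray]:
        return {GENOME_SCAFFOLD: self.sequence}


@dataclass
class Assembly:
    """Emulated draft assembly: the genome minus deleted (collapsed) copy loci,
    split into scaffolds at each deletion breakpoint."""

    scaffold_names: list[str]
    scaffolds: dict[str, np.ndarray]
    te_annotations: list[TEAnnotation]
    gene_models: list[GeneModel]
    collapse_map: dict[str, str]  # copy_id -> representative copy_id
    copy_loci: dict[str, tuple[str, int, int]]  # retained copy_id -> assembly locus
    # genome-partition arrays used to map genome coordinates onto the assembly
    piece_bounds: np.ndarray  # genome start of each piece (retained / deleted alternating)
    piece_scaffold: np.ndarray  # scaffold index each piece maps to
    piece_shift: np.ndarray  # assembly_start = genome_pos - shift[piece]
    genome_length: int

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    @property
    def te_bp(self) -> int:
        return sum(a.length for a in self.te_annotations)


@dataclass
class Alignments:
    """Column-oriented container of fragment placements (one row per fragment)."""

    scaffold_names: list[str]
    scaffold_idx: np.ndarray  # int32, -1 when unaligned
    start: np.ndarray
    end: np.ndarray
    is_aligned: np.ndarray  # bool
    fragment_length: int

    def __len__(self) -> int:
        return len(self.start)

    @property
    def n_aligned(self) -> int:
        return int(self.is_aligned.sum())

    def records(self) -> Iterable[AlignmentRecord]:
        for i in range(len(self)):
            if self.is_aligned[i]:
                yield AlignmentRecord(
                    f"frag{i:08d}",
                    self.scaffold_names[self.scaffold_idx[i]],
                    int(self.start[i]),
                    int(self.end[i]),
                    True,
                )
            else:
                yield AlignmentRecord(f"frag{i:08d}", "*", 0, 0, False)

    @classmethod
    def from_records(cls, records: Sequence[AlignmentRecord], fragment_length: int = 0) -> "Alignments":
        names: list[str] = []
        index: dict[str, int] = {}
        sidx = np.empty(len(records), dtype=np.int32)
        start = np.zeros(len(records), dtype=np.int64)
        end = np.zeros(len(records), dtype=np.int64)
        aligned = np.zeros(len(records), dtype=bool)
        for i, rec in enumerate(records):
            if rec.is_aligned:
                if rec.scaffold not in index:
                    index[rec.scaffold] = len(names)
                    names.append(rec.scaffold)
                sidx[i] = index[rec.scaffold]
                start[i], end[i], aligned[i] = rec.start, rec.end, True
            else:
                sidx[i] = -1
        if fragment_length == 0 and aligned.any():
            fragment_length = int((end[aligned] - start[aligned]).max())
        return cls(names, sidx, start, end, aligned, fragment_length)


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator):
    """Substitute each site independently with probability ``divergence``.

    Returns the mutated copy plus the substitution record (positions, new bases);
    substituted bases always differ from the original.
    """
    mask = rng.random(len(seq)) < divergence
    pos = np.flatnonzero(mask)
    out = seq.copy()
    if len(pos):
        old = _BASE_INDEX[seq[pos]].astype(np.int64)
        new = (old + rng.integers(1, 4, size=len(pos))) % 4
        out[pos] = BASES[new]
    return out, pos.astype(np.int64), out[pos]


def apply_divergence(sequence, divergence: float, seed: int):
    """Independently substitute each site with probability ``divergence``.

    Accepts a string or uint8 array; returns the same type. Length is preserved
    and substituted sites always change base.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must lie in [0, 0.5]")
    as_str = isinstance(sequence, str)
    seq = str_to_seq(sequence) if as_str else np.asarray(sequence, dtype=np.uint8)
    out, _, _ = _mutate(seq, divergence, np.random.default_rng(seed))
    return seq_to_str(out) if as_str else out


def _place_items(lengths: Sequence[int], space: int, margin: int, gap: int, rng: np.random.Generator) -> list[int]:
    """Uniform non-overlapping placement of items with given lengths in
    [margin, space - margin), keeping >= ``gap`` between consecutive items.

    Uses the spacings construction (sorted uniform slack), so placement never
    needs rejection sampling: infeasible requests fail immediately.
    """
    k = len(lengths)
    if k == 0:
        return []
    slack = space - 2 * margin - sum(lengths) - (k - 1) * gap
    if slack < 0:
        raise ValueError(
            f"genome overfull: need {sum(lengths) + (k - 1) * gap + 2 * margin} bp "
            f"of background, have {space}"
        )
    cuts = np.sort(rng.random(k)) * slack
    starts = []
    acc = margin
    for i, length in enumerate(lengths):
        starts.append(int(acc + cuts[i]))
        acc += length + gap
    return starts


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the true genome: background + TE copies + gene models + truth."""
    rngs = _streams(config.seed)
    consensus = {
        f.family_id: random_sequence(f.consensus_length, rngs["consensus"]) for f in config.families
    }

    # jointly place genes (background intervals) and TE insertion points
    # (zero-length in background space) so nothing overlaps
    gene_spans = [
        int(rngs["placement"].integers(config.gene_span_range[0], config.gene_span_range[1] + 1))
        for _ in range(config.n_genes)
    ]
    copy_specs = [(f, i) for f in config.families for i in range(f.copy_number)]
    items = [("gene", g, gene_spans[g]) for g in range(config.n_genes)] + [
        ("te", c, 0) for c in range(len(copy_specs))
    ]
    order = rngs["placement"].permutation(len(items))
    items = [items[i] for i in order]
    starts = _place_items([it[2] for it in items], config.background_length, config.min_gap, config.min_gap, rngs["placement"])

    background = random_sequence(config.background_length, rngs["background"])

    # TE insertion points sorted along the background; splice copies in
    te_items = sorted(
        ((starts[i], items[i][1]) for i in range(len(items)) if items[i][0] == "te")
    )
    copies: list[TECopy] = []
    chunks: list[np.ndarray] = []
    prev = 0
    offset = 0
    insertion_offset_at: list[tuple[int, int]] = []  # (background pos, cumulative inserted bp)
    for bg_pos, ci in te_items:
        fam, copy_index = copy_specs[ci]
        mutated, pos, new = _mutate(consensus[fam.family_id], fam.divergence, rngs["mutation"])
        chunks.append(background[prev:bg_pos])
        chunks.append(mutated)
        g_start = bg_pos + offset
        copies.append(
            TECopy(
                copy_id=f"{fam.family_id}_c{copy_index:04d}",
                family_id=fam.family_id,
                superfamily=fam.superfamily,
                start=g_start,
                end=g_start + fam.consensus_length,
                mut_positions=pos,
                mut_bases=new,
            )
        )
        offset += fam.consensus_length
        insertion_offset_at.append((bg_pos, offset))
        prev = bg_pos
    chunks.append(background[prev:])
    sequence = np.concatenate(chunks) if chunks else background

    # hemizygosity flags
    if config.heterozygosity_mode == "hemizygous_te" and copies:
        n_hemi = int(round(config.hemizygous_fraction * len(copies)))
        for i in rngs["hemizygous"].choice(len(copies), size=n_hemi, replace=False):
            copies[i].hemizygous = True

    # map gene background coordinates -> genome coordinates
    ins_pos = np.array([p for p, _ in insertion_offset_at], dtype=np.int64)
    ins_off = np.array([o for _, o in insertion_offset_at], dtype=np.int64)

    def bg_to_genome(x: int) -> int:
        j = int(np.searchsorted(ins_pos, x, side="right"))
        return x + (int(ins_off[j - 1]) if j > 0 else 0)

    genes: list[GeneModel] = []
    for i, (kind, gi, length) in enumerate(items):
        if kind != "gene":
            continue
        s = bg_to_genome(starts[i])
        e = s + length
        # three exons with two introns at fixed relative coordinates
        rel = [(0.0, 0.30), (0.45, 0.70), (0.80, 1.0)]
        exons = tuple((s + int(a * length), s + int(b * length)) for a, b in rel)
        genes.append(GeneModel(f"ceg{gi:04d}", GENOME_SCAFFOLD, "+", exons))
    genes.sort(key=lambda g: g.span[0])

    annotations = [
        TEAnnotation(
            GENOME_SCAFFOLD,
            c.start,
            c.end,
            "+",
            c.family_id,
            c.superfamily,
            next(f.path for f in config.families if f.family_id == c.family_id),
            c.pct_identity,
        )
        for c in sorted(copies, key=lambda c: c.start)
    ]

    sf_bp: dict[str, int] = {}
    for c in copies:
        sf_bp[c.superfamily] = sf_bp.get(c.superfamily, 0) + c.length
    te_bp = sum(sf_bp.values())
    glen = len(sequence)
    truth = SyntheticTruth(
        copy_number={f.family_id: f.copy_number for f in config.families},
        superfamily_bp=sf_bp,
        superfamily_fraction={k: v / glen for k, v in sf_bp.items()},
        te_bp=te_bp,
        genome_length=glen,
        te_fraction=te_bp / glen,
    )
    copies.sort(key=lambda c: c.start)
    return SimulatedGenome(config, sequence, consensus, copies, annotations, genes, truth)


def copy_pair_identity(a: TECopy, b: TECopy, length: int) -> float:
    """Identity between two copies of one family, from their substitution
    records (exact; no realignment)."""
    both, ia, ib = np.intersect1d(a.mut_positions, b.mut_positions, return_indices=True)
    diff = len(a.mut_positions) + len(b.mut_positions) - 2 * len(both)
    diff += int((a.mut_bases[ia] != b.mut_bases[ib]).sum())
    return 1.0 - diff / length


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def collapse_assembly(sim: SimulatedGenome, threshold: float | None = None) -> Assembly:
    """Group each family's copies by single-linkage at the identity threshold,
    retain one representative per group, delete the other loci, and split the
    sequence into scaffolds at each deletion breakpoint."""
    if threshold is None:
        threshold = sim.config.collapse_identity_threshold
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")

    by_family: dict[str, list[TECopy]] = {}
    for c in sim.copies:
        by_family.setdefault(c.family_id, []).append(c)

    collapse_map: dict[str, str] = {}
    deleted: list[TECopy] = []
    retained: list[TECopy] = []
    for fam_copies in by_family.values():
        fam_copies = sorted(fam_copies, key=lambda c: c.start)
        n = len(fam_copies)
        uf = _UnionFind(n)
        length = fam_copies[0].length
        for i in range(n):
            for j in range(i + 1, n):
                if copy_pair_identity(fam_copies[i], fam_copies[j], length) >= threshold:
                    uf.union(i, j)
        groups: dict[int, list[TECopy]] = {}
        for i, c in enumerate(fam_copies):
            groups.setdefault(uf.find(i), []).append(c)
        for members in groups.values():
            rep = min(members, key=lambda c: c.start)
            for m in members:
                collapse_map[m.copy_id] = rep.copy_id
                if m is rep:
                    retained.append(m)
                else:
                    deleted.append(m)

    deleted.sort(key=lambda c: c.start)
    retained.sort(key=lambda c: c.start)
    glen = sim.length

    # genome partition: alternating retained segments and deleted loci
    bounds = [0]
    piece_is_deleted = [False]
    for d in deleted:
        bounds.extend([d.start, d.end])
        piece_is_deleted.extend([True, False])
    piece_bounds = np.array(bounds, dtype=np.int64)
    piece_end = np.append(piece_bounds[1:], glen)

    # retained segments become scaffolds (in genome order)
    scaffold_names: list[str] = []
    scaffolds: dict[str, np.ndarray] = {}
    piece_scaffold = np.full(len(piece_bounds), -1, dtype=np.int64)
    piece_shift = np.zeros(len(piece_bounds), dtype=np.int64)
    seg_of_pos: list[tuple[int, int, int]] = []  # (g_start, g_end, scaffold idx)
    for p in range(len(piece_bounds)):
        if piece_is_deleted[p]:
            continue
        s, e = int(piece_bounds[p]), int(piece_end[p])
        if s == e:  # empty flank (deletion at sequence edge)
            continue
        idx = len(scaffold_names)
        name = f"scf{idx + 1:05d}"
        scaffold_names.append(name)
        scaffolds[name] = sim.sequence[s:e]
        piece_scaffold[p] = idx
        piece_shift[p] = s
        seg_of_pos.append((s, e, idx))

    seg_starts = np.array([s for s, _, _ in seg_of_pos], dtype=np.int64)

    def to_assembly(g_start: int, g_end: int) -> tuple[str, int, int]:
        j = int(np.searchsorted(seg_starts, g_start, side="right")) - 1
        s, e, idx = seg_of_pos[j]
        assert g_end <= e, "interval crosses a deletion breakpoint"
        return scaffold_names[idx], g_start - s, g_end - s

    copy_loci = {c.copy_id: to_assembly(c.start, c.end) for c in retained}

    # deleted pieces map onto their representative's assembly locus
    for p, d in zip(range(1, len(piece_bounds), 2), deleted):
        rep_scf, rep_start, _ = copy_loci[collapse_map[d.copy_id]]
        piece_scaffold[p] = scaffold_names.index(rep_scf)
        piece_shift[p] = d.start - rep_start

    fam_meta = {f.family_id: f for f in sim.config.families}
    te_annotations = []
    for c in retained:
        scf, s, e = copy_loci[c.copy_id]
        te_annotations.append(
            TEAnnotation(scf, s, e, "+", c.family_id, c.superfamily,
                         fam_meta[c.family_id].path, c.pct_identity)
        )

    gene_models = []
    for g in sim.gene_models:
        scf, s0, _ = to_assembly(*g.span)
        shift = g.span[0] - s0
        gene_models.append(
            GeneModel(g.gene_id, scf, g.strand, tuple((a - shift, b - shift) for a, b in g.exons))
        )

    return Assembly(
        scaffold_names=scaffold_names,
        scaffolds=scaffolds,
        te_annotations=te_annotations,
        gene_models=gene_models,
        collapse_map=collapse_map,
        copy_loci=copy_loci,
        piece_bounds=piece_bounds,
        piece_scaffold=piece_scaffold,
        piece_shift=piece_shift,
        genome_length=glen,
    )


def simulate_alignments(sim: SimulatedGenome, assembly: Assembly,
                        config: SimulationConfig | None = None) -> Alignments:
    """Draw fragments from the (circular) genome and place each at the assembly
    coordinates of its source locus; fragments from collapsed copies land on the
    group representative, fragments spanning deletion breakpoints are unaligned.

    In ``hemizygous_te`` mode, fragments whose midpoint falls in a hemizygous TE
    copy are emitted at half rate (the removed half are reported unaligned).
    """
    if config is None:
        config = sim.config
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    L = config.fragment_length
    G = sim.length
    n = int(round(config.coverage * G / L))
    rng = _streams(config.seed)["fragments"]
    if config.tiling_mode == "exact":
        starts = (np.arange(n, dtype=np.int64) * G) // n
    else:
        starts = rng.integers(0, G, size=n, dtype=np.int64)

    dropped = np.zeros(n, dtype=bool)
    hemi = [c for c in sim.copies if c.hemizygous]
    if hemi:
        hstarts = np.array([c.start for c in hemi], dtype=np.int64)
        hends = np.array([c.end for c in hemi], dtype=np.int64)
        mids = (starts + L // 2) % G
        j = np.searchsorted(hstarts, mids, side="right") - 1
        subject = (j >= 0) & (mids < hends[np.clip(j, 0, None)])
        if config.tiling_mode == "exact":
            dropped = subject & (np.arange(n) % 2 == 1)
        else:
            dropped = subject & (rng.random(n) < 0.5)

    bounds = assembly.piece_bounds
    ends_g = starts + L
    i_a = np.searchsorted(bounds, starts, side="right") - 1
    i_e = np.searchsorted(bounds, ends_g - 1, side="right") - 1
    wrap = ends_g > G
    single_scaffold = len(assembly.scaffold_names) == 1 and len(bounds) == 1
    same_piece = i_a == i_e
    aligned = ~dropped & same_piece & (~wrap | single_scaffold)
    # a deleted piece whose representative exists is mappable; scaffold -1 never occurs
    scaf = assembly.piece_scaffold[i_a]
    aligned &= scaf >= 0

    out_start = starts - assembly.piece_shift[i_a]
    out_end = out_start + L
    if single_scaffold:
        out_end = np.minimum(out_end, len(next(iter(assembly.scaffolds.values()))))
    scaf = np.where(aligned, scaf, -1).astype(np.int32)
    out_start = np.where(aligned, out_start, 0)
    out_end = np.where(aligned, out_end, 0)
    return Alignments(assembly.scaffold_names, scaf, out_start, out_end, aligned, L)


def depth_profile(alignments: Alignments, scaffold: str, length: int,
                  circular: bool = False) -> np.ndarray:
    """Per-base aligned-fragment depth on one scaffold.

    With ``circular=True``, records clipped at the scaffold end (shorter than
    the fragment length) also contribute their wrapped tail at the origin.
    """
    idx = alignments.scaffold_names.index(scaffold)
    mask = alignments.is_aligned & (alignments.scaffold_idx == idx)
    diff = np.zeros(length + 1, dtype=np.int64)
    s = alignments.start[mask]
    e = alignments.end[mask]
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    if circular:
        tail = alignments.fragment_length - (e - s)
        w = tail > 0
        if w.any():
            np.add.at(diff, np.zeros(int(w.sum()), dtype=np.int64), 1)
            np.add.at(diff, tail[w], -1)
    return np.cumsum(diff[:-1])
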