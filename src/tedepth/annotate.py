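"""Repeat annotation handling and family clustering.

Two of the field's bookkeeping rules live here:

* overlapping repeat hits are resolved by keeping, at every base, the hit with
  the highest percent identity to its consensus (lower-identity hits are
  trimmed to their non-overlapping remainder);
* consensus elements are grouped into families under the 80-80-80 rule —
  two elements belong together when they are >= 80% identical over >= 80% of
  the shorter sequence across an alignment of >= 80 bp, on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import Align
from Bio.Seq import reverse_complement

from .model import TEAnnotation

MIN_REMAINDER = 80  # bp floor for trimmed remainders, echoing the 80-80-80 rule


@dataclass(frozen=True)
class ConsensusElement:
    element_id: str
    sequence: str
    classification_path: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"element {self.element_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TEFamily:
    family_id: str
    member_ids: list[str]
    representative_id: str
    classification_path: tuple[str, ...] = ()


class IdentityResult(NamedTuple):
    identity: float
    coverage_of_shorter: float
    aligned_length: int


def read_repeatmasker_out(path) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` file (3 header lines, whitespace-delimited).

    Percent identity is 100 minus the reported percent divergence; the 1-based
    inclusive query coordinates become 0-based half-open; a ``C`` strand is
    read as ``-``.
    """
    annotations: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            cols = line.split()
            try:
                score = int(cols[0])
                divergence = float(cols[1])
                scaffold = cols[4]
                start = int(cols[5]) - 1
                end = int(cols[6])
                strand = "-" if cols[8] == "C" else cols[8]
                repeat_id = cols[9]
                classification = tuple(p for p in cols[10].split("/") if p)
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed RepeatMasker row at line {lineno}: {exc}") from exc
            superfamily = classification[-1] if classification else "Unknown"
            annotations.append(
                TEAnnotation(
                    scaffold, start, end, strand, repeat_id, superfamily,
                    classification, 100.0 - divergence, score,
                )
            )
    return annotations


def _subtract(interval: tuple[int, int], claimed: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of ``interval`` not covered by the (sorted, disjoint) claimed set."""
    s, e = interval
    out = []
    for cs, ce in claimed:
        if ce <= s:
            continue
        if cs >= e:
            break
        if cs > s:
            out.append((s, cs))
        s = max(s, ce)
        if s >= e:
            break
    if s < e:
        out.append((s, e))
    return out


def _claim(claimed: list[tuple[int, int]], piece: tuple[int, int]) -> None:
    """Insert a piece into the sorted disjoint claimed list, merging neighbours."""
    import bisect

    s, e = piece
    i = bisect.bisect_left(claimed, (s, e))
    claimed.insert(i, (s, e))
    # merge around i
    j = max(i - 1, 0)
    while j < len(claimed) - 1:
        a, b = claimed[j]
        c, d = claimed[j + 1]
        if c <= b:
            claimed[j] = (a, max(b, d))
            del claimed[j + 1]
        else:
            j += 1


def deduplicate_annotations(
    annotations: Iterable[TEAnnotation],
    min_remainder: int = MIN_REMAINDER,
    trim: bool = True,
) -> list[TEAnnotation]:
    """Resolve overlapping hits, keeping the highest-identity match at every base.

    Hits are processed best-first (identity, then score, then length, then
    repeat_id); each claims the bases not already claimed by a better hit.  With
    ``trim=True`` a partially overlapped hit is cut back to its non-overlapping
    remainder, and contiguous remainders shorter than ``min_remainder`` are
    dropped (but still shadow the interval against worse hits, so the
    best-at-every-base guarantee holds).  With ``trim=False`` any overlapped
    loser is dropped whole.
    """
    anns = list(annotations)
    for a in anns:
        if a.start >= a.end:  # pragma: no cover - TEAnnotation already validates
            raise ValueError(f"invalid annotation {a}")
    order = sorted(
        anns,
        key=lambda a: (-a.pct_identity, -a.score, -(a.end - a.start), a.repeat_id, a.scaffold, a.start),
    )
    claimed: dict[str, list[tuple[int, int]]] = {}
    kept: list[TEAnnotation] = []
    for a in order:
        cl = claimed.setdefault(a.scaffold, [])
        pieces = _subtract((a.start, a.end), cl)
        if not pieces:
            continue
        whole = len(pieces) == 1 and pieces[0] == (a.start, a.end)
        if not trim and not whole:
            continue
        for s, e in pieces:
            _claim(cl, (s, e))
            if whole or e - s >= min_remainder:
                kept.append(
                    TEAnnotation(a.scaffold, s, e, a.strand, a.repeat_id, a.superfamily,
                                 a.classification_path, a.pct_identity, a.score)
                )
    kept.sort(key=lambda a: (a.scaffold, a.start))
    return kept


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _identity_of(alignment) -> tuple[float, int, tuple[int, int], tuple[int, int]]:
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    coords = alignment.coordinates
    span_a = (int(coords[0, 0]), int(coords[0, -1]))
    span_b = (int(coords[1, 0]), int(coords[1, -1]))
    identity = counts.identities / columns if columns else 0.0
    return identity, columns, span_a, span_b


def pairwise_identity(seq_a: str, seq_b: str) -> IdentityResult:
    """Best local alignment summary between two nucleotide sequences.

    identity = matches / aligned columns; coverage_of_shorter = aligned span on
    the shorter sequence / its length; aligned_length = alignment columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    identity, columns, span_a, span_b = _identity_of(alignment)
    if len(seq_a) <= len(seq_b):
        short_span, short_len = span_a, len(seq_a)
    else:
        short_span, short_len = span_b, len(seq_b)
    coverage = (short_span[1] - short_span[0]) / short_len
    return IdentityResult(identity, coverage, columns)


def _meets_family_rule(seq: str, rep: str, id_thr: float, cov_thr: float, min_len: int) -> bool:
    for candidate in (seq, reverse_complement(seq)):  # either strand
        res = pairwise_identity(candidate, rep)
        if res.identity >= id_thr and res.coverage_of_shorter >= cov_thr and res.aligned_length >= min_len:
            return True
    return False


def cluster_families(
    elements: Iterable[ConsensusElement],
    id_threshold: float = 0.80,
    cov_threshold: float = 0.80,
    min_len: int = 80,
) -> list[TEFamily]:
    """Greedy centroid clustering under the 80-80-80 rule.

    Elements are processed longest-first (ties broken by element_id); each joins
    the first existing family whose representative it matches on either strand,
    otherwise it founds a new family.  The founder is the longest member and is
    the representative.  Family classification is the lowest (most specific)
    rank level shared by all members.
    """
    ordered = sorted(elements, key=lambda e: (-e.length, e.element_id))
    families: list[TEFamily] = []
    reps: dict[str, ConsensusElement] = {}
    for el in ordered:
        placed = False
        for fam in families:
            if _meets_family_rule(el.sequence, reps[fam.family_id].sequence,
                                  id_threshold, cov_threshold, min_len):
                fam.member_ids.append(el.element_id)
                placed = True
                break
        if not placed:
            fam_id = f"FAM{len(families) + 1:05d}"
            families.append(TEFamily(fam_id, [el.element_id], el.element_id))
            reps[fam_id] = el
    paths = {e.element_id: e.classification_path for e in ordered}
    for fam in families:
        fam.classification_path = consolidate_classification(fam, paths)
    return families


def consolidate_classification(
    family: TEFamily, classification_paths: Mapping[str, Sequence[str]]
) -> tuple[str, ...]:
    """Longest classification prefix (general -> specific) shared by all members."""
    if not family.member_ids:
        raise ValueError("empty family")
    member_paths = [tuple(classification_paths[m]) for m in family.member_ids]
    prefix = member_paths[0]
    for p in member_paths[1:]:
        k = 0
        while k < min(len(prefix), len(p)) and prefix[k] == p[k]:
            k += 1
        prefix = prefix[:k]
    return prefix
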