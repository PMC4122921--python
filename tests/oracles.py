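"""Independent oracles used by the test suite.

These deliberately re-derive results by the dumbest correct route (per-fragment
interval scans, quadratic DP alignment, all-pairs threshold audits) so they
share no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np

from tedepth.quantify import CountTable, FeatureSet


def brute_force_counts(records, features: FeatureSet) -> CountTable:
    """Per-fragment linear scan over every feature interval."""
    counts = {f: 0 for f in features.feature_ids}
    assigned = ambiguous = no_feature = unaligned = total = 0
    for rec in records:
        total += 1
        if not rec.is_aligned:
            unaligned += 1
            continue
        hits = set()
        for fid, ivs in features.intervals.items():
            for scf, s, e in ivs:
                if scf == rec.scaffold and rec.start < e and rec.end > s:
                    hits.add(fid)
        if not hits:
            no_feature += 1
        elif len(hits) == 1:
            counts[hits.pop()] += 1
            assigned += 1
        else:
            ambiguous += 1
    return CountTable(counts, assigned, ambiguous, no_feature, unaligned, total)


def smith_waterman_score(a: str, b: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1) -> float:
    """Affine-gap local alignment score by direct DP (Gotoh)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_interior(seq: str, n_subs: int, rng: np.random.Generator, margin: int = 5) -> str:
    """Substitute exactly n interior sites (never touching the ends)."""
    pos = rng.choice(np.arange(margin, len(seq) - margin), size=n_subs, replace=False)
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in pos:
        out[p] = rot[out[p]]
    return "".join(out)


def random_binary_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random binary topology over the given leaf labels (unit branch lengths)."""
    nodes = [f"{lab}:1" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1")
    return nodes[0] + ";"
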