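"""Readers and writers for the standard flat formats the pipeline consumes and
emits: FASTA, GFF3 (TE annotations and exon-bearing gene models), BED6, SAM,
the 4-column fragment TSV dialect, and plain TSV tables.

GFF3 and RepeatMasker use 1-based inclusive coordinates; everything in memory
is 0-based half-open, and the conversion happens only here.
"""

from __future__ import annotations

import urllib.parse
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneModel, TEAnnotation
from .simulate import Alignments, seq_to_str


# -- FASTA -----------------------------------------------------------------

def write_fasta(sequences: Mapping[str, object], path) -> None:
    records = []
    for name, seq in sequences.items():
        if isinstance(seq, np.ndarray):
            seq = seq_to_str(seq)
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# -- GFF3 ------------------------------------------------------------------

def _attr(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" /:_-.")


def write_te_gff3(annotations: Iterable[TEAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in sorted(annotations, key=lambda a: (a.scaffold, a.start)):
            attrs = (
                f"ID={_attr(a.repeat_id)};superfamily={_attr(a.superfamily)};"
                f"pct_identity={a.pct_identity:.2f};"
                f"classification={_attr('/'.join(a.classification_path))}"
            )
            fh.write(
                f"{a.scaffold}\ttedepth\tdispersed_repeat\t{a.start + 1}\t{a.end}\t"
                f"{a.score}\t{a.strand}\t.\t{attrs}\n"
            )


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = urllib.parse.unquote(v.strip())
    return out


def read_te_gff3(path) -> list[TEAnnotation]:
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 row at line {lineno}")
            attrs = _parse_attrs(cols[8])
            path_ranks = tuple(p for p in attrs.get("classification", "").split("/") if p)
            score = cols[5]
            annotations.append(
                TEAnnotation(
                    scaffold=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    repeat_id=attrs.get("ID", f"repeat_{lineno}"),
                    superfamily=attrs.get("superfamily", path_ranks[-1] if path_ranks else "Unknown"),
                    classification_path=path_ranks,
                    pct_identity=float(attrs.get("pct_identity", 100.0)),
                    score=int(float(score)) if score not in (".", "") else 0,
                )
            )
    return annotations


def write_gene_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.span[0])):
            s, e = g.span
            fh.write(
                f"{g.scaffold}\ttedepth\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={_attr(g.gene_id)}\n"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.scaffold}\ttedepth\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={_attr(g.gene_id)}.exon{i};Parent={_attr(g.gene_id)}\n"
                )


def read_gene_gff3(path) -> list[GeneModel]:
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "exon":
                continue
            attrs = _parse_attrs(cols[8])
            parent = attrs.get("Parent") or attrs.get("ID", "gene")
            if parent not in exons:
                exons[parent] = []
                order.append(parent)
            exons[parent].append((cols[0], cols[6], int(cols[3]) - 1, int(cols[4])))
    genes = []
    for gid in order:
        rows = exons[gid]
        genes.append(
            GeneModel(gid, rows[0][0], rows[0][1], tuple(sorted((s, e) for _, _, s, e in rows)))
        )
    return genes


# -- BED6 ------------------------------------------------------------------

def write_bed6(annotations: Iterable[TEAnnotation], path) -> None:
    """BED6 with name=repeat_id and score = pct_identity x 10, rounded."""
    with open(path, "w") as fh:
        for a in sorted(annotations, key=lambda a: (a.scaffold, a.start)):
            fh.write(
                f"{a.scaffold}\t{a.start}\t{a.end}\t{a.repeat_id}\t"
                f"{round(a.pct_identity * 10)}\t{a.strand}\n"
            )


# -- alignments ------------------------------------------------------------

def write_alignments_tsv(alignments: Alignments, path) -> None:
    """4-column dialect: fragment_id, scaffold, start, end.

    Unaligned fragments are written with scaffold '*' and coordinates -1.
    """
    with open(path, "w") as fh:
        fh.write("fragment_id\tscaffold\tstart\tend\n")
        for rec in alignments.records():
            if rec.is_aligned:
                fh.write(f"{rec.fragment_id}\t{rec.scaffold}\t{rec.start}\t{rec.end}\n")
            else:
                fh.write(f"{rec.fragment_id}\t*\t-1\t-1\n")


def read_alignments_tsv(path) -> Alignments:
    df = pd.read_csv(path, sep="\t", dtype={"fragment_id": str, "scaffold": str})
    names = [s for s in df["scaffold"].unique() if s != "*"]
    index = {s: i for i, s in enumerate(names)}
    sidx = np.array([index.get(s, -1) for s in df["scaffold"]], dtype=np.int32)
    aligned = sidx >= 0
    start = np.where(aligned, df["start"].to_numpy(), 0).astype(np.int64)
    end = np.where(aligned, df["end"].to_numpy(), 0).astype(np.int64)
    frag_len = int((end[aligned] - start[aligned]).max()) if aligned.any() else 0
    return Alignments(names, sidx, start, end, aligned, frag_len)


def write_sam(alignments: Alignments, scaffold_lengths: Mapping[str, int], path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": int(scaffold_lengths[name])} for name in alignments.scaffold_names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, rec in enumerate(alignments.records()):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.fragment_id
            if rec.is_aligned:
                seg.flag = 0
                seg.reference_id = alignments.scaffold_idx[i]
                seg.reference_start = rec.start
                seg.mapping_quality = 60
                seg.cigarstring = f"{rec.end - rec.start}M"
            else:
                seg.flag = 4  # unmapped
                seg.reference_id = -1
                seg.reference_start = -1
            out.write(seg)


def read_sam(path) -> Alignments:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        names = list(sam.references)
        sidx, start, end, aligned = [], [], [], []
        for seg in sam.fetch(until_eof=True):
            if seg.is_unmapped:
                sidx.append(-1)
                start.append(0)
                end.append(0)
                aligned.append(False)
            else:
                sidx.append(seg.reference_id)
                start.append(seg.reference_start)
                end.append(seg.reference_end)
                aligned.append(True)
    start = np.array(start, dtype=np.int64)
    end = np.array(end, dtype=np.int64)
    aligned = np.array(aligned, dtype=bool)
    frag_len = int((end[aligned] - start[aligned]).max()) if aligned.any() else 0
    return Alignments(names, np.array(sidx, dtype=np.int32), start, end, aligned, frag_len)


# -- tables ----------------------------------------------------------------

def write_counts_tsv(counts, path) -> None:
    df = pd.DataFrame(
        sorted(counts.counts.items()), columns=["feature_id", "count"]
    )
    totals = pd.DataFrame(
        {
            "feature_id": ["__assigned__", "__ambiguous__", "__no_feature__", "__unaligned__", "__total__"],
            "count": [counts.assigned, counts.ambiguous, counts.no_feature, counts.unaligned, counts.total_fragments],
        }
    )
    pd.concat([df, totals]).to_csv(path, sep="\t", index=False)


def write_families_tsv(families, path) -> None:
    rows = []
    for fam in families:
        for m in fam.member_ids:
            rows.append(
                {
                    "family_id": fam.family_id,
                    "member_id": m,
                    "is_representative": m == fam.representative_id,
                    "classification": "/".join(fam.classification_path),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_tsv(summaries, genome_summary, path) -> None:
    rows = [
        {
            "superfamily": s.superfamily,
            "assembled_bp": s.assembled_bp,
            "assembled_fraction": s.assembled_fraction,
            "s_t": s.s_t,
            "s_t_prefloor": s.s_t_prefloor,
            "corrected_bp": s.corrected_bp,
            "corrected_fraction": s.corrected_fraction,
            "mode": s.mode,
            "floor_applied": s.floor_applied,
        }
        for s in summaries
    ]
    rows.append(
        {
            "superfamily": "__genome__",
            "assembled_bp": genome_summary.assembled_te_bp,
            "assembled_fraction": genome_summary.assembled_te_fraction,
            "s_t": float("nan"),
            "s_t_prefloor": float("nan"),
            "corrected_bp": genome_summary.corrected_te_bp,
            "corrected_fraction": genome_summary.corrected_te_fraction,
            "mode": "",
            "floor_applied": False,
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_clades_tsv(reports, path) -> None:
    rows = [
        {"node_id": r.node_id, "species": r.species, "size": r.size, "members": ",".join(r.members)}
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
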