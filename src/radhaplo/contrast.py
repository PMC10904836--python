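"""Habitat contrast: unique loci → transcriptome hit → GO tally → fold filter.

The procedure mirrors the freshwater-versus-saline comparison: loci present
in exactly one habitat group are aligned against a transcriptome; for each
locus the best hit's first annotation contributes its GO terms to that
habitat's tally; terms are then screened by a minimum locus count and a
minimum fold difference between the two habitats.

Alignment uses a k-mer-seeded, ungapped, X-drop-extended local aligner
(+1 match / −2 mismatch), searching both strands.  An adapter for external
tabular alignment results (BLAST outfmt-6-style TSV) is provided for real
data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import AnnotationTable, LocusCatalog
from .simulate import reverse_complement

TABLE3_COLUMNS = ("go_term", "go_annotation", "freshwater_count", "saltwater_count")


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped local alignment of a locus against a transcript."""

    locus_id: str
    transcript_id: str
    score: int
    identity: float
    start: int  # 0-based, half-open on the transcript
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 1):
            raise ValueError("identity must lie in [0, 1]")
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class ContrastParams:
    """Screening thresholds for habitat-unique GO terms."""

    min_count: int = 10
    min_fold: float = 10.0

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.min_fold <= 1:
            raise ValueError("min_fold must be > 1")


class TranscriptomeIndex:
    """Exact k-mer index over a transcript collection for seeded alignment."""

    def __init__(self, transcripts: Mapping[str, str], k: int = 11):
        if not transcripts:
            raise ValueError("empty transcriptome")
        self.k = k
        self.transcripts = dict(transcripts)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.transcripts.items():
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((tid, pos))

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 11) -> "TranscriptomeIndex":
        from Bio import SeqIO

        transcripts = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(transcripts, k=k)


MATCH_SCORE = 1
MISMATCH_SCORE = -2
XDROP = 10


def _extend_ungapped(query: str, subject: str, qpos: int, tpos: int, k: int):
    """X-drop ungapped extension of an exact k-mer seed on one diagonal.

    Returns (score, q_start, q_end, t_start, t_end, n_matches).
    """
    # seed interval scores k matches
    score = k * MATCH_SCORE
    matches = k
    # extend right
    best, best_qe, best_te, best_m = score, qpos + k, tpos + k, matches
    s, m = score, matches
    qi, ti = qpos + k, tpos + k
    while qi < len(query) and ti < len(subject):
        if query[qi] == subject[ti]:
            s += MATCH_SCORE
            m += 1
        else:
            s += MISMATCH_SCORE
        qi += 1
        ti += 1
        if s > best:
            best, best_qe, best_te, best_m = s, qi, ti, m
        elif best - s > XDROP:
            break
    # extend left
    score, matches = best, best_m
    best_l, best_qs, best_ts, best_lm = score, qpos, tpos, matches
    s, m = score, matches
    qi, ti = qpos - 1, tpos - 1
    while qi >= 0 and ti >= 0:
        if query[qi] == subject[ti]:
            s += MATCH_SCORE
            m += 1
        else:
            s += MISMATCH_SCORE
        if s > best_l:
            best_l, best_qs, best_ts, best_lm = s, qi, ti, m
        elif best_l - s > XDROP:
            break
        qi -= 1
        ti -= 1
    return best_l, best_qs, best_qe, best_ts, best_te, best_lm


def align_locus(
    query: str,
    index: TranscriptomeIndex,
    min_score: int = 20,
    locus_id: str = "query",
) -> list[AlignmentHit]:
    """Seeded ungapped local alignment of one locus on both strands.

    Hits with score >= ``min_score`` are returned sorted by score
    descending, then transcript id ascending, then leftmost start.
    """
    query = query.upper()
    if len(query) < index.k:
        raise ValueError(f"query shorter than seed length {index.k}")
    found: dict[tuple[str, str, int, int], AlignmentHit] = {}
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        seen_diag: set[tuple[str, int]] = set()
        for qpos in range(len(q) - index.k + 1):
            for tid, tpos in index._index.get(q[qpos : qpos + index.k], ()):
                diag = (tid, tpos - qpos)
                if diag in seen_diag:
                    continue
                seen_diag.add(diag)
                subject = index.transcripts[tid]
                score, qs, qe, ts, te, m = _extend_ungapped(q, subject, qpos, tpos, index.k)
                if score < min_score:
                    continue
                hit = AlignmentHit(
                    locus_id=locus_id,
                    transcript_id=tid,
                    score=score,
                    identity=m / (te - ts),
                    start=ts,
                    end=te,
                    strand=strand,
                )
                key = (tid, strand, ts, te)
                if key not in found or found[key].score < score:
                    found[key] = hit
    return sorted(found.values(), key=lambda h: (-h.score, h.transcript_id, h.start))


def top_hit_go(
    hits: Sequence[AlignmentHit],
    annotation: AnnotationTable,
    mode: str = "strict",
) -> tuple[str, tuple[str, ...], str] | None:
    """GO terms of the top hit's first annotation, or None.

    ``strict`` (default): if the single best-scoring hit's transcript lacks
    annotation the locus is ignored.  ``lenient``: fall through to the best
    *annotated* hit.
    Returns (transcript_id, go_terms, annotation_label) or None.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    if not hits:
        return None
    candidates = hits[:1] if mode == "strict" else hits
    for hit in candidates:
        annots = annotation.annotations_of(hit.transcript_id)
        if annots:
            label, terms = annots[0]
            return hit.transcript_id, terms, label
        if mode == "strict":
            return None
    return None


def tally_contrast(
    unique: Mapping[str, Iterable[str]],
    catalog: LocusCatalog,
    index: TranscriptomeIndex,
    annotation: AnnotationTable,
    params: ContrastParams = ContrastParams(),
    min_score: int = 20,
    mode: str = "strict",
    external_hits: Mapping[str, list[AlignmentHit]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally GO terms over each habitat group's unique loci.

    ``unique`` must map exactly the groups {"freshwater", "saline"} to locus
    id sets.  Every unique locus contributes +1 to each GO term returned by
    :func:`top_hit_go`.  Returns (table, per_locus_log): the Table-3-shaped
    count table sorted by max count descending then GO term, and a log with
    one row per tallied locus.
    """
    if set(unique) != {"freshwater", "saline"}:
        raise ValueError("unique map must have exactly the groups freshwater and saline")
    by_id = {loc.locus_id: loc for loc in catalog.loci}
    counts: dict[str, dict[str, int]] = {}
    labels: dict[str, str] = {}
    log_rows = []
    col_of = {"freshwater": "freshwater_count", "saline": "saltwater_count"}
    for group in ("freshwater", "saline"):
        for locus_id in sorted(unique[group]):
            if external_hits is not None:
                hits = external_hits.get(locus_id, [])
            else:
                hits = align_locus(
                    by_id[locus_id].consensus, index, min_score=min_score, locus_id=locus_id
                )
            top = top_hit_go(hits, annotation, mode=mode)
            if top is None:
                continue
            tid, terms, label = top
            for term in terms:
                counts.setdefault(term, {"freshwater_count": 0, "saltwater_count": 0})
                counts[term][col_of[group]] += 1
                labels[term] = label
            log_rows.append(
                {
                    "locus_id": locus_id,
                    "group": group,
                    "transcript_id": tid,
                    "annotation_label": label,
                    "go_terms": ";".join(terms),
                }
            )
    rows = [
        {
            "go_term": term,
            "go_annotation": labels[term],
            "freshwater_count": c["freshwater_count"],
            "saltwater_count": c["saltwater_count"],
        }
        for term, c in counts.items()
    ]
    table = pd.DataFrame(rows, columns=list(TABLE3_COLUMNS))
    if len(table):
        table["_max"] = table[["freshwater_count", "saltwater_count"]].max(axis=1)
        table = (
            table.sort_values(["_max", "go_term"], ascending=[False, True])
            .drop(columns="_max")
            .reset_index(drop=True)
        )
    log = pd.DataFrame(
        log_rows, columns=["locus_id", "group", "transcript_id", "annotation_label", "go_terms"]
    )
    return table, log


def filter_contrast(
    table: pd.DataFrame, params: ContrastParams = ContrastParams()
) -> tuple[list[str], list[str]]:
    """Split GO terms into (saltwater_unique, freshwater_unique) lists.

    A term is group-unique when the focal group's count is at least
    ``min_count`` and the other group's count is zero or at least
    ``min_fold`` times smaller.
    """
    salt: list[str] = []
    fresh: list[str] = []
    for row in table.itertuples(index=False):
        fw = int(row.freshwater_count)
        sw = int(row.saltwater_count)
        if fw < 0 or sw < 0:
            raise ValueError("counts must be non-negative")
        if sw >= params.min_count and (fw == 0 or sw / fw >= params.min_fold):
            salt.append(row.go_term)
        if fw >= params.min_count and (sw == 0 or fw / sw >= params.min_fold):
            fresh.append(row.go_term)
    return salt, fresh


def read_table3(path: str | Path | None = None) -> pd.DataFrame:
    """Read a Table-3-shaped GO count table (packaged fixture by default)."""
    if path is None:
        source = importlib.resources.files("radhaplo.data") / "table3_go_counts.tsv"
        with importlib.resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != TABLE3_COLUMNS:
        raise ValueError(f"expected columns {TABLE3_COLUMNS}, got {tuple(df.columns)}")
    return df


def read_external_hits(path: str | Path) -> dict[str, list[AlignmentHit]]:
    """Adapter for BLAST outfmt-6-style TSV alignment results.

    Columns used: qseqid, sseqid, pident (0–100), sstart, send (1-based,
    reversed when on the minus strand) and bitscore (rounded to int score).
    """
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    out: dict[str, list[AlignmentHit]] = {}
    for row in df.itertuples(index=False):
        s, e = int(row.sstart), int(row.send)
        strand = "+" if s <= e else "-"
        start, end = (s - 1, e) if s <= e else (e - 1, s)
        out.setdefault(str(row.qseqid), []).append(
            AlignmentHit(
                locus_id=str(row.qseqid),
                transcript_id=str(row.sseqid),
                score=int(round(float(row.bitscore))),
                identity=float(row.pident) / 100.0,
                start=start,
                end=end,
                strand=strand,
            )
        )
    for hits in out.values():
        hits.sort(key=lambda h: (-h.score, h.transcript_id, h.start))
    return out
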