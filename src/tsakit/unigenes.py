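"""Unigene reduction and homology-hit summaries over tabular BLAST-style files.

Trinity inflates the apparent gene count: one locus is split over several
contigs and isoforms.  Two reductions give per-locus ("unigene") views:

* LCPC — longest contig per component, the representative sequence;
* BHPC — best (highest-bitscore) homology hit per component, the
  representative annotation.

The hit tables are the 12-column tabular dialect (qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore); extra
columns are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import TranscriptRecord, parse_trinity_id

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must lie in [0, 100]")


def read_outfmt6(path: str | Path) -> list[HomologyHit]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 tab-separated columns, got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = OUTFMT6_COLUMNS
    return [
        HomologyHit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            percent_identity=float(r.pident),
            alignment_length=int(r.length),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def select_lcpc(records: Iterable[TranscriptRecord]) -> list[TranscriptRecord]:
    """Longest contig per component; length ties go to the smaller id."""
    best: dict[str, TranscriptRecord] = {}
    for rec in records:
        comp = rec.component_id
        cur = best.get(comp)
        if cur is None or (-rec.length, rec.transcript_id) < (-cur.length, cur.transcript_id):
            best[comp] = rec
    return [best[k] for k in sorted(best)]


def best_hit_per_component(
    hits: Iterable[HomologyHit], evalue_cutoff: float = 1e-6
) -> list[HomologyHit]:
    """Highest-bitscore hit per Trinity component among hits passing the cutoff.

    Ties resolve to the lowest E-value, then the smaller subject id.
    """
    best: dict[str, HomologyHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        comp = parse_trinity_id(hit.query_id)[0]
        cur = best.get(comp)
        key = (-hit.bitscore, hit.evalue, hit.subject_id, hit.query_id)
        if cur is None or key < (-cur.bitscore, cur.evalue, cur.subject_id, cur.query_id):
            best[comp] = hit
    return [best[k] for k in sorted(best)]


def evalue_bin_summary(
    hits: Iterable[HomologyHit],
    edges: Sequence[float],
    total: int | None = None,
) -> pd.DataFrame:
    """Partition hits into half-open E-value intervals (<= upper, > lower).

    ``edges`` must be strictly decreasing, e.g. ``[1e-75, 1e-100, ..., 1e-200,
    0]``; an E-value of exactly 0 lands in the terminal bin.  Percentages
    (1 dp) are relative to ``total`` when given (e.g. the size of the whole
    query set), else to the number of binned hits.
    """
    edges = list(edges)
    if len(edges) < 2 or any(a <= b for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly decreasing")
    evs = [h.evalue for h in hits]
    counts = [0] * (len(edges) - 1)
    for e in evs:
        if e > edges[0]:
            continue
        for i in range(len(edges) - 1):
            if e > edges[i + 1] or (i == len(edges) - 2 and e >= edges[-1]):
                counts[i] += 1
                break
    denom = total if total is not None else sum(counts)
    rows = []
    for i, c in enumerate(counts):
        lo = edges[i + 1]
        label = (
            f"<= {edges[i]:g}, = {lo:g}" if i == len(edges) - 2 and lo == 0
            else f"<= {edges[i]:g}, > {lo:g}"
        )
        rows.append(
            {"range": label, "count": c, "percent": round(100.0 * c / denom, 1) if denom else 0.0}
        )
    return pd.DataFrame(rows)


def union_hit_count(hit_tables: Sequence[Iterable[HomologyHit]], evalue_cutoff: float) -> int:
    """Distinct queries hitting at least one of N databases under the cutoff."""
    seen: set[str] = set()
    for table in hit_tables:
        seen.update(h.query_id for h in table if h.evalue <= evalue_cutoff)
    return len(seen)


def reciprocal_overlap_summary(
    hits_ab: Iterable[HomologyHit],
    hits_ba: Iterable[HomologyHit],
    cutoff: float,
    edges: Sequence[float] | None = None,
    total_a: int | None = None,
    total_b: int | None = None,
) -> dict:
    """Two-way overlap between assemblies A and B from reciprocal hit tables.

    For each direction: distinct queries with best E-value <= cutoff, a
    per-bin breakdown, and the count of distinct subjects hit.  The A-side
    additionally reports BHPC counts when A uses Trinity identifiers.
    """
    hits_ab, hits_ba = list(hits_ab), list(hits_ba)
    if edges is None:
        edges = [cutoff, 1e-100, 1e-125, 1e-150, 1e-175, 1e-200, 0.0]

    def _direction(hits: list[HomologyHit], total: int | None) -> dict:
        passing = [h for h in hits if h.evalue <= cutoff]
        best = {}
        for h in passing:
            if h.query_id not in best or h.evalue < best[h.query_id].evalue:
                best[h.query_id] = h
        d = {
            "n_queries_hit": len(best),
            "n_subjects_hit": len({h.subject_id for h in passing}),
            "bins": evalue_bin_summary(list(best.values()), edges, total=total),
        }
        return d

    out = {"a_to_b": _direction(hits_ab, total_a), "b_to_a": _direction(hits_ba, total_b)}
    try:
        bhpc = best_hit_per_component(hits_ab, cutoff)
    except Exception:
        bhpc = None
    if bhpc is not None:
        out["a_to_b"]["n_bhpc_hit"] = len(bhpc)
        out["a_to_b"]["bhpc_bins"] = evalue_bin_summary(bhpc, edges, total=total_a)
    return out
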