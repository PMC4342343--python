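"""Data model for Trinity-style assemblies and assembly-level summary metrics.

Trinity names every contig ``comp{X}_c{Y}_seq{Z}``: a *component* (putative
gene locus, ``compX``) groups one or more *subcomponents* (gene-like clusters,
``compX_cY``), each holding one or more isoform transcripts (``_seqZ``).
This module parses that three-level identity, wraps FASTA input/output, and
computes the usual assembly report card (N50, %GC, length statistics,
contig/subcomponent/component counts).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_TRINITY_ID = re.compile(r"^comp(\d+)_c(\d+)(?:_seq(\d+))?$")


class TrinityIdError(ValueError):
    """Raised when an identifier does not follow the compX_cY[_seqZ] scheme."""


def parse_trinity_id(raw_id: str) -> tuple[str, str, int]:
    """Split a Trinity identifier into (component, subcomponent, isoform index).

    Identifiers without the ``_seq`` suffix (subcomponent-level ids, as used in
    expression tables) are accepted and map to isoform 1.

    >>> parse_trinity_id("comp41991_c0_seq2")
    ('comp41991', 'comp41991_c0', 2)
    """
    m = _TRINITY_ID.match(raw_id)
    if m is None:
        raise TrinityIdError(f"not a Trinity-style identifier: {raw_id!r}")
    comp, sub, seq = m.groups()
    component = f"comp{comp}"
    subcomponent = f"{component}_c{sub}"
    return component, subcomponent, int(seq) if seq is not None else 1


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled contig with its parsed Trinity identity."""

    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.transcript_id}")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.transcript_id}: non-nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def component_id(self) -> str:
        return parse_trinity_id(self.transcript_id)[0]

    @property
    def subcomponent_id(self) -> str:
        return parse_trinity_id(self.transcript_id)[1]

    @property
    def isoform_index(self) -> int:
        return parse_trinity_id(self.transcript_id)[2]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyMetrics:
    n_transcripts: int
    n_subcomponents: int
    n_components: int
    gc_percent: float  # NaN when no unambiguous base exists
    n50: int
    longest: int
    median_length: float
    mean_length: float
    total_bases: int


def compute_n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L jointly cover >= 50% of bases."""
    if not lengths:
        raise ValueError("N50 of an empty assembly is undefined")
    half = sum(lengths) / 2.0
    acc = 0
    for n in sorted(lengths, reverse=True):
        acc += n
        if acc >= half:
            return n
    raise AssertionError("unreachable")


def compute_assembly_metrics(records: Iterable[TranscriptRecord]) -> AssemblyMetrics:
    """Summary metrics over an assembly (order-independent)."""
    recs = list(records)
    if not recs:
        raise ValueError("cannot summarise an empty assembly")
    lengths = sorted(r.length for r in recs)
    n = len(lengths)
    gc = at = 0
    for r in recs:
        s = r.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    gc_percent = 100.0 * gc / (gc + at) if gc + at else math.nan
    mid = n // 2
    median = float(lengths[mid]) if n % 2 else (lengths[mid - 1] + lengths[mid]) / 2.0
    total = sum(lengths)
    return AssemblyMetrics(
        n_transcripts=n,
        n_subcomponents=len({r.subcomponent_id for r in recs}),
        n_components=len({r.component_id for r in recs}),
        gc_percent=gc_percent,
        n50=compute_n50(lengths),
        longest=lengths[-1],
        median_length=median,
        mean_length=total / n,
        total_bases=total,
    )


# ---------------------------------------------------------------------------
# FASTA / TSV interchange
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    return [
        TranscriptRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.transcript_id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


_METRIC_ROWS = [
    ("Trinity transcripts", "n_transcripts", "{:d}"),
    ("Trinity sub-components", "n_subcomponents", "{:d}"),
    ("Trinity components", "n_components", "{:d}"),
    ("%GC", "gc_percent", "{:.1f}"),
    ("N50", "n50", "{:d}"),
    ("Longest contig", "longest", "{:d}"),
    ("Median contig length", "median_length", "{:.1f}"),
    ("Average contig length", "mean_length", "{:.1f}"),
    ("Total bases", "total_bases", "{:d}"),
]


def metrics_to_tsv(metrics: AssemblyMetrics) -> str:
    """Two-column TSV, one metric per row."""
    lines = []
    for label, attr, fmt in _METRIC_ROWS:
        value = getattr(metrics, attr)
        lines.append(f"{label}\t{fmt.format(value)}")
    return "\n".join(lines) + "\n"
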