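"""Six-frame ORF discovery, translation and completeness classification.

Every reading frame on both strands is scanned stop-to-stop.  A segment that
starts with the transcript (no upstream in-frame stop) is *open* at the 5'
boundary; a segment that runs off the 3' end without a stop is open there.
The four completeness classes follow from which boundaries are closed:

=================  ==========  =========================================
class              start..stop  meaning
=================  ==========  =========================================
complete           ATG..stop   full coding sequence
partial_3prime     ATG..end    C-terminus truncated (no stop codon)
partial_5prime     open..stop  N-terminus truncated (no usable ATG)
internal           open..end   both termini missing
=================  ==========  =========================================

A 5'-open segment that does contain an ATG is reported once, from that ATG
(avoids counting one segment under two classes).  Codons containing N
translate to X and can serve neither as start nor as stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio.Seq import Seq

Completeness = Literal["complete", "partial_5prime", "partial_3prime", "internal"]

COMPLETENESS_CLASSES: tuple[str, ...] = (
    "complete",
    "partial_5prime",
    "partial_3prime",
    "internal",
)

# tie-break preference for longest_orf_per_group
_CLASS_RANK = {"complete": 0, "partial_3prime": 1, "partial_5prime": 2, "internal": 3}

_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate()) for c in product("ACGT", repeat=3)
}


def translate_codon(codon: str) -> str:
    """Standard genetic code; any codon containing N (or stop) yields X/*. """
    return _CODON_TABLE.get(codon, "X")


@dataclass(frozen=True)
class OrfRecord:
    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2, offset on the reading strand
    nt_start: int  # 0-based half-open, forward-strand coordinates
    nt_end: int
    peptide: str
    completeness: str

    @property
    def aa_length(self) -> int:
        return len(self.peptide)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_frame(codons: list[str], raw: list[str]) -> Iterable[tuple[int, int, str]]:
    """Yield (start_codon, end_codon, class) for one frame.

    ``codons`` are translated residues ('*' marks stops), ``raw`` the
    nucleotide triplets (needed to spot exact ATG starts).
    """
    n = len(codons)
    seg_start = 0
    i = 0
    while seg_start < n:
        # advance to the next stop (or end of frame)
        i = seg_start
        while i < n and codons[i] != "*":
            i += 1
        closed3 = i < n
        open5 = seg_start == 0
        atg = next((j for j in range(seg_start, i) if raw[j] == "ATG"), None)
        if atg is not None:
            yield (atg, i, "complete" if closed3 else "partial_3prime")
        elif open5 and i > seg_start:
            yield (seg_start, i, "partial_5prime" if closed3 else "internal")
        seg_start = i + 1


def find_orfs(record, min_len_aa: int = 100) -> list[OrfRecord]:
    """All ORFs of peptide length >= ``min_len_aa`` across the six frames."""
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    seq = record.sequence
    length = len(seq)
    out: list[OrfRecord] = []
    for strand in "+-":
        s = seq if strand == "+" else _revcomp(seq)
        for frame in range(3):
            raw = [s[i : i + 3] for i in range(frame, length - 2, 3)]
            codons = [translate_codon(c) for c in raw]
            for a, b, cls in _scan_frame(codons, raw):
                pep = "".join(codons[a:b])
                if len(pep) < min_len_aa:
                    continue
                lo, hi = frame + 3 * a, frame + 3 * b
                if strand == "-":
                    lo, hi = length - hi, length - lo
                out.append(
                    OrfRecord(record.transcript_id, strand, frame, lo, hi, pep, cls)
                )
    out.sort(key=lambda o: (o.nt_start, o.nt_end, o.strand, o.frame))
    return out


def longest_orf_per_group(
    orfs: Iterable[OrfRecord], group_by: str = "component"
) -> list[OrfRecord]:
    """One maximal-length ORF per Trinity component or subcomponent.

    Ties go to the more complete class, then the lexicographically smallest
    transcript id (then coordinates, for full determinism).
    """
    from .core import parse_trinity_id

    if group_by not in ("component", "subcomponent"):
        raise ValueError(f"group_by must be component or subcomponent, got {group_by!r}")
    idx = 0 if group_by == "component" else 1
    best: dict[str, OrfRecord] = {}
    for orf in orfs:
        key = parse_trinity_id(orf.transcript_id)[idx]
        cur = best.get(key)
        if cur is None or _orf_sort_key(orf) < _orf_sort_key(cur):
            best[key] = orf
    return [best[k] for k in sorted(best)]


def _orf_sort_key(o: OrfRecord):
    return (-o.aa_length, _CLASS_RANK[o.completeness], o.transcript_id, o.nt_start, o.strand, o.frame)


def completeness_summary(orfs: Iterable[OrfRecord]) -> pd.DataFrame:
    counts = {c: 0 for c in COMPLETENESS_CLASSES}
    for orf in orfs:
        counts[orf.completeness] += 1
    return completeness_summary_from_counts(counts)


def completeness_summary_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Four-class count/percent table (plus a total row), percents to 1 dp."""
    total = sum(counts.get(c, 0) for c in COMPLETENESS_CLASSES)
    rows = []
    for cls in COMPLETENESS_CLASSES:
        n = counts.get(cls, 0)
        rows.append(
            {"class": cls, "count": n, "percent": round(100.0 * n / total, 1) if total else 0.0}
        )
    rows.append({"class": "total", "count": total, "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


_DEFAULT_ORIGIN = {"nt": 200, "aa": 99}
_DEFAULT_WIDTH = {"nt": 100, "aa": 50}


def length_histogram(
    items: Iterable[int | tuple[int, str]],
    unit: str = "nt",
    bin_width: int | None = None,
    origin: int | None = None,
) -> pd.DataFrame:
    """Closed-open length bins [lo, lo + width), optionally split by class.

    ``items`` are lengths, or (length, label) pairs for per-class columns.
    Defaults mirror the usual assembly report: nucleotide bins of 100 from
    200 nt, amino-acid bins of 50 from 99 aa.
    """
    if unit not in _DEFAULT_ORIGIN:
        raise ValueError("unit must be 'nt' or 'aa'")
    width = bin_width if bin_width is not None else _DEFAULT_WIDTH[unit]
    if width < 1:
        raise ValueError("bin_width must be >= 1")
    start = origin if origin is not None else _DEFAULT_ORIGIN[unit]
    pairs = [(it, "count") if isinstance(it, int) else tuple(it) for it in items]
    if not pairs:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    labels = sorted({lab for _, lab in pairs})
    table: dict[int, dict[str, int]] = {}
    for length, lab in pairs:
        lo = start + ((length - start) // width) * width
        table.setdefault(lo, {l: 0 for l in labels})[lab] += 1
    rows = [
        {"bin_lo": lo, "bin_hi": lo + width, **table[lo]} for lo in sorted(table)
    ]
    return pd.DataFrame(rows)


def write_protein_fasta(orfs: Sequence[OrfRecord], path: str | Path) -> None:
    """Headers carry ``{transcript_id}|{strand}{frame}|{completeness}``."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f">{o.transcript_id}|{o.strand}{o.frame}|{o.completeness}\n")
            for i in range(0, len(o.peptide), 60):
                fh.write(o.peptide[i : i + 60] + "\n")
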