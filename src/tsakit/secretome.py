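"""Neurosecretome prediction: signal peptide, TM helix and mitochondrial
targeting surrogates, and the filtering cascade that combines them.

A classically secreted protein is expected to (1) carry an N-terminal signal
peptide, (2) lack transmembrane helices — except a single helix ending
within the first 60 residues, which is almost always the signal peptide
itself re-called as a TM segment — and (3) lack a mitochondrial targeting
presequence.  The three predictors here are transparent, deterministic
scorers built from the classical sequence features those tools exploit:

* signal peptide: positively charged n-region, hydrophobic h-region
  (Kyte-Doolittle windowed mean), and a (-3,-1) small-residue signal
  peptidase site, combined through a fixed logistic;
* TM helices: runs of high window-17 Kyte-Doolittle hydropathy;
* mitochondrial presequence: arginine-rich, acid-poor, hydroxylated
  N-terminus without a competing signal-peptidase site.

Each keeps the decision contract of the published cascade (a [0,1] score
compared against 0.5, residue intervals, a boolean), so the filter
thresholds retain their meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Kyte & Doolittle hydropathy scale; unknown residues (X, etc.) score 0.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}

# signal-peptidase (-3,-1) rule: allowed small residues
_CLEAVE_MINUS1 = set("AGSCTQ")
_CLEAVE_MINUS3 = set("AGSCTVIL")

# fixed logistic weights for the signal-peptide score; chosen so that the
# full n/h/c feature set clears 0.5 and a missing h-region never does
SP_BIAS = -4.0
SP_W_NREGION = 1.0
SP_W_HREGION = 3.5
SP_W_CREGION = 1.5


@dataclass(frozen=True)
class HydropathyProfile:
    window: int
    values: np.ndarray  # len = max(0, L - window + 1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SecretomeCall:
    protein_id: str
    sp_score: float
    sp_cleavage_pos: int | None
    tm_segments: tuple[tuple[int, int], ...]
    mito_flag: bool
    verdict: str
    completeness_class: str | None  # full_length / c_terminal_truncated


def kyte_doolittle_profile(peptide: str, window: int = 17) -> HydropathyProfile:
    """Windowed-mean hydropathy; positions lacking a full window are omitted."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    scores = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in peptide], dtype=float)
    if len(scores) < window:
        return HydropathyProfile(window, np.empty(0))
    kernel = np.ones(window) / window
    return HydropathyProfile(window, np.convolve(scores, kernel, mode="valid"))


def predict_tm_helices(
    profile: HydropathyProfile, threshold: float = 1.6, min_span: int = 15
) -> list[tuple[int, int]]:
    """Candidate TM helices as 1-based inclusive residue intervals.

    Maximal runs of window centres with hydropathy > threshold are found,
    runs separated by fewer than 5 positions are merged, runs of at least
    ``min_span`` centres are kept, and each run is widened by half a window
    on both sides to convert centre positions back to residue coordinates.
    """
    above = profile.values > threshold
    runs: list[list[int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if runs and i - runs[-1][1] - 1 < 5:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    out = []
    for a, b in runs:
        if b - a + 1 >= min_span:
            # profile index a covers residues [a, a + window); run [a, b]
            # extended by window/2 around the centres spans a .. b+window-1
            out.append((a + 1, b + profile.window))
    return out


def predict_signal_peptide(peptide: str) -> tuple[float, int | None]:
    """Surrogate SignalP-style score in [0, 1] plus the best cleavage position.

    Evaluated on residues 1-45.  Three binary sub-features feed a fixed
    logistic: an n-region basic residue (K/R within residues 2-8), an
    h-region (some >= 7-residue window inside residues 5-30 with mean
    hydropathy >= 1.8), and a c-region (-3,-1) site at a position 15-45.
    The cleavage position counts residues in the signal peptide (cleavage
    occurs after that many residues).
    """
    if not peptide or peptide[0] != "M":
        raise ValueError("signal peptide scoring expects a start-methionine-bearing protein")
    head = peptide[:45]
    n_region = any(a in "KR" for a in head[1:8])
    h_region = _best_h_window(head) is not None
    cleave = _best_cleavage_site(head)
    z = (
        SP_BIAS
        + SP_W_NREGION * n_region
        + SP_W_HREGION * h_region
        + SP_W_CREGION * (cleave is not None)
    )
    score = 1.0 / (1.0 + math.exp(-z))
    return score, cleave


def _best_h_window(head: str) -> tuple[int, int] | None:
    """Earliest >=7-residue window within residues 5-30 with mean KD >= 1.8."""
    lo, hi = 4, min(30, len(head))  # 0-based slice bounds for residues 5..30
    region = head[lo:hi]
    for w in range(7, len(region) + 1):
        for s in range(0, len(region) - w + 1):
            seg = region[s : s + w]
            if sum(KYTE_DOOLITTLE.get(a, 0.0) for a in seg) / w >= 1.8:
                return lo + s, lo + s + w
    return None


def cleavage_site_score(head: str, pos: int) -> float:
    """Preference score of a (-3,-1) signal-peptidase site after residue ``pos``."""
    m1, m3 = head[pos - 1], head[pos - 3]
    if m1 not in _CLEAVE_MINUS1 or m3 not in _CLEAVE_MINUS3:
        return -math.inf
    s = 2.0 if m1 in "AGS" else 1.0
    s += 1.0 if m3 in "AGSCT" else 0.5
    return s - 0.05 * pos  # earlier sites slightly preferred


def _best_cleavage_site(head: str) -> int | None:
    best, best_score = None, -math.inf
    for pos in range(15, min(45, len(head)) + 1):
        s = cleavage_site_score(head, pos)
        if s > best_score:
            best, best_score = pos, s
    return best if best_score > -math.inf else None


def predict_mito_targeting(peptide: str) -> bool:
    """Mitochondrial presequence call on residues 2-30.

    Requires >= 4 arginines, <= 1 acidic residue (D/E) and >= 2 S/T, and a
    composite presequence strength exceeding the signal-peptide score (a
    stronger signal-peptidase interpretation wins the ambiguous cases).
    """
    if not peptide or peptide[0] != "M":
        raise ValueError("mito targeting expects a start-methionine-bearing protein")
    region = peptide[1:30]
    n_r = region.count("R")
    n_acid = region.count("D") + region.count("E")
    n_st = region.count("S") + region.count("T")
    if not (n_r >= 4 and n_acid <= 1 and n_st >= 2):
        return False
    strength = min(1.0, 0.15 * n_r + 0.1 * n_st - 0.2 * n_acid)
    sp_score, _ = predict_signal_peptide(peptide)
    return strength > sp_score


@dataclass(frozen=True)
class ProteinSeq:
    """Minimal start-bearing protein for the cascade (id, sequence, ORF class)."""

    protein_id: str
    sequence: str
    completeness: str = "complete"  # complete or partial_3prime


def classify_protein(
    protein: ProteinSeq,
    sp_threshold: float = 0.5,
    tm_window: int = 17,
    tm_threshold: float = 1.6,
    tm_min_span: int = 15,
    tm_nterm_limit: int = 60,
) -> SecretomeCall:
    """Run the full cascade on one protein and return its call."""
    seq = protein.sequence
    if not seq or seq[0] != "M" or protein.completeness not in ("complete", "partial_3prime"):
        return SecretomeCall(
            protein.protein_id, 0.0, None, (), False, "rejected_incomplete", None
        )
    sp_score, cleave = predict_signal_peptide(seq)
    profile = kyte_doolittle_profile(seq, tm_window)
    tms = tuple(predict_tm_helices(profile, tm_threshold, tm_min_span))
    mito = predict_mito_targeting(seq)
    comp_class = "full_length" if protein.completeness == "complete" else "c_terminal_truncated"
    if sp_score < sp_threshold:
        verdict = "rejected_no_signal"
    elif mito:
        verdict = "rejected_mito"
    elif len(tms) == 0 or (len(tms) == 1 and tms[0][1] <= tm_nterm_limit):
        verdict = "secreted"
    else:
        verdict = "rejected_tm"
    return SecretomeCall(
        protein.protein_id, sp_score, cleave, tms, mito, verdict,
        comp_class if verdict == "secreted" else None,
    )


def secretome_filter(proteins: Iterable[ProteinSeq], **thresholds) -> list[SecretomeCall]:
    """Cascade verdicts for a deduplicated, start-bearing protein set."""
    return [classify_protein(p, **thresholds) for p in proteins]


def deduplicate_proteins(proteins: Iterable[ProteinSeq]) -> list[ProteinSeq]:
    """Drop exact duplicates and exact substrings of longer sequences.

    The longest representative wins; among equal sequences the smaller id is
    kept.  Output order is deterministic (by id) regardless of input order.
    """
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.protein_id))
    kept: list[ProteinSeq] = []
    for p in ordered:
        if any(p.sequence in q.sequence for q in kept):
            continue
        kept.append(p)
    return sorted(kept, key=lambda p: p.protein_id)


def calls_to_frame(calls: Sequence[SecretomeCall]) -> pd.DataFrame:
    """Per-protein annotation sheet (scores, intervals, verdicts)."""
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "sp_score": [round(c.sp_score, 4) for c in calls],
            "sp_cleavage_pos": [c.sp_cleavage_pos for c in calls],
            "tm_segments": [
                ";".join(f"{a}-{b}" for a, b in c.tm_segments) for c in calls
            ],
            "mito_flag": [c.mito_flag for c in calls],
            "verdict": [c.verdict for c in calls],
            "completeness_class": [c.completeness_class for c in calls],
        }
    )


def write_secretome_fasta(
    proteins: Sequence[ProteinSeq], calls: Sequence[SecretomeCall], path: str | Path
) -> None:
    secreted = {c.protein_id for c in calls if c.verdict == "secreted"}
    with open(path, "w") as fh:
        for p in proteins:
            if p.protein_id in secreted:
                fh.write(f">{p.protein_id}\n")
                for i in range(0, len(p.sequence), 60):
                    fh.write(p.sequence[i : i + 60] + "\n")
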