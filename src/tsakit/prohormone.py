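"""Mature peptide derivation from secreted precursors.

Neuropeptide pre-pro-proteins are processed by prohormone convertases at
basic-residue motifs: dibasic pairs (KR, RR, KK, RK) and monobasic arginines
helped by an additional basic residue 4, 6 or 8 positions upstream.  After
cleavage, carboxypeptidase removes the exposed basic residues and a
C-terminal glycine is converted to an amide (the hallmark of e.g.
FMRFamide and the small cardioactive peptides).

Rules implemented here:

* a cleavage site sits immediately C-terminal to the basic residue(s);
* overlapping dibasic matches (basic runs) merge into one site consuming
  the whole run;
* basic residues already consumed by a dibasic site do not double as the
  upstream anchor of the monobasic rule — otherwise every tandem repeat of
  the form ``...GKR|FMRF...`` would be cut inside the repeat;
* monobasic sites directly followed by proline are suppressed (convertases
  disfavour P at P1');
* sites inside the signal peptide are discarded;
* each liberated fragment is trimmed of flanking K/R runs, and a trailing
  glycine is removed with the peptide flagged as amidated.

Derivation is conservative: peptides, trimmed basics and removed glycines
concatenate back to the exact mature region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DIBASIC_PAIRS = ("KR", "RR", "KK", "RK")
MONOBASIC_ANCHOR_OFFSETS = (4, 6, 8)


@dataclass(frozen=True)
class MaturePeptide:
    precursor_id: str
    start: int  # 0-based half-open coordinates of the stored sequence
    end: int
    sequence: str
    amidated: bool


def predict_cleavage_sites(
    precursor: str,
    sp_cleavage: int,
    suppress_proline: bool = True,
    anchor_offsets: Sequence[int] = MONOBASIC_ANCHOR_OFFSETS,
) -> list[int]:
    """Ordered convertase cleavage positions (0-based, cleavage before index).

    ``sp_cleavage`` is the signal-peptide length; sites at or before it are
    discarded.
    """
    if sp_cleavage >= len(precursor):
        raise ValueError("signal peptide cleavage position beyond precursor end")
    n = len(precursor)
    consumed = [False] * n
    sites: set[int] = set()

    # dibasic rule: maximal K/R runs of length >= 2 cleave after the run
    i = 0
    while i < n:
        if precursor[i] in "KR":
            j = i
            while j + 1 < n and precursor[j + 1] in "KR":
                j += 1
            if j > i:
                sites.add(j + 1)
                for k in range(i, j + 1):
                    consumed[k] = True
            i = j + 1
        else:
            i += 1

    # monobasic rule: lone R with an unconsumed K/R at -4, -6 or -8
    for i, aa in enumerate(precursor):
        if aa != "R" or consumed[i]:
            continue
        if suppress_proline and i + 1 < n and precursor[i + 1] == "P":
            continue
        for off in anchor_offsets:
            j = i - off
            if j >= 0 and precursor[j] in "KR" and not consumed[j]:
                sites.add(i + 1)
                break

    return sorted(s for s in sites if s > sp_cleavage)


def derive_peptides(
    precursor: str,
    sp_cleavage: int,
    sites: Sequence[int],
    precursor_id: str = "precursor",
) -> list[MaturePeptide]:
    """Split the mature region at the given sites and post-process fragments.

    Flanking K/R runs are trimmed off each fragment, a trailing glycine is
    converted to an amide flag, and empty fragments are dropped.
    """
    n = len(precursor)
    bounds = [sp_cleavage, *sorted(sites), n]
    if any(b <= sp_cleavage for b in sites) or any(b > n for b in sites):
        raise ValueError("cleavage sites must lie inside the mature region")
    peptides: list[MaturePeptide] = []
    for lo, hi in zip(bounds, bounds[1:]):
        a, b = lo, hi
        while a < b and precursor[a] in "KR":
            a += 1
        while b > a and precursor[b - 1] in "KR":
            b -= 1
        if a == b:
            continue
        amidated = precursor[b - 1] == "G"
        if amidated:
            b -= 1
        if a == b:
            continue
        peptides.append(
            MaturePeptide(precursor_id, a, b, precursor[a:b], amidated)
        )
    return peptides


def count_peptide_repeats(
    precursor: str, motif: str, sp_cleavage: int = 0
) -> int:
    """Number of derived mature peptides equal to ``motif``.

    Matching is amidation-normalised: the stored sequence already has the
    amide-donating glycine removed, so ``motif`` is compared against the
    processed peptide directly.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    sites = predict_cleavage_sites(precursor, sp_cleavage)
    peptides = derive_peptides(precursor, sp_cleavage, sites)
    return sum(p.sequence == motif for p in peptides)


def conservation_parts(
    precursor: str, sp_cleavage: int, peptides: Iterable[MaturePeptide]
) -> tuple[int, int, int]:
    """(total peptide residues, trimmed basics, removed glycines) of a derivation."""
    peps = list(peptides)
    kept = sum(len(p.sequence) for p in peps)
    glycines = sum(p.amidated for p in peps)
    mature_len = len(precursor) - sp_cleavage
    return kept, mature_len - kept - glycines, glycines


def write_peptide_fasta(peptides: Sequence[MaturePeptide], path: str | Path) -> None:
    """Headers carry precursor id, coordinates and the amidation flag."""
    with open(path, "w") as fh:
        for p in peptides:
            amide = "amidated" if p.amidated else "free"
            fh.write(f">{p.precursor_id}|{p.start}-{p.end}|{amide}\n{p.sequence}\n")


def peptides_to_frame(peptides: Sequence[MaturePeptide]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "precursor_id": [p.precursor_id for p in peptides],
            "start": [p.start for p in peptides],
            "end": [p.end for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "amidated": [p.amidated for p in peptides],
        }
    )
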