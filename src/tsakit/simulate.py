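"""Truth-labelled synthetic transcriptomes for end-to-end pipeline testing.

The generator emulates the statistical structure a de-novo CNS assembly
presents to each pipeline stage: a multi-component assembly whose contig
lengths follow a heavy-tailed log-normal peaking in the 200-399 nt range,
a realistic GC content, open reading frames of all four completeness
classes in configurable proportions, planted secreted precursors (signal
peptide + convertase sites + amidated peptide repeats), transmembrane and
mitochondrial proteins, ambiguously mapping reads, and cross-contaminated
sequence pairs with strongly asymmetric expression.

Signal-peptide, mitochondrial and transmembrane templates are parameterised
families randomised within rule-satisfying bounds rather than fixed
strings, so predictor tests are non-trivial.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import TranscriptRecord, parse_trinity_id
from .orfs import COMPLETENESS_CLASSES
from .quantify import ReadCompatibility

# codon table grouped by residue, for GC-steered reverse translation
_CODONS_BY_AA: dict[str, list[str]] = {}
from itertools import product as _product
from Bio.Seq import Seq as _Seq

for _c in _product("ACGT", repeat=3):
    codon = "".join(_c)
    aa = str(_Seq(codon).translate())
    _CODONS_BY_AA.setdefault(aa, []).append(codon)

# amino-acid sampling weights for random coding regions: AT-rich-codon
# residues up-weighted, GC-forcing ones down-weighted, so that GC-steered
# synonymous codon choice lands coding GC at the molluscan target (~39.4%)
_AA_POOL = "ACDEFGHIKLMNPQRSTVWY"
_AA_WEIGHTS = np.array(
    [
        0.0 if a == "M" else 0.75 if a in "AGPRW" else 1.3 if a in "FIKLNY" else 1.0
        for a in _AA_POOL
    ]
)  # M weight 0 - start codons are always planted explicitly
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

_POLAR = "NQSTYHDE"
_HYDROPHOBIC = "LIVF"


@dataclass
class SimConfig:
    seed: int = 0
    n_components: int = 600
    # isoform count distribution per component
    isoform_dist: tuple[tuple[int, float], ...] = ((1, 0.75), (2, 0.15), (3, 0.07), (4, 0.03))
    # log-normal contig lengths: median exp(mu) ~= 363 nt, heavy right tail
    length_log_mu: float = math.log(363.0)
    length_log_sigma: float = 1.2
    min_length: int = 200
    max_length: int = 20000
    gc_target: float = 39.4
    # (complete, partial_5prime, partial_3prime, internal)
    class_mix: tuple[float, float, float, float] = (0.513, 0.196, 0.127, 0.164)
    n_secreted: int = 120
    n_tm: int = 100
    n_mito: int = 80
    n_cytosolic: int = 200
    repeat_counts: tuple[int, ...] = (2, 3, 5, 7)
    repeat_motif: str = "FMRF"
    # (fraction of components copied, expression ratio, per-base mutation rate)
    contamination: tuple[float, float, float] = (0.1, 0.01, 0.01)

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        for n in (self.n_secreted, self.n_tm, self.n_mito, self.n_cytosolic):
            if n < 0:
                raise ValueError("protein counts must be >= 0")


@dataclass
class TruthLabels:
    # transcript_id -> (strand, nt_start, nt_end, completeness)
    orfs: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    # protein_id (== transcript id of the carrying contig) -> category
    protein_category: dict[str, str] = field(default_factory=dict)
    protein_sequence: dict[str, str] = field(default_factory=dict)
    sp_length: dict[str, int] = field(default_factory=dict)
    cleavage_sites: dict[str, tuple[int, ...]] = field(default_factory=dict)
    planted_peptides: dict[str, tuple[tuple[str, bool], ...]] = field(default_factory=dict)
    repeat_count: dict[str, int] = field(default_factory=dict)
    # injected contaminant: new subcomponent id -> (source subcomponent, ratio)
    contaminants: dict[str, tuple[str, float]] = field(default_factory=dict)
    theta: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# residue- and nucleotide-level helpers
# ---------------------------------------------------------------------------

def _random_aa(rng: np.random.Generator, n: int, pool: str = _AA_POOL,
               weights: np.ndarray | None = None) -> str:
    if pool == _AA_POOL and weights is None:
        weights = _AA_WEIGHTS
    idx = rng.choice(len(pool), size=n, p=weights)
    return "".join(pool[i] for i in idx)


_CODON_CUMW_CACHE: dict[tuple[str, float], tuple[list[str], np.ndarray]] = {}


def _codon_cumw(aa: str, gc: float) -> tuple[list[str], np.ndarray]:
    """Synonymous codons with cumulative per-base GC-steered weights."""
    key = (aa, round(gc, 4))
    if key not in _CODON_CUMW_CACHE:
        g = gc / 100.0
        options = _CODONS_BY_AA[aa]
        w = np.array(
            [
                float(np.prod([g / 2 if b in "GC" else (1 - g) / 2 for b in c]))
                for c in options
            ]
        )
        _CODON_CUMW_CACHE[key] = (options, np.cumsum(w / w.sum()))
    return _CODON_CUMW_CACHE[key]


def _reverse_translate(rng: np.random.Generator, protein: str, gc: float) -> str:
    u = rng.random(len(protein))
    out = []
    for aa, x in zip(protein, u):
        options, cum = _codon_cumw(aa, gc)
        out.append(options[int(np.searchsorted(cum, x))])
    return "".join(out)


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    g = gc / 100.0
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    idx = rng.choice(4, size=n, p=p)
    return "".join("AGCT"[i] for i in idx)


# ---------------------------------------------------------------------------
# protein template families
# ---------------------------------------------------------------------------

def make_signal_peptide(rng: np.random.Generator) -> str:
    """Randomised n/h/c signal peptide satisfying the classical feature rules."""
    n_len = int(rng.integers(1, 4))
    n_region = list(_random_aa(rng, n_len, pool="NQST", weights=None))
    n_region[int(rng.integers(0, n_len))] = "K" if rng.random() < 0.5 else "R"
    h_len = int(rng.integers(9, 13))
    h_region = _random_aa(rng, h_len, pool="LLIVFA", weights=None)
    c_len = int(rng.integers(4, 9))
    c_region = list(_random_aa(rng, c_len, pool="STVQAG", weights=None))
    c_region[-1] = "AGS"[int(rng.integers(0, 3))]
    c_region[-3] = "AGS"[int(rng.integers(0, 3))]
    return "M" + "".join(n_region) + h_region + "".join(c_region)


def make_secreted_protein(
    rng: np.random.Generator, n_repeats: int, motif: str
) -> tuple[str, int, tuple[int, ...], tuple[tuple[str, bool], ...]]:
    """Signal peptide + acidic spacer + n x (motif-G-KR) repeats + tail.

    Returns (sequence, sp_length, planted cleavage sites, planted peptides).
    """
    sp = make_signal_peptide(rng)
    spacer = "E" + _random_aa(rng, int(rng.integers(4, 12)), pool="NQSTYP") + "D"
    # acidic propeptide domain, as in real prohormones; keeps precursors in
    # the 100-150 aa range TransDecoder-style ORF calling reports
    filler = _random_aa(rng, int(rng.integers(60, 91)), pool="NQSTYPADE")
    tail = _random_aa(rng, int(rng.integers(4, 10)), pool="NQSTYAD")
    seq = sp + spacer + "KR"
    sites = [len(seq)]
    peptides: list[tuple[str, bool]] = [(spacer, False)]
    seq += filler + "KR"
    sites.append(len(seq))
    peptides.append((filler, False))
    for _ in range(n_repeats):
        seq += motif + "G" + "KR"
        sites.append(len(seq))
        peptides.append((motif, True))
    seq += tail
    peptides.append((tail, False))
    return seq, len(sp), tuple(sites), tuple(peptides)


def make_tm_protein(rng: np.random.Generator) -> str:
    """Signal-anchored membrane protein: one long hydrophobic block after aa 60."""
    sp = make_signal_peptide(rng)
    linker = _random_aa(rng, 65 - len(sp) + int(rng.integers(0, 20)), pool=_POLAR)
    block = _random_aa(rng, int(rng.integers(30, 35)), pool=_HYDROPHOBIC)
    tail = _random_aa(rng, int(rng.integers(30, 60)), pool=_POLAR)
    return sp + linker + block + tail


def make_mito_protein(rng: np.random.Generator) -> str:
    """Arginine-rich, acid-free presequence without a hydrophobic core."""
    pre_len = int(rng.integers(29, 41))
    pre = []
    for i in range(pre_len):
        if i % 3 == 1:
            pre.append("R")
        else:
            pre.append("LSAFST"[int(rng.integers(0, 6))])
    mature = _random_aa(rng, int(rng.integers(60, 140)))
    return "M" + "".join(pre) + mature


def make_cytosolic_protein(rng: np.random.Generator) -> str:
    """Polar-biased N-terminus (no h-region), unconstrained body."""
    nterm = _random_aa(rng, 34, pool=_POLAR + "AGKRP")
    body = _random_aa(rng, int(rng.integers(60, 200)))
    return "M" + nterm + body


# ---------------------------------------------------------------------------
# transcript assembly
# ---------------------------------------------------------------------------

def _embed_orf(
    rng: np.random.Generator,
    protein: str,
    completeness: str,
    total_len: int,
    gc: float,
) -> tuple[str, int, int]:
    """Place a coding region for ``protein`` into a transcript of ~total_len.

    Returns (sequence, nt_start, nt_end) of the ORF on the forward strand.
    An in-frame TAA is planted directly upstream of the ATG so the ORF
    classifies exactly as intended.
    """
    coding = _reverse_translate(rng, protein, gc)
    if completeness == "complete":
        core = "ATG" + coding[3:] if protein[0] == "M" else "ATG" + coding
        core += "TAA"
        budget = total_len - len(core) - 3
        utr5 = max(0, int(rng.integers(0, max(1, budget))) if budget > 0 else 0)
        seq = _random_nt(rng, utr5, gc) + "TAA" + core
        start = utr5 + 3
        end = start + len(core) - 3  # stop excluded
        seq += _random_nt(rng, max(0, total_len - len(seq)), gc)
    elif completeness == "partial_3prime":
        core = ("ATG" + coding[3:]) if protein[0] == "M" else ("ATG" + coding)
        utr5 = max(0, total_len - len(core) - 3)
        seq = _random_nt(rng, utr5, gc) + "TAA" + core
        start = utr5 + 3
        end = start + len(core)
    elif completeness == "partial_5prime":
        seq = coding + "TAA"
        start, end = 0, len(coding)
        seq += _random_nt(rng, max(0, total_len - len(seq)), gc)
    elif completeness == "internal":
        seq = coding
        start, end = 0, len(coding)
    else:  # pragma: no cover
        raise ValueError(completeness)
    return seq, start, end


def _sample_orf_protein(rng: np.random.Generator, aa_len: int, with_start: bool) -> str:
    body = _random_aa(rng, max(1, aa_len - (1 if with_start else 0)))
    return ("M" + body) if with_start else body


def generate_transcriptome(config: SimConfig) -> tuple[list[TranscriptRecord], TruthLabels]:
    """Deterministic truth-labelled assembly per the configuration."""
    rng = np.random.default_rng(config.seed)
    labels = TruthLabels()
    records: list[TranscriptRecord] = []

    special = (
        [("secreted", i) for i in range(config.n_secreted)]
        + [("tm", i) for i in range(config.n_tm)]
        + [("mito", i) for i in range(config.n_mito)]
        + [("cytosolic", i) for i in range(config.n_cytosolic)]
    )
    n_special = len(special)
    if config.n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_special > config.n_components:
        raise ValueError(
            f"infeasible config: {n_special} planted proteins need at least as "
            f"many components (got {config.n_components})"
        )

    iso_counts, iso_probs = zip(*config.isoform_dist)
    mix = np.array(config.class_mix)
    comp_classes = rng.choice(4, size=config.n_components, p=mix)

    repeat_cycle = list(config.repeat_counts) or [3]
    special_idx = 0
    for ci in range(config.n_components):
        comp = f"comp{ci}"
        n_sub = 2 if rng.random() < 0.05 else 1
        for si in range(n_sub):
            sub = f"{comp}_c{si}"
            n_iso = int(rng.choice(iso_counts, p=iso_probs))
            # draw the contig length
            length = int(np.clip(
                rng.lognormal(config.length_log_mu, config.length_log_sigma),
                config.min_length, config.max_length,
            ))
            if special_idx < n_special and si == 0:
                category = special[special_idx][0]
                special_idx += 1
                tid = f"{sub}_seq1"
                if category == "secreted":
                    n_rep = repeat_cycle[special_idx % len(repeat_cycle)]
                    prot, sp_len, sites, peps = make_secreted_protein(
                        rng, n_rep, config.repeat_motif
                    )
                    labels.sp_length[tid] = sp_len
                    labels.cleavage_sites[tid] = sites
                    labels.planted_peptides[tid] = peps
                    labels.repeat_count[tid] = n_rep
                elif category == "tm":
                    prot = make_tm_protein(rng)
                elif category == "mito":
                    prot = make_mito_protein(rng)
                else:
                    prot = make_cytosolic_protein(rng)
                # secreted/tm/mito need an evaluable N-terminus
                cls = (
                    "complete" if category != "secreted" or rng.random() < 0.75
                    else "partial_3prime"
                )
                # compact UTRs: keeps the planted ORF the longest in its
                # subcomponent, as for real neuropeptide-sized transcripts
                total = 3 * len(prot) + 6 + int(rng.integers(20, 80))
                seq, start, end = _embed_orf(rng, prot, cls, total, config.gc_target)
                labels.protein_category[tid] = category
                labels.protein_sequence[tid] = prot
                labels.orfs[tid] = ("+", start, end, cls)
            else:
                cls = COMPLETENESS_CLASSES[comp_classes[ci] if si == 0 else rng.integers(0, 4)]
                aa_len = max(12, (length - 40) // 3)
                prot = _sample_orf_protein(rng, aa_len, cls in ("complete", "partial_3prime"))
                tid = f"{sub}_seq1"
                seq, start, end = _embed_orf(rng, prot, cls, length, config.gc_target)
                labels.orfs[tid] = ("+", start, end, cls)
            records.append(TranscriptRecord(tid, seq))
            # additional isoforms: internal deletion variants (unlabelled)
            base = records[-1].sequence
            for iso in range(2, n_iso + 1):
                if len(base) < 3 * config.min_length:
                    break
                cut = int(rng.integers(len(base) // 3, 2 * len(base) // 3))
                width = int(rng.integers(len(base) // 10, len(base) // 4))
                variant = base[:cut] + base[cut + width:]
                if len(variant) >= config.min_length:
                    records.append(TranscriptRecord(f"{sub}_seq{iso}", variant))
    return records, labels


def generate_reads(
    assembly: Sequence[TranscriptRecord],
    theta: Mapping[str, float],
    n_reads: int,
    ambiguity: float = 0.0,
    seed: int = 0,
) -> list[ReadCompatibility]:
    """Draw read-compatibility records ∝ theta_i * length_i per subcomponent.

    An ``ambiguity`` fraction of reads is additionally made compatible with
    a sibling subcomponent of the same component (or a random other
    subcomponent when the component has no sibling).
    """
    if n_reads == 0:
        return []
    if not 0 <= ambiguity <= 1:
        raise ValueError("ambiguity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sub_len: dict[str, int] = {}
    for rec in assembly:
        sub = rec.subcomponent_id
        sub_len[sub] = max(sub_len.get(sub, 0), rec.length)
    subs = list(theta)
    missing = [s for s in subs if s not in sub_len]
    if missing:
        raise KeyError(f"theta references unknown subcomponents: {missing[:5]}")
    th = np.array([theta[s] for s in subs], dtype=float)
    if abs(th.sum() - 1.0) > 1e-6:
        raise ValueError("theta must sum to 1")
    w = th * np.array([sub_len[s] for s in subs])
    w = w / w.sum()
    comp_of = {s: parse_trinity_id(s)[0] for s in subs}
    siblings: dict[str, list[str]] = {}
    for s in subs:
        siblings.setdefault(comp_of[s], []).append(s)

    draws = rng.choice(len(subs), size=n_reads, p=w)
    ambiguous = rng.random(n_reads) < ambiguity
    reads = []
    for i, (d, amb) in enumerate(zip(draws, ambiguous)):
        origin = subs[d]
        ids = {origin}
        if amb and len(subs) > 1:
            sibs = [s for s in siblings[comp_of[origin]] if s != origin]
            pool = sibs if sibs else [s for s in subs if s != origin]
            ids.add(pool[int(rng.integers(0, len(pool)))])
        reads.append(ReadCompatibility(f"read{i:07d}", frozenset(ids)))
    return reads


def inject_contamination(
    assembly_a: Sequence[TranscriptRecord],
    assembly_b: Sequence[TranscriptRecord],
    config: SimConfig,
) -> tuple[list[TranscriptRecord], TruthLabels]:
    """Copy a fraction of A's components into B with mutations and low TPM.

    Returns the augmented B and labels mapping each injected subcomponent to
    (source subcomponent, expression ratio).
    """
    fraction, ratio, mut_rate = config.contamination
    if not 0 <= fraction <= 1:
        raise ValueError("contamination fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1)
    labels = TruthLabels()
    new_b = list(assembly_b)
    comps = sorted({r.component_id for r in assembly_a})
    n_pick = int(round(fraction * len(comps)))
    if n_pick == 0:
        return new_b, labels
    picked = set(rng.choice(comps, size=n_pick, replace=False))
    next_comp = 1 + max(
        (int(r.component_id[4:]) for r in assembly_b), default=-1
    )
    alloc: dict[str, str] = {}
    for rec in assembly_a:
        if rec.component_id not in picked:
            continue
        if rec.component_id not in alloc:
            alloc[rec.component_id] = f"comp{next_comp}"
            next_comp += 1
        comp, sub, iso = parse_trinity_id(rec.transcript_id)
        new_sub = f"{alloc[comp]}_c{sub.rsplit('_c', 1)[1]}"
        seq = list(rec.sequence)
        n_mut = rng.binomial(len(seq), mut_rate)
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = "ACGT"[(("ACGT".index(seq[pos]) if seq[pos] in "ACGT" else 0)
                               + int(rng.integers(1, 4))) % 4]
        new_b.append(TranscriptRecord(f"{new_sub}_seq{iso}", "".join(seq)))
        labels.contaminants[new_sub] = (sub, ratio)
    return new_b, labels


def apply_contamination_tpm(
    expr_b: Mapping[str, float],
    expr_a: Mapping[str, float],
    labels: TruthLabels,
) -> dict[str, float]:
    """Expression table for the augmented B: injected copies get ratio x source."""
    out = dict(expr_b)
    for new_sub, (src_sub, ratio) in labels.contaminants.items():
        out[new_sub] = ratio * expr_a[src_sub]
    return out
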