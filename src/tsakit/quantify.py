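"""TPM quantification with a lightweight EM allocation of ambiguous reads.

Expression is quantified at the Trinity subcomponent ("gene") level.  With
per-gene read counts :math:`c_i` and effective lengths :math:`l_i`,

.. math:: \\mathrm{TPM}_i = 10^6 \\cdot \\frac{c_i / l_i}{\\sum_j c_j / l_j}

so the column always sums to one million.  Reads compatible with several
genes (shared exons, isoform cross-mapping) are split by
expectation-maximisation: under the generative model in which a read arises
from gene *i* with probability proportional to its expected read count, the
E-step distributes each ambiguous read over its compatible set in proportion
to the current expected counts, and the M-step re-estimates the counts from
the fractional assignments.  Uniquely mapping reads therefore reproduce
``compute_tpm`` exactly, and the observed-data log-likelihood never
decreases across iterations.

Effective length is taken as the plain sequence length: no fragment-length
model is applied, which leaves relative abundances (the only thing TPM
encodes) untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionRecord:
    subcomponent_id: str
    est_count: float
    effective_length: float
    tpm: float


@dataclass(frozen=True)
class ReadCompatibility:
    read_id: str
    compatible_subcomponents: frozenset[str]

    def __post_init__(self) -> None:
        if not self.compatible_subcomponents:
            raise ValueError(f"read {self.read_id}: empty compatibility set")


def compute_tpm(
    counts_and_lengths: Iterable[tuple[str, float, float]]
) -> list[ExpressionRecord]:
    """Length-normalised relative abundance; all-zero counts give all-zero TPM."""
    items = list(counts_and_lengths)
    for sid, c, l in items:
        if l <= 0:
            raise ValueError(f"{sid}: effective length must be positive, got {l}")
        if c < 0:
            raise ValueError(f"{sid}: count must be non-negative, got {c}")
    rates = np.array([c / l for _, c, l in items], dtype=float)
    denom = rates.sum()
    tpms = rates / denom * 1e6 if denom > 0 else np.zeros_like(rates)
    return [
        ExpressionRecord(sid, float(c), float(l), float(t))
        for (sid, c, l), t in zip(items, tpms)
    ]


def em_allocate(
    reads: Iterable[ReadCompatibility],
    lengths: Mapping[str, float],
    max_iter: int = 1000,
    tol: float = 1e-3,
) -> list[ExpressionRecord]:
    """EM read allocation; ``tol`` is the max per-gene TPM change at convergence.

    Deterministic given input order: genes are indexed in the order of
    ``lengths`` and reads are collapsed to compatibility classes.
    """
    ids = list(lengths)
    index = {sid: i for i, sid in enumerate(ids)}
    lens = np.array([lengths[sid] for sid in ids], dtype=float)
    if np.any(lens <= 0):
        raise ValueError("all effective lengths must be positive")

    classes: dict[frozenset[str], int] = {}
    for read in reads:
        unknown = read.compatible_subcomponents - index.keys()
        if unknown:
            raise KeyError(
                f"read {read.read_id} references unknown gene(s): {sorted(unknown)}"
            )
        classes[read.compatible_subcomponents] = classes.get(read.compatible_subcomponents, 0) + 1

    n_reads = sum(classes.values())
    if n_reads == 0:
        return compute_tpm([(sid, 0.0, lengths[sid]) for sid in ids])
    members = [np.fromiter((index[s] for s in sorted(cs)), dtype=int) for cs in classes]
    weights = np.array(list(classes.values()), dtype=float)

    counts = np.full(len(ids), n_reads / len(ids), dtype=float)
    tpm = _tpm_from_counts(counts, lens)
    for _ in range(max_iter):
        new_counts = np.zeros_like(counts)
        for idx, w in zip(members, weights):
            p = counts[idx]
            s = p.sum()
            new_counts[idx] += w * (p / s if s > 0 else 1.0 / len(idx))
        new_tpm = _tpm_from_counts(new_counts, lens)
        delta = float(np.max(np.abs(new_tpm - tpm)))
        counts, tpm = new_counts, new_tpm
        if delta < tol:
            break
    return [
        ExpressionRecord(sid, float(c), float(l), float(t))
        for sid, c, l, t in zip(ids, counts, lens, tpm)
    ]


def em_log_likelihood(
    reads: Iterable[ReadCompatibility], counts: Mapping[str, float]
) -> float:
    """Observed-data log-likelihood of read compatibility sets given counts."""
    total = sum(counts.values())
    ll = 0.0
    for read in reads:
        p = sum(counts[s] for s in read.compatible_subcomponents) / total
        ll += math.log(p) if p > 0 else -math.inf
    return ll


def _tpm_from_counts(counts: np.ndarray, lens: np.ndarray) -> np.ndarray:
    rates = counts / lens
    denom = rates.sum()
    return rates / denom * 1e6 if denom > 0 else np.zeros_like(rates)


def expression_share(
    expr: Iterable[ExpressionRecord], subset_ids: Iterable[str]
) -> dict[str, float]:
    """TPM share and fold-enrichment of a gene subset versus the rest.

    ``fold`` is mean(subset) / mean(rest) with the subset excluded from the
    rest; NaN when either side is empty or the rest has zero mean.
    """
    records = list(expr)
    subset = set(subset_ids)
    ids = {r.subcomponent_id for r in records}
    missing = subset - ids
    if missing:
        raise KeyError(f"subset ids not in expression table: {sorted(missing)[:5]}")
    in_vals = [r.tpm for r in records if r.subcomponent_id in subset]
    out_vals = [r.tpm for r in records if r.subcomponent_id not in subset]
    sum_subset = float(sum(in_vals))
    sum_rest = float(sum(out_vals))
    total = sum_subset + sum_rest
    mean_subset = sum_subset / len(in_vals) if in_vals else math.nan
    mean_rest = sum_rest / len(out_vals) if out_vals else math.nan
    fold = (
        mean_subset / mean_rest
        if in_vals and out_vals and mean_rest > 0
        else math.nan
    )
    return {
        "sum_subset": sum_subset,
        "sum_rest": sum_rest,
        "percent_share": 100.0 * sum_subset / total if total > 0 else 0.0,
        "mean_subset": mean_subset,
        "mean_rest": mean_rest,
        "fold": fold,
    }


def top_expressed(
    expr: Iterable[ExpressionRecord],
    annotations: Mapping[str, Mapping[str, object]] | None = None,
    n: int = 30,
) -> pd.DataFrame:
    """Top-``n`` genes by TPM (ties broken by id), with optional annotations."""
    records = sorted(expr, key=lambda r: (-r.tpm, r.subcomponent_id))[: max(n, 0)]
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subcomponent_id": r.subcomponent_id,
            "tpm": r.tpm,
            "est_count": r.est_count,
            "effective_length": r.effective_length,
        }
        if annotations and r.subcomponent_id in annotations:
            row.update(annotations[r.subcomponent_id])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RSEM-like TSV interchange: id, length, expected_count, TPM
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "length", "expected_count", "TPM"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        ExpressionRecord(str(r.gene_id), float(r.expected_count), float(r.length), float(r.TPM))
        for r in df.itertuples(index=False)
    ]


def write_expression_tsv(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.subcomponent_id for r in records],
            "length": [r.effective_length for r in records],
            "expected_count": [r.est_count for r in records],
            "TPM": [r.tpm for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
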