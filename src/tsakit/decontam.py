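"""Cross-assembly contamination detection and removal.

Samples multiplexed on one sequencing run can bleed into each other at low
level.  A contig in assembly A is deemed a contaminant from assembly B when
it aligns to a B contig over at least 50 nt at >= 97% identity while being
expressed at most one tenth as highly (TPM) as the aligned B sequence — a
genuine transcript shared by related species would not show such an extreme
expression asymmetry.  Whole components are removed together, since all
isoforms of a contaminating locus originate from the same foreign source.

The aligner is a k-mer-seeded, greedily extended, gapped local aligner
(match +1, mismatch -2, gap -2.5, X-drop 20) — adequate for the
near-identical regime (>= 97%) the rule consults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import TranscriptRecord, parse_trinity_id
from .quantify import ExpressionRecord

MATCH = 1.0
MISMATCH = -2.0
GAP = -2.5
XDROP = 20.0


@dataclass(frozen=True)
class CrossMatch:
    query_id: str
    subject_id: str
    alignment_length: int
    percent_identity: float
    score: float = 0.0
    query_tpm: float | None = None
    subject_tpm: float | None = None


@dataclass(frozen=True)
class ContaminationVerdict:
    component_id: str
    removed: bool
    triggering_match: CrossMatch | None


def _run_len(a: str, b: str, i: int, j: int, limit: int = 20) -> int:
    n = 0
    while n < limit and i + n < len(a) and j + n < len(b) and a[i + n] == b[j + n]:
        n += 1
    return n


def _extend(a: str, b: str, i: int, j: int, di: int) -> tuple[float, int, int, int]:
    """Greedy gapped extension in one direction (di=+1 forward, -1 backward).

    Returns (best score, matches, mismatches+gaps columns, consumed columns)
    at the best-scoring prefix of the extension.
    """
    score = best = 0.0
    matches = mm = 0
    best_state = (0, 0)
    if di < 0:
        i, j = i - 1, j - 1
    while 0 <= i < len(a) and 0 <= j < len(b):
        if a[i] == b[j]:
            score += MATCH
            matches += 1
            i += di
            j += di
        else:
            # choose substitution vs. a single gap by exact-match lookahead
            if di > 0:
                la = _run_len(a, b, i + 1, j + 1)
                lg_a = _run_len(a, b, i, j + 1)  # gap in query
                lg_b = _run_len(a, b, i + 1, j)  # gap in subject
            else:
                la = _run_len(a[::-1], b[::-1], len(a) - i, len(b) - j)
                lg_a = _run_len(a[::-1], b[::-1], len(a) - 1 - i, len(b) - j)
                lg_b = _run_len(a[::-1], b[::-1], len(a) - i, len(b) - 1 - j)
            best_opt = max(
                (MISMATCH + la, "s"), (GAP + lg_a, "a"), (GAP + lg_b, "b"),
                key=lambda t: t[0],
            )[1]
            mm += 1
            if best_opt == "s":
                score += MISMATCH
                i += di
                j += di
            elif best_opt == "a":
                score += GAP
                j += di
            else:
                score += GAP
                i += di
        if score > best:
            best = score
            best_state = (matches, mm)
        if score < best - XDROP:
            break
    return best, *best_state, best_state[0] + best_state[1]


def align_pair(a: str, b: str, qpos: int, spos: int, k: int) -> CrossMatch | None:
    """Extend one exact k-mer seed into a local alignment."""
    f = _extend(a, b, qpos + k, spos + k, +1)
    r = _extend(a, b, qpos, spos, -1)
    score = k * MATCH + f[0] + r[0]
    matches = k + f[1] + r[1]
    columns = k + f[3] + r[3]
    if columns == 0:
        return None
    return CrossMatch(
        query_id="", subject_id="",
        alignment_length=columns,
        percent_identity=100.0 * matches / columns,
        score=score,
    )


def find_cross_matches(
    assembly_a: Sequence[TranscriptRecord],
    assembly_b: Sequence[TranscriptRecord],
    k: int = 21,
) -> list[CrossMatch]:
    """Best local alignment per query-subject pair sharing an exact k-mer."""
    if not assembly_a or not assembly_b:
        raise ValueError("both assemblies must be non-empty")
    index: dict[str, list[tuple[int, int]]] = {}
    for bi, rec in enumerate(assembly_b):
        s = rec.sequence
        for p in range(len(s) - k + 1):
            index.setdefault(s[p : p + k], []).append((bi, p))

    best: dict[tuple[int, int], CrossMatch] = {}
    for ai, rec in enumerate(assembly_a):
        q = rec.sequence
        tried: dict[int, list[tuple[int, int]]] = {}
        for qp in range(len(q) - k + 1):
            for bi, sp in index.get(q[qp : qp + k], ()):  # noqa: B020
                # skip seeds with the same diagonal already extended
                diag = qp - sp
                spans = tried.setdefault(bi, [])
                if any(d == diag and lo <= qp <= hi for d, (lo, hi) in spans):
                    continue
                m = align_pair(q, assembly_b[bi].sequence, qp, sp, k)
                if m is None:
                    continue
                spans.append((diag, (qp - m.alignment_length, qp + m.alignment_length)))
                m = replace(
                    m, query_id=rec.transcript_id, subject_id=assembly_b[bi].transcript_id
                )
                key = (ai, bi)
                if key not in best or m.score > best[key].score:
                    best[key] = m
    return [best[k_] for k_ in sorted(best)]


def flag_contaminants(
    matches: Iterable[CrossMatch],
    min_len: int = 50,
    min_identity: float = 97.0,
    max_tpm_ratio: float = 0.1,
) -> list[ContaminationVerdict]:
    """Component-level removal decisions; all thresholds are inclusive.

    A component is removed when any member sequence has a qualifying match:
    alignment >= ``min_len`` nt, identity >= ``min_identity`` %, and query
    TPM <= ``max_tpm_ratio`` x subject TPM.  An unexpressed subject
    (TPM 0) cannot certify contamination.
    """
    verdicts: dict[str, ContaminationVerdict] = {}
    for m in matches:
        if m.query_tpm is None or m.subject_tpm is None:
            raise ValueError(
                f"match {m.query_id} vs {m.subject_id} lacks attached TPM values"
            )
        comp = parse_trinity_id(m.query_id)[0]
        qualifies = (
            m.alignment_length >= min_len
            and m.percent_identity >= min_identity
            and m.subject_tpm > 0
            and m.query_tpm <= max_tpm_ratio * m.subject_tpm
        )
        cur = verdicts.get(comp)
        if qualifies and (cur is None or not cur.removed):
            verdicts[comp] = ContaminationVerdict(comp, True, m)
        elif cur is None:
            verdicts[comp] = ContaminationVerdict(comp, False, None)
    return [verdicts[c] for c in sorted(verdicts)]


def _tpm_lookup(expr) -> Mapping[str, float]:
    if isinstance(expr, Mapping):
        return expr
    return {r.subcomponent_id: r.tpm for r in expr}


def attach_tpm(
    matches: Iterable[CrossMatch],
    expr_query: Mapping[str, float] | Iterable[ExpressionRecord],
    expr_subject: Mapping[str, float] | Iterable[ExpressionRecord],
) -> list[CrossMatch]:
    """Attach subcomponent-level TPM of the two matched sequences."""
    eq, es = _tpm_lookup(expr_query), _tpm_lookup(expr_subject)
    out = []
    for m in matches:
        q_sub = parse_trinity_id(m.query_id)[1]
        s_sub = parse_trinity_id(m.subject_id)[1]
        if q_sub not in eq:
            raise KeyError(f"no TPM for matched query {q_sub}")
        if s_sub not in es:
            raise KeyError(f"no TPM for matched subject {s_sub}")
        out.append(replace(m, query_tpm=eq[q_sub], subject_tpm=es[s_sub]))
    return out


def decontaminate(
    assembly_a: Sequence[TranscriptRecord],
    assembly_b: Sequence[TranscriptRecord],
    expr_a,
    expr_b,
    min_len: int = 50,
    min_identity: float = 97.0,
    max_tpm_ratio: float = 0.1,
    k: int = 21,
    matches: Sequence[CrossMatch] | None = None,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Clean assembly A against assembly B; returns (clean assembly, verdicts).

    ``matches`` may carry a pre-computed hit set (e.g. parsed from a tabular
    file) in place of the internal aligner.
    """
    if not assembly_b:
        return list(assembly_a), pd.DataFrame(
            columns=["component_id", "removed", "query_id", "subject_id",
                     "alignment_length", "percent_identity", "query_tpm", "subject_tpm"]
        )
    if matches is None:
        matches = find_cross_matches(assembly_a, assembly_b, k=k)
    matches = attach_tpm(matches, expr_a, expr_b)
    verdicts = flag_contaminants(matches, min_len, min_identity, max_tpm_ratio)
    removed = {v.component_id for v in verdicts if v.removed}
    clean = [r for r in assembly_a if r.component_id not in removed]
    rows = []
    for v in verdicts:
        m = v.triggering_match
        rows.append(
            {
                "component_id": v.component_id,
                "removed": v.removed,
                "query_id": m.query_id if m else None,
                "subject_id": m.subject_id if m else None,
                "alignment_length": m.alignment_length if m else None,
                "percent_identity": m.percent_identity if m else None,
                "query_tpm": m.query_tpm if m else None,
                "subject_tpm": m.subject_tpm if m else None,
            }
        )
    return clean, pd.DataFrame(rows)
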