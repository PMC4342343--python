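import numpy as np
import pytest
from Bio.Seq import Seq

from tsakit.core import TranscriptRecord
from tsakit.orfs import (
    OrfRecord,
    completeness_summary,
    completeness_summary_from_counts,
    find_orfs,
    length_histogram,
    longest_orf_per_group,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle: translate each frame wholesale, split the
# peptide string on stops, classify chunks by their boundaries
# ---------------------------------------------------------------------------

def _translate_frame(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(str(Seq(codon).translate()) if "N" not in codon else "X")
    return "".join(out)


def _oracle_orfs(seq: str, min_aa: int):
    found = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            aa = _translate_frame(s[frame:])
            chunks = aa.split("*")
            codon_off = 0
            for ci, chunk in enumerate(chunks):
                followed_by_stop = ci < len(chunks) - 1
                if "M" in chunk:
                    m = chunk.index("M")
                    pep = chunk[m:]
                    cls = "complete" if followed_by_stop else "partial_3prime"
                    a = codon_off + m
                elif ci == 0 and chunk:
                    pep = chunk
                    cls = "partial_5prime" if followed_by_stop else "internal"
                    a = 0
                else:
                    pep = None
                if pep and len(pep) >= min_aa:
                    lo = frame + 3 * a
                    hi = lo + 3 * len(pep)
                    if strand == "-":
                        lo, hi = L - hi, L - lo
                    found.add((strand, lo, hi, pep, cls))
                codon_off += len(chunk) + 1
    return found


def _as_set(orfs):
    return {(o.strand, o.nt_start, o.nt_end, o.peptide, o.completeness) for o in orfs}


def test_minimal_complete_orf():
    rec = TranscriptRecord("comp0_c0_seq1", "ATGAAATAA")
    complete = [o for o in find_orfs(rec, 2) if o.completeness == "complete"]
    assert len(complete) == 1
    assert complete[0].peptide == "MK"
    assert (complete[0].nt_start, complete[0].nt_end) == (0, 6)  # stop excluded


def test_runoff_orf_is_3prime_partial():
    rec = TranscriptRecord("comp0_c0_seq1", "ATGAAAAAA")
    partial = [o for o in find_orfs(rec, 2) if o.completeness == "partial_3prime"]
    assert [o.peptide for o in partial] == ["MKK"]


def test_n_codons_translate_to_x_and_cannot_start():
    rec = TranscriptRecord("comp0_c0_seq1", "ATNAAATAA")  # broken ATG
    orfs = find_orfs(rec, 2)
    assert all(o.completeness != "complete" for o in orfs if o.strand == "+")
    p5 = [o for o in orfs if o.completeness == "partial_5prime" and o.strand == "+"]
    assert p5 and p5[0].peptide == "XK"


def test_finder_matches_bruteforce_oracle_on_random_sequences():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(60, 400))
        seq = "".join("ACGTN"[i] for i in rng.choice(5, size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        rec = TranscriptRecord("comp0_c0_seq1", seq)
        assert _as_set(find_orfs(rec, 10)) == _oracle_orfs(seq, 10)


def test_reverse_complement_maps_strands():
    rng = np.random.default_rng(7)
    for _ in range(30):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 240))
        rc = str(Seq(seq).reverse_complement())
        fwd = _as_set(find_orfs(TranscriptRecord("comp0_c0_seq1", seq), 8))
        rev = _as_set(find_orfs(TranscriptRecord("comp0_c0_seq1", rc), 8))
        L = len(seq)
        flipped = {
            ("+-"[s == "+"], L - hi, L - lo, pep, cls) for s, lo, hi, pep, cls in fwd
        }
        assert flipped == rev


def test_longest_orf_per_group_length_and_tie_rules():
    mk = lambda tid, pep, cls: OrfRecord(tid, "+", 0, 0, 3 * len(pep), pep, cls)
    a = mk("comp1_c0_seq1", "M" * 120, "internal")
    b = mk("comp1_c0_seq2", "M" * 300, "complete")
    assert longest_orf_per_group([a, b]) == [b]
    # equal length: completeness rank breaks the tie
    c = mk("comp2_c0_seq1", "A" * 50, "internal")
    d = mk("comp2_c0_seq2", "A" * 50, "complete")
    assert longest_orf_per_group([c, d], "component") == [d]
    # grouping by subcomponent yields one record per subcomponent
    e = mk("comp3_c0_seq1", "A" * 10, "complete")
    f = mk("comp3_c1_seq1", "A" * 20, "complete")
    g = mk("comp4_c0_seq1", "A" * 30, "complete")
    assert len(longest_orf_per_group([e, f, g], "subcomponent")) == 3


def test_completeness_percentages_match_published_style_rounding():
    table = completeness_summary_from_counts(
        {"complete": 17313, "partial_5prime": 6631, "partial_3prime": 4296, "internal": 5538}
    )
    by_class = dict(zip(table["class"], table["percent"]))
    assert by_class["complete"] == 51.3
    assert by_class["partial_5prime"] == 19.6
    assert by_class["partial_3prime"] == 12.7
    assert by_class["internal"] == 16.4
    assert table[table["class"] == "total"]["count"].item() == 33778


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"complete": 1}, [100.0, 0.0, 0.0, 0.0]),
        ({c: 1 for c in ("complete", "partial_5prime", "partial_3prime", "internal")},
         [25.0, 25.0, 25.0, 25.0]),
        ({}, [0.0, 0.0, 0.0, 0.0]),
    ],
)
def test_completeness_summary_edge_cases(counts, expected):
    table = completeness_summary_from_counts(counts)
    assert list(table["percent"][:4]) == expected


def test_completeness_percents_sum_to_100(rng):
    counts = {c: int(n) for c, n in zip(
        ("complete", "partial_5prime", "partial_3prime", "internal"),
        rng.integers(1, 10000, 4))}
    table = completeness_summary_from_counts(counts)
    assert sum(table["percent"][:4]) == pytest.approx(100.0, abs=0.2)


def test_length_histogram_binning_and_conservation(rng):
    df = length_histogram([250, 260, 399, 400], "nt", bin_width=100, origin=200)
    assert list(df["count"]) == [2, 1, 1]
    assert list(df["bin_lo"]) == [200, 300, 400]
    assert length_histogram([], "nt").empty
    lengths = [int(x) for x in rng.integers(200, 3000, 500)]
    df = length_histogram(lengths, "nt")
    assert df["count"].sum() == 500


def test_length_histogram_per_class_columns():
    df = length_histogram([(120, "complete"), (130, "internal"), (170, "complete")], "aa")
    row = df[df["bin_lo"] == 99].iloc[0]
    assert row["complete"] == 1 and row["internal"] == 1
    assert df[df["bin_lo"] == 149].iloc[0]["complete"] == 1
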