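import numpy as np
import pytest

from tsakit.secretome import (
    KYTE_DOOLITTLE,
    ProteinSeq,
    classify_protein,
    deduplicate_proteins,
    kyte_doolittle_profile,
    predict_mito_targeting,
    predict_signal_peptide,
    predict_tm_helices,
    secretome_filter,
)
from tsakit.simulate import (
    make_cytosolic_protein,
    make_mito_protein,
    make_secreted_protein,
    make_signal_peptide,
)

CANONICAL_SP = "MKTLLILAVLAAVSSA"  # n (K), h (hydrophobic core), c (A-S-A end)


def test_kd_profile_constant_sequences():
    assert kyte_doolittle_profile("I" * 17).values == pytest.approx([4.5])
    assert kyte_doolittle_profile("G" * 17).values == pytest.approx([-0.4])
    assert len(kyte_doolittle_profile("AAA")) == 0  # shorter than the window


def test_kd_profile_matches_naive_windowed_mean(rng):
    aas = list(KYTE_DOOLITTLE) + ["X"]
    pep = "".join(aas[i] for i in rng.integers(0, len(aas), 100))
    prof = kyte_doolittle_profile(pep, 17)
    naive = [
        sum(KYTE_DOOLITTLE.get(a, 0.0) for a in pep[i : i + 17]) / 17
        for i in range(len(pep) - 16)
    ]
    assert prof.values == pytest.approx(naive)
    with pytest.raises(ValueError, match="odd"):
        kyte_doolittle_profile(pep, 16)


def test_tm_detection_positive_negative_and_two_blocks():
    polar = "S" * 60
    block = "L" * 30
    one = predict_tm_helices(kyte_doolittle_profile(polar + block + polar))
    assert len(one) == 1
    lo, hi = one[0]
    assert lo <= 61 + 8 and hi >= 90 - 8  # covers the Leu block +- window margin
    assert predict_tm_helices(kyte_doolittle_profile("S" * 120)) == []
    two = predict_tm_helices(kyte_doolittle_profile(polar + block + "S" * 40 + block + polar))
    assert len(two) == 2


def test_signal_peptide_canonical_and_negative():
    score, cleave = predict_signal_peptide(CANONICAL_SP + "EDQSTNNAYPQDSTNNAY")
    assert score >= 0.5
    assert cleave == len(CANONICAL_SP)
    neg, _ = predict_signal_peptide("M" + "S" * 40 + "EDQ")
    assert neg < 0.5  # no h-region
    with pytest.raises(ValueError, match="methionine"):
        predict_signal_peptide("KTLLIL")


def test_signal_peptide_on_generated_families():
    rng = np.random.default_rng(99)
    planted = [make_signal_peptide(rng) + "EDQSTNNAYPQDSTNNAY" for _ in range(100)]
    assert all(predict_signal_peptide(p)[0] >= 0.5 for p in planted)
    cytosolic = [make_cytosolic_protein(rng) for _ in range(100)]
    neg = sum(predict_signal_peptide(p)[0] < 0.5 for p in cytosolic)
    assert neg >= 95


def test_mito_targeting_positive_negative():
    rng = np.random.default_rng(5)
    mito = [make_mito_protein(rng) for _ in range(100)]
    assert sum(predict_mito_targeting(p) for p in mito) >= 90
    acidic = "M" + "EDED" * 10
    assert not predict_mito_targeting(acidic)
    secreted = [make_secreted_protein(rng, 3, "FMRF")[0] for _ in range(100)]
    assert sum(predict_mito_targeting(p) for p in secreted) <= 5


def _mk(seq, cls="complete"):
    return classify_protein(ProteinSeq("p1", seq, cls))


def test_cascade_verdicts():
    mature = "EDQSTNNAYPQDSTNNAY" * 6
    assert _mk(CANONICAL_SP + mature).verdict == "secreted"
    # single TM ending within the first 60 aa is tolerated (mis-called SP)
    early_tm = CANONICAL_SP + "L" * 28 + mature
    call = _mk(early_tm)
    assert call.verdict == "secreted"
    assert len(call.tm_segments) == 1 and call.tm_segments[0][1] <= 60
    # a late TM helix disqualifies
    late_tm = CANONICAL_SP + mature[:90] + "L" * 30 + mature
    assert _mk(late_tm).verdict == "rejected_tm"
    # no start codon -> not evaluable
    assert _mk("KTLL" + mature).verdict == "rejected_incomplete"
    assert _mk(CANONICAL_SP + mature, cls="partial_5prime").verdict == "rejected_incomplete"


def test_cascade_secreted_invariant_and_exclusivity(protein_bench):
    _, truth = protein_bench
    calls = secretome_filter(
        ProteinSeq(tid, seq, truth.orfs[tid][3])
        for tid, seq in truth.protein_sequence.items()
    )
    verdicts = {
        "secreted", "rejected_no_signal", "rejected_mito", "rejected_tm",
        "rejected_incomplete",
    }
    for c in calls:
        assert c.verdict in verdicts
        if c.verdict == "secreted":
            assert c.sp_score >= 0.5 and not c.mito_flag
            assert c.sp_cleavage_pos is not None and c.sp_cleavage_pos <= 45
            assert len(c.tm_segments) == 0 or (
                len(c.tm_segments) == 1 and c.tm_segments[0][1] <= 60
            )


def test_monotone_ablation_flips_verdicts():
    rng = np.random.default_rng(17)
    seq, sp_len, _, _ = make_secreted_protein(rng, 3, "FMRF")
    call = classify_protein(ProteinSeq("x", seq))
    assert call.verdict == "secreted"
    # deleting the signal peptide (restoring a start M) removes the signal
    ablated = "M" + seq[sp_len:]
    assert classify_protein(ProteinSeq("x", ablated)).verdict == "rejected_no_signal"
    # inserting a late poly-Leu block creates a disqualifying TM helix
    long_seq = seq + "STNQYD" * 20
    with_tm = long_seq[:100] + "L" * 25 + long_seq[100:]
    assert classify_protein(ProteinSeq("x", with_tm)).verdict == "rejected_tm"


def test_deduplicate_exact_and_substring():
    a = ProteinSeq("a", "MKLV")
    b = ProteinSeq("b", "MKLV")
    c = ProteinSeq("c", "MKLVVA")
    d = ProteinSeq("d", "KLVV")
    out = deduplicate_proteins([a, b, c, d])
    assert [p.protein_id for p in out] == ["c"]
    # order invariance
    rng = np.random.default_rng(0)
    pool = [ProteinSeq(f"p{i}", s) for i, s in enumerate(["MAAA", "AAA", "MAAA", "MQQQV", "QQQ"])]
    ref = deduplicate_proteins(pool)
    for _ in range(5):
        rng.shuffle(pool)
        assert deduplicate_proteins(pool) == ref
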