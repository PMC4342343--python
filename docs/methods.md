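# Methods

This note documents the models and rules each `tsakit` stage implements,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical conventions chosen where the design was open.

## Assembly metrics

N50 is computed on total assembled bases: the largest length L such that
contigs of length ≥ L jointly cover at least half of all bases, with ties
resolved at the contig length where the descending cumulative sum first
reaches half. %GC is G+C over A+C+G+T only; N is excluded from both
numerator and denominator, and an assembly consisting solely of N reports
NaN rather than a misleading 0 or 100. Identifiers without a `_seq` suffix
(subcomponent-level ids, as in expression tables) are accepted and map to
isoform 1.

## ORF discovery and completeness

All six frames are scanned stop-to-stop with the standard genetic code.
Codons containing N translate to X; X counts toward peptide length but can
serve neither as start nor stop. Within a stop-delimited segment, an ORF
is reported from the segment's first ATG (complete if the segment ends at
a stop, 3′-partial if it runs off the contig); a segment that is open at
the contig's 5′ boundary and contains no ATG is reported whole
(5′-partial or internal). Reporting the ATG-initiated ORF *or* the open
run — never both — keeps one segment from being counted under two
classes. The stop codon is excluded from the peptide and from coordinates,
which are 0-based half-open on the forward strand for both strands.

The default minimum ORF length is 100 aa, the conventional default of
TransDecoder-style peptide prediction; it is configurable everywhere.
No hexamer/Markov coding-likelihood model is applied: selection among
ORFs is purely by length and completeness class. Consequently long
antisense open runs can out-length a genuine coding ORF; the secretome
extraction below therefore filters to start-bearing classes *before*
taking the longest ORF per subcomponent.

## Unigene reduction and E-value summaries

LCPC keeps the longest contig per component (ties: smaller id). BHPC
keeps the highest-bitscore hit per component among hits passing the
E-value cutoff (ties: lower E-value, then smaller subject id). Hit tables
are the de-facto 12-column tabular dialect; extra columns are ignored.

E-value bins are half-open intervals (≤ upper, > lower) over strictly
decreasing edges. An E-value of exactly 0 is kept as zero (no flooring)
and joins the terminal bin, so an edge list ending in 0 yields k−1 bins
for k edges, the last reading "≤ edge, = 0". Percentages are reported to
one decimal, against a caller-supplied total (e.g. the full query-set
size) or the binned-hit count.

## TPM and EM read allocation

TPM_i = 10⁶·(c_i/l_i)/Σ_j(c_j/l_j), computed at the subcomponent ("gene")
level. Effective length is the plain sequence length — no fragment-length
correction, since only relative abundances are consumed downstream.
All-zero counts yield all-zero TPM rather than NaN.

Ambiguous reads are split by EM under the generative model in which a
read originates from gene *i* with probability proportional to its
expected read count (abundance × length). The E-step distributes each
compatibility class over its members proportionally to current expected
counts; the M-step re-estimates counts from the fractional assignments.
This choice — rather than weighting by abundance alone — is what makes
the observed-data log-likelihood non-decreasing at every iteration and
lets EM on uniquely-mapping reads reproduce the closed-form TPM exactly.
Initialisation is uniform counts; convergence when the largest per-gene
TPM change falls below 10⁻³ (default), capped at 1,000 iterations;
deterministic given input order.

Caveat on identifiability: EM allocates ambiguity by relative abundance
within each compatible set. When the probability that a read is observed
as ambiguous depends on which gene it came from (non-symmetric sibling
structure), the mixture model is misspecified and estimates for the
rarely-sibling genes are biased. The recovery benchmark therefore uses
symmetric sibling ambiguity, which is also what shared-exon isoform
groups produce.

## Secretome cascade

External predictors are not called; each is replaced by a transparent,
deterministic surrogate that keeps the published decision contract (a
[0,1] score against 0.5; residue intervals; a boolean), so the cascade's
thresholds retain their meaning:

* **Signal peptide.** Three binary sub-features on residues 1–45: an
  n-region basic residue (K/R within residues 2–8); an h-region (a ≥ 7
  residue window within residues 5–30 with mean Kyte-Doolittle hydropathy
  ≥ 1.8); and a c-region (−3,−1) site at some position 15–45 with the −1
  residue in {A,G,S,C,T,Q} and −3 in {A,G,S,C,T,V,I,L}. A fixed logistic
  (bias −4.0; weights 1.0, 3.5, 1.5) combines them, chosen so that all
  three features clear 0.5 while a missing h-region can never reach it.
  The cleavage position is the best-scoring valid site, preferring
  A/G/S at −1 and earlier positions.
* **TM helices.** Maximal runs of window-17 hydropathy centres above 1.6
  (classical hydropathy-analysis convention), runs separated by fewer
  than 5 centres merged, runs of ≥ 15 centres kept and widened by half a
  window into residue coordinates.
* **Mitochondrial presequence.** Residues 2–30 must contain ≥ 4 R, ≤ 1
  D/E and ≥ 2 S/T, and the composite presequence strength
  (0.15·R + 0.1·S/T − 0.2·acid, capped at 1) must exceed the
  signal-peptide score — a stronger signal-peptidase interpretation wins
  ambiguous N-termini.

The cascade order is: no start methionine (or a 5′-truncated ORF class) →
`rejected_incomplete`; score < 0.5 → `rejected_no_signal`; mito →
`rejected_mito`; then `secreted` iff there is no TM segment or exactly
one whose **end** lies within the first 60 residues (such early helices
are nearly always the signal peptide re-called as TM). Secreted calls are
split into full-length versus C-terminally-truncated by ORF class.

Input to the cascade is the start-bearing (complete or 3′-truncated)
longest ORF per subcomponent, deduplicated by exact identity and exact
substring (longest representative kept, ties to the smaller id).
Similarity-threshold clustering (CD-HIT-style) is deliberately not
used: exact semantics keep the stage order-independent and testable; a
percent-identity mode is left as an extension.

## Prohormone processing

Cleavage sites sit immediately C-terminal to the basic residue(s) of any
dibasic pair (KR, RR, KK, RK) — maximal K/R runs merge into a single site
consuming the whole run — or of a monobasic R with a helper K/R at
−4, −6 or −8. Two documented refinements: basic residues consumed by a
dibasic site cannot double as the monobasic helper (otherwise tandem
`…GKR|FMRF…` repeats would be cut inside every repeat), and monobasic
sites directly followed by proline are suppressed (convertases disfavour
P at P1′). Sites inside the signal peptide are discarded.

Each liberated fragment is trimmed of flanking K/R runs; a then-trailing
glycine is removed and the peptide flagged amidated. Derivation is
conservative: kept residues + trimmed basics + removed glycines
reconstruct the mature region exactly, and the test suite asserts this on
randomised precursors. Repeat counting compares the processed
(amidation-normalised) peptide against the motif.

## Decontamination

The aligner is k-mer-seeded (k = 21), with greedy gapped extension
(match +1, mismatch −2, gap −2.5, X-drop 20) and one best alignment per
query-subject pair; identity is matches over alignment columns. These
scores approximate megablast behaviour in the only regime the rule
consults (≥ 97% identity); tests cross-check identities against a full
Smith-Waterman oracle. A pre-computed tabular hit file can replace the
internal aligner.

A component is removed when **any** member contig has a match of
≥ 50 nt, ≥ 97% identity, and query TPM ≤ 0.1 × subject TPM — all three
comparisons inclusive. TPMs are the subcomponent-level values of the two
matched sequences. An unexpressed subject (TPM 0) cannot certify
contamination. Removal is component-atomic, and cleaning is directional:
one focal assembly is cleaned against each other assembly in turn;
symmetric cleaning is two calls with roles swapped.

## Synthetic data: what it emulates, what it does not

Contig lengths are log-normal (median ≈ 363 nt, σ = 1.2, clipped to
200–20,000 nt), giving the heavy right tail and the 200–399 nt peak
typical of these assemblies. The GC target (39.4% by default) is hit by
drawing UTR bases at the target frequency and steering synonymous-codon
choice per base, with amino-acid sampling mildly biased toward
AT-rich-codon residues; realized GC stays within ±2 points. Completeness
classes are sampled from a configurable mix (defaults ≈ 51/20/13/16%) and
enforced structurally: an in-frame stop is planted directly upstream of
each ATG so every planted ORF classifies exactly as labelled, and
open-ended classes use M-free amino-acid streams so no spurious in-frame
start exists.

Protein categories are parameterised families randomised within
rule-satisfying bounds (not fixed strings, so the predictors cannot
trivially memorise their generator): signal peptides with randomised
n/h/c regions; secreted precursors with an acidic spacer, a 60–90 aa
propeptide domain (keeping precursors in the 100–150 aa range ORF calling
reports), `motif-G-KR` repeat blocks and a polar tail; membrane proteins
as signal-anchored chains with a 30–34 aa hydrophobic block after residue
60; mitochondrial proteins with a 29–40 aa arginine-rich presequence;
cytosolic proteins with polar-biased N-termini. Protein-bearing
transcripts get compact UTRs so the planted ORF is its subcomponent's
longest. Reads are drawn ∝ abundance × length; an ambiguity fraction is
additionally made compatible with a sibling subcomponent. Contamination
copies a fraction of components into a second assembly with per-base
substitutions and an assigned expression ratio.

Not emulated: sequencing errors and quality scores, fragment-length
effects, indel polymorphism between assemblies, chimeric contigs,
non-coding RNA, and homology structure for BLAST-style annotation (hit
tables in tests are constructed directly). Passing the synthetic
benchmarks therefore demonstrates that each stage implements its rule
correctly and recovers planted structure at the stated noise levels — not
that the surrogate predictors match trained tools on real proteomes.

## Problem sizes and determinism

Benchmarks run at deliberately moderate scale: 5,000 components for
distributional checks, 520 components / 520 planted proteins for the
secretome benchmark, 50,000 reads for EM recovery, 200 components with 20
planted contaminants for decontamination. All randomness flows from
numpy `default_rng` seeded from a single integer; regenerating with the
same seed is byte-identical, and the pipeline writes a config hash (I/O
paths excluded) plus a key=value run log so two runs of the same analysis
can be diffed file by file.
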