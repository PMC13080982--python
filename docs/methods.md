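# Methods

## Model

A SMILES-encoded dataset D is modelled as a sequence of independent draws
from a multinomial distribution over a vocabulary V = H ∪ Σ_res, where H is
a learned set of substrings (the codebook, each entry given a fresh
codeword) and Σ_res are the residual base symbols still present after all
substitutions. The hypothesis H is chosen by Minimum Message Length: the
score of a candidate codebook is the length in bits of a three-part message
that would transmit (1) the substrings themselves, (2) the multinomial
parameters and vocabulary counts via the Wallace–Freeman (MML87) closed
form, and (3) the particular arrangement of the N vocabulary items, i.e. the
log multinomial coefficient. Sender and receiver are assumed to have
pre-agreed on the relative frequencies P(s) of base symbols in the original
dataset; that symbol model prices codebook substrings in part 1 and is
frozen for the whole search — updating it mid-search would change the
receiver's decoder without having been transmitted. The receiver is likewise
assumed to know the per-molecule token counts, which is what licenses
treating part 3 as a pure arrangement cost and keeps molecules independent:
substrings never span molecule boundaries.

Model selection is a greedy loop. Every contiguous token run of length
2..`max_substring_len` in the *current* encoded stream is a candidate
(single tokens are excluded: replacing one symbol by another is a pure
relabelling that leaves parts 2 and 3 unchanged and strictly grows part 1).
Candidates are filtered by the substructure validity rules, scored by the
exact change ΔM in total message length — no heuristic surrogate — and the
best strictly improving candidate is accepted: all its non-overlapping,
leftmost-first occurrences are replaced by a fresh codeword. Because
candidates are drawn from the encoded stream they may contain earlier
codewords, so effective substructure size is unbounded even with a small
enumeration cap. When an accepted substring consumes instances of an earlier
codeword, that entry's count falls with the stream; an entry whose count
reaches zero is dropped from the codebook and vocabulary. Entries store
their full base-symbol expansion, so decoding is a single replacement pass
and entry costs are independent of later removals. Each acceptance strictly
decreases a quantity bounded below on finite data, so the search terminates
without an iteration cap.

## Tokenization and the validity filter

Tokenization is character-level except the two-letter organic-subset atoms
(Cl, Br) and `%nn` ring-closure labels, which are single symbols;
bracket-atom interiors stay character tokens because the filter rules reason
about individual characters. The validity rules are:

1. *Brackets.* Square brackets must pair exactly — a truncated bracket atom
   is meaningless. A round `)` must close a `(` opened inside the substring;
   a trailing unclosed `(` is tolerated, provided the substring contains at
   least one atom, on the reading that a branch opening can be completed by
   rightward extension while a dangling close has no anchor. This asymmetry
   is a deliberate calibration: it makes the worked five-token example
   molecule C(=O) yield exactly 8 valid substrings out of its 15, the
   anchoring figure for the filter, while symmetric strict matching would
   yield only 5.
2. *Bonds and stereocentres.* Each of `= # - / \ @` must be adjacent to an
   atom token within the substring.
3. *Ring closures.* Every ring label must occur an even number of times;
   digits inside a matched bracket atom (H-counts, charges, isotopes) are
   exempt, as they are not ring bonds.
4. The disconnection dot `.` is forbidden (configurable set).

Validity is always checked on a candidate's base-symbol *expansion*, so
codeword-containing candidates are admitted exactly when the substructure
they denote is admissible.

## Numerical conventions

* All logarithms are base 2; codelengths are real-valued bits, never rounded
  — MML compares ideal codelengths, no bitstream is emitted.
* `log_star(n)` defaults to the convention "first term `log₂ n` always,
  subsequent iterated-log terms only while strictly greater than 1", which
  anchors `log*(4) = 2` as in the worked seven-bit example; the literal
  series (`log*(4) = 3`) and Rissanen's normalised variant are selectable.
* The codebook size is announced with the same code; an empty codebook is a
  single flag bit (the code covers n ≥ 1 only, and some finite convention is
  required even though a converged codebook is never empty in practice).
* Parts 2 and 3 are evaluated through `scipy.special.gammaln`, exact to
  float precision at any N; the test suite certifies part 3 against
  big-integer multinomial coefficients and part 2 against 60-digit
  arbitrary-precision evaluation to 1e−9 bits.
* A one-item vocabulary makes the MML87 expression degenerate
  (`log((M−1)π) → −∞`); with no free parameters and counts implied by N,
  its P2 is defined as 0 (and P3 is 0 regardless). `part2` itself rejects
  M < 2; the special case lives only in the total.
* Acceptance requires ΔM < −10⁻⁹ bits, guarding termination against float
  noise in near-ties. Ties are broken deterministically: longer expansion
  first, then lexicographic order of the expansion text. The incremental
  scorer used by the search is certified step-by-step against a brute-force
  oracle that re-performs each substitution and recomputes all three parts
  from scratch.
* Uniform prior over the multinomial parameters is taken as already absorbed
  in the MML87 expression as written; no extra prior term is added.

## Fingerprints and evaluation

A molecule's fingerprint is the integer vector of non-overlapping,
leftmost-first occurrence counts of each codebook substructure in its
(canonical) SMILES token stream — the same policy as the codec, so a
singleton dataset fingerprints exactly as it would compress. An alternative
`smarts` mode counts RDKit graph matches of the wildcard-completed SMARTS
patterns instead; the two modes are never mixed in one matrix. The
representation discards connectivity between substructures by design.

The evaluation harness fits `sklearn` ridge regressions on five random
75/25 train/test splits, selecting the penalty from {0.001, 0.01, 0.1, 1}
by closed-form leave-one-out CV on the training set; count features enter
unscaled. Representations are compared across datasets with two-sided
Wilcoxon signed-rank tests (exact null for ≤ 25 pairs) under
Benjamini–Hochberg correction at α = 0.05. Baselines come from RDKit:
166-bit MACCS keys and a radius-2 Morgan fingerprint hashed to the same
length as the codebook fingerprint for that dataset; they are validated for
shape and determinism only.

## Synthetic data

The generator composes molecules by concatenating 2–4 fragments from a
curated list of simple valid pieces (C, N, O, short chains, benzene,
cyclopropane, one-atom branches); concatenation of these fragments is
always parseable, which RDKit verifies with bounded resampling. A motif
(default the amide `C(=O)N`) is inserted at a random fragment boundary in
exactly ⌈rate·n⌉ molecules, and unplanted molecules are resampled if they
contain the motif by accident, so ground truth is exact. The QSAR variant
plants several motifs at random multiplicities and emits
`activity = Σ βᵢ·countᵢ + N(0, σ²)` with counts measured on the emitted
SMILES, so a noiseless run is exactly linear in motif counts. Defaults (100
molecules, plant rate 0.5, β = (2, −1, 0.5), σ = 0.1) are sized so that a
planted motif is decisively compressive within a few iterations while runs
stay interactive. These molecules exercise the token machinery, not
chemistry: they are small, repetitive, and far more compressible than
curated bioactivity corpora (the worked example compresses ~59%; real
corpora compress far less), so passing tests demonstrate correctness of the
calculus and search, not expected compression rates or predictive gains on
real data.

## Problem sizes and limitations

Tests and examples run at desk scale: datasets of 6–100 synthetic molecules,
enumeration caps of 4–6, a few to ten iterations — sizes chosen so the
brute-force oracles (exhaustive candidate rescoring, exact factorials,
arbitrary-precision gamma) remain feasible companions to every run.
Corpus-scale behaviour (millions of molecules, hundreds of iterations,
cap 8) uses the same code paths but is not exercised here; enumeration cost
grows steeply with the cap, and the greedy, no-lookahead search inherits the
usual risk of locally optimal codebooks. The search space is restricted to
contiguous SMILES substrings, so substructures that no canonical SMILES
writes contiguously are invisible, and the same group may surface under
multiple SMILES spellings (the ring-relabel deduplication removes only the
numbering artifact). Candidate occurrence replacement is leftmost-first
non-overlapping; other orders are conceivable but nondeterministic or
costlier, and the choice only matters for self-overlapping patterns.
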