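# fgcompress

Unsupervised discovery of molecular substructures by data compression, and
count-based fingerprints built from them.

Chemists describe molecules in terms of functional groups — amide, carbonyl,
benzene — but there is no canonical, objectively derived list of them.
`fgcompress` treats the question as one of compression: a SMILES-encoded
dataset is modelled as independent draws from a multinomial distribution over
a dictionary of substrings (a *codebook*), and the Minimum Message Length
(MML) principle selects the codebook that minimises the total number of bits
needed to transmit both the dictionary and the dataset encoded with it.
Substrings that pay for their own description by shortening the data are,
empirically, exactly the familiar functional groups; counting their
occurrences per molecule gives a compact, collision-free integer fingerprint
for QSAR regression. The intended users are cheminformaticians who want
dataset-specific substructure vocabularies or interpretable count features
for linear models.

## The message-length calculus

For a codebook H = {(s₁, p₁), …} over SMILES symbol alphabet Σ, the cost in
bits of the three-part message is

* **P1 — the substrings.**  Each substring Sᵢ costs
  `C(Sᵢ) = log*|Sᵢ| − Σ_{s∈Σ} count(s, Sᵢ) · log₂ P(s)`,
  where `log*` is the log-star universal integer code and P(s) is the
  symbol's relative frequency in the original dataset (pre-agreed, frozen).
  `P1 = log*|H| + Σᵢ C(Sᵢ)`.
* **P2 — the multinomial parameters and counts.**  The Wallace–Freeman
  (MML87) codelength for a multinomial with M vocabulary items (codewords
  plus residual symbols) and counts s₁…s_M summing to N:
  `P2 = log₂ Γ(N+M)/Γ(M) + Σₘ log₂ 1/Γ(sₘ+1) + ½ log₂((M−1)π) − 0.4`.
* **P3 — the arrangement.**  `P3 = log₂ N!/(s₁!···s_M!)`, the log of the
  multinomial coefficient.

The search greedily enumerates every contiguous token run (up to a maximum
length) of the current encoded stream, filters out runs that are not valid
substructures (unmatched brackets, bonds with no adjacent atom, unpaired
ring digits, disconnection dots), scores the exact ΔM of substituting each
survivor by a fresh codeword, and accepts the best candidate while ΔM < 0.
Because candidates may contain earlier codewords, discovered substructures
can grow far beyond the enumeration cap. The encoding is lossless at every
step: decoding the codewords reproduces the input SMILES exactly.

## Worked example

```python
from fgcompress import FGCompress
from fgcompress.synthetic import generate_planted

data = generate_planted(100, motif="C(=O)N", plant_rate=0.5, seed=42)
model = FGCompress(data.smiles, canonicalize=False,
                   max_substring_len=6, max_iterations=10)
res = model.fit()
print(res.summary(top=5))
```

```
FGCompress results
==================
molecules:            100
iterations accepted:  7
codebook size:        6
baseline length:      6105.0506 bits (symbols only)
message length:       2511.7524 bits (P1=113.2899, P2=1228.1055, P3=1170.3570)
compression:          58.9%

top substructures (discovery order, first 5):
    1. C(=O)N  (count 50)
    2. c1ccccc1  (count 16)
    3. C1CC1  (count 29)
    4. C(O)  (count 22)
    5. C(N)  (count 23)
```

The amide motif planted in half of the synthetic molecules is recovered at
iteration 1; benzene and cyclopropane scaffold fragments follow. The baseline
length is the dataset transmitted symbol-by-symbol (empty codebook); the
message length is the codebook plus the re-encoded dataset, here 58.9%
shorter. `res.decode()` reproduces the input exactly, and

```python
res.fingerprint("CC(=O)Nc1ccccc1")   # -> [1 1 0 0 0 0]
```

counts each discovered substructure in a new molecule (one amide, one
benzene), in codebook order.

The same objects drive the CLI:

```bash
fgcompress compress molecules.smi --max-len 8 --out codebook.json --trace trace.csv
fgcompress postprocess codebook.json --out substructures.csv
fgcompress fingerprint molecules.smi --codebook codebook.json --out fp.csv
fgcompress eval data.csv --codebook codebook.json --baselines maccs,morgan --out report.json
```

`eval` trains ridge regressors (penalty chosen from {0.001, 0.01, 0.1, 1} by
closed-form leave-one-out CV) on five random 75/25 splits and reports mean
test MSE ± standard error for the codebook fingerprint against MACCS keys
and an equal-length hashed Morgan fingerprint;
`fgcompress.evaluation.compare_representations` adds paired Wilcoxon
signed-rank tests with Benjamini–Hochberg correction across datasets.

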