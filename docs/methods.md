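# Methods

## Codec model

The codec is a per-sequence choice between two fixed codes over the
frequency-ranked alphabet nt1…nt4 (ties broken alphabetically so the whole
pipeline is deterministic): the 2-bit block code (nt1=`00`, nt2=`01`,
nt3=`10`, nt4=`11`) and a static prefix code (nt1=`1`, nt2=`01`, nt3=`001`,
nt4=`000`). "Huffman" here means this fixed code shape — the optimal binary
prefix code for any source with f₁ ≥ f₂ ≥ f₃ ≥ f₄ and four symbols — not a
per-sequence tree construction. The selection rule compares exact payload
sizes, 2L versus c₁ + 2c₂ + 3(c₃ + c₄); algebraically the prefix code wins
iff 2c₁ + c₂ > L, i.e. only under pronounced single-base dominance. Ties go
to the 2-bit code (fixed-width decoding, smaller tail ambiguity).

Sources of convention, fixed once:

* **Prefix-code assignment for nt3/nt4.** Two equivalent 3-bit assignments
  circulate (`001`/`000` vs `000`/`001`); both give identical lengths and
  rates. We fix nt3=`001`, nt4=`000` so that byte-exact output is defined.
* **Base64 dialect.** RFC 4648 standard alphabet, big-endian 6-bit groups,
  no `=` characters; padding happens at the bit level with `0`s.
* **Bit order.** All fields are most-significant-bit-first, matching
  left-to-right string concatenation.

## Header profiles and the padding ambiguity

A decoder needs the scheme and the base permutation. The header is the
3-bit scheme tag (`000` prefix code, `111` binary) plus a 6-bit order field
(fixed 2-bit IDs A=00, C=01, G=10, T=11 for nt1..nt3; nt4 implied) — 9 bits
total in the `paper` profile. This 9-bit layout is the one whose output
length ⌈(2L+9)/6⌉ reproduces the published simulated rates (0.345, 0.34,
0.3375 at L = 200, 300, 400) exactly, which is why it is the default for
rate analytics.

Because `0` padding bits are valid codeword prefixes (`00` = nt1 in binary,
`000` = nt4 in the prefix code), a 9-bit-header stream is tail-ambiguous.
The `paper`-profile decoder therefore enumerates every pad count in [0, 5]
consistent with the tail (trailing bits all zero, remaining payload decoding
to complete codewords), decodes the maximal-padding interpretation — the one
that reproduces the worked example `BvQ` → `AAAT` — and sets a
`tail_ambiguous` flag whenever more than one interpretation existed. The
error mode is bounded: up to two trailing nt1 (binary) or one trailing nt4
(prefix code) may be dropped, never invented. The `robust` profile removes
the ambiguity with a 3-bit pad-count field (12-bit header) and is exactly
lossless; it is the default for encode/decode round trips.

## QR layer

The Base64 text is rendered in byte mode (8-bit ISO 8859-1 characters; the
alphanumeric mode cannot carry lowercase). Version 1–40 symbols, all four
error-correction levels, standard Reed–Solomon blocks over GF(256)
(primitive polynomial 0x11d), mask selection by the four-rule penalty score.
Defaults: error correction M, 10 px/module, 4-module quiet zone. The reader
handles clean, axis-aligned images (any uniform scale): finder patterns are
located by 1:1:3:1:1 run scanning with diagonal and 7×7-template
verification, the grid is sampled from the three finder centres, format
information is nearest-codeword decoded (Hamming distance ≤ 3), and each
block passes through Berlekamp–Massey error correction. Photographic
distortions (rotation, perspective, uneven lighting) are out of scope. The
block-structure table is cross-validated in the test suite against an
independent re-derivation of codeword totals from symbol geometry for all
40 versions, and Reed–Solomon encoding against the standard's published
worked example.

## Simulation model

`generate_sequence(L, f, b)` fixes base *b* at proportion *f* ∈ [0.25, 1]
and draws the three minor proportions from a flat Dirichlet on the
remaining mass, then samples positions i.i.d. A maximum frequency below 1/4
is impossible, hence the lower bound; *f* = 0.25 is the uniform
composition. The minor proportions are constrained to not exceed *f* (a
violating draw is shrunk linearly toward the centroid): the dominant base
must actually dominate for *f* to be interpretable as the maximum
frequency, and this is what makes the *f* = 0.25 cell exactly uniform and
keeps near-uniform cells in the 2-bit coding regime, where the mean rate is
the closed form ⌈(2L+9)/6⌉/L for every replicate. Note the regime statement
is about compositions: at short lengths near the Huffman threshold,
finite-sample count noise can still flip individual replicates.

`run_sweep` computes rates from multinomial count draws rather than
materialized strings — the rate is a function of the counts alone
(payload = min(2L, c₁+2c₂+3(c₃+c₄)), characters = ⌈(header+payload)/6⌉) —
which is distributionally identical to sampling each position and encoding,
is asserted equal to the full string path in the tests, and keeps a
500-replicate sweep at three lengths under a tenth of a second. Default
replicates: 500 per (length, composition) cell, the study's condition.

Comparator analysis is abstracted behind a `compress_size(seq)` interface
(`ratio_series` divides mean DDQR rate by mean comparator rate per length).
An external-binary adapter (`SubprocessComparator`) can wrap tools like
GeCo3, but no external compressor is required: cutoff detection is
validated against synthetic ratio series and a brute-force window-scan
oracle instead of against a specific compressor build. `detect_cutoff`
slides an 11-point window (lengths i−10 … i, consecutive) and declares the
crossover at i−5 the first time at least 6 of the 11 ratios exceed 1;
fractional published-style thresholds arise as means over replicate series
(`mean_cutoff`).

## Datasets

FASTA parsing and writing delegate to Biopython; a pre-scan supplies
line-numbered errors for data before the first header. The codec alphabet
is strictly {A,C,G,T}: records with ambiguity codes or gaps are flagged and
excluded from statistics (logged), never silently altered — silent data
loss is unacceptable in a codec. Length filter presets: 150–600 bp for the
four plant markers, 100–700 bp for COI, bounds inclusive. Orientation
checking and flank trimming are not implemented; inputs are assumed
pre-processed. Rate histograms use 0.005-wide bins over [0.15, 0.40] plus
underflow/overflow bins.

The fixture generator (`ddqr make-fixtures`, `MARKER_PROFILES`) writes
synthetic stand-ins for the five marker datasets: truncated-normal lengths
around each marker's characteristic mean (rbcL 1184, matK 1200, psbA-trnH
393, ITS2 219, COI 659 bp) with a plausible dominant-base composition per
marker (e.g. the AT-rich psbA-trnH spacer gets a T-dominant 0.38). These
emulate length and gross composition only — not positional conservation,
codon structure, indel patterns or sequencing artifacts of real GenBank
data — so tests passing on them validate the statistics machinery, not
claims about any real marker dataset.

## Numerical and degenerate-input choices

* Empty input, non-ACGT characters (including N and IUPAC codes, RNA U,
  gaps) are errors with 1-based positions; batch mode may drop whole
  offending records behind an explicit flag.
* A single-base sequence (`A`) encodes to one prefix-code bit plus header.
* Base frequencies are exact rational counts; no floating comparison enters
  the scheme choice.
* Scheme ties → 2-bit code; rank ties → alphabetical.
* QR capacity overflow raises with the level's version-40 maximum; empty
  QR payloads are rejected.

## Problem sizes in the distributed checks

The test suite and acceptance script use 500-replicate sweeps at lengths
200–400, 10⁴-sequence round-trip and scheme-identity batches, 10³ random
ratio series, and 200 QR image round trips (3 px/module) — sizes chosen to
exercise every code path with comfortable statistical resolution while the
whole suite stays fast on a laptop.

## Known limitations

* The 9-bit `paper` header is a reconstruction: the published description
  fixes only the 3-bit scheme tag, and the order-field layout is inferred
  from the exact match of the closed-form rates. Interoperability with the
  original web server's strings is therefore plausible but unverified.
* `paper`-profile decoding can drop up to two trailing bases (see above);
  use `robust` when losslessness matters.
* The QR reader assumes one clean, axis-aligned symbol per image.
* Compression is only worthwhile below roughly 800 bp against modern
  context-mixing compressors; the package characterizes but does not
  extend that envelope.
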