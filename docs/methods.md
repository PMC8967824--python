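# Methods

## The problem

Centroided LC–MS runs from proteomics and metabolomics instruments are
commonly exchanged as mzML, which Base64-encodes every m/z and intensity
array into XML text. The files are large, and reading a single spectrum
requires scanning text. This package implements a computation-oriented
alternative: a lossy-but-bounded integer representation of m/z, a stacked
integer codec that exploits the similarity of adjacent spectra, and a
two-file container (JSON index + binary blocks) with per-stack random access
and fast extracted-ion-chromatogram (XIC) queries.

## Quantization

m/z values (Daltons) are stored as `round_half_up(mz * 10^dp)` with
`dp ∈ {4, 5, 6}` decimal places (`dp = 5` by default; 4 dp corresponds to
roughly 1 ppm at a 10 Da reference, 5 dp to 0.1 ppm). Rounding is half-up on
the *printed* (shortest round-trip) decimal representation of each float,
which is deterministic and matches what a user sees; an exact-decimal
fallback handles the rare values whose scaled float product lands within a
few ulp of a half-way point. Consequences:

* reconstruction error ≤ `0.5 × 10^-dp` relative to the printed value, and
  at most one float ulp more (≲2×10⁻¹² for m/z ≤ 12 000 Da) relative to the
  binary double — far below instrument precision at any supported dp;
* quantization is monotone, so sorted spectra stay sorted;
* decoded values re-quantize to the same integers (stable round trips).

At 6 dp, m/z above ~4294 Da exceeds 32 bits; the codec therefore stores the
first value of each sorted array as an unbounded varint and only requires
the *gaps* to fit 32 bits (a gap ≥ 2³² Da·10⁻⁶ would mean a >4000 Da hole in
one spectrum and is rejected).

## Integer codec

Sorted quantized arrays are delta-encoded (first value + non-negative gaps),
the gaps packed with a patched frame-of-reference (PFor) codec, and the
result zlib-compressed (RFC 1950, level 6). The PFor variant is this
package's own, fully specified in `format.md`: 128-value miniblocks, per
miniblock the bit width `b ∈ 0..32` chosen by brute-force byte-cost
minimization (packed area + varint-coded exceptions; ties to the smaller
width), LSB-first little-endian bit packing. This favours simplicity and
testability over SIMD throughput: the encoder is vectorized NumPy, and the
test suite pins the layout against a deliberately naive per-bit reference
decoder and against exhaustive enumeration on small alphabets.

## Stacking

Up to `2^n` spectra of the same MS level (and, for MS2, the same isolation
window) are merged into one globally sorted quantized array; an `n`-bit tag
per peak records the source spectrum, bit-packed to exactly
`ceil(peaks·n/8)` bytes and zlib-compressed. Neighbouring spectra that share
centroids put near-identical values adjacent in the merged array, so the
gaps shrink and repeat — the regime where delta+PFor+zlib wins. The tag
stream is the price. `n = 8` (256 spectra) is the default: each tag is then
exactly one byte, which is also the friendliest shape for zlib's byte-level
matching. `n = 0` degenerates to the plain single-spectrum codec.

Intensities travel in merged order (one permutation serves m/z and
intensity; an m/z window is a contiguous slice for XIC), serialized as
little-endian floats and zlib-compressed. They are narrowed to 32-bit by
default — the one deliberately lossy step besides m/z quantization, matching
common mzML practice — with a 64-bit option that is exactly lossless.
Merge ties break by ascending layer index and duplicates are preserved, so
encoding is deterministic down to the byte.

## Container and block layout

A run is `<stem>.mini-aird.json` plus `<stem>.mini-aird.bin` (layout in
`format.md`). Spectra are reordered from acquisition (RT) order into blocks:
MS1 spectra form one stacked block; in DIA, MS2 spectra form one stacked
block per isolation window (windows keyed after rounding to 4 decimals to
absorb float jitter in precursor records); in DDA, where the precursor set
changes every cycle and groups are small, MS2 spectra are grouped under
their triggering MS1 scan and stored unstacked (`n = 0` per spectrum).
Global spectrum ids are 0-based in acquisition order, so provenance survives
the reordering. Retention times live in the JSON index, so enumerating time
points or locating a spectrum never touches the binary.

XIC extraction binary-searches each stack's merged sorted array for the
requested m/z window, widened by one quantum, then filters exactly on the
dequantized values and attributes intensities to spectra through the tag
stream — per-spectrum arrays are never materialized. Matching peaks are
summed per spectrum; spectra with no match contribute zero at their RT.

## Mode detection

A run is classified DIA when its distinct (rounded) isolation windows form a
small set (≤ 64), each observed at least 3 times, repeating cyclically in
acquisition order; anything else — including MS1-only runs — is treated as
DDA. An all-window AIF-style acquisition with one wide repeating window
satisfies the cyclic rule and is handled as single-window DIA.

## Synthetic data

The generator emulates the one property the stacked codec exploits: adjacent
spectra sharing near-identical centroids, as produced by TOF instruments
cycling quickly over a stable ion population. Per block it draws a fixed
table of base centroids (default 500, uniform over 400–1200 Da); each scan
includes base peak *j* with probability *p* (default 0.9), jittered by
N(0, σ²) with σ = 2×10⁻⁴ Da, plus Poisson(50) uniform decoy peaks that
create realistic tag entropy; intensities are log-normal (ln-mean 6,
ln-sd 1.5). A DIA run cycles one MS1 scan plus one MS2 scan per window
(default 4 equal windows); a DDA run draws a fresh top-5 precursor set per
cycle. All randomness derives from one seed via per-scan substreams, so a
configuration is reproducible bit for bit. Default sizes (256 cycles,
~500 peaks/spectrum) were chosen to fill the default 256-spectrum stack
exactly while keeping a full acceptance run in seconds on one CPU.

What the generator does *not* model — isotope envelopes, charge states,
chromatographic peak shapes, mass-dependent resolution, detector saturation
— bounds what the tests show: they demonstrate codec correctness on any
input and compression *benefit* under the stated similarity regime, not the
compression ratios of any particular instrument's files.

## Benchmarks

`layer_sweep` encodes one homogeneous block at each layer exponent and
reports the m/z / tag / intensity byte split; a size is only reported after
a verified decode round trip. The stacking trade-off is between the m/z
payload (shrinks with n) and the tag payload (grows with n); the intensity
payload is invariant to n (same values, same zlib), so the *benefit ratio*
used in tests is defined on m/z+tag bytes, while totals are reported for
context. `compression_report` compares raw array bytes (8 B/m/z + stored
intensity width) against plain zlib, the unstacked codec, and the stacked
files; to make a report regenerated from files match one taken at
conversion time exactly, all baselines are computed from the stored
(quantized, narrowed) representation. Encode/decode wall times are logged
but never asserted — they are hardware facts, not codec properties.

## Numerical and design choices

* zlib level 6 everywhere, pinned for byte determinism.
* Empty spectra occupy a layer with zero peaks and survive round trips;
  a partial final stack keeps its block's tag width.
* Decoding with the wrong precision configuration rescales m/z by the scale
  ratio; a dedicated test documents this hazard.
* Corrupt payloads (bad magic, truncation, tag/count inconsistency) raise
  format errors rather than returning partial data; some corruptions inside
  a packed area are by construction undetectable without checksums, which
  the format deliberately omits (the index, not the payload, is
  authoritative).
* The reduction percentages printed by the tools follow
  `(baseline − encoded) / baseline × 100` with the baseline named in the
  key; vendor-format baselines are out of scope, so raw array bytes, plain
  zlib and the unstacked codec serve as references.

## Known limitations

mzML support is a documented subset (1.1, float arrays, zlib/none
compression, MS levels 1–2; Numpress rejected by name). The published Aird
binary layout is not read or written — the mini-Aird layout is this
package's own, documented to bit precision. SRM/MRM/PRM acquisitions, where
adjacent-spectrum similarity is absent, are out of scope, as are profile
re-centroiding and lossy intensity schemes beyond float32 narrowing.
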