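# szdpd

Stacked delta/PFor/zlib compression for centroided mass-spectrometry runs,
with a random-access container ("mini-Aird": JSON index + binary blocks).

## Who this is for

Proteomics and metabolomics tooling that stores or serves raw LC–MS runs.
mzML Base64-encodes every m/z and intensity array into XML; the files are
huge and every read scans text. `szdpd` converts an mzML run into a compact
binary form with a human-readable JSON index, per-stack random access, and
fast extracted-ion-chromatogram (XIC) queries — at a precision you choose.

## The codec in one paragraph

Each sorted m/z array is quantized to integers, `q_i = ⌊mz_i·10^dp + ½⌋`
with `dp ∈ {4,5,6}` decimal places (default 5, ≈0.1 ppm; error bounded by
`0.5·10^-dp`). The arrays of up to `2^n` adjacent same-level spectra
(default `n = 8`, 256 spectra) are merged into one globally sorted array,
delta-encoded (`q_i − q_{i−1}`), packed with a patched frame-of-reference
integer codec (128-value miniblocks, minimal bit width, varint exceptions)
and zlib-wrapped. An `n`-bit tag per peak — exactly one byte at `n = 8` —
records which spectrum each merged element came from, making the merge
exactly reversible. Neighbouring spectra from TOF-style acquisitions share
most of their centroids, so the merged gaps are small and repetitive, which
is precisely what delta+PFor+zlib rewards; intensities ride along in merged
order as (by default) 32-bit floats. MS1 spectra are gathered into one
block; DIA MS2 spectra into one block per isolation window; DDA MS2 groups
stay unstacked under their triggering MS1 scan.

See `docs/methods.md` for the science and `docs/format.md` for the byte
layout.

## Worked example

Generate a small synthetic DIA run (64 cycles, 4 isolation windows — the
high-similarity regime the codec targets), convert it, and query it:

```
$ szdpd generate run.mzML --mode DIA --n-ms1 64 --seed 42
run.mzML.truth.json

$ szdpd convert run.mzML run --precision 5 --layers 8
320 spectra, 160116 peaks -> 828696 bytes (72.5% smaller than the mzML)
```

The converter printed the whole-run result: 320 spectra (64 MS1 + 4×64 MS2)
holding 160 116 peaks compressed to 829 kB, 72.5 % below the 3.0 MB mzML.
An XIC for one of the generated base peaks, ±30 ppm, straight from the
container (one row per MS1 spectrum; summed intensity at each retention
time):

```
$ szdpd extract run --mz 402.609804956778 --ppm 30
rt,intensity
0.0,308.6075134277344
1.0,104.84081268310547
2.0,172.48898315429688
...
```

How the trade-off between merged-array savings and tag cost moves with the
stack depth `n` (sizes in bytes for the same 64-spectrum MS1 block; the m/z
payload shrinks as stacks deepen while the tag payload grows):

```
$ szdpd sweep --n 0..6 --seed 42 --spectra 64 | cut -d, -f1-5
n,mz_bytes,tag_bytes,intensity_bytes,total_bytes
0,82350,0,120933,203283
1,71278,4375,119027,194680
2,52639,8205,118201,179045
3,39938,12124,117882,169944
4,31423,16089,117855,165367
5,25609,20078,117888,163575
6,21255,24082,117848,163185
```

`szdpd stats run` prints the byte decomposition of an existing container
against raw-array, plain-zlib and unstacked baselines. The same
functionality is available as a library (`szdpd.convert`,
`szdpd.extract_xic`, `szdpd.encode_stack`, ...).

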