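# mini-Aird on-disk format, version `mini-aird-1`

A run is stored as two files sharing a stem:

| file | content |
|---|---|
| `<stem>.mini-aird.json` | metadata and index (authoritative; human-readable) |
| `<stem>.mini-aird.bin`  | concatenated payload segments, no in-band framing |

All multi-byte integers anywhere in the binary layout are **little-endian**.
Offsets and lengths in the JSON are byte counts into the `.bin` file and fit
64 bits.

## Binary file

The `.bin` file is the concatenation, in JSON descriptor order, of each
stack's three segments:

```
mz_payload | tag_payload | intensity_payload
```

Segment lengths come from the JSON (`mz_bytes`, `tag_bytes`,
`intensity_bytes`); `offset` is the absolute position of the stack's first
byte. Offsets are strictly increasing and segments never overlap.

### mz_payload — sorted-array codec

A zlib stream (RFC 1950, level 6). After inflation:

```
varint element_count
if element_count > 0:
    varint first_value          # unbounded; may exceed 32 bits
    pfor_payload of the gaps    # element_count - 1 values, each < 2^32
```

Varints are unsigned LEB128: 7 value bits per byte, LSB group first, high
bit set on continuation bytes.

The decoded array is `first_value` followed by the cumulative sums of the
gaps. A gap ≥ 2^32 is invalid (encoders must reject it).

### pfor_payload — patched bit-packing codec

```
magic   4 bytes  "SPF1"
version 1 byte   0x01
varint  element_count
miniblocks until element_count values are produced
```

Each miniblock covers 128 value slots:

```
bit_width b   1 byte, 0..32
varint        exception_count
packed area   ceil(128*b / 8) bytes
exceptions    exception_count pairs of (varint position_delta, varint high_bits)
```

* Packed area: the low `b` bits of each of the 128 slots, packed LSB-first
  into a little-endian byte stream (bit `j` of slot `i` is bit
  `(i*b + j) mod 8` of byte `(i*b + j) div 8`). `b = 0` packs nothing.
* A final partial miniblock still packs 128 slots; slots beyond the
  remaining element count are zero and are discarded on decode.
* Exceptions restore values that did not fit in `b` bits:
  positions are recovered as a running sum of `position_delta` values
  (first delta is the absolute position, 0-based within the miniblock);
  the decoded value is `packed_low_bits | (high_bits << b)`.
* Encoders choose, per miniblock, the `b` in 0..32 minimizing
  `ceil(128*b/8)` + total exception bytes; ties go to the smaller `b`.

### tag_payload

The per-peak layer tags (which spectrum each merged element came from),
`n` bits each where `n` is the stack's `layer_exponent`, packed LSB-first in
the same bit order as the pFor packed area into exactly
`ceil(total_peaks * n / 8)` bytes, then zlib-compressed (level 6).
For `n = 0` (single-layer stacks) the payload is empty (0 bytes).

### intensity_payload

Intensities in **merged order** (aligned with the merged m/z array) as IEEE
floats, little-endian, `intensity_width` bits each (32 by default, 64 when
requested), zlib-compressed (level 6). The tag stream drives the scatter of
both m/z and intensity back into per-spectrum arrays.

## JSON index

See `mini-aird.schema.json` in this directory for the machine-readable
schema. Top-level fields: `format_version`, `precision`
(`decimal_places` in {4,5,6}; `scale = 10^dp`), `acquisition_mode`
(`"DDA"` or `"DIA"`), `source` (free-form provenance), `total_spectra`,
`binary_file`, `blocks`.

Each block: `block_id`, `ms_level`, `layer_exponent`, `precursor_window`
(`[lo, hi]` in Da rounded to 4 decimals, or `null` for MS1 and DDA MS2
blocks), and `stacks`. Each stack descriptor: `offset`, `mz_bytes`,
`tag_bytes`, `intensity_bytes`, `layer_exponent`, `spectrum_count`,
`peaks_per_layer`, `intensity_width`, `rt` (seconds, one per spectrum),
`spectrum_ids` (global 0-based ids in original acquisition order), and an
optional per-stack `precursor_window` (used by DDA MS2 stacks, whose windows
vary within a block).

Determinism: the same spectra and configuration always serialize to
bit-identical files (pinned zlib level, pinned merge tie-breaks, pinned
miniblock width choice).
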