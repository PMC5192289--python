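# Checkpoint file format (version 1)

A `nodulefpr` checkpoint is a single self-describing binary file.  All
multi-byte integers are little-endian; all arrays are little-endian float64.

| offset | size | content |
| ------ | ---- | ------- |
| 0      | 8    | magic `NFPRCKPT` (ASCII) |
| 8      | 4    | `uint32` format version (currently `1`) |
| 12     | 4    | `uint32` header length `H` in bytes |
| 16     | H    | UTF-8 JSON header (keys sorted) |
| 16+H   | —    | raw array payloads, concatenated in header order |

The JSON header holds:

* `format_version` — repeated for self-description;
* `config` — the network architecture (`input_size`, `n_classes`, and the
  ordered `layers` list with each layer's kind, geometry and activation);
* `arrays` — an ordered manifest of `{name, shape}` entries.  Names are
  `layer<i>.<part>` with `part` one of `weights`, `biases`, `v_weights`,
  `v_biases` (the momentum velocity buffers), and `<i>` the layer index in
  the config.

Each payload is the C-order `<f8` byte dump of its array; its length is
`8 * prod(shape)` bytes.  Loading verifies the magic, version, header
completeness, every array's byte count and the absence of trailing bytes;
any failure raises without returning partial state.  Because the JSON is
serialized with sorted keys and arrays are dumped bit-exactly,
save → load → save reproduces the file byte for byte.
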