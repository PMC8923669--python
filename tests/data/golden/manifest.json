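{
  "config_hash": "unhashed",
  "fearpeth_version": "0.1.0",
  "n_sessions": 2,
  "seed": 123
}
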