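[
  {
    "character": "character:color",
    "kind": "affirm",
    "value": "state:blue",
    "ordinal": 0,
    "invalidated": false
  },
  {
    "character": "character:size",
    "kind": "affirm",
    "value": "state:small",
    "ordinal": 1,
    "invalidated": false
  }
]
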