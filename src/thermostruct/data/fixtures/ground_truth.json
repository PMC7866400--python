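{
  "floppy": {
    "active_site": [
      [
        "A",
        27
      ],
      [
        "A",
        29
      ]
    ],
    "floppy_loop_span": [
      11,
      22
    ],
    "sigma_nm": [
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.15,
      0.15,
      0.15,
      0.15,
      0.15,
      0.15,
      0.15,
      0.15,
      0.15,
      0.15,
      0.15,
      0.15,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03
    ]
  },
  "stable": {
    "active_site": [
      [
        "A",
        19
      ],
      [
        "A",
        21
      ]
    ],
    "floppy_loop_span": [
      11,
      14
    ],
    "sigma_nm": [
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03,
      0.03
    ]
  }
}
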