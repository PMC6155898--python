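[
  {
    "name": "substrate-1",
    "tdc_pattern": "T[H/N]W[L/M]SP",
    "tydc_pattern": "THWQSP",
    "tdc_position": 92,
    "tydc_position": 137,
    "binding": "Substrate",
    "diagnostic_hint": [4]
  },
  {
    "name": "substrate-2",
    "tdc_pattern": "FPATVSSAAF",
    "tydc_pattern": "[F/Y][P/A]S[S/N][G/S/T]S[I/V/T]AGF",
    "tdc_position": 103,
    "tydc_position": 148,
    "binding": "Substrate",
    "diagnostic_hint": [3, 4, 5, 7, 9]
  },
  {
    "name": "substrate-3",
    "tdc_pattern": "[H/Q][G/N]TTSE[A/S]ILCT",
    "tydc_pattern": "QGT[T/A/S][C/S]EA[V/I]L[C/V][T/V]",
    "tdc_position": 167,
    "tydc_position": 217,
    "binding": "Substrate",
    "diagnostic_hint": []
  },
  {
    "name": "substrate-plp",
    "tdc_pattern": "SPHKW",
    "tydc_pattern": "NAHKW",
    "tdc_position": 318,
    "tydc_position": 369,
    "binding": "Substrate, PLP",
    "diagnostic_hint": [1, 2]
  }
]
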