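{
  "schema_version": 1,
  "description": "Rate constants of the De Young-Keizer IP3 receptor subunit scheme (De Young & Keizer, PNAS 1992). Each subunit carries three binding sites: IP3 (site 1/3), inhibitory Ca2+ (site 2/4) and activating Ca2+ (site 5). Association rates a_i in 1/(uM s), dissociation rates b_i = a_i * d_i in 1/s.",
  "a1": 400.0,
  "a2": 0.2,
  "a3": 400.0,
  "a4": 0.2,
  "a5": 20.0,
  "d1": 0.13,
  "d2": 1.049,
  "d3": 0.9434,
  "d4": 0.1445,
  "d5": 0.08234
}
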