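# Mechanistic candidate-site types for hAOX-catalyzed ring-carbon oxidation.
# Users may edit or extend; disabled entries are ignored by the enumerator.
site_types:
  - type_code: A
    smarts: "[$([c;H1;R]:[n;X2;R])]"
    description: >-
      Aromatic ring carbon bearing exactly one hydrogen, adjacent to a
      two-connected aromatic ring nitrogen (alpha position).
    enabled: true
  - type_code: B
    smarts: "[$([#6;X3;H1;R]:,=[*]:,=[*]:,=[#7;X2;R])]"
    description: >-
      Ring carbon with one hydrogen and two heavy neighbors, three
      conjugated (aromatic or double) bonds away from a two-connected ring
      nitrogen (gamma position).
    enabled: true
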