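# Substrate-specificity rule table (data, not code).
# Each rule matches the four ar/R selectivity-filter residues (H2, H5,
# LE1, LE2); an entry is a string of allowed letters, "*" matches any.
# An optional `spacing` pins the NPA-NPA spacing. The first matching
# rule supplies the (substrate, confidence tier) predictions; tier 1 is
# strong evidence, tier 2 suggestive. Silicic acid additionally requires
# the exact Lsi1-type signature (G-S-G-R, spacing 108) and is enforced
# in code as well as here.
rules:
  - name: lsi1_silicic
    sf: ["G", "S", "G", "R"]
    spacing: 108
    substrates:
      - {substrate: water, tier: 2}
      - {substrate: "silicic acid", tier: 1}
  - name: pip_water
    sf: ["F", "H", "T", "R"]
    substrates:
      - {substrate: water, tier: 1}
      - {substrate: H2O2, tier: 2}
  - name: nip_I_glycerol
    sf: ["WV", "VI", "A", "R"]
    substrates:
      - {substrate: water, tier: 1}
      - {substrate: glycerol, tier: 2}
      - {substrate: ammonia, tier: 2}
  - name: nip_II_boric
    sf: ["A", "IVN", "GA", "R"]
    substrates:
      - {substrate: "boric acid", tier: 1}
      - {substrate: urea, tier: 2}
  - name: tip_water_urea
    sf: ["HNA", "IVM", "AG", "VRC"]
    substrates:
      - {substrate: water, tier: 1}
      - {substrate: urea, tier: 2}
      - {substrate: H2O2, tier: 2}
  - name: sip_water
    sf: ["STV", "HVF", "GP", "AI"]
    substrates:
      - {substrate: water, tier: 2}
  - name: fallback_water
    sf: ["*", "*", "*", "*"]
    substrates:
      - {substrate: water, tier: 3}
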