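# Dutch Lipid Clinic Network (DLCN) point table, genetic items excluded.
#
# Sections: family history and physical examination contribute the maximum
# of their applicable items; clinical history items are summed; the LDLC
# band is scored on estimated pre-treatment LDLC in mmol/L.
family_history:
  combine: max
  items:
    relative_premature_chd: 1        # first-degree relative with premature CHD
    relative_high_ldl: 1             # first-degree relative with LDLC > 95th pct
    relative_xanthoma_or_arcus: 2    # first-degree relative with tendon xanthomata / arcus
    child_high_ldl: 2                # child < 18 y with LDLC > 95th pct
clinical_history:
  combine: sum
  items:
    premature_chd: 2                 # personal premature coronary heart disease
    premature_cerebral_peripheral: 1 # personal premature cerebral / peripheral disease
physical_exam:
  combine: max
  items:
    tendon_xanthomata: 6
    arcus_cornealis_before_45: 4
# LDLC bands on eLDLC (mmol/L): lower bound (inclusive) -> points.
ldl_bands_mmol:
  - [8.5, 8]
  - [6.5, 5]
  - [5.0, 3]
  - [4.0, 1]
# FH probability categories on total points.
categories:
  unlikely: [0, 2]
  possible: [3, 5]
  probable: [6, 8]
  definite: [9, null]
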