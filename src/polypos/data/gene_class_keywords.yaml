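# Default description keywords used to assign gene-class flags.
# Matching is case-insensitive substring search against the product
# description; the pseudogene flag is additionally assigned from the GFF3
# `pseudogene` feature type. Override with your own mapping to audit or
# extend the removed classes.
vsg:
  - variant surface glycoprotein
esag:
  - expression site-associated
  - expression-site-associated
  - ESAG
multilocus:
  - retrotransposon hot spot
  - GRESAG4
pseudogene:
  - pseudogene
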