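# Sound-class inventory and diacritic conventions for ASJP-style transcriptions.
# Editable: any section may be overridden by passing a custom file to
# lexiphylo.sound_model.load_inventory.

[symbols]
# The 41 sound classes, one string, one character per class.
classes = pbfvmw8tdszcnrlSZCjT5ykgxNqXG7h!L4ieE3auo

[diacritics]
# Characters deleted outright during normalization (post-posed modifiers:
# glottalization, nasalization, stress/space debris).
delete = "*%
# Juxtaposition markers: the marker collapses the preceding k symbols into one
# segment, represented by the first of them.
combine2 = ~
combine3 = $
# Digraphs reduced to their first symbol (aspirated plosive series); applied
# after marker handling, repeatedly until stable.
digraphs = ph th kh qh ch Ch Th
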