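# Cross-forum topic label canonicalization: surface label -> canonical label.
# Covers German->English translation and near-synonym merging for the three
# CML patient forums. Lookups are case-insensitive; labels absent from this
# table are canonical as-is (lowercased). Edit freely per analysis.
leukämie: leukemia
arzt: doctor
antwort: answer/reply
answer: answer/reply
reply: answer/reply
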