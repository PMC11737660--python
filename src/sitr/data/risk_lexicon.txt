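# Default risk lexicon (English stand-in; fully user-replaceable).
# High-risk signal tokens: suicide-related terms, practices and
# instruments of cutting, and signs of depression, trauma, and
# (borderline) personality pathology.
suicide
suicidal
die
death
kill
overdose
pills
knife
cutter
blade
razor
cut
cutting
scar
scars
wound
blood
bleed
depression
depressed
hopeless
worthless
trauma
abuse
panic
borderline
self-hate
insomnia
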