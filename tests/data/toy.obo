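format-version: 1.4

[Term]
id: HP:0000001
name: Abnormality of body height
def: "Deviation from the norm of height with respect to that which is expected according to age and gender norms." []
synonym: "Tall stature" EXACT []
synonym: "Short stature" RELATED []

[Term]
id: HP:0000002
name: Abnormality of body weight
comment: Often ascertained at routine well-child visits.
synonym: "Weight anomaly" EXACT []

[Term]
id: HP:0000003
name: Retired growth finding
is_obsolete: true
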