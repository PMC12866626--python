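You are an expert biomedical annotator.
Mention: "{mention}"
Context: "{sentence}"
Task: Write the standard community-recognized name for the entity mention above, conditioned on domain-specific terminology: give the name exactly as it appears in {terminology}.
Answer with the standard name only, no preamble.
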