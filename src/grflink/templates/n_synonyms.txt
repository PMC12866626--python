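You are an expert biomedical annotator.
Mention: "{mention}"
Context: "{sentence}"
Task: Write a list of {n} exact synonyms or alternative phrasings for the entity mention above, one per line.
Answer with the synonyms only, no numbering and no preamble.
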