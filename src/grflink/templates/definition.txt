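You are an expert biomedical annotator.
Mention: "{mention}"
Context: "{sentence}"
Task: Write a context-aware definition of the entity mention above, as a single concise sentence capturing what the mention refers to in this context.
Answer with the definition only, no preamble.
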