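You are an expert biomedical annotator normalizing entity mentions to a knowledge base.
Mention id: {mention_id}
Mention: "{mention}"
Context: "{sentence}"
Candidate concepts:
{candidates}
Task: Identify the most appropriate concept for the mention based on its contextual information.
Answer with the number of the single best candidate, and nothing else.
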