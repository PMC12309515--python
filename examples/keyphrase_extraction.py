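"""Walk one radiology report through the NLP pipeline.

Sections the text, tags tokens, builds the co-occurrence graph, ranks terms
with the damped random walk, maps key phrases to oncology concept clusters,
and prints the 11-entry feature vector.
"""

from ctsurveil.nlp import (
    ConceptLexicon,
    NLPConfig,
    build_cooccurrence_graph,
    featurize_report,
    map_phrase_to_cluster,
    rank_keyphrases,
    segment_report,
    tokenize_and_tag,
)

TEXT = """INDICATION: Routine surveillance imaging of the chest. History of
lung cancer. Status after lobectomy for lung cancer.
TECHNIQUE: Helical acquisition of the thorax was performed.
COMPARISON: Comparison is made with prior examination.
FINDINGS: The lungs are clear. No suspicious nodule is identified.
IMPRESSION: This is a surveillance chest examination.
Recommend follow-up imaging in one year."""

sectioned = segment_report(TEXT)
print("sections:", list(sectioned.sections))

tokens = tokenize_and_tag(sectioned)
graph = build_cooccurrence_graph(tokens, window=3)
scores, phrases = rank_keyphrases(graph, tokens)

lexicon = ConceptLexicon.default()
print("\ntop key phrases (salience, concept cluster):")
for phrase in phrases[:8]:
    cluster = map_phrase_to_cluster(phrase, lexicon)
    print(f"  {phrase.text:28s} {phrase.score:.3f}  {cluster or '-'}")

vector = featurize_report(TEXT, lexicon, NLPConfig())
print("\nfeature vector:")
for name, value in vector.as_dict().items():
    print(f"  {name:26s} {value:.2f}")

# The cluster counts say how often salient phrases from each oncology
# concept appear; the binaries flag surveillance/symptom wording in the
# clinical-indication section — the signals the indication classifier uses.
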