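"""Phenotype semantic similarity on a toy ontology.

Builds a five-term diamond ontology, propagates two variants' annotations to
their ancestor closures, and prints Jaccard/Resnik/Lin similarities. Jaccard
is the propagated-set overlap in [0, 1]; Resnik is the information content
(bits) of the best-matching common ancestors; Lin rescales Resnik by the
terms' own IC into [0, 1].
"""

from phenomkl import (OntologyGraph, TermSet, information_content,
                      set_similarity, similarity_matrix)

graph = OntologyGraph(
    parents={
        "ROOT": frozenset(),
        "NEURO": frozenset({"ROOT"}),
        "SEIZURE": frozenset({"NEURO"}),
        "MOTOR": frozenset({"ROOT"}),
        "ATAXIA": frozenset({"NEURO", "MOTOR"}),  # two parents
    },
    root="ROOT",
)

corpus = [
    TermSet.from_raw("variant1", {"SEIZURE"}, graph),
    TermSet.from_raw("variant2", {"SEIZURE", "ATAXIA"}, graph),
    TermSet.from_raw("variant3", {"MOTOR"}, graph),
]
ic = information_content(graph, corpus)

print("propagated sets:")
for ts in corpus:
    print(f"  {ts.variant_id}: {sorted(ts.propagated_terms)}")
print("\nIC (bits):", {t: round(v, 3) for t, v in sorted(ic.ic.items())})

for measure in ("jaccard", "resnik", "lin"):
    s12 = set_similarity(measure, corpus[0], corpus[1], graph, ic)
    s13 = set_similarity(measure, corpus[0], corpus[2], graph, ic)
    print(f"\n{measure}: sim(v1,v2) = {s12:.3f}, sim(v1,v3) = {s13:.3f}")
    # v1 and v2 share the seizure phenotype, so their similarity exceeds
    # the pair that shares only coarse ancestors

m = similarity_matrix("jaccard", corpus)
print("\nJaccard similarity matrix:\n", m.values.round(3))
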