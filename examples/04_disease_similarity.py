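"""Disease semantic similarity from a MeSH-style hierarchy.

Builds a small random disease hierarchy, computes the information content
of every term (rare terms are informative), and scores disease pairs by the
semantic weight of the ancestors they share.
"""

from mirflow import (
    build_disease_semantic_similarity,
    build_ic_table,
    generate_mesh_fixture,
)

dag, diseases = generate_mesh_fixture(n_diseases=12, depth=4, branching=2, seed=3)
ic = build_ic_table(dag, diseases)

print("information content of a few terms (IC = -ln p, p = DAG frequency):")
for term in diseases[:4]:
    print(f"  {term}: tree numbers {sorted(dag.terms[term])} IC={ic[term]:.3f}")

matrix = build_disease_semantic_similarity(dag, diseases)
print(f"\nsemantic similarity matrix: {len(matrix)}x{len(matrix)}")

import numpy as np

off = matrix.values - np.eye(len(matrix))
i, j = np.unravel_index(np.argmax(off), off.shape)
a, b = matrix.labels[i], matrix.labels[j]
print(f"most similar pair: SS({a}, {b}) = {matrix.loc(a, b):.3f}")
print("1.0 means identical DAGs; 0.0 means no informative shared ancestors")
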