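"""Build per-term gold standards from an ontology and annotations.

Annotations live at the most specific ontology term; propagating them up
the is_a hierarchy lets every ancestor term inherit its descendants'
genes. Positives for a term are then the genes annotated at or below it;
negatives are all other universe genes.
"""

import io

from phenonet import (
    AnnotationSet,
    build_gold_standard,
    collapse_alleles,
    parse_obo,
    propagate_annotations,
)

OBO = """\
format-version: 1.2
ontology: example-phenotypes

[Term]
id: MP:0000001
name: phenotype root

[Term]
id: MP:0005390
name: skeleton phenotype
is_a: MP:0000001

[Term]
id: MP:0002896
name: abnormal bone mineralization
is_a: MP:0005390
"""

dag = parse_obo(io.StringIO(OBO))
print(f"ontology: {len(dag.terms)} terms, roots = {sorted(dag.roots)}")

# allele-level records: two alleles of Timp2 hit the same term
annots = AnnotationSet((
    ("Timp2", "MP:0002896", "Timp2<tm1Pds>"),
    ("Timp2", "MP:0002896", "Timp2<tm2>"),
    ("Abcg8", "MP:0002896", "Abcg8<tm1Elk>"),
    ("Sparc", "MP:0005390", None),
))
collapsed = collapse_alleles(annots)
propagated = propagate_annotations(collapsed, dag)

universe = ["Timp2", "Abcg8", "Sparc", "Mmp2", "Col1a1", "Bgn"]
for term in ("MP:0002896", "MP:0005390"):
    gs = build_gold_standard(term, propagated, universe)
    print(f"{term}: n_p={gs.n_p} positives={sorted(gs.positives)} n_n={gs.n_n}")

# The leaf term keeps only its direct genes; the parent skeleton term also
# inherits them, so its positive set is strictly larger.
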