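"""Discover metabolic subtypes in one synthetic cohort.

Generates a cohort with a two-subtype structure planted in the genes of
PATHWAY_A, then runs the per-pair procedure: Duda-Hart gate on the
rank-space points, PAM on the Spearman distance, silhouette-based
choice of k. The null pathway (PATHWAY_B) should be gated out.
"""

import numpy as np

from metasub import cluster_gene_set, demo_spec, generate_cohort, nmi

spec = demo_spec(seed=42)
cohort = generate_cohort(spec)

for name in ("PATHWAY_A_METABOLISM", "PATHWAY_B_METABOLISM"):
    sol = cluster_gene_set(cohort.expression, spec.gene_sets[name],
                           tumor_type="DEMO")
    print(f"{name}: status={sol.status}, Duda-Hart p={sol.duda_hart_p:.3g}")
    if sol.clustered:
        truth = np.array(cohort.truth["assignments"][name])
        agreement = nmi(truth, sol.assignments.to_numpy())
        print(f"  k={sol.k}, average silhouette={sol.avg_silhouette:.3f}, "
              f"NMI vs planted truth={agreement:.3f}")
# A Duda-Hart p below 0.001 admits the pair; NMI of 1 means the planted
# two subtypes were recovered exactly (silhouette near 0.9 reflects the
# strong planted separation).
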