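"""Printed summary counts from the six-patient multi-region HGSC cohort.

These are the cohort-level tallies reported for the study design this
package re-implements: mutation category totals across all cases, fallopian
tube (FT) lesion mutation counts for the two cases with tubal lesions,
plasma ctDNA assay tallies for the four cases with plasma, and the
per-tumour-mass conservation percentages.  They serve as inputs to the
worked examples; none of them is produced by this package.
"""

from __future__ import annotations

#: Unique validated somatic mutations across the cohort, by category.
MUTATION_CATEGORY_COUNTS: dict[str, int] = {
    "non_synonymous": 334,
    "synonymous": 46,
    "small_indel": 24,
}

#: Mutations found in the fallopian-tube lesion vs the case's unique total.
FT_LESION_MUTATIONS: dict[str, tuple[int, int]] = {
    "case4": (17, 65),
    "case5": (44, 137),
}

#: Plasma ctDNA assay tallies: mutations assayed per case, and the pooled
#: covered / detected counts over the reported assay total.
PLASMA_ASSAYED_PER_CASE: dict[str, int] = {
    "case1": 72,
    "case2": 49,
    "case4": 63,
    "case5": 131,
}
PLASMA_ASSAYED_TOTAL = 312
PLASMA_COVERED = 215
PLASMA_DETECTED = 38

#: Percentage of mutations conserved across every sample of a single
#: tumour mass (five masses sampled with >= 4 regions each).
MASS_CONSERVATION_PCT: dict[str, float] = {
    "1a-d": 67.1,
    "2a-d": 55.6,
    "4a-e": 81.2,
    "4f-i": 94.4,
    "5b-e": 17.6,
}
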