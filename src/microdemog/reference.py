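"""Worked-example reference values from the 118-subject Midwestern cohort.

These are *inputs* for validating arithmetic, not test fixtures generated
by this package: the printed group-mean proportions of the taxa reported
as BMI/race/sex/alcohol signatures (with their published log2 fold
changes), and the printed cohort-composition counts by age stratum (with
their published percentages).  The analysis code must reproduce the
published derived numbers from these raw inputs.
"""

from __future__ import annotations

#: (slug, rank, taxon, mean_exposed, mean_reference, published_log2fc)
#: exposed = obese (BMI signatures); reference = normal.
TAXON_GROUP_MEANS = [
    ("bacteroidetes", "phylum", "Bacteroidetes", 4.339e-01, 5.004e-01, -0.206),
    ("firmicutes", "phylum", "Firmicutes", 5.226e-01, 4.660e-01, 0.165),
    ("chrysiogenetes", "phylum", "Chrysiogenetes", 1.927e-05, 1.680e-04, -3.124),
    ("fusobacteria", "phylum", "Fusobacteria", 1.433e-02, 1.446e-03, 3.309),
    ("barnesiellaceae", "family", "Bacteroidetes; Barnesiellaceae",
     9.637e-03, 2.734e-02, -1.505),
    ("erysipelotrichaceae", "family", "Firmicutes; Erysipelotrichaceae",
     2.898e-02, 1.942e-02, 0.578),
    ("lachnospiraceae", "family", "Firmicutes; Lachnospiraceae",
     1.796e-01, 1.401e-01, 0.358),
    ("alcaligenaceae", "family", "Proteobacteria; Alcaligenaceae",
     1.909e-03, 6.867e-04, 1.475),
    ("bacteroidetes_unclassified", "genus", "Bacteroidetes; unclassified",
     3.534e-02, 6.134e-02, -0.795),
    ("acidaminococcus", "genus", "Firmicutes; Acidaminococcus",
     3.915e-04, 3.081e-04, 0.346),
    ("blautia", "genus", "Firmicutes; Blautia", 6.326e-02, 3.883e-02, 0.704),
    ("dorea", "genus", "Firmicutes; Dorea", 2.743e-02, 1.757e-02, 0.643),
    ("eubacterium", "genus", "Firmicutes; Eubacterium",
     8.339e-03, 4.210e-03, 0.986),
    ("sutterella", "genus", "Proteobacteria; Sutterella",
     1.909e-03, 6.867e-04, 1.475),
]

#: cohort composition: stratum -> (n, {characteristic: (count, published %)})
COHORT_COUNTS = {
    "Age <50 years": (58, {
        "Sex, F": (30, 51.7),
        "Race, W": (49, 84.5),
        "BMI >30 kg/m^2": (14, 24.1),
        "Alcohol use (Y)": (41, 70.7),
        "Smoking (Y)": (9, 15.5),
    }),
    "Age >=50 years": (60, {
        "Sex, F": (30, 50.0),
        "Race, W": (54, 90.0),
        "BMI >30 kg/m^2": (20, 33.3),
        "Alcohol use (Y)": (39, 65.0),
        "Smoking (Y)": (8, 13.3),
    }),
}
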