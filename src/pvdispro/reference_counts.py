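"""Published summary counts for the bempedoic-acid vs atorvastatin contrast.

These are the report-level marginal counts of the EudraVigilance
line-listing extraction of suspected-ADR reports for bempedoic acid
(target) and atorvastatin (comparator), earliest availability through
30 June 2024, after deduplication: cohort sizes, demographic
distributions, report-level SOC presence, and per muscle-related-PT
outcome distributions.  They serve two purposes: replication tests of
the disproportionality statistics against the published estimates, and
the deterministic fixture (:func:`pvdispro.simulate.reference_fixture`)
whose marginals reproduce them exactly.

Group keys: ``target_only`` (bempedoic acid without atorvastatin),
``comparator_only`` (atorvastatin without bempedoic acid), ``both``
(co-administration).  Outcome count tuples follow the severity order
(fatal, recovered with sequelae, not recovered, recovering, recovered,
unknown).
"""

from __future__ import annotations

GROUP_SIZES = {"target_only": 2_667, "comparator_only": 76_137, "both": 126}

#: (healthcare professional, non-healthcare professional, not specified)
QUALIFICATION = {
    "target_only": (2_169, 498, 0),
    "comparator_only": (48_584, 27_107, 446),
    "both": (119, 7, 0),
}

#: (EEA, non-EEA, not specified)
SOURCE_AREA = {
    "target_only": (2_375, 292, 0),
    "comparator_only": (32_159, 43_976, 2),
    "both": (124, 2, 0),
}

#: (pediatric, adult, elderly, very elderly, not specified)
AGE_GROUP = {
    "target_only": (0, 712, 1_042, 34, 879),
    "comparator_only": (171, 29_250, 27_411, 2_914, 16_391),
    "both": (0, 23, 22, 2, 79),
}

#: (female, male, not specified)
SEX = {
    "target_only": (1_439, 1_201, 27),
    "comparator_only": (36_388, 33_669, 6_080),
    "both": (66, 57, 3),
}

#: Report-level SOC presence: number of reports with >=1 PT in the SOC.
#: Order fixed (alphabetical, as published); values (both, comparator, target).
SOC_PRESENCE: dict[str, dict[str, int]] = {
    "Blood and lymphatic system disorders": {"both": 0, "comparator_only": 1_462, "target_only": 25},
    "Cardiac disorders": {"both": 2, "comparator_only": 2_852, "target_only": 62},
    "Congenital, familial, and genetic disorders": {"both": 0, "comparator_only": 50, "target_only": 0},
    "Ear and labyrinth disorders": {"both": 0, "comparator_only": 616, "target_only": 7},
    "Endocrine disorders": {"both": 0, "comparator_only": 141, "target_only": 0},
    "Eye disorders": {"both": 2, "comparator_only": 1_684, "target_only": 32},
    "Gastrointestinal disorders": {"both": 30, "comparator_only": 7_793, "target_only": 610},
    "General disorders": {"both": 22, "comparator_only": 12_267, "target_only": 556},
    "Hepatobiliary disorders": {"both": 1, "comparator_only": 7_190, "target_only": 29},
    "Immune system disorders": {"both": 2, "comparator_only": 5_701, "target_only": 83},
    "Infections and infestations": {"both": 0, "comparator_only": 1_155, "target_only": 15},
    "Injury, poisoning, and procedural complications": {"both": 3, "comparator_only": 7_881, "target_only": 191},
    "Investigations": {"both": 16, "comparator_only": 15_105, "target_only": 514},
    "Metabolism and nutrition disorders": {"both": 3, "comparator_only": 14_490, "target_only": 94},
    "Musculoskeletal and connective tissue disorders": {"both": 110, "comparator_only": 21_474, "target_only": 1_251},
    "Nervous system disorders": {"both": 25, "comparator_only": 14_180, "target_only": 500},
    "Psychiatric disorders": {"both": 12, "comparator_only": 5_101, "target_only": 137},
    "Renal and urinary disorders": {"both": 1, "comparator_only": 3_781, "target_only": 100},
    "Respiratory, thoracic, and mediastinal disorders": {"both": 6, "comparator_only": 6_029, "target_only": 134},
    "Skin and subcutaneous tissue disorders": {"both": 7, "comparator_only": 7_911, "target_only": 324},
    "Vascular disorders": {"both": 1, "comparator_only": 5_312, "target_only": 76},
}

#: Outcome counts (fatal, with sequelae, not recovered, recovering,
#: recovered, unknown) per muscle-related PT and group; tuples sum to the
#: published PT report totals.
MR_PT_OUTCOMES: dict[str, dict[str, tuple[int, int, int, int, int, int]]] = {
    "myalgia": {
        "both": (1, 0, 4, 2, 66, 13),
        "comparator_only": (16, 106, 1_456, 1_527, 4_650, 2_860),
        "target_only": (0, 1, 57, 69, 405, 99),
    },
    "blood creatine phosphokinase increased": {
        "both": (0, 0, 1, 2, 5, 2),
        "comparator_only": (21, 27, 449, 817, 1_218, 1_305),
        "target_only": (0, 0, 5, 5, 21, 30),
    },
    "rhabdomyolysis": {
        "both": (0, 0, 1, 2, 0, 1),
        "comparator_only": (169, 55, 329, 969, 1_247, 1_053),
        "target_only": (0, 0, 0, 1, 2, 4),
    },
    "muscle spasms": {
        "both": (0, 0, 3, 0, 11, 0),
        "comparator_only": (0, 18, 423, 305, 848, 686),
        "target_only": (0, 0, 24, 17, 75, 28),
    },
    "muscular weakness": {
        "both": (0, 0, 1, 1, 1, 0),
        "comparator_only": (11, 41, 504, 346, 433, 632),
        "target_only": (0, 0, 14, 10, 20, 7),
    },
    "myopathy": {
        "both": (0, 0, 1, 0, 3, 0),
        "comparator_only": (13, 19, 166, 240, 415, 386),
        "target_only": (0, 0, 0, 0, 11, 11),
    },
    "musculoskeletal stiffness": {
        "both": (0, 0, 0, 0, 0, 0),
        "comparator_only": (1, 7, 95, 36, 86, 122),
        "target_only": (0, 0, 5, 2, 5, 4),
    },
    "muscle disorder": {
        "both": (0, 0, 0, 0, 0, 0),
        "comparator_only": (5, 1, 47, 28, 45, 129),
        "target_only": (0, 0, 2, 0, 3, 5),
    },
    "muscle discomfort": {
        "both": (0, 0, 1, 2, 7, 1),
        "comparator_only": (0, 2, 32, 19, 90, 57),
        "target_only": (0, 0, 7, 3, 26, 8),
    },
    "musculoskeletal pain": {
        "both": (0, 0, 0, 0, 0, 0),
        "comparator_only": (0, 1, 30, 22, 34, 57),
        "target_only": (0, 0, 4, 1, 2, 1),
    },
    "musculoskeletal discomfort": {
        "both": (0, 0, 0, 2, 1, 0),
        "comparator_only": (0, 0, 23, 9, 38, 29),
        "target_only": (0, 0, 3, 2, 13, 6),
    },
    "myositis": {
        "both": (0, 0, 0, 0, 0, 0),
        "comparator_only": (14, 6, 93, 118, 101, 199),
        "target_only": (0, 0, 0, 0, 0, 0),
    },
    "necrotising myositis": {
        "both": (0, 0, 0, 0, 0, 0),
        "comparator_only": (2, 2, 31, 53, 33, 42),
        "target_only": (0, 0, 0, 0, 0, 0),
    },
}

#: Filler PT used for each SOC when a report needs a reaction in that SOC
#: but no specific PT is prescribed by the marginals.  The musculoskeletal
#: filler (arthralgia) is deliberately a non-muscle-related PT; the
#: Investigations filler avoids the CPK PT.
SOC_FILLER_PT = {
    "Blood and lymphatic system disorders": "anaemia",
    "Cardiac disorders": "palpitations",
    "Congenital, familial, and genetic disorders": "atrial septal defect",
    "Ear and labyrinth disorders": "tinnitus",
    "Endocrine disorders": "hypothyroidism",
    "Eye disorders": "vision blurred",
    "Gastrointestinal disorders": "nausea",
    "General disorders": "fatigue",
    "Hepatobiliary disorders": "hepatitis",
    "Immune system disorders": "hypersensitivity",
    "Infections and infestations": "nasopharyngitis",
    "Injury, poisoning, and procedural complications": "fall",
    "Investigations": "alanine aminotransferase increased",
    "Metabolism and nutrition disorders": "gout",
    "Musculoskeletal and connective tissue disorders": "arthralgia",
    "Nervous system disorders": "headache",
    "Psychiatric disorders": "insomnia",
    "Renal and urinary disorders": "acute kidney injury",
    "Respiratory, thoracic, and mediastinal disorders": "dyspnoea",
    "Skin and subcutaneous tissue disorders": "rash",
    "Vascular disorders": "hypertension",
}

#: PT report totals implied by the outcome tuples.
def mr_pt_totals() -> dict[str, dict[str, int]]:
    return {
        pt: {group: sum(counts) for group, counts in per_group.items()}
        for pt, per_group in MR_PT_OUTCOMES.items()
    }
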