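"""Published childhood-cancer corpus statistics used as pipeline inputs.

These are the per-subgroup case counts of the 29 206-report childhood
cancer corpus (ages 0-19, six SEER registries), the counts retained after
confidence-based abstention, and the number of age-20-39 cases the CCDI
advisory group recommends treating as pediatric for eight subgroups.
They parameterize the synthetic corpus generator (class imbalance) and the
in-corpus arithmetic (abstention rates, augmentation totals).
"""

from __future__ import annotations

#: Number of pathology reports per ICCC subgroup in the childhood corpus.
CASE_COUNTS: dict[str, int] = {
    "011": 8042, "012": 1694, "013": 294, "014": 137, "015": 212,
    "021": 1530, "022": 1993, "023": 801, "024": 316, "025": 25,
    "031": 391, "032": 1441, "033": 803, "034": 278, "035": 881, "036": 36,
    "041": 1639, "042": 26,
    "050": 71,
    "061": 736, "062": 99,
    "071": 334, "072": 87,
    "081": 617, "082": 40, "083": 627, "084": 30, "085": 25,
    "091": 840, "092": 159, "093": 6, "094": 772, "095": 225,
    "101": 155, "102": 152, "103": 688, "104": 44, "105": 18,
    "111": 16, "112": 1112, "113": 46, "114": 427, "115": 23, "116": 715,
    "121": 75, "122": 20,
    "999": 508,
}

#: Reports retained (not abstained) per subgroup under the 0.9-threshold
#: confidence model applied to the direct ICCC classifier.
RETAINED_COUNTS: dict[str, int] = {
    "011": 7171, "012": 1450, "013": 248, "014": 61, "015": 127,
    "021": 1380, "022": 1498, "023": 641, "024": 299, "025": 14,
    "031": 333, "032": 1238, "033": 681, "034": 156, "035": 704, "036": 16,
    "041": 1558, "042": 12,
    "050": 68,
    "061": 694, "062": 87,
    "071": 315, "072": 73,
    "081": 581, "082": 35, "083": 433, "084": 20, "085": 10,
    "091": 764, "092": 102, "093": 1, "094": 508, "095": 128,
    "101": 105, "102": 101, "103": 619, "104": 24, "105": 6,
    "111": 8, "112": 1096, "113": 40, "114": 392, "115": 9, "116": 639,
    "121": 44, "122": 3,
    "999": 400,
}

#: Age-20-39 cases augmented to training for the eight CCDI pediatric-type
#: subgroups (nephroblastoma, hepatoblastoma, the five bone-tumor
#: subgroups, and rhabdomyosarcoma).
CCDI_AUGMENT_COUNTS: dict[str, int] = {
    "061": 26, "071": 11,
    "081": 301, "082": 232, "083": 193, "084": 90, "085": 23,
    "091": 179,
}

#: All 47 subgroup codes (46 ICCC third-edition subgroups plus the "999"
#: not-classified/in-situ fallback), in sorted order.
SUBGROUP_CODES: tuple[str, ...] = tuple(sorted(CASE_COUNTS))

TOTAL_REPORTS: int = sum(CASE_COUNTS.values())
TOTAL_RETAINED: int = sum(RETAINED_COUNTS.values())

#: ICCC main groups and their descriptions.
MAIN_GROUPS: dict[str, str] = {
    "01": "Leukemias, myeloproliferative, and myelodysplastic diseases",
    "02": "Lymphomas and reticuloendothelial neoplasms",
    "03": "CNS and miscellaneous intracranial and intraspinal neoplasms",
    "04": "Neuroblastoma and other peripheral nervous cell tumors",
    "05": "Retinoblastoma",
    "06": "Renal tumors",
    "07": "Hepatic tumors",
    "08": "Malignant bone tumors",
    "09": "Soft tissue and other extraosseous sarcomas",
    "10": "Germ cell tumors, trophoblastic tumors, and neoplasms of gonads",
    "11": "Other malignant epithelial neoplasms and malignant melanomas",
    "12": "Other and unspecified malignant neoplasms",
    "999": "Not classified by SEER or in situ",
}
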