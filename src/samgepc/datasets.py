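"""Bundled reference DEG lists and summary counts.

These are the published per-platform directional DEG lists and summary counts
from a longitudinal β-blocker reverse-remodeling study of dilated
cardiomyopathy (47 patients, "All-Subjects" cohort ``A-S``; a 12-patient
"Super-Responder" subcohort ``S-R``), measured by RT-qPCR, microarray and
RNA-Seq.  They serve as worked examples and as desk-scale inputs for
recomputing the study's headline concordance values with this package.

Only gene symbols, directions and summary counts are bundled; p-values and
fold changes were published per-gene but are not needed for concordance
arithmetic.
"""

from __future__ import annotations

from .concordance import DirectionalSet

N_CANDIDATE_GENES = 50


def _dset(label: str, up: list[str], down: list[str]) -> DirectionalSet:
    return DirectionalSet(
        label, {**{g: "up" for g in up}, **{g: "down" for g in down}}
    )


# --- Candidate genes, A-S cohort, RT-qPCR vs microarray --------------------

CANDIDATE_AS_QPCR_R = _dset(
    "A-S qPCR R",
    up=["ADRB1", "PDK4", "PLN", "TNNT2", "THRA1"],
    down=[
        "GNAS", "GNAI2", "SLC9A1", "HK2", "PDHX", "CASQ2", "SLC8A1", "ACTA1",
        "ACTC1", "MYL2", "TNNC1", "TNNI3", "NPPA", "NPPB", "CSRP3", "CTF1",
        "IL6", "THRA2",
    ],
)

CANDIDATE_AS_ARRAY_R = _dset(
    "A-S microarray R",
    up=[
        "ADRB1", "ADRB2", "HNRNPD", "ADRA1A", "AGTR1", "PFKM", "PLN", "RYR2",
        "MYL3", "THRA1",
    ],
    down=[
        "GNAI2", "SLC9A1", "EDN1", "HK2", "CASQ2", "SLC8A1", "CANX", "ACTA1",
        "TNNI3", "DMD", "NPPA", "NPPB", "CSRP3", "IL6",
    ],
)

CANDIDATE_AS_QPCR_RVSNR = _dset(
    "A-S qPCR R/NR",
    up=[
        "ADRB1", "ADRB2", "ADRA1A", "PFKM", "PDHX", "CPT1B", "ATP2A2", "PLN",
        "RYR2", "MYH6", "MYL3",
    ],
    down=["NPPA", "NPPB"],
)

CANDIDATE_AS_ARRAY_RVSNR = _dset(
    "A-S microarray R/NR",
    up=["ADRB2", "PFKM", "PLN", "RYR2", "MYH6", "MYL3"],
    down=["SLC9A1", "EDN1", "ACTA1", "TNNI3", "DMD", "NPPA", "NPPB"],
)

# --- Candidate genes, cross-cohort (RT-qPCR, A-S vs S-R) -------------------

CANDIDATE_SR_QPCR_R = _dset(
    "S-R qPCR R",
    up=["ADRB1", "AGTR1", "PLN"],
    down=[
        "GNAI2", "SLC9A1", "AGT", "HK2", "PDHX", "CASQ2", "SLC8A1", "DMD",
        "NPPB", "IL6",
    ],
)

CANDIDATE_SR_QPCR_RVSNR = _dset(
    "S-R qPCR R/NR",
    up=["ATP2A2"],
    down=["CASQ2", "NPPB"],
)

# --- Global gene expression: published summary counts ----------------------

#: S-R cohort, microarray vs RNA-Seq (cross-platform), per analysis:
#: per-side DEG counts (up, down) and concordant counts (up, down).
GLOBAL_SR_CROSS_PLATFORM = {
    "R": {
        "array": (279, 294),
        "rnaseq": (631, 1093),
        "concordant": (15, 12),
    },
    "RvsNR": {
        "array": (869, 936),
        "rnaseq": (378, 1078),
        "concordant": (92, 205),
    },
}

#: Microarray detected 19,672 transcripts; 15,364 were also detected by
#: RNA-Seq, forming the shared analysis universe.
GLOBAL_UNIVERSE = {"array_genes": 19672, "shared_genes": 15364, "rnaseq_genes": 15366}

#: Detection counts used for platform-sensitivity comparison (R analysis):
#: microarray 573 of 19,672 vs RNA-Seq 1,724 of 15,364.
GLOBAL_SR_DETECTION_R = {"array": (573, 19672), "rnaseq": (1724, 15364)}

#: Cross-cohort (A-S vs S-R), microarray, global genes: per-cohort DEG counts
#: (up, down) and concordant counts (up, down).
GLOBAL_CROSS_COHORT_ARRAY = {
    "R": {
        "A-S": (2931, 3274),
        "S-R": (2294, 2095),
        "concordant": (60, 42),
    },
    "RvsNR": {
        "A-S": (850, 1085),
        "S-R": (869, 936),
        "concordant": (391, 393),
    },
}

#: Candidate genes, S-R cohort, microarray/RNA-Seq R/NR: 3 concordant of
#: 16 summed DEGs — compared against the global R/NR concordance.
CANDIDATE_SR_ARRAY_RNASEQ_RVSNR_COUNTS = {"concordant": 3, "summed_degs": 16}

# --- Biologic categories of the S-R R/NR concordant genes ------------------

#: (n_up, n_down) per curated category for the 297 concordant global changes.
CATEGORY_UPDOWN_COUNTS = [
    ("Contractile and associated proteins", 3, 2),
    ("Metabolism", 8, 9),
    ("Growth/hypertrophy Regulation", 8, 21),
    ("Channels, Solute Exchangers, Transporters", 8, 7),
    ("Ca2+ Handling or signaling", 0, 1),
    ("Cell Homeostasis", 8, 25),
    ("Fibroblast growth, Extracellular Matrix or TGF signaling", 3, 21),
    ("Extracellular to intracellular signaling", 16, 33),
    ("Apoptosis", 2, 8),
    ("Microtubules", 0, 3),
    ("Immune function other than cytokines", 5, 2),
    ("Vascular/thrombosis", 1, 3),
    ("Cytoskeleton", 0, 6),
    ("Gene regulation", 14, 24),
    ("Unclassified/Unknown Function", 16, 40),
]

#: LVEF-change tertile concordance inputs (candidate genes, qPCR/microarray,
#: A-S cohort): per-tertile changed-gene counts by platform and the published
#: per-tertile concordance values in percent.
TERTILE_CHANGED_COUNTS = {"qpcr": (25, 12, 20), "array": (2, 13, 17)}
TERTILE_CCPT_PERCENT = (15.0, 32.0, 59.0)
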