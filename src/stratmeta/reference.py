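"""Published reference results for the PDAC marker-stratification study.

These are the published per-cohort and pooled summary statistics for
intratumoral PROS1 stratification of pancreatic ductal adenocarcinoma
cohorts hosted on cBioPortal. They serve two purposes: as worked-example
inputs (the per-cohort hazard-ratio rows are the inputs to the pooled
meta-analysis, and the 48-gene pooled correlation panel is the input to
the differential-correlation classifier), and as regression fixtures for
the test suite.

Expression-level data are not shipped; only these printed summary rows.
"""

from __future__ import annotations

from .cohort_io import GenePanel

#: Per-cohort Mantel-Haenszel hazard ratios (HIGH vs LOW marker expression)
#: for overall survival: (cohort_id, n, hr, ci_low, ci_high).
SURVIVAL_COHORTS = [
    ("TCGA GDC", 143, 0.620, 0.394, 0.975),
    ("TCGA PanCancer", 142, 0.586, 0.377, 0.918),
    ("CPTAC Cell 2021", 112, 0.507, 0.277, 0.926),
]

#: Published pooled summary for the rows above (fixed-effects inverse variance).
#: The upper CI bound as printed is not recoverable from the per-cohort rows
#: via the stated formulas and is retained for reference only.
PUBLISHED_POOLED_HR = {
    "n": 397,
    "hr": 0.581,
    "ci_low": 0.438,
    "ci_high": 0.724,
    "weights_pct": (38, 40, 22),
    "p": 0.000135,
}

#: Pooled stratum-specific Spearman correlations of each candidate gene with
#: the marker across four PDAC cohorts, with the published delta, direction
#: and interpretation labels:
#: (gene, rho_low, rho_high, delta, direction, interpretation).
CORRELATION_PANEL = [
    ("CASP9", 0.230, 0.408, 0.178, "Negligible", "Independent correlation"),
    ("AKT1", 0.266, 0.357, 0.090, "Negligible", "Independent correlation"),
    ("CD8A", 0.348, 0.407, 0.059, "Negligible", "Independent correlation"),
    ("CDH1", 0.290, 0.333, 0.043, "Negligible", "Independent correlation"),
    ("MAPK1", 0.346, 0.384, 0.038, "Negligible", "Independent correlation"),
    ("HIF3A", 0.230, 0.268, 0.037, "Negligible", "Independent correlation"),
    ("IL1B", 0.276, 0.288, 0.012, "Negligible", "Independent correlation"),
    ("HIF1A", 0.256, 0.261, 0.005, "Negligible", "Independent correlation"),
    ("PFKFB4", -0.296, -0.295, 0.001, "Negligible", "Independent correlation"),
    ("CASP3", 0.323, 0.323, 0.000, "Negligible", "Independent correlation"),
    ("E2F1", -0.359, -0.370, -0.011, "Negligible", "Independent correlation"),
    ("PIK3CA", 0.388, 0.377, -0.011, "Negligible", "Independent correlation"),
    ("PTK2", 0.314, 0.300, -0.014, "Negligible", "Independent correlation"),
    ("NRAS", 0.304, 0.283, -0.021, "Negligible", "Independent correlation"),
    ("SNAI1", 0.306, 0.271, -0.034, "Negligible", "Independent correlation"),
    ("HRAS", -0.273, -0.319, -0.046, "Negligible", "Independent correlation"),
    ("MERTK", 0.377, 0.323, -0.054, "Negligible", "Independent correlation"),
    ("TYRO3", 0.346, 0.283, -0.064, "Negligible", "Independent correlation"),
    ("PDK1", 0.338, 0.265, -0.073, "Negligible", "Independent correlation"),
    ("STAT3", 0.343, 0.264, -0.079, "Negligible", "Independent correlation"),
    ("PFKFB3", 0.363, 0.282, -0.081, "Negligible", "Independent correlation"),
    ("CD4", 0.429, 0.346, -0.083, "Negligible", "Independent correlation"),
    ("EPAS1", 0.379, 0.296, -0.084, "Negligible", "Independent correlation"),
    ("PECAM1", 0.501, 0.328, -0.173, "Negligible", "Independent correlation"),
    ("PROM1", 0.324, 0.142, -0.181, "Negligible", "Independent correlation"),
    ("KRAS", 0.331, 0.117, -0.214, "Negligible", "Independent correlation"),
    ("IL6", 0.295, 0.065, -0.230, "Negligible", "Independent correlation"),
    ("CDK1", -0.112, -0.367, -0.255, "Negligible", "Independent correlation"),
    ("VIM", 0.410, 0.121, -0.289, "Negligible", "Independent correlation"),
    ("MYC", 0.294, -0.073, -0.367, "Decreased", "Independent correlation"),
    ("MKI67", 0.068, -0.312, -0.379, "Decreased", "Independent correlation"),
    ("CD44", 0.304, -0.118, -0.422, "Decreased", "Independent correlation"),
    ("CDK2", 0.219, -0.303, -0.522, "Decreased", "Independent correlation"),
    ("VEGFA", 0.245, -0.282, -0.527, "Decreased", "Independent correlation"),
    ("SRC", 0.254, -0.296, -0.550, "Decreased", "Independent correlation"),
    ("AXL", 0.282, -0.270, -0.552, "Decreased", "Independent correlation"),
    ("SLC2A1", 0.312, -0.300, -0.612, "Decreased", "Lower magnitude Δρ"),
    ("NOTCH1", 0.342, -0.277, -0.619, "Decreased", "Lower magnitude Δρ"),
    ("HK2", 0.272, -0.363, -0.636, "Decreased", "Lower magnitude Δρ"),
    ("TWIST1", 0.276, -0.407, -0.683, "Decreased", "Lower magnitude Δρ"),
    ("CDH2", 0.282, -0.420, -0.702, "Decreased", "Intermediate magnitude Δρ"),
    ("TNF", 0.265, -0.440, -0.705, "Decreased", "Intermediate magnitude Δρ"),
    ("TGFB1", 0.384, -0.337, -0.721, "Decreased", "Intermediate magnitude Δρ"),
    ("CA9", 0.357, -0.366, -0.723, "Decreased", "Intermediate magnitude Δρ"),
    ("MMP9", 0.300, -0.432, -0.733, "Decreased", "Intermediate magnitude Δρ"),
    ("MMP7", 0.419, -0.372, -0.791, "Decreased", "Intermediate magnitude Δρ"),
    ("MMP2", 0.468, -0.382, -0.849, "Decreased", "High magnitude Δρ"),
    ("SNAI2", 0.425, -0.431, -0.856, "Decreased", "High magnitude Δρ"),
]

MARKER_GENE = "PROS1"

#: The default candidate panel: the 48 published genes, marker excluded.
DEFAULT_PANEL = GenePanel(
    marker_gene=MARKER_GENE,
    candidate_genes=[row[0] for row in CORRELATION_PANEL],
)
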