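"""Shared vocabulary: marker groups and the seven nutrient-cycling variables."""

MARKER_GROUPS = ("16S", "ITS", "phoD")

#: Organism domain sequenced by each marker gene.
GROUP_DOMAIN = {"16S": "bacteria", "ITS": "fungi", "phoD": "phoD"}

#: Single-letter codes used in edge-type composition labels (B-B, B-F, ...).
DOMAIN_LETTER = {"bacteria": "B", "fungi": "F", "phoD": "P"}

N_VARIABLES = ("TN", "NAG", "net_Nmin", "N_inorg")
P_VARIABLES = ("TP", "AP", "AKP")
NUTRIENT_VARIABLES = N_VARIABLES + P_VARIABLES

#: Family membership of every nutrient variable (4 N-cycling + 3 P-cycling).
VARIABLE_FAMILY = {v: "N" for v in N_VARIABLES} | {v: "P" for v in P_VARIABLES}

TAXONOMY_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

COUPLED_TAXON_LABELS = ("coupled_positive", "coupled_negative")
DECOUPLED_TAXON_LABELS = ("decoupled_N", "decoupled_P")
TAXON_LABELS = COUPLED_TAXON_LABELS + DECOUPLED_TAXON_LABELS + ("inconsistent", "none")
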