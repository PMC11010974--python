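"""Canonical channel and annotation names used throughout the pipeline.

The five analysis markers drive the t-SNE embedding and the HSPC
classification; CD45, the viability dye and the scatter channels are used
only during pre-gating. PD-L1 is carried through the embedding but is not
part of the phenotype decision table.
"""

MARKERS = ("CD34", "CD38", "CD45RA", "CD123", "PD-L1")
"""Markers entering the expression matrix (scaled) and the embedding."""

CLASSIFICATION_MARKERS = ("CD34", "CD38", "CD45RA", "CD123")
"""Markers consulted by the HSPC phenotype decision table."""

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")

CHANNELS = MARKERS + ("CD45", "VIABILITY") + SCATTER_CHANNELS
"""Full analysis channel set every event table must provide."""

PATIENT_COL = "patient_id"
GROUP_COL = "group"
TSNE1 = "tSNE1"
TSNE2 = "tSNE2"

GROUP_CR = "CR"
GROUP_AD = "AD"
GROUPS = (GROUP_CR, GROUP_AD)
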