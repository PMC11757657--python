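"""Label vocabularies shared across the pipeline.

Tissue classes are integer-coded so prediction maps can be stored as plain
integer grids; IPS (infiltration pattern score) classes are the three
case-level categories derived from per-slide 1-5 infiltration scores.
"""

from __future__ import annotations

# Tissue-class codes used in prediction maps and synthetic tissue maps.
BACKGROUND = 0
PANNET = 1
NNPP = 2  # non-neoplastic pancreatic parenchyma
STROMA = 3

TISSUE_LABELS = (BACKGROUND, PANNET, NNPP, STROMA)
TISSUE_NAMES = {
    BACKGROUND: "background",
    PANNET: "PanNET",
    NNPP: "NNPP",
    STROMA: "stroma",
}
TISSUE_CODES = {name: code for code, name in TISSUE_NAMES.items()}

# Case-level infiltration pattern score classes.
IPS1 = "IPS1"  # non/minimally infiltrative
IPS2 = "IPS2"  # moderately infiltrative
IPS3 = "IPS3"  # highly infiltrative
IPS_CLASSES = (IPS1, IPS2, IPS3)
IPS_INDEX = {label: i for i, label in enumerate(IPS_CLASSES)}

# Per-slide infiltration scores range over 1..5; a case is scored from the
# total of its three slides.
SLIDE_SCORE_MIN = 1
SLIDE_SCORE_MAX = 5
N_SLIDES_PER_CASE = 3

# Total-score bands for the three case classes (inclusive).
IPS_BANDS = {
    IPS1: (3, 6),
    IPS2: (7, 9),
    IPS3: (10, 15),
}
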