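"""Closed vocabularies shared across the package."""

# MR contrasts acquired per subject (ADC is a quantitative diffusion map).
SEQUENCES = ("T1w", "GdT1w", "T2w", "FLAIR", "ADC")

# Segmented lesion compartments, in label-map order.
TISSUES = ("necrosis", "CET", "nCET", "edema")

# Intraoperative sampling sites (5-ALA fluorescence: absent/bright/weak).
SITES = ("necrosis", "core", "margin")

# Label-map integer coding. 0 = background / normal-appearing tissue.
# Hemorrhage (5) is segmented but excluded from every downstream feature.
LABEL_CODES = {"necrosis": 1, "CET": 2, "nCET": 3, "edema": 4, "hemorrhage": 5}

VALID_LABELS = frozenset(range(6))
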