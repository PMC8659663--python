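"""sicklenet: two-phase image-analysis pipeline for adhered sickle red
blood cells in protein-functionalized microfluidic channels.

Phase I segments whole-channel phase-contrast mosaics into background,
adhered sRBC and non-functionally-adhered pixels with an encoder-decoder
network trained on a combined cross-entropy + Jaccard loss; Phase II cuts
32x32 crops at detected cluster centroids and classifies them into
deformable sRBC, non-deformable sRBC or non-sRBC. Supporting analyses:
class activation maps, occlusion tests, aspect-ratio deformability
statistics, ensemble averaging, and count-agreement evaluation. A
synthetic scene generator provides fully labeled test data.
"""

from . import (
    channel,
    classification,
    deformability,
    extraction,
    interpretability,
    nn,
    pipeline,
    segmentation,
    synthetic,
)

__version__ = "0.1.0"

__all__ = [
    "channel",
    "classification",
    "deformability",
    "extraction",
    "interpretability",
    "nn",
    "pipeline",
    "segmentation",
    "synthetic",
    "__version__",
]
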