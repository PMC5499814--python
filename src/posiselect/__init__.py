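"""posiselect: genome-wide branch-site scans for positively selected genes.

A self-contained toolkit covering ortholog-catalog construction, isoform
selection, alignment and column filtering, species-tree inference, the
branch-site likelihood-ratio test of positive selection, plausibility
filtering with multiple-testing correction, and a codon-evolution simulator
for validating the whole pipeline.
"""

from .codon_model import (BranchSiteModel, BranchSiteParams, BranchSiteResults,
                          CodonRateModel, LRTResult, lrt)
from .seq_io import (CodonAlignment, OrthologGroup, Transcript,
                     parse_transcripts, parse_tree, read_catalog, write_catalog)
from .trees import SpeciesTree

__version__ = "0.1.0"


def __getattr__(name):
    # heavier entry points are imported lazily to keep `import posiselect` light
    if name == "run_scan":
        from .selection_pipeline import run_scan
        return run_scan
    if name == "run_validation":
        from .simulator import run_validation
        return run_validation
    raise AttributeError(f"module 'posiselect' has no attribute {name!r}")


__all__ = [
    "BranchSiteModel", "BranchSiteParams", "BranchSiteResults",
    "CodonRateModel", "LRTResult", "lrt",
    "CodonAlignment", "OrthologGroup", "Transcript",
    "parse_transcripts", "parse_tree", "read_catalog", "write_catalog",
    "SpeciesTree", "run_scan", "run_validation",
]
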