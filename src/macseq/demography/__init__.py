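"""SMC-HMM demographic inference from one diploid genome (PSMC-style)."""

from .bins import (BinSequence, TimeGrid, bins_from_het_positions, make_bins,
                   parse_pattern, time_grid)
from .model import (PsmcModel, PsmcResults, ScalingConstants, SmcModel,
                    forward_backward, scale_fit, state_quantities)

__all__ = [
    "BinSequence", "TimeGrid", "make_bins", "bins_from_het_positions",
    "parse_pattern", "time_grid",
    "SmcModel", "ScalingConstants", "PsmcModel", "PsmcResults",
    "forward_backward", "scale_fit", "state_quantities", "em_fit",
]


def em_fit(binseq, pattern: str = "6+29*2", iterations: int = 25, **kwargs):
    """Functional entry point: build a :class:`PsmcModel` and fit it."""
    return PsmcModel(binseq, pattern=pattern, **kwargs).fit(iterations=iterations)
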