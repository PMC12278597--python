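"""Chain-class vocabulary shared across the pipeline.

BCR chains are the variable light (VL) and heavy (VH) domains; TCR chains are
alpha/beta and gamma/delta.  For region-span reporting the classes group into
"light-type" (VL, alpha, gamma -- nucleotides covering IMGT positions 1-127)
and "heavy-type" (VH, beta, delta -- IMGT 1-128).
"""

from __future__ import annotations

#: Region names in variable-domain order (IMGT tiling).
REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

LIGHT_TYPE = frozenset({"VL", "alpha", "gamma"})
HEAVY_TYPE = frozenset({"VH", "beta", "delta"})
CHAIN_CLASSES = tuple(sorted(LIGHT_TYPE | HEAVY_TYPE))

#: Last IMGT position included in the reported nucleotide span, per type.
REPORTED_SPAN_END = {"light": 127, "heavy": 128}


def chain_type(chain_class: str) -> str:
    """Return ``"light"`` or ``"heavy"`` for a chain class."""
    if chain_class in LIGHT_TYPE:
        return "light"
    if chain_class in HEAVY_TYPE:
        return "heavy"
    raise ValueError(f"unknown chain class: {chain_class!r}")


def reported_span_end(chain_class: str) -> int:
    """Last IMGT position of the exported nucleotide span for this class."""
    return REPORTED_SPAN_END[chain_type(chain_class)]
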