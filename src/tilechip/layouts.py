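"""Bundled genome layouts.

``WS170`` carries the C. elegans WS170/ce4 chromosome lengths used by the
original tiling-array design, so that the uniform-by-length expectations for
peak placement can be reproduced without external downloads.
"""

from __future__ import annotations

from .models import GenomeLayout

# C. elegans WS170 (UCSC ce4) chromosome lengths in bp.
WS170_LENGTHS: dict[str, int] = {
    "I": 15_072_419,
    "II": 15_279_316,
    "III": 13_783_681,
    "IV": 17_493_784,
    "V": 20_919_398,
    "X": 17_718_852,
}

AUTOSOMES = ("I", "II", "III", "IV", "V")


def ws170_layout(focal: str = "X") -> GenomeLayout:
    """The WS170/ce4 layout with X as the default focal chromosome."""
    return GenomeLayout(lengths=dict(WS170_LENGTHS), focal=focal)


NAMED_LAYOUTS = {"ws170": ws170_layout, "ce4": ws170_layout}


def get_layout(name: str) -> GenomeLayout:
    try:
        return NAMED_LAYOUTS[name.lower()]()
    except KeyError:
        raise KeyError(f"unknown layout {name!r}; known: {sorted(NAMED_LAYOUTS)}") from None
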