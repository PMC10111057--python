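"""Default 16-channel 10/20 scalp montage.

The recording setup uses sixteen scalp electrodes placed per the 10/20
International System, referenced to A1 with ground at Cz (reference and
ground are not data channels).  The exact channel list is configurable
everywhere it is consumed; this module only provides the default set and
approximate 2-D head coordinates for topographic display.
"""

from __future__ import annotations

MONTAGE_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T7", "T8", "P3", "P4", "P7", "P8", "O1", "O2",
)

#: Approximate (x, y) positions on a unit head disc, nose up.
MONTAGE_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.25, 0.85), "Fp2": (0.25, 0.85),
    "F7": (-0.70, 0.50), "F3": (-0.35, 0.50), "F4": (0.35, 0.50), "F8": (0.70, 0.50),
    "T7": (-0.85, 0.00), "C3": (-0.40, 0.00), "C4": (0.40, 0.00), "T8": (0.85, 0.00),
    "P7": (-0.70, -0.50), "P3": (-0.35, -0.50), "P4": (0.35, -0.50), "P8": (0.70, -0.50),
    "O1": (-0.25, -0.85), "O2": (0.25, -0.85),
}


def channel_index(channels: tuple[str, ...] | list[str], name: str) -> int:
    """Index of ``name`` in ``channels``; raises ``ValueError`` when absent."""
    return list(channels).index(name)
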