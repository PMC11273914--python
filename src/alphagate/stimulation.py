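"""Stimulation dosimetry arithmetic."""

from __future__ import annotations


def current_density(current_ma: float, electrode_area_cm2: float) -> float:
    """Current density (mA/cm^2) of a surface electrode.

    E.g. 2 mA through a 35 cm^2 sponge electrode gives ~0.057 mA/cm^2,
    well within conventional safety limits.
    """
    if current_ma < 0:
        raise ValueError("current must be non-negative")
    if electrode_area_cm2 <= 0:
        raise ValueError("electrode area must be positive")
    return current_ma / electrode_area_cm2
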