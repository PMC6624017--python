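"""Unit conversions for the monolayer model.

All positions are micrometres, concentrations millimolar, times hours unless
a suffix says otherwise.  Diffusion coefficients and uptake rates are commonly
quoted per second in the literature, so the seconds<->hours conversion is
centralised here.
"""

from __future__ import annotations

GLUCOSE_MOLAR_MASS_G_PER_MOL = 180.16
SECONDS_PER_HOUR = 3600.0


def percent_to_millimolar(percent_w_vol: float) -> float:
    """Convert a glucose concentration in % w/vol to millimolar.

    1% w/vol is 10 g/L; dividing by the molar mass of glucose and scaling to
    mmol gives e.g. 2% -> 111 mM and 8% -> 444 mM.

    Parameters
    ----------
    percent_w_vol : float
        Grams of glucose per 100 mL, non-negative.
    """
    if percent_w_vol < 0:
        raise ValueError(f"concentration must be non-negative, got {percent_w_vol}%")
    return percent_w_vol * 10.0 / GLUCOSE_MOLAR_MASS_G_PER_MOL * 1000.0


def millimolar_to_percent(concentration_mM: float) -> float:
    """Inverse of :func:`percent_to_millimolar`."""
    if concentration_mM < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration_mM} mM")
    return concentration_mM * GLUCOSE_MOLAR_MASS_G_PER_MOL / 10.0 / 1000.0


def per_second_to_per_hour(rate_per_s: float) -> float:
    return rate_per_s * SECONDS_PER_HOUR


def per_hour_to_per_second(rate_per_h: float) -> float:
    return rate_per_h / SECONDS_PER_HOUR
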