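"""Medium construction helpers.

The sign convention: an exchange reaction is written ``1 M ->``, so uptake is
negative flux.  A published *upper limit of the uptake rate* u therefore maps
to ``lower_bound = -u``; a published *lower limit of the absorption rate* of
-5 mmol/gDW/h maps directly to ``lower_bound = -5``.
"""

from __future__ import annotations

from typing import Iterable

from .model import FREE_BOUND, MediumSpec

__all__ = ["aerobic_minimal_medium"]


def aerobic_minimal_medium(
    glucose: str,
    o2: str,
    co2: str,
    phosphate: str,
    sulfate: str,
    ammonia: str,
    free_ion_exchanges: Iterable[str] = (),
    glucose_uptake: float = 9.5,
    o2_uptake: float = 10.9,
    co2_uptake: float = 15.1,
    mineral_uptake: float = 5.0,
) -> MediumSpec:
    """Glucose minimal medium in the style used for *B. subtilis* models.

    Uptake caps default to the measured values 9.5 (glucose), 10.9 (O2) and
    15.1 (CO2) mmol/gDW/h, minerals (phosphate, sulfate, NH3) to 5, and the
    freely transported ions (H2O, Ca2+, H+, K+, Mg2+, Na+, Fe3+) get the
    conventional unbounded sentinel (-1000, 1000).  All unlisted exchanges
    are closed for uptake.
    """
    bounds: dict[str, tuple[float, float]] = {
        glucose: (-float(glucose_uptake), FREE_BOUND),
        o2: (-float(o2_uptake), FREE_BOUND),
        co2: (-float(co2_uptake), FREE_BOUND),
        phosphate: (-float(mineral_uptake), FREE_BOUND),
        sulfate: (-float(mineral_uptake), FREE_BOUND),
        ammonia: (-float(mineral_uptake), FREE_BOUND),
    }
    for rid in free_ion_exchanges:
        bounds[rid] = (-FREE_BOUND, FREE_BOUND)
    return MediumSpec(bounds=bounds, default_closed=True)
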