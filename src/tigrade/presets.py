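"""Fitted TI parameter sets for porcine tricuspid (TV) and mitral (MV)
valve tissues: chordae tendinae (CT), leaflet (LL) and papillary
muscle (PM).

Units: C1--C3 and C5 in Pa; C4 and lambda_star dimensionless.  All
fits share a bulk modulus K = 1.464e8 Pa and C2 = 0; C6 is derived
from C0 continuity at lambda_star.
"""

from __future__ import annotations

from .ti_core import TIParams

BULK_MODULUS = 1.464e8  # Pa

_TABLE = {
    # name: (C1, C2, C3, C4, C5, lambda_star)
    "TV_CT": (3.00e7, 0.0, 0.70e4, 80.00, 5.441e8, 1.086),
    "TV_LL": (1.95e4, 0.0, 1.00e5, 13.50, 4.80e7, 1.28),
    "TV_PM": (0.30e4, 0.0, 0.50e2, 28.50, 1.024e5, 1.15),
    "MV_CT": (3.37e6, 0.0, 8.82e3, 60.00, 9.21e7, 1.086),
    "MV_LL": (3.00e5, 0.0, 9.00e4, 40.00, 5.38e6, 1.010),
    "MV_PM": (1.05e4, 0.0, 0.50e3, 24.50, 1.111e5, 1.09),
}


def material(name: str) -> TIParams:
    """Look up a fitted valve-tissue parameter set by name.

    Names are ``{TV,MV}_{CT,LL,PM}`` (case-insensitive).
    """
    key = name.upper().replace("-", "_")
    try:
        c1, c2, c3, c4, c5, ls = _TABLE[key]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(_TABLE)}"
        ) from None
    return TIParams.from_fit(c1, c2, c3, c4, c5, ls, BULK_MODULUS, name=key)


def material_names() -> list[str]:
    return sorted(_TABLE)
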