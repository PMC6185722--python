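"""Bundled reference data: the six characterized digestates.

Three small tables ship with the package: the substrate composition of the
six biogas residues (the index gives the maize share of the input, in %),
their chemical properties, and the turnover parameters fitted to the
incubation experiment, with Fisher-information standard deviations and the
final RMSE of each fit. A checksum guards against a corrupted install.
"""

from __future__ import annotations

import hashlib
import io

import pandas as pd

from .property_regression import BGRProperties, derive_ratios

__all__ = ["load_fixtures", "fixture_properties", "FixtureError"]


class FixtureError(RuntimeError):
    """Bundled data failed its checksum: corrupted install."""


_COMPOSITION_CSV = """\
bgr,maize_silage,grass_silage,rye_silage,shredded_grain,pig_slurry,cattle_slurry,farmyard_manure
D17,17,0,0,0,19,64,0
D24,24,31,8,0,0,37,0
D33,33,0,25,0,20,0,22
D52,52,8,0,2,35,0,3
D61,61,0,0,5,34,0,0
D100,100,0,0,0,0,0,0
"""

_PROPERTIES_CSV = """\
bgr,dm,dm_org,ph,ct,nh4n,norg,nt,ct_nt,ct_norg
D17,5.5,28.1,8.0,38.4,2.9,3.4,6.3,6.1,11.3
D24,9.2,27.9,7.8,39.2,3.5,3.0,6.5,6.0,13.1
D33,9.6,33.0,8.0,41.3,2.0,3.0,5.0,8.3,13.8
D52,7.2,29.2,7.7,40.7,4.3,3.4,7.7,5.3,12.0
D61,8.1,33.48,7.9,42.0,5.5,2.7,8.2,5.1,15.6
D100,6.8,34.08,7.7,43.2,2.9,4.3,7.2,6.0,10.0
"""

_PARAMETERS_CSV = """\
bgr,k,sd_k,eta,sd_eta,rmse
D17,0.362,0.060,0.844,0.009,0.007
D24,0.420,0.075,0.871,0.018,0.008
D33,0.279,0.036,0.828,0.018,0.006
D52,0.506,0.081,0.851,0.016,0.008
D61,0.391,0.034,0.802,0.015,0.009
D100,0.575,0.076,0.890,0.009,0.009
"""

_SHA256 = "f716fbde3094faf7cd053f200d29b919c0135dd65dae16e6565c7d0496ec9b1c"

#: literature C_t/N_org range from a 23-digestate survey
LITERATURE_CT_NORG = (5.9, 26.4)


def load_fixtures():
    """Return (composition, properties, parameters) as indexed DataFrames."""
    blob = (_COMPOSITION_CSV + _PROPERTIES_CSV + _PARAMETERS_CSV).encode()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != _SHA256:
        raise FixtureError(
            f"bundled tables failed checksum ({digest[:12]}…): corrupted install"
        )
    comp = pd.read_csv(io.StringIO(_COMPOSITION_CSV)).set_index("bgr")
    props = pd.read_csv(io.StringIO(_PROPERTIES_CSV)).set_index("bgr")
    params = pd.read_csv(io.StringIO(_PARAMETERS_CSV)).set_index("bgr")
    return comp, props, params


def fixture_properties() -> list[BGRProperties]:
    """The six digestates as property records.

    The derived columns (norg, ct_nt, ct_norg) carry the published rounded
    values rather than being recomputed to full precision, so that the
    regression screen reproduces the published coefficients.
    """
    _, props, _ = load_fixtures()
    out = []
    for bgr, row in props.iterrows():
        out.append(
            BGRProperties(
                bgr_id=bgr, dm=row["dm"], dm_org=row["dm_org"], ph=row["ph"],
                ct=row["ct"], nh4n=row["nh4n"], nt=row["nt"],
                norg=row["norg"], ct_nt=row["ct_nt"], ct_norg=row["ct_norg"],
            )
        )
    return out
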