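"""Worked-example rate inputs.

``uk_cohort_annual_counts`` is the printed annual numerator/denominator
table from a published UK primary-care cohort study of resistant
hypertension, 1995-2015: incident case counts with person-years at risk,
and prevalent case counts with the treated-hypertensive denominator at
each year end.  It is shipped as input data for the crude-rate
operations — a worked example with known printed answers — not as
anything the package recomputes from records.  Incidence starts in 1996
(the first year is burn-in for the incident definition).
"""

from __future__ import annotations

import io

import pandas as pd

_ANNUAL = """\
year,incident_cases,person_years,prevalent_cases,prevalent_denominator
1995,,,1657,90885
1996,944,97842.4,2476,102534
1997,912,114684.9,3217,122552
1998,1250,137338.3,4236,147899
1999,2152,164924.6,6077,180905
2000,3836,211231.4,9424,238657
2001,5755,276205.0,14475,303426
2002,6808,328707.7,20158,362534
2003,8266,392679.0,26975,433536
2004,9706,453736.8,34779,502592
2005,9046,507018.8,41517,555801
2006,7684,532992.9,45993,579957
2007,6638,548982.9,48720,594430
2008,5424,562479.1,50074,613436
2009,4630,572852.2,50093,618126
2010,4253,572209.5,49080,612663
2011,3656,562208.6,47624,601090
2012,3245,557515.6,45680,589656
2013,2752,525711.3,41409,543900
2014,2243,476279.0,34678,477887
2015,1773,406033.6,26877,379686
"""


def uk_cohort_annual_counts() -> pd.DataFrame:
    """The worked-example annual counts table (see module docstring)."""
    return pd.read_csv(io.StringIO(_ANNUAL))
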