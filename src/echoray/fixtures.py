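"""Bundled per-subject surfactant protein measurements.

The package ships serum SP-A and SP-D concentrations (ng/mL) for 50 stable
COPD patients and 50 healthy controls, transcribed to full printed precision.
They are the worked material for the ROC and Welch statistics: COPD cases run
higher on both markers.  The file's SHA-256 checksum is verified on load so a
corrupted installation fails loudly rather than silently shifting statistics.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from echoray.errors import DataIntegrityError
from echoray.stats import TwoGroupSample

_FIXTURE_NAME = "sp_measurements.csv"
_FIXTURE_SHA256 = "2ac8d13611265fbccf0ba8192bcd235744d73b95b4f19b36643b8c2992f47186"


def fixture_bytes() -> bytes:
    """Raw bytes of the bundled measurement table, checksum-verified."""
    data = resources.files("echoray.data").joinpath(_FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise DataIntegrityError(
            f"bundled fixture {_FIXTURE_NAME} checksum mismatch: "
            f"expected {_FIXTURE_SHA256}, got {digest}"
        )
    return data


def load_sp_dataframe() -> pd.DataFrame:
    """The measurement table as a tidy DataFrame (subject, group, analyte, value)."""
    import io

    return pd.read_csv(io.BytesIO(fixture_bytes()))


def load_sp_fixture() -> dict[str, TwoGroupSample]:
    """Return {"SP-A": sample, "SP-D": sample} with control/COPD groups.

    ``group_a`` holds the 50 control values, ``group_b`` the 50 COPD values,
    each exactly as printed.
    """
    df = load_sp_dataframe()
    out: dict[str, TwoGroupSample] = {}
    for analyte, sub in df.groupby("analyte", sort=True):
        con = tuple(sub.loc[sub.group == "control", "value"])
        copd = tuple(sub.loc[sub.group == "copd", "value"])
        out[analyte] = TwoGroupSample(
            group_a=con, group_b=copd, label_a="control", label_b="copd", units="ng/mL"
        )
    return out
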