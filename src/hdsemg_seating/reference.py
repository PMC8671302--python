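"""Reference tables of the 16-pianist cohort used in worked examples.

The demographics table describes the studied cohort (sex, age,
anthropometrics, subcutaneous adipose tissue thickness at the lumbar
erector spinae, and musical experience).  BMI is recomputed from body mass
and height; the table also carries the BMI column exactly as published
(``bmi_reported``), which differs from mass/height^2 for three subjects --
column means quoted elsewhere refer to the published values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_demographics", "compute_bmi"]


def compute_bmi(body_mass_kg: float, height_m: float) -> float:
    """Body mass index, kg/m^2."""
    if height_m <= 0 or body_mass_kg <= 0:
        raise ValueError("mass and height must be positive")
    return body_mass_kg / height_m**2


def load_demographics() -> pd.DataFrame:
    """Demographics of the 16 pianists, one row per subject.

    Adds a ``bmi`` column computed as mass/height^2 next to the published
    ``bmi_reported`` column.
    """
    with resources.files("hdsemg_seating.data").joinpath("demographics.csv").open() as fh:
        df = pd.read_csv(fh)
    df["bmi"] = df["body_mass_kg"] / df["height_m"] ** 2
    return df
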