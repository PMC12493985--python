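"""Trophic and eutrophication status indices.

Overlying water is scored with the TRIX trophic index,

    TRIX = (log10(Chl-a * aD%O * DIN * P) + x) / m,    x = 1.5, m = 1.2,

where Chl-a is chlorophyll-a (ug/L), aD%O the absolute % deviation of
dissolved oxygen from saturation, DIN dissolved inorganic nitrogen (ug N/L)
and P soluble reactive phosphorus (ug P/L).  TRIX <= 4 is oligotrophic,
4 < TRIX <= 5 mesotrophic, TRIX > 5 eutrophic.

Sediments are scored with organic nitrogen ON = TN x 95% and the organic
index OI = TOC x ON, classified into four pollution levels (I-IV).  The OI
level boundaries are 0.05 / 0.20 / 0.50; ON boundaries default to 0.0033 /
0.066 / 0.13 and are configurable (the middle ON bound is not fixed by a
single convention in the literature).  Level boundaries are lower-inclusive.

Nutrient concentrations arrive in umol/L and are converted to the ug/L mass
scale TRIX expects using the molar masses of N and P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ValidationError

#: Molar masses (g/mol) for the umol/L -> ug/L conversions.
N_MOLAR_MASS = 14.007
P_MOLAR_MASS = 30.974

TRIX_CLASSES = ("oligotrophic", "mesotrophic", "eutrophic")
SEDIMENT_LEVELS = ("I", "II", "III", "IV")


class TrixUndefinedError(ValueError):
    """TRIX is undefined when any of its four factors is zero."""


@dataclass(frozen=True)
class TrixCoefficients:
    """Scale coefficients fixing the lower limit and span of the TRIX scale."""

    x: float = 1.5
    m: float = 1.2

    def __post_init__(self) -> None:
        if self.m == 0:
            raise ValidationError("TRIX scale divisor m must be non-zero")


@dataclass(frozen=True)
class SedimentThresholds:
    """Lower-inclusive level boundaries for OI and ON (levels I-IV)."""

    oi: tuple[float, float, float] = (0.05, 0.20, 0.50)
    on: tuple[float, float, float] = (0.0033, 0.066, 0.13)

    def __post_init__(self) -> None:
        for name, bounds in (("oi", self.oi), ("on", self.on)):
            if not all(a < b for a, b in zip(bounds, bounds[1:])):
                raise ValidationError(f"{name} thresholds must be strictly increasing: {bounds}")


def _require_non_negative(**values: float) -> None:
    for name, value in values.items():
        if value < 0:
            raise ValidationError(f"{name} must be non-negative, got {value}")


def din_mass(ammonia_umol_l: float, nitrite_umol_l: float, nitrate_umol_l: float) -> float:
    """Dissolved inorganic nitrogen in ug N/L from molar nutrient species."""
    _require_non_negative(
        ammonia=ammonia_umol_l, nitrite=nitrite_umol_l, nitrate=nitrate_umol_l
    )
    return (ammonia_umol_l + nitrite_umol_l + nitrate_umol_l) * N_MOLAR_MASS


def srp_mass(phosphate_umol_l: float) -> float:
    """Soluble reactive phosphorus in ug P/L from phosphate in umol/L."""
    _require_non_negative(phosphate=phosphate_umol_l)
    return phosphate_umol_l * P_MOLAR_MASS


def oxygen_saturation(temperature_c: float, salinity: float) -> float:
    """Equilibrium dissolved-oxygen concentration (mg/L) in seawater.

    Benson & Krause (1984) fit as a function of temperature (deg C) and
    salinity (practical scale); the standard basis for % saturation when a
    directly measured saturation value is unavailable.
    """
    t = temperature_c + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / t
        - 6.642308e7 / t**2
        + 1.2438e10 / t**3
        - 8.621949e11 / t**4
        - salinity * (0.017674 - 10.754 / t + 2140.7 / t**2)
    )
    return math.exp(ln_c)


def oxygen_deviation(
    do_mg_l: float | None = None,
    temperature_c: float | None = None,
    salinity: float | None = None,
    do_saturation_pct: float | None = None,
) -> float:
    """Absolute % deviation of dissolved oxygen from saturation (aD%O).

    If a measured saturation percentage is supplied it takes precedence;
    otherwise the saturation concentration is computed from temperature and
    salinity and compared with the measured DO concentration.
    """
    if do_saturation_pct is not None:
        _require_non_negative(do_saturation_pct=do_saturation_pct)
        return abs(do_saturation_pct - 100.0)
    if do_mg_l is None or temperature_c is None or salinity is None:
        raise ValidationError(
            "oxygen_deviation needs either do_saturation_pct or "
            "(do_mg_l, temperature_c, salinity)"
        )
    _require_non_negative(do_mg_l=do_mg_l)
    c_sat = oxygen_saturation(temperature_c, salinity)
    return abs(100.0 * do_mg_l / c_sat - 100.0)


def trix(
    chl_a_ug_l: float,
    ado_pct: float,
    din_ug_l: float,
    p_ug_l: float,
    coeffs: TrixCoefficients = TrixCoefficients(),
) -> float:
    """TRIX trophic index from its four state factors."""
    _require_non_negative(chl_a=chl_a_ug_l, ado=ado_pct, din=din_ug_l, p=p_ug_l)
    product = chl_a_ug_l * ado_pct * din_ug_l * p_ug_l
    if product == 0:
        zero = [
            name
            for name, v in (
                ("chl_a", chl_a_ug_l), ("aD%O", ado_pct), ("DIN", din_ug_l), ("P", p_ug_l),
            )
            if v == 0
        ]
        raise TrixUndefinedError(f"TRIX undefined (zero factor): {', '.join(zero)}")
    return (math.log10(product) + coeffs.x) / coeffs.m


def classify_trix(value: float) -> str:
    """Map a TRIX value onto the three-class trophic scale.

    Boundary values fall into the lower-severity class (the scale is stated
    with inclusive upper bounds: <=4 oligotrophic, <=5 mesotrophic).
    """
    if not math.isfinite(value):
        raise ValidationError(f"TRIX must be finite, got {value}")
    if value <= 4.0:
        return "oligotrophic"
    if value <= 5.0:
        return "mesotrophic"
    return "eutrophic"


def organic_nitrogen(tn_pct: float) -> float:
    """Organic nitrogen (% dry weight): ON = TN x 95%."""
    _require_non_negative(tn=tn_pct)
    return tn_pct * 0.95


def organic_index(toc_pct: float, on_pct: float) -> float:
    """Organic index: OI = TOC x ON."""
    _require_non_negative(toc=toc_pct, on=on_pct)
    return toc_pct * on_pct


def _classify_level(value: float, bounds: tuple[float, float, float]) -> str:
    # lower-inclusive: value == bound belongs to the higher level
    for level, bound in zip(SEDIMENT_LEVELS[:3], bounds):
        if value < bound:
            return level
    return "IV"


def classify_sediment(
    oi: float, on: float, thresholds: SedimentThresholds = SedimentThresholds()
) -> tuple[str, str]:
    """Pollution levels (I-IV) for the organic index and organic nitrogen."""
    _require_non_negative(oi=oi, on=on)
    return _classify_level(oi, thresholds.oi), _classify_level(on, thresholds.on)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as the reported tables use."""
    factor = 10**decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


# ---------------------------------------------------------------------------
# Table-level assessments
# ---------------------------------------------------------------------------

def assess_water(
    water: pd.DataFrame, coeffs: TrixCoefficients = TrixCoefficients()
) -> pd.DataFrame:
    """Per-site TRIX and classification from a water-chemistry table.

    Sites with missing inputs or a zero factor get ``NaN`` TRIX and a
    ``not_computable`` class rather than a fabricated number.
    """
    required = (
        "chl_a_ug_l", "ammonia_umol_l", "nitrite_umol_l", "nitrate_umol_l", "phosphate_umol_l",
    )
    rows = []
    for _, rec in water.iterrows():
        row = {"site_id": rec["site_id"]}
        if any(pd.isna(rec.get(k)) for k in required):
            row.update(
                din_ug_l=np.nan, p_ug_l=np.nan, ado_pct=np.nan,
                trix=np.nan, trix_2dp=np.nan, trix_class="not_computable",
            )
            rows.append(row)
            continue
        try:
            din = din_mass(rec["ammonia_umol_l"], rec["nitrite_umol_l"], rec["nitrate_umol_l"])
            p = srp_mass(rec["phosphate_umol_l"])
            sat = rec.get("do_saturation_pct")
            ado = oxygen_deviation(
                do_mg_l=rec.get("do_mg_l"),
                temperature_c=rec.get("temperature_c"),
                salinity=rec.get("salinity"),
                do_saturation_pct=None if pd.isna(sat) else sat,
            )
            value = trix(rec["chl_a_ug_l"], ado, din, p, coeffs)
            row.update(
                din_ug_l=din, p_ug_l=p, ado_pct=ado,
                trix=value, trix_2dp=round_half_up(value),
                trix_class=classify_trix(value),
            )
        except (TrixUndefinedError, ValidationError, TypeError):
            row.update(
                din_ug_l=np.nan, p_ug_l=np.nan, ado_pct=np.nan,
                trix=np.nan, trix_2dp=np.nan, trix_class="not_computable",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def assess_sediment(
    sediment: pd.DataFrame, thresholds: SedimentThresholds = SedimentThresholds()
) -> pd.DataFrame:
    """Per-site ON, OI and pollution levels from a sediment-chemistry table."""
    rows = []
    for _, rec in sediment.iterrows():
        row = {"site_id": rec["site_id"]}
        if pd.isna(rec["tn_pct"]) or pd.isna(rec["toc_pct"]):
            row.update(
                on_pct=np.nan, oi=np.nan, on_2dp=np.nan, oi_2dp=np.nan,
                on_level="not_computable", oi_level="not_computable",
            )
        else:
            on = organic_nitrogen(rec["tn_pct"])
            oi = organic_index(rec["toc_pct"], on)
            oi_level, on_level = classify_sediment(oi, on, thresholds)
            row.update(
                on_pct=on, oi=oi,
                on_2dp=round_half_up(on), oi_2dp=round_half_up(oi),
                on_level=on_level, oi_level=oi_level,
            )
        rows.append(row)
    return pd.DataFrame(rows)
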