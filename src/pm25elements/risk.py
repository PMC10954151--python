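"""US-EPA style inhalation risk metrics for PM2.5-bound elements.

Non-carcinogenic pathway:
    ADD = C * IR * ED * EFreq / (BW * AT_nc)      [ng/kg/day]
    HQ  = ADD / RfD                                (>1 flags potential risk)

Carcinogenic pathway:
    LADD = C * IR * ED * EFreq / (BW * AT_c)       (AT_c a 70-year lifetime)
    SF   = IUR * (1 / IR) * BW
    ELCR = LADD * SF, judged against the acceptable band [1e-6, 1e-4].

IUR values are declared per (ug/m3); since concentrations are canonical
ng/m3, an explicit ng->ug factor keeps ELCR dimensionless.  Two age groups
are evaluated: adolescents (12-18 y) and adults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import ConcentrationTable, SiteSummary, ValidationError, apply_nd_policy
from .study_tables import EXPOSURE_DEFAULTS, IUR_DEFAULTS, RFD_DEFAULTS

NON_CARCINOGENS = ("Co", "Ni", "Cu", "Zn", "As", "Pb")
CARCINOGENS = ("Ni", "As", "Pb")
AGE_GROUPS = ("adolescent", "adult")

#: acceptable excess-lifetime-cancer-risk band
ELCR_BAND = (1e-6, 1e-4)

#: ng -> ug, the IUR concentration-unit conversion
NG_TO_IUR_UNIT = 1e-3


@dataclass(frozen=True)
class ExposureParams:
    """Inhalation exposure factors for one age group.

    IR m3/day; ED years; EFreq days/year; BW kg; averaging times in days
    (AT_nc non-carcinogenic, AT_c carcinogenic / lifetime).
    """

    IR: float
    ED: float
    EFreq: float
    BW: float
    AT_nc: float
    AT_c: float

    def __post_init__(self):
        vals = (self.IR, self.ED, self.EFreq, self.BW, self.AT_nc, self.AT_c)
        if any(v <= 0 for v in vals):
            raise ValidationError("exposure factors must be positive")
        if self.EFreq > 366:
            raise ValidationError("EFreq cannot exceed 366 days/year")

    @classmethod
    def default(cls, group: str) -> "ExposureParams":
        try:
            return cls(**EXPOSURE_DEFAULTS[group])
        except KeyError:
            raise ValidationError(f"unknown age group {group!r}") from None


@dataclass(frozen=True)
class ToxicityTable:
    """RfD (ng/kg/day) per non-carcinogen and IUR ((ug/m3)^-1) per carcinogen."""

    rfd: dict[str, float] = field(default_factory=lambda: dict(RFD_DEFAULTS))
    iur: dict[str, float] = field(default_factory=lambda: dict(IUR_DEFAULTS))

    def __post_init__(self):
        if any(v <= 0 for v in self.rfd.values()):
            raise ValidationError("RfD values must be positive")
        if any(v < 0 for v in self.iur.values()):
            raise ValidationError("IUR values must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "ToxicityTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(rfd={k: float(v) for k, v in doc.get("rfd", {}).items()},
                   iur={k: float(v) for k, v in doc.get("iur", {}).items()})


def load_exposure_yaml(path) -> dict[str, ExposureParams]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {group: ExposureParams(**{k: float(v) for k, v in params.items()})
            for group, params in doc.items()}


def write_default_risk_config(path) -> None:
    """Editable single-file config: age-group exposure factors + toxicity."""
    doc = {"exposure": EXPOSURE_DEFAULTS,
           "toxicity": {"rfd": RFD_DEFAULTS, "iur": IUR_DEFAULTS}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def average_daily_dose(C, p: ExposureParams) -> np.ndarray | float:
    """ADD in ng/kg/day from concentration(s) C in ng/m3."""
    C = np.asarray(C, float)
    if np.nanmin(C, initial=0.0) < 0:
        raise ValidationError("concentration must be >= 0")
    out = C * p.IR * p.ED * p.EFreq / (p.BW * p.AT_nc)
    return float(out) if out.ndim == 0 else out


def lifetime_add(C, p: ExposureParams) -> np.ndarray | float:
    """LADD: the same dose averaged over a lifetime (AT_c)."""
    C = np.asarray(C, float)
    out = C * p.IR * p.ED * p.EFreq / (p.BW * p.AT_c)
    return float(out) if out.ndim == 0 else out


def hazard_quotient(add, rfd: float):
    """HQ = ADD / RfD; significant iff HQ > 1."""
    if not rfd > 0:
        raise ValidationError("RfD must be positive")
    out = np.asarray(add, float) / rfd
    return float(out) if out.ndim == 0 else out


def slope_factor(iur: float, p: ExposureParams,
                 unit_factor: float = NG_TO_IUR_UNIT) -> float:
    """SF = IUR * (1/IR) * BW, in (ng/kg/day)^-1 after unit conversion."""
    if iur < 0:
        raise ValidationError("IUR must be >= 0")
    return iur * (1.0 / p.IR) * p.BW * unit_factor


def elcr(ladd, sf: float):
    """Excess lifetime cancer risk = LADD * SF."""
    out = np.asarray(ladd, float) * sf
    return float(out) if out.ndim == 0 else out


def classify_elcr(value: float, band=ELCR_BAND) -> str:
    if value < band[0]:
        return "below"
    if value <= band[1]:
        return "acceptable"
    return "above"


def _aggregate(values: np.ndarray, n_nd: int) -> dict:
    vals = values[np.isfinite(values)]
    return {"mean": vals.mean() if vals.size else np.nan,
            "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
            "min": np.nan if n_nd > 0 else (vals.min() if vals.size else np.nan),
            "max": vals.max() if vals.size else np.nan,
            "n": int(vals.size), "n_nd": n_nd}


def risk_table(table: ConcentrationTable,
               exposure: dict[str, ExposureParams] | None = None,
               toxicity: ToxicityTable | None = None,
               nd_policy: str = "exclude") -> pd.DataFrame:
    """Per-sample HQ and ELCR, aggregated per (site, element, age group).

    Not-detected concentrations propagate as not-detected under the default
    policy: they are excluded from the aggregation and force an "N.D."
    (NaN) minimum, mirroring the campaign's printed tables.
    """
    exposure = exposure or {g: ExposureParams.default(g) for g in AGE_GROUPS}
    toxicity = toxicity or ToxicityTable()
    mat = apply_nd_policy(table, nd_policy)
    rows = []
    for site in table.sites:
        idx = table.values.index[table.values["site"] == site]
        for group, params in exposure.items():
            for element in NON_CARCINOGENS:
                if element not in toxicity.rfd:
                    raise ValidationError(f"no RfD for {element}")
                C = mat.loc[idx, element].to_numpy(float)
                n_nd = int((table.flags.loc[idx, element] == "not_detected").sum())
                hq = hazard_quotient(average_daily_dose(C, params),
                                     toxicity.rfd[element])
                rec = {"site": site, "group": group, "element": element,
                       "metric": "HQ", **_aggregate(np.asarray(hq), n_nd)}
                rec["flag"] = "potential_risk" if rec["mean"] > 1 else "negligible"
                rows.append(rec)
            for element in CARCINOGENS:
                C = mat.loc[idx, element].to_numpy(float)
                n_nd = int((table.flags.loc[idx, element] == "not_detected").sum())
                sf = slope_factor(toxicity.iur.get(element, 0.0), params)
                risk = elcr(lifetime_add(C, params), sf)
                rec = {"site": site, "group": group, "element": element,
                       "metric": "ELCR", **_aggregate(np.asarray(risk), n_nd)}
                rec["flag"] = classify_elcr(rec["mean"])
                rows.append(rec)
    return pd.DataFrame(rows).set_index(["metric", "site", "group", "element"])


def risk_from_means(summary: SiteSummary,
                    exposure: dict[str, ExposureParams] | None = None,
                    toxicity: ToxicityTable | None = None) -> pd.DataFrame:
    """HQ and ELCR evaluated at site-mean concentrations (both metrics are
    linear in C, so this equals the mean of per-sample values)."""
    exposure = exposure or {g: ExposureParams.default(g) for g in AGE_GROUPS}
    toxicity = toxicity or ToxicityTable()
    rows = []
    for site in summary.sites:
        for group, params in exposure.items():
            for element in NON_CARCINOGENS:
                C = summary.mean(site, element)
                hq = hazard_quotient(average_daily_dose(C, params),
                                     toxicity.rfd[element])
                rows.append({"site": site, "group": group, "element": element,
                             "metric": "HQ", "value": hq,
                             "flag": "potential_risk" if hq > 1 else "negligible"})
            for element in CARCINOGENS:
                C = summary.mean(site, element)
                sf = slope_factor(toxicity.iur.get(element, 0.0), params)
                value = elcr(lifetime_add(C, params), sf)
                rows.append({"site": site, "group": group, "element": element,
                             "metric": "ELCR", "value": value,
                             "flag": classify_elcr(value)})
    return pd.DataFrame(rows).set_index(["metric", "site", "group", "element"])
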