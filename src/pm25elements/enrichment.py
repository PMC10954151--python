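"""Crustal enrichment factors with Fe reference and log-EF classification.

EF(E) = (C_E / C_R)_air / (a_E / a_R)_crust with R the reference element
(Fe by default), C site-mean air concentrations and a crustal mass
fractions.  log10(EF) < 1 is read as "not enriched" (crustal origin),
[1, 3) slightly, [3, 4] moderately and > 4 strongly enriched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .core import SiteSummary, ValidationError
from .study_tables import CRUSTAL_CRC, CRUSTAL_FE_AL_033

#: the elements for which the campaign reports EFs (reference Fe included,
#: its EF is identically 1)
EF_ELEMENTS = ("Ba", "Se", "Sc", "Br", "Cl", "Zn", "Co", "Pb", "Cu", "As",
               "Ga", "Ni", "Cr", "Sr", "Al", "V", "Mn", "Fe")

#: class band edges on log10(EF): (<1, [1,3), [3,4], >4)
DEFAULT_BANDS = (1.0, 3.0, 4.0)
CLASSES = ("not_enriched", "slightly", "moderately", "strongly")


@dataclass(frozen=True)
class CrustalReference:
    """Upper-continental-crust mass fractions (%) with a source tag."""

    abundances: dict[str, float]
    tag: str = "custom"

    def __post_init__(self):
        if any(v <= 0 for v in self.abundances.values()):
            raise ValidationError("crustal abundances must be positive")

    def abundance(self, element: str) -> float:
        try:
            return self.abundances[element]
        except KeyError:
            raise ValidationError(
                f"no crustal abundance for element {element!r}") from None

    def ratio(self, element: str, reference: str) -> float:
        return self.abundance(element) / self.abundance(reference)

    @classmethod
    def default(cls) -> "CrustalReference":
        """Composition with the Fe/Al mass ratio 0.33 the campaign adopted."""
        return cls(dict(CRUSTAL_FE_AL_033), tag="fe_al_033")

    @classmethod
    def crc(cls) -> "CrustalReference":
        """CRC-handbook composition (Fe/Al = 0.68)."""
        return cls(dict(CRUSTAL_CRC), tag="crc")

    @classmethod
    def from_yaml(cls, path) -> "CrustalReference":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls({k: float(v) for k, v in doc["abundances"].items()},
                   tag=str(doc.get("tag", "custom")))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"tag": self.tag, "abundances": self.abundances}, fh)


def classify_enrichment(log_ef: float,
                        bands: tuple[float, float, float] = DEFAULT_BANDS) -> str:
    """Map log10(EF) onto the enrichment classes (monotone in log_ef)."""
    if not math.isfinite(log_ef):
        raise ValidationError("log EF must be finite")
    lo, mid, hi = bands
    if log_ef < lo:
        return "not_enriched"
    if log_ef < mid:
        return "slightly"
    if log_ef <= hi:
        return "moderately"
    return "strongly"


def enrichment_factor(summary: SiteSummary, crust: CrustalReference,
                      element: str, site: str,
                      reference: str = "Fe") -> dict:
    """EF of one element at one site from site-mean concentrations."""
    mean_e = summary.mean(site, element)
    mean_r = summary.mean(site, reference)
    if not mean_r > 0:
        raise ValidationError(f"reference {reference} mean not positive at {site}")
    if not mean_e > 0:
        raise ValidationError(f"element {element} mean not positive at {site}")
    ef = (mean_e / mean_r) / crust.ratio(element, reference)
    log_ef = math.log10(ef)
    return {"site": site, "element": element, "reference": reference,
            "EF": ef, "logEF": log_ef, "class": classify_enrichment(log_ef)}


def ef_table(summary: SiteSummary, crust: CrustalReference | None = None,
             elements=EF_ELEMENTS, reference: str = "Fe") -> pd.DataFrame:
    """EF / logEF / class per (site, element); reference element included
    with EF = 1 by construction."""
    crust = crust or CrustalReference.default()
    rows = [enrichment_factor(summary, crust, el, site, reference)
            for site in summary.sites for el in elements]
    return pd.DataFrame(rows).set_index(["site", "element"])
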