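"""Core containers: element panel, concentration tables, site summaries.

A :class:`ConcentrationTable` holds per-sample element concentrations in a
single canonical unit (ng/m3) together with measurement flags so that
below-detection-limit samples can be excluded (the default), zero-substituted
or half-minimum-substituted downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_tables import ELEMENTS, NATIVE_UNITS, SITE_N, SITE_STATISTICS

ALLOWED_UNITS = ("ng/m3", "ug/m3")
ND_TOKEN = "N.D."

#: measurement flags
MEASURED = "measured"
NOT_DETECTED = "not_detected"
MISSING = "missing"


class FormatError(ValueError):
    """Input file does not follow the expected CSV dialect."""


class ValidationError(ValueError):
    """Input values violate a contract (negative concentration, bad date...)."""


def unit_factor_to_ng(unit: str) -> float:
    """Multiplier converting a mass-per-volume unit to ng/m3."""
    if unit == "ng/m3":
        return 1.0
    if unit == "ug/m3":
        return 1000.0
    raise ValidationError(f"unsupported unit {unit!r}; allowed: {ALLOWED_UNITS}")


@dataclass(frozen=True)
class ElementPanel:
    """Ordered element identifiers plus each element's native reporting unit."""

    symbols: tuple[str, ...]
    native_units: dict[str, str]

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("panel symbols must be unique")
        for sym in self.symbols:
            unit = self.native_units.get(sym)
            if unit not in ALLOWED_UNITS:
                raise ValidationError(
                    f"element {sym}: unit {unit!r} not in {ALLOWED_UNITS}")

    @classmethod
    def default(cls) -> "ElementPanel":
        """The campaign's 25-element panel."""
        return cls(symbols=ELEMENTS, native_units=dict(NATIVE_UNITS))


@dataclass
class ConcentrationTable:
    """Per-sample, per-element concentrations in canonical ng/m3.

    ``values`` has columns ``site``, ``date`` and one column per panel
    element (float, NaN where not detected or missing); ``flags`` mirrors the
    element columns with ``measured`` / ``not_detected`` / ``missing``.
    """

    panel: ElementPanel
    values: pd.DataFrame
    flags: pd.DataFrame
    unit: str = "ng/m3"

    def __post_init__(self):
        for sym in self.panel.symbols:
            if sym not in self.values.columns:
                raise ValidationError(f"missing element column {sym}")
        mat = self.values[list(self.panel.symbols)].to_numpy(float)
        if np.nanmin(mat, initial=0.0) < 0:
            raise ValidationError("negative concentration in table")

    @property
    def sites(self) -> list[str]:
        return list(pd.unique(self.values["site"]))

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def matrix(self) -> pd.DataFrame:
        """n_samples x n_elements view (ng/m3)."""
        return self.values[list(self.panel.symbols)]

    def for_site(self, site: str) -> "ConcentrationTable":
        mask = self.values["site"] == site
        if not mask.any():
            raise ValidationError(f"no samples for site {site!r}")
        return ConcentrationTable(self.panel, self.values[mask].reset_index(drop=True),
                                  self.flags[mask].reset_index(drop=True), self.unit)


@dataclass
class SiteSummary:
    """Mean/sd/min/max/n per (site, element), in ng/m3.

    ``frame`` is indexed by (site, element) with columns
    ``mean, sd, min, max, n``; a NaN min together with ``n_nd > 0`` mirrors a
    printed "N.D." minimum.
    """

    frame: pd.DataFrame

    def stat(self, site: str, element: str, which: str = "mean") -> float:
        return float(self.frame.loc[(site, element), which])

    def mean(self, site: str, element: str) -> float:
        return self.stat(site, element, "mean")

    @property
    def sites(self) -> list[str]:
        return list(self.frame.index.get_level_values("site").unique())

    @classmethod
    def from_site_statistics(cls, stats: dict | None = None,
                             panel: ElementPanel | None = None,
                             site_n: dict | None = None) -> "SiteSummary":
        """Build a summary directly from a published site-statistics table
        (native units converted to ng/m3)."""
        stats = SITE_STATISTICS if stats is None else stats
        panel = panel or ElementPanel.default()
        site_n = SITE_N if site_n is None else site_n
        rows = []
        for sym in panel.symbols:
            f = unit_factor_to_ng(panel.native_units[sym])
            for site, (mean, sd, lo, hi) in stats[sym].items():
                rows.append({
                    "site": site, "element": sym,
                    "mean": mean * f, "sd": sd * f,
                    "min": np.nan if lo is None else lo * f,
                    "max": hi * f, "n": site_n[site],
                    "n_nd": 1 if lo is None else 0,
                })
        frame = pd.DataFrame(rows).set_index(["site", "element"])
        return cls(frame)


def _parse_element_header(col: str) -> tuple[str, str]:
    """``"Si[ug/m3]"`` -> ``("Si", "ug/m3")``; bare names default to ng/m3."""
    col = col.strip()
    if "[" in col:
        if not col.endswith("]"):
            raise FormatError(f"malformed element column {col!r}")
        sym, unit = col[:-1].split("[", 1)
        return sym.strip(), unit.strip()
    return col, "ng/m3"


def read_concentration_table(path, panel: ElementPanel | None = None) -> ConcentrationTable:
    """Read the ``site,date,<element>[unit]`` CSV dialect into canonical ng/m3.

    ``N.D.`` cells are flagged not-detected; empty cells are flagged missing.
    """
    panel = panel or ElementPanel.default()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      comment="#", skipinitialspace=True)
    cols = list(raw.columns)
    if len(cols) < 3 or cols[0] != "site" or cols[1] != "date":
        raise FormatError("expected header starting with site,date")
    sym_units = {}
    for col in cols[2:]:
        sym, unit = _parse_element_header(col)
        if sym not in panel.symbols:
            raise FormatError(f"unknown element column {sym!r}")
        if unit not in ALLOWED_UNITS:
            raise FormatError(f"element {sym}: bad unit {unit!r}")
        sym_units[col] = (sym, unit)
    missing_cols = set(panel.symbols) - {s for s, _ in sym_units.values()}
    if missing_cols:
        raise FormatError(f"panel elements absent from file: {sorted(missing_cols)}")

    try:
        dates = pd.to_datetime(raw["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable date: {exc}") from exc

    values = pd.DataFrame({"site": raw["site"].astype(str), "date": dates})
    flags = pd.DataFrame(index=raw.index)
    for col, (sym, unit) in sym_units.items():
        cells = raw[col].str.strip()
        nd = cells == ND_TOKEN
        empty = cells == ""
        numeric = pd.to_numeric(cells.where(~(nd | empty), None), errors="raise")
        if (numeric.dropna() < 0).any():
            raise ValidationError(f"negative value in column {sym}")
        values[sym] = numeric * unit_factor_to_ng(unit)
        flags[sym] = np.where(nd, NOT_DETECTED, np.where(empty, MISSING, MEASURED))
    return ConcentrationTable(panel, values, flags)


def write_concentration_table(table: ConcentrationTable, path) -> None:
    """Write a table back out in each element's native unit (round-trip safe)."""
    out = pd.DataFrame({"site": table.values["site"],
                        "date": table.values["date"].dt.strftime("%Y-%m-%d")})
    for sym in table.panel.symbols:
        f = unit_factor_to_ng(table.panel.native_units[sym])
        col = table.values[sym] / f
        cells = col.map(lambda v: "" if pd.isna(v) else repr(float(v)))
        cells = cells.where(table.flags[sym] != NOT_DETECTED, ND_TOKEN)
        out[f"{sym}[{table.panel.native_units[sym].replace('ug/m3', 'ug/m3')}]"] = cells
    out.to_csv(path, index=False)


def apply_nd_policy(table: ConcentrationTable, policy: str = "exclude") -> pd.DataFrame:
    """Return the element matrix with the not-detected policy applied.

    ``exclude``   -> N.D. stays NaN (dropped from summaries / sums)
    ``zero``      -> N.D. replaced by 0
    ``half_min``  -> N.D. replaced by half the site minimum detected value
    """
    mat = table.matrix().copy()
    if policy == "exclude":
        return mat
    if policy == "zero":
        return mat.fillna(0.0)
    if policy == "half_min":
        out = mat.copy()
        for site in table.sites:
            idx = table.values.index[table.values["site"] == site]
            sub = mat.loc[idx]
            out.loc[idx] = sub.fillna(sub.min() / 2.0)
        return out
    raise ValidationError(f"unknown N.D. policy {policy!r}")


def summarise_by_site(table: ConcentrationTable, nd_policy: str = "exclude") -> SiteSummary:
    """Site-level mean, sample sd (n-1), min, max and n per element."""
    mat = apply_nd_policy(table, nd_policy)
    rows = []
    for site in table.sites:
        idx = table.values.index[table.values["site"] == site]
        if len(idx) == 0:
            raise ValidationError(f"empty site group {site!r}")
        for sym in table.panel.symbols:
            col = mat.loc[idx, sym].dropna()
            n = int(col.size)
            n_nd = int((table.flags.loc[idx, sym] == NOT_DETECTED).sum())
            rows.append({
                "site": site, "element": sym,
                "mean": col.mean() if n else np.nan,
                "sd": col.std(ddof=1) if n > 1 else np.nan,
                "min": col.min() if n else np.nan,
                "max": col.max() if n else np.nan,
                "n": n, "n_nd": n_nd,
            })
    return SiteSummary(pd.DataFrame(rows).set_index(["site", "element"]))


def site_ratio_table(summary: SiteSummary, num_site: str, den_site: str
                     ) -> tuple[pd.Series, float]:
    """Per-element ratio of site mean concentrations plus the panel-total ratio.

    The total ratio divides the sums of the per-element means (ng/m3) over
    the full panel, mirroring the published BOS/COS and BOS/POS comparison.
    """
    for site in (num_site, den_site):
        if site not in summary.sites:
            raise ValidationError(f"site {site!r} absent from summary")
    num = summary.frame.xs(num_site, level="site")["mean"]
    den = summary.frame.xs(den_site, level="site")["mean"]
    if (den == 0).any() or den.isna().any():
        bad = den.index[(den == 0) | den.isna()].tolist()
        raise ValidationError(f"zero/undefined denominator mean for {bad}")
    ratios = (num / den).rename(f"{num_site}/{den_site}")
    total_ratio = float(num.sum() / den.sum())
    return ratios, total_ratio
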