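"""Concentration-table I/O, unit harmonisation and site summaries."""

import io

import numpy as np
import pandas as pd
import pytest

from pm25elements.core import (ElementPanel, FormatError, ValidationError,
                               NOT_DETECTED, read_concentration_table,
                               site_ratio_table, summarise_by_site,
                               unit_factor_to_ng, write_concentration_table)


def _mini_panel():
    return ElementPanel(symbols=("Si", "As", "Fe"),
                        native_units={"Si": "ug/m3", "As": "ng/m3", "Fe": "ug/m3"})


MINI_CSV = """site,date,Si[ug/m3],As[ng/m3],Fe[ug/m3]
COS,2020-07-01,596,9.95,1.43
COS,2020-07-05,600,N.D.,1.50
BOS,2021-02-17,865,28.4,2.95
"""


def test_read_converts_to_canonical_ng(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text(MINI_CSV)
    table = read_concentration_table(path, _mini_panel())
    assert table.values.loc[0, "Si"] == 596_000.0
    assert table.values.loc[0, "As"] == 9.95
    assert table.flags.loc[1, "As"] == NOT_DETECTED
    assert np.isnan(table.values.loc[1, "As"])


def test_write_read_round_trip(tmp_path):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    p1.write_text(MINI_CSV)
    table = read_concentration_table(p1, _mini_panel())
    write_concentration_table(table, p2)
    again = read_concentration_table(p2, _mini_panel())
    pd.testing.assert_frame_equal(table.values, again.values)
    pd.testing.assert_frame_equal(table.flags, again.flags)


@pytest.mark.parametrize("bad,err", [
    ("site,date,Xx[ng/m3]\nCOS,2020-07-01,1\n", FormatError),
    ("site,date,Si[ug/m3],As[ng/m3],Fe[ug/m3]\nCOS,2020-07-01,-3,1,1\n",
     ValidationError),
    ("site,date,Si[ug/m3],As[ng/m3],Fe[ug/m3]\nCOS,notadate,3,1,1\n",
     ValidationError),
])
def test_read_rejects_malformed_input(tmp_path, bad, err):
    path = tmp_path / "bad.csv"
    path.write_text(bad)
    with pytest.raises(err):
        read_concentration_table(path, _mini_panel())


def test_unit_conversion_is_involutive():
    vals = np.array([0.138, 596.0, 1.43])
    ng = vals * unit_factor_to_ng("ug/m3")
    back = ng / unit_factor_to_ng("ug/m3")
    np.testing.assert_array_equal(back, vals)


def _table_from_rows(rows):
    panel = _mini_panel()
    values = pd.DataFrame(rows, columns=["site", "date", "Si", "As", "Fe"])
    values["date"] = pd.to_datetime(values["date"])
    flags = pd.DataFrame("measured", index=values.index,
                         columns=list(panel.symbols))
    from pm25elements.core import ConcentrationTable
    return ConcentrationTable(panel, values, flags)


def test_summarise_hand_arithmetic():
    table = _table_from_rows([("A", "2020-07-01", 1.0, 5.0, 5.0),
                              ("A", "2020-07-02", 2.0, 5.0, 5.0),
                              ("A", "2020-07-03", 3.0, 5.0, 5.0)])
    s = summarise_by_site(table)
    assert s.mean("A", "Si") == 2.0
    assert s.stat("A", "Si", "sd") == 1.0
    assert s.stat("A", "Si", "min") == 1.0
    assert s.stat("A", "Si", "max") == 3.0
    # constant column
    assert s.stat("A", "As", "sd") == 0.0
    assert s.stat("A", "As", "min") == s.stat("A", "As", "max") == 5.0


def test_summarise_permutation_invariant():
    rows = [("A", f"2020-07-{d:02d}", float(d), float(d) * 2, 1.0)
            for d in range(1, 11)]
    s1 = summarise_by_site(_table_from_rows(rows))
    s2 = summarise_by_site(_table_from_rows(rows[::-1]))
    pd.testing.assert_frame_equal(s1.frame, s2.frame)


def test_site_ratio_published_values(published_summary):
    ratios_c, total_c = site_ratio_table(published_summary, "BOS", "COS")
    assert round(ratios_c["Se"], 2) == 4.24
    ratios_p, total_p = site_ratio_table(published_summary, "BOS", "POS")
    assert round(ratios_p["S"], 2) == 8.67
    assert round(total_c, 2) == 1.47
    assert round(total_p, 2) == 1.46


def test_total_ratio_matches_brute_force(published_summary):
    _, total = site_ratio_table(published_summary, "BOS", "COS")
    num = den = 0.0
    for el in published_summary.frame.index.get_level_values("element").unique():
        num += published_summary.mean("BOS", el)
        den += published_summary.mean("COS", el)
    assert total == pytest.approx(num / den, rel=1e-12)


def test_identical_sites_give_unit_ratios():
    table = _table_from_rows([("A", "2020-07-01", 1.0, 2.0, 3.0),
                              ("A", "2020-07-02", 2.0, 3.0, 4.0),
                              ("B", "2020-07-01", 1.0, 2.0, 3.0),
                              ("B", "2020-07-02", 2.0, 3.0, 4.0)])
    ratios, total = site_ratio_table(summarise_by_site(table), "A", "B")
    assert np.allclose(ratios, 1.0)
    assert total == pytest.approx(1.0)
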