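"""Shared builders for test fixtures."""

import pandas as pd

from vascde.quantification import CountTable


def make_count_table() -> CountTable:
    """Two lanes per condition with one clearly induced gene."""
    counts = pd.DataFrame(
        {
            "c1": {"gA": 50, "gB": 40, "gC": 0},
            "c2": {"gA": 55, "gB": 38, "gC": 1},
            "o1": {"gA": 48, "gB": 160, "gC": 0},
            "o2": {"gA": 52, "gB": 170, "gC": 2},
        }
    )
    samples = pd.DataFrame(
        {
            "condition": ["control", "control", "oe", "oe"],
            "lane": [1, 2, 1, 2],
        },
        index=pd.Index(["c1", "c2", "o1", "o2"], name="sample_id"),
    )
    totals = pd.Series({"c1": 1000, "c2": 1100, "o1": 1050, "o2": 1150})
    return CountTable(counts=counts, samples=samples, mapped_total=totals)
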