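"""Stage boundary ages and time-bin construction.

Boundary ages follow the International Chronostratigraphic Chart (v2023/06)
for the late Carboniferous and Permian.  Two binning schemes are provided:
the coarse five-bin early/middle/late Permian scheme (bins chosen to be of
roughly equal length and to hold two or more taxa each) and the fine
stage-level scheme running from the Gzhelian to the Changhsingian.
"""

from __future__ import annotations

from .datamodel import TimeBin, TimeBinSet

__all__ = ["ICS_CHART_VERSION", "STAGE_BOUNDARIES", "make_bins"]

ICS_CHART_VERSION = "ICS 2023/06"

# stage -> (start Ma, end Ma), oldest first
STAGE_BOUNDARIES: dict[str, tuple[float, float]] = {
    "Gzhelian": (303.7, 298.9),
    "Asselian": (298.9, 293.52),
    "Sakmarian": (293.52, 290.1),
    "Artinskian": (290.1, 283.5),
    "Kungurian": (283.5, 273.01),
    "Roadian": (273.01, 266.9),
    "Wordian": (266.9, 264.28),
    "Capitanian": (264.28, 259.51),
    "Wuchiapingian": (259.51, 254.14),
    "Changhsingian": (254.14, 251.902),
}

_FIVE_BIN_SPEC = [
    ("Asselian-Sakmarian", "Asselian", "Sakmarian"),
    ("Artinskian", "Artinskian", "Artinskian"),
    ("Kungurian", "Kungurian", "Kungurian"),
    ("Guadalupian", "Roadian", "Capitanian"),
    ("Lopingian", "Wuchiapingian", "Changhsingian"),
]


def make_bins(spec: str = "five", chart: dict | None = None) -> TimeBinSet:
    """Build a bin set: ``"five"`` coarse Permian bins or ``"stages"``
    (Gzhelian through Changhsingian, one bin per stage)."""
    chart = chart or STAGE_BOUNDARIES
    if spec == "five":
        bins = []
        for name, first, last in _FIVE_BIN_SPEC:
            if first not in chart or last not in chart:
                raise KeyError(f"unknown stage name {first!r} or {last!r}")
            bins.append(TimeBin(name=name, start=chart[first][0], end=chart[last][1]))
        return TimeBinSet(bins)
    if spec == "stages":
        return TimeBinSet(
            [TimeBin(name=n, start=se[0], end=se[1]) for n, se in chart.items()]
        )
    raise ValueError(f"unknown bin spec {spec!r} (use 'five' or 'stages')")
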