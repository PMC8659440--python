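"""Reference chemistry: HPLC content formula and fermentation summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import COMPONENTS, ChemTable


class ChemistryError(ValueError):
    pass


@dataclass(frozen=True)
class HplcMeasurement:
    """One external-standard HPLC quantitation.

    a: peak area of the test liquid; a1: peak area of the standard;
    v: test-liquid volume in mL; c: standard concentration in mg/mL;
    m: dry-matter fraction of the sample (dimensionless, in (0, 1]);
    m1: sample mass in g.
    """

    a: float
    a1: float
    v: float
    c: float
    m: float
    m1: float

    def __post_init__(self):
        if self.a < 0:
            raise ChemistryError("peak area a must be >= 0")
        for name in ("a1", "v", "c", "m", "m1"):
            if getattr(self, name) <= 0:
                raise ChemistryError(f"{name} must be > 0")


def catechin_content(meas: HplcMeasurement) -> float:
    """Catechin content in % dry mass from an external-standard HPLC run.

    content(%) = (a * v * c) / (a1 * m * 10^3 * m1) * 100

    The 10^3 converts mg to g so that the ratio is mass of catechin per mass
    of dry sample; m is the dry-matter *fraction*, making the result a
    percentage of dry mass.
    """
    return (meas.a * meas.v * meas.c) / (meas.a1 * meas.m * 1e3 * meas.m1) * 100.0


def append_content_column(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised Eq. over a table with columns a, a1, v, c, m, m1."""
    out = df.copy()
    out["content_pct"] = [
        catechin_content(HplcMeasurement(r.a, r.a1, r.v, r.c, r.m, r.m1))
        for r in df.itertuples()
    ]
    return out


def percent_decrease(series) -> float:
    """100 * (first - last) / first for a time-ordered content series."""
    s = np.asarray(series, float)
    if s.size == 0:
        raise ChemistryError("series is empty")
    if s[0] <= 0:
        raise ChemistryError("first value must be > 0")
    return 100.0 * (s[0] - s[-1]) / s[0]


@dataclass
class LayerSummary:
    """Per (time, layer) mean contents and the content-maximal layer per time."""

    means: pd.DataFrame          # index (time_h, layer), columns = components
    argmax_layer: pd.DataFrame   # index time_h, columns = components (layer name)
    ties: pd.DataFrame           # same shape as argmax_layer, bool


def layer_contrast(chem: ChemTable, components=COMPONENTS,
                   tie_tol: float = 1e-12) -> LayerSummary:
    """Group contents by (time, layer) and find where each component peaks.

    Raises if any (time, layer) cell has no samples; exact ties for the
    maximal layer are flagged rather than silently broken.
    """
    df = chem.data
    counts = df.groupby(["time_h", "layer"]).size()
    times = sorted(df["time_h"].unique())
    layers = sorted(df["layer"].unique())
    missing = [(t, l) for t in times for l in layers if (t, l) not in counts.index]
    if missing:
        raise ChemistryError(f"missing (time, layer) cells: {missing}")

    means = df.groupby(["time_h", "layer"])[list(components)].mean()
    argmax = {}
    ties = {}
    for comp in components:
        wide = means[comp].unstack("layer")
        best = wide.idxmax(axis=1)
        top = wide.max(axis=1)
        tie = (wide.ge(top - tie_tol, axis=0).sum(axis=1) > 1)
        argmax[comp] = best
        ties[comp] = tie
    return LayerSummary(means, pd.DataFrame(argmax), pd.DataFrame(ties))
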