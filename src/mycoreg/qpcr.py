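"""Quantitative PCR: standard-curve quantitation and ChIP percent-of-input.

RT-qPCR copy numbers come from a per-gene standard curve, an ordinary
least-squares fit of Ct on log10(copies); amplification efficiency is
``10**(-1/slope) - 1`` (a perfect doubling per cycle gives slope
-1/log10(2) = -3.32 and efficiency 1.0).  Target copies are normalized to a
reference gene (actin).

ChIP enrichment uses the percent-of-input method.  With an input aliquot
that is a fraction ``f`` of the IP chromatin (0.1 when 0.1 mg input is run
against 1 mg IP), the input Ct is first shifted by log2(1/f) to the value a
100% aliquot would have given::

    dCt        = Ct_IP - (Ct_Input - log2(1/f))
    efficiency = 2**(-dCt) * 100   (percent of input)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_INPUT_FRACTION = 0.1


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    locus: str
    role: str  # "IP" | "input" | "target" | "reference"
    replicate: int
    ct: float


@dataclass(frozen=True)
class StandardCurve:
    slope: float      # Ct per log10(copies); negative for valid curves
    intercept: float  # Ct at 1 copy
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_ct(self, copies: float) -> float:
        return self.intercept + self.slope * math.log10(copies)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS of Ct on log10(copies) over dilution-series points.

    ``points`` are (log10 copies, Ct) pairs; at least 3 points over at least
    2 distinct dilutions are required.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 standard-curve points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("standard curve needs >= 2 distinct dilutions")
    res = stats.linregress(x, y)
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


def quantify_copies(ct: float, curve: StandardCurve) -> float:
    """Invert the curve: copies = 10**((ct - intercept) / slope)."""
    if curve.slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def normalize_to_reference(copies_target: float, copies_reference: float) -> float:
    """Target copies relative to the reference (actin) gene."""
    if copies_reference <= 0:
        raise ValueError("reference copies must be positive")
    return copies_target / copies_reference


def chip_efficiency(ct_ip: float, ct_input: float,
                    input_fraction: float = DEFAULT_INPUT_FRACTION) -> float:
    """Percent-of-input ChIP enrichment with the input-dilution correction."""
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    if ct_ip <= 0 or ct_input <= 0:
        raise ValueError("Ct values must be positive")
    dct = ct_ip - (ct_input - math.log2(1.0 / input_fraction))
    return 2.0 ** (-dct) * 100.0


def chip_efficiency_table(ct_table: pd.DataFrame,
                          input_fraction: float = DEFAULT_INPUT_FRACTION) -> pd.DataFrame:
    """Per-replicate percent-of-input from a long Ct table.

    Expects columns sample_id, locus, role ("IP"/"input"), replicate, ct;
    IP and input rows are paired on (sample_id, locus, replicate).
    """
    ip = ct_table[ct_table["role"] == "IP"].set_index(["sample_id", "locus", "replicate"])["ct"]
    inp = ct_table[ct_table["role"] == "input"].set_index(["sample_id", "locus", "replicate"])["ct"]
    joined = pd.DataFrame({"ct_ip": ip, "ct_input": inp}).dropna()
    if joined.empty:
        raise ValueError("no paired IP/input measurements in table")
    joined["percent_input"] = [
        chip_efficiency(r.ct_ip, r.ct_input, input_fraction) for r in joined.itertuples()
    ]
    return joined.reset_index()


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def aggregate_replicates(
    values: Sequence[float],
    groups: Sequence[str],
    welch: bool = False,
) -> dict:
    """Mean ± SD per group and an unpaired two-tailed t-test between two groups.

    The default is the classic pooled-variance Student's t; ``welch=True``
    drops the equal-variance assumption.  Singleton groups get an undefined
    (NaN) SD and are flagged.
    """
    if len(values) != len(groups):
        raise ValueError("values and groups must align")
    frame = pd.DataFrame({"value": values, "group": groups})
    names = list(dict.fromkeys(groups))
    summary = {}
    for name in names:
        v = frame.loc[frame["group"] == name, "value"].to_numpy(dtype=float)
        summary[name] = {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size >= 2 else float("nan"),
            "singleton": v.size < 2,
        }
    out = {"groups": summary}
    if len(names) == 2:
        a = frame.loc[frame["group"] == names[0], "value"].to_numpy(dtype=float)
        b = frame.loc[frame["group"] == names[1], "value"].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        out.update(t=float(t), p=float(p), stars=significance_stars(float(p)))
    return out
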