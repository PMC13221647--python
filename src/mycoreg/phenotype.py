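"""Colony and hyphal phenotype statistics for filamentous fungi.

Covered quantities:

* EAI — enzymatic activity index, the ratio of the clearing-halo diameter to
  the colony diameter on substrate agar (b/a);
* Ē — colony radial extension rate, the least-squares slope of colony
  *radius* (µm) against time (h);
* L_hgu (G) — hyphal growth unit length, total mycelium length per hyphal
  tip, pooled over the measured hyphal elements;
* µmax — maximum specific growth rate from the relation Ē = µmax · G.

Rates are conventionally printed to one decimal, µmax to two decimals and
percentages to one decimal; computations return full precision and rounding
belongs to reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ColonySeries:
    strain: str
    timepoints_h: tuple[float, ...]
    diameters_mm: tuple[float, ...]
    halo_diameters_mm: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.timepoints_h) != len(self.diameters_mm):
            raise ValueError("timepoints and diameters must align")
        if any(t2 <= t1 for t1, t2 in zip(self.timepoints_h, self.timepoints_h[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(d < 0 for d in self.diameters_mm):
            raise ValueError("diameters must be non-negative")


@dataclass(frozen=True)
class HyphalMeasure:
    element_id: str
    total_length_um: float
    tip_count: int

    def __post_init__(self):
        if self.total_length_um <= 0:
            raise ValueError("hyphal length must be positive")
        if self.tip_count < 1:
            raise ValueError("tip count must be >= 1")


def eai(halo_diameter: float, colony_diameter: float) -> float:
    """Enzymatic activity index b/a; the halo encircles the colony (b >= a)."""
    if colony_diameter <= 0:
        raise ValueError("colony diameter must be positive")
    if halo_diameter < colony_diameter:
        raise ValueError("halo diameter cannot be smaller than the colony")
    return halo_diameter / colony_diameter


def radial_rate(series: ColonySeries) -> float:
    """Radial extension rate Ē in µm/h from a daily colony-diameter series.

    Fits radius = diameter/2 (converted mm -> µm) on time by ordinary least
    squares; the slope is the extension rate of one colony margin.
    """
    if len(series.timepoints_h) < 2:
        raise ValueError("need at least two timepoints")
    t = np.asarray(series.timepoints_h, dtype=float)
    radius_um = np.asarray(series.diameters_mm, dtype=float) / 2.0 * 1000.0
    slope, _ = np.polyfit(t, radius_um, 1)
    return float(slope)


def percent_reduction(mutant_rate: float, wt_rate: float) -> float:
    """100 * (1 - mutant/WT); by construction plus 100*mutant/WT it sums to 100."""
    if wt_rate <= 0:
        raise ValueError("WT rate must be positive")
    return 100.0 * (1.0 - mutant_rate / wt_rate)


def hyphal_growth_unit(measures: Sequence[HyphalMeasure],
                       mean_of_ratios: bool = False) -> float:
    """L_hgu in µm: pooled total length / total tips over all elements.

    ``mean_of_ratios=True`` averages the per-element length/tips ratios
    instead of pooling totals.
    """
    if not measures:
        raise ValueError("need at least one hyphal element")
    if mean_of_ratios:
        return float(np.mean([m.total_length_um / m.tip_count for m in measures]))
    total_len = sum(m.total_length_um for m in measures)
    total_tips = sum(m.tip_count for m in measures)
    return total_len / total_tips


def mu_max(radial_rate_um_h: float, hyphal_growth_unit_um: float) -> float:
    """Maximum specific growth rate µmax = Ē / G (per hour)."""
    if hyphal_growth_unit_um <= 0:
        raise ValueError("hyphal growth unit must be positive")
    return radial_rate_um_h / hyphal_growth_unit_um


def relative_conidiation(mutant_count: float, wt_count: float) -> float:
    """Conidia yield as percent of the wild-type level."""
    if wt_count <= 0:
        raise ValueError("WT count must be positive")
    return 100.0 * mutant_count / wt_count
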