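"""Soma morphometry, per-mouse summaries and thermal place preference scoring.

Soma diameter comes from the equivalent-circle relation A = πr²: pixel area
is converted to μm² with the pixel-area constant (default 6.718 μm²/px) and
d = 2·√(A/π).  Diameter classes follow the field's small/large convention:
small ≤ 25 μm, large > 30 μm; the 25–30 μm band is tracked explicitly as
"intermediate" rather than forced into either class.

Group summaries are descriptive only (mean ± SEM across mice, neurons
pooled within mouse); the tidy long-format tables this module emits are
intended to feed standard inferential routines elsewhere.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .classify import CellRecord, pooled_tcell_density


@dataclasses.dataclass
class MorphometryParams:
    pixel_area_um2: float = 6.718
    small_max_um: float = 25.0
    large_min_um: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")
        if not self.small_max_um < self.large_min_um:
            raise ValueError("small_max_um must be < large_min_um "
                             "(the band between them is 'intermediate')")


@dataclasses.dataclass
class DiameterFit:
    """Single-Gaussian maximum-likelihood fit of a diameter sample."""

    mean_um: float
    sd_um: float
    n: int
    group: str = ""

    @property
    def mode_um(self) -> float:
        # the mode of a single Gaussian is its mean
        return self.mean_um


@dataclasses.dataclass
class TPPTrial:
    """One thermal place preference trial (trial 1 is habituation)."""

    mouse_id: str
    trial_index: int
    seconds_on_test_plate: float
    trial_length_s: float = 180.0
    excluded: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.seconds_on_test_plate <= self.trial_length_s:
            raise ValueError(
                f"seconds_on_test_plate must lie in [0, {self.trial_length_s}], "
                f"got {self.seconds_on_test_plate}")


def area_to_diameter(area_px: float, params: MorphometryParams) -> float:
    """Equivalent-circle diameter (μm) of a pixel area: 2·√(area·k/π)."""
    if area_px < 0:
        raise ValueError("area_px must be >= 0")
    return 2.0 * math.sqrt(area_px * params.pixel_area_um2 / math.pi)


def diameter_to_area_px(diameter_um: float, params: MorphometryParams) -> float:
    """Inverse of :func:`area_to_diameter` (continuous, not rasterised)."""
    return math.pi * (diameter_um / 2.0) ** 2 / params.pixel_area_um2


def classify_size(records: list[CellRecord],
                  params: MorphometryParams) -> list[CellRecord]:
    """Assign diameters (from area) and small/intermediate/large classes.

    Every record lands in exactly one class: small (≤ small_max_um),
    large (> large_min_um) or intermediate.
    """
    out = []
    for r in records:
        d = r.diameter_um
        if d is None:
            d = area_to_diameter(r.area_px, params)
        if d <= params.small_max_um:
            cls = "small"
        elif d > params.large_min_um:
            cls = "large"
        else:
            cls = "intermediate"
        out.append(dataclasses.replace(r, diameter_um=d, size_class=cls))
    return out


def fit_diameter_distribution(diameters, group: str = "") -> DiameterFit:
    """ML Gaussian fit (sample mean, sd with ddof=0) of pooled diameters.

    The soma-diameter population is bimodal overall; this single-component
    fit is meant for one size population at a time (the small/large split
    is handled by :func:`classify_size`, not by mixture modelling).
    """
    d = np.asarray(list(diameters), dtype=float)
    if d.size < 10:
        raise ValueError(f"need at least 10 diameters to fit, got {d.size}")
    sd = float(d.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate diameter sample (sd = 0); fit rejected")
    return DiameterFit(mean_um=float(d.mean()), sd_um=sd, n=int(d.size),
                       group=group)


def diameter_histogram(diameters, bin_width_um: float = 2.0) -> pd.DataFrame:
    """Histogram table (bin left edge, count) for pooled-neuron plots."""
    d = np.asarray(list(diameters), dtype=float)
    if d.size == 0:
        return pd.DataFrame({"bin_left_um": [], "count": []})
    edges = np.arange(0.0, d.max() + bin_width_um, bin_width_um)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({"bin_left_um": edges[:-1], "count": counts})


def _positive_fraction(records, rule: str):
    meas = [r for r in records if r.measurable and rule in r.flags]
    if not meas:
        return float("nan")
    return sum(r.flags[rule] for r in meas) / len(meas)


def summarize_mouse(mouse_id: str,
                    records: list[CellRecord],
                    puncta_sets=None,
                    tcell_counts=None,
                    tissue_areas_px=None,
                    params: MorphometryParams | None = None,
                    mhcii_rule: str = "MHCII_positive",
                    rfx1_rule: str = "RFX1_positive") -> dict:
    """One summary row per mouse, neurons pooled across the mouse's sections.

    Positive fractions are pooled counts over pooled neurons (not means of
    per-section percentages); the T-cell density is the pooled ratio of
    total cells over total tissue area.
    """
    params = params or MorphometryParams()
    measurable = [r for r in records if r.measurable]
    if not measurable:
        raise ValueError(f"mouse {mouse_id}: no measurable neurons")
    classed = classify_size(measurable, params)
    small = [r for r in classed if r.size_class == "small"]
    large = [r for r in classed if r.size_class == "large"]

    row = {
        "mouse_id": mouse_id,
        "n_neurons": len(classed),
        "n_small": len(small),
        "n_large": len(large),
        "pct_mhcii_pos": 100.0 * _positive_fraction(classed, mhcii_rule),
        "pct_mhcii_pos_small": 100.0 * _positive_fraction(small, mhcii_rule),
        "pct_mhcii_pos_large": 100.0 * _positive_fraction(large, mhcii_rule),
        "pct_rfx1_pos": 100.0 * _positive_fraction(
            [r for r in classed if r.has_nucleus], rfx1_rule),
    }
    if puncta_sets is not None:
        scored = [p for p in puncta_sets if p.scored]
        row["mean_puncta_per_neuron"] = (
            float(np.mean([p.count for p in scored])) if scored else float("nan"))
        row["mean_pct_puncta_area"] = (
            float(np.mean([p.percent_area for p in scored])) if scored
            else float("nan"))
    if tcell_counts is not None and tissue_areas_px is not None:
        row["tcells_per_mm2"] = pooled_tcell_density(
            tcell_counts, tissue_areas_px, params.pixel_area_um2)
    return row


def group_summary(mouse_rows: list[dict], group: str = "") -> pd.DataFrame:
    """Mean ± SEM across mice for every numeric per-mouse column.

    SEM is left blank (NaN) for a group of one mouse.
    """
    df = pd.DataFrame(mouse_rows)
    stats = []
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            continue
        vals = df[col].dropna()
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 \
            else float("nan")
        stats.append({"group": group, "measure": col, "n_mice": int(len(vals)),
                      "mean": float(vals.mean()) if len(vals) else float("nan"),
                      "sem": sem})
    return pd.DataFrame(stats)


def score_tpp(trials: list[TPPTrial]) -> pd.DataFrame:
    """Percent time on the test plate per trial, with habituation exclusion.

    percent = 100 · seconds on test plate / trial length.  A mouse that
    spent strictly less than 30 s on the test plate during the habituation
    trial (trial 1) is excluded: its habituation row is kept, flagged
    ``excluded``, and its test-trial rows (2–4) are dropped.
    """
    by_mouse: dict[str, list[TPPTrial]] = {}
    for t in trials:
        by_mouse.setdefault(t.mouse_id, []).append(t)
    rows = []
    for mouse_id, ts in by_mouse.items():
        hab = [t for t in ts if t.trial_index == 1]
        if not hab:
            raise ValueError(f"mouse {mouse_id}: no habituation trial (index 1)")
        excluded = hab[0].seconds_on_test_plate < 30.0
        for t in sorted(ts, key=lambda t: t.trial_index):
            if excluded and t.trial_index > 1:
                continue
            rows.append({
                "mouse_id": mouse_id,
                "trial_index": t.trial_index,
                "percent_time_on_test_plate":
                    100.0 * t.seconds_on_test_plate / t.trial_length_s,
                "excluded": excluded,
            })
    return pd.DataFrame(rows, columns=["mouse_id", "trial_index",
                                       "percent_time_on_test_plate", "excluded"])
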