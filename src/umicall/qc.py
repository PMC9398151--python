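"""Sample quality controls.

Five checks guard each plasma sample before its ctDNA result is
trusted:

* cellular-DNA contamination -- long/short qPCR amplicon quantity ratio
  against a nonfragmented genomic-DNA reference; more than 5% cellular
  DNA flags the sample;
* PCR inhibition -- Cq shift of an inhibition control against its
  reference (1 cycle = inhibited, 2 = strongly inhibited; the category
  boundaries are package conventions and configurable);
* cfDNA quantification -- regression on a standard curve of genomic DNA
  from 10 ng down to 0.37 ng in threefold dilutions;
* spike-in recovery -- per-run median centering of spike-in molecule
  counts, flagging samples far below/above the global median;
* undersequencing -- mean reads per UMI family below 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

CONTAMINATION_MAX_FRACTION = 0.05  # strictly more than 5% flags
UNDERSEQUENCED_MEAN_READS = 7.0  # strictly fewer than 7 flags
INHIBITED_SHIFT_CYCLES = 1.0
STRONGLY_INHIBITED_SHIFT_CYCLES = 2.0
SPIKEIN_LOW_FACTOR = 0.25
SPIKEIN_HIGH_FACTOR = 4.0


@dataclass
class StandardCurve:
    points: list[tuple[float, float]]  # (quantity ng, Cq)
    slope: float
    intercept: float

    @property
    def efficiency(self) -> float:
        """PCR efficiency as a fraction: 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def quantify(self, cq: float) -> float:
        """Invert the curve: quantity (ng) for an observed Cq."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Cq versus log10(quantity)."""
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 points")
    q = np.array([p[0] for p in points], dtype=float)
    cq = np.array([p[1] for p in points], dtype=float)
    if np.ptp(q) == 0:
        raise ValueError("standard curve quantities are degenerate (all equal)")
    slope, intercept = np.polyfit(np.log10(q), cq, 1)
    if slope >= 0:
        raise ValueError("standard curve slope must be negative (Cq falls with quantity)")
    return StandardCurve(list(points), float(slope), float(intercept))


def assess_contamination(
    short_qty: float,
    long_qty: float,
    genomic_ref_ratio: float = 1.0,
) -> tuple[float, bool]:
    """Cellular-DNA contamination fraction and flag (strictly > 5%).

    The long amplicon amplifies only from intact cellular DNA; its
    quantity relative to the short (total cfDNA) amplicon, normalized to
    what pure genomic DNA yields, estimates the cellular fraction.
    """
    if short_qty <= 0:
        raise ValueError("contamination is undefined for short-amplicon quantity 0")
    fraction = (long_qty / short_qty) / genomic_ref_ratio
    return fraction, fraction > CONTAMINATION_MAX_FRACTION


def assess_inhibition(
    cq_sample_control: float,
    cq_reference: float,
    inhibited_at: float = INHIBITED_SHIFT_CYCLES,
    strong_at: float = STRONGLY_INHIBITED_SHIFT_CYCLES,
) -> str:
    """Classify the inhibition-control Cq shift: none / inhibited / strongly_inhibited."""
    if not (math.isfinite(cq_sample_control) and math.isfinite(cq_reference)):
        raise ValueError("inhibition assessment needs finite Cq values")
    shift = cq_sample_control - cq_reference
    if shift >= strong_at:
        return "strongly_inhibited"
    if shift >= inhibited_at:
        return "inhibited"
    return "none"


def center_spikein_counts(
    counts_by_run: Mapping[str, Sequence[tuple[str, float]]],
    low_factor: float = SPIKEIN_LOW_FACTOR,
    high_factor: float = SPIKEIN_HIGH_FACTOR,
) -> tuple[dict[str, float], dict[str, str]]:
    """Median-center spike-in counts across sequencing runs.

    Each raw count is scaled by (global median of run medians)/(its run
    median), so run medians coincide afterwards.  Samples whose centered
    count falls below ``low_factor`` x or above ``high_factor`` x the
    global median are flagged.  Runs with median 0 are excluded.
    """
    run_medians = {}
    for run, pairs in counts_by_run.items():
        if not pairs:
            raise ValueError(f"run {run!r} has no spike-in counts")
        med = float(np.median([c for _, c in pairs]))
        if med == 0:
            continue  # excluded with warning semantics: unusable scaling
        run_medians[run] = med
    if not run_medians:
        return {}, {}
    global_median = float(np.median(list(run_medians.values())))
    centered: dict[str, float] = {}
    flags: dict[str, str] = {}
    for run, pairs in counts_by_run.items():
        if run not in run_medians:
            continue
        scale = global_median / run_medians[run]
        for sample, count in pairs:
            c = count * scale
            centered[sample] = c
            if c < low_factor * global_median:
                flags[sample] = "spikein_low"
            elif c > high_factor * global_median:
                flags[sample] = "spikein_high"
    return centered, flags


def flag_undersequenced(mean_family_size: float) -> bool:
    """True iff the mean UMI-family size is strictly below 7 reads."""
    if mean_family_size < 0:
        raise ValueError("mean family size cannot be negative")
    return mean_family_size < UNDERSEQUENCED_MEAN_READS


@dataclass
class QcReport:
    """Per-sample QC numbers with flags derived purely from them."""

    sample_id: str
    contamination_fraction: float | None = None
    inhibition_shift: float | None = None
    cfdna_ng_per_ml: float | None = None
    mean_family_size: float | None = None
    spikein_centered_count: float | None = None
    spikein_global_median: float | None = None
    molecule_count: int | None = None
    flags: set[str] = field(default_factory=set)

    def derive_flags(self) -> set[str]:
        flags: set[str] = set()
        if self.contamination_fraction is not None and self.contamination_fraction > CONTAMINATION_MAX_FRACTION:
            flags.add("contaminated")
        if self.inhibition_shift is not None:
            if self.inhibition_shift >= STRONGLY_INHIBITED_SHIFT_CYCLES:
                flags.add("strongly_inhibited")
            elif self.inhibition_shift >= INHIBITED_SHIFT_CYCLES:
                flags.add("inhibited")
        if self.mean_family_size is not None and flag_undersequenced(self.mean_family_size):
            flags.add("undersequenced")
        if self.spikein_centered_count is not None and self.spikein_global_median is not None:
            if self.spikein_centered_count < SPIKEIN_LOW_FACTOR * self.spikein_global_median:
                flags.add("spikein_low")
            elif self.spikein_centered_count > SPIKEIN_HIGH_FACTOR * self.spikein_global_median:
                flags.add("spikein_high")
        if self.molecule_count is not None and self.molecule_count < 50:
            flags.add("low_input")
        self.flags = flags
        return flags

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "contamination_fraction": self.contamination_fraction,
            "inhibition_shift": self.inhibition_shift,
            "cfdna_ng_per_ml": self.cfdna_ng_per_ml,
            "mean_family_size": self.mean_family_size,
            "spikein_centered_count": self.spikein_centered_count,
            "molecule_count": self.molecule_count,
            "flags": sorted(self.flags),
        }
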