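"""Host-cell-reactivation (HCR) relative-expression statistic from flow events.

The HCR assay transfects cells with a UV-damaged GFP reporter plasmid; the
cell's nucleotide-excision-repair capacity is read out as recovered reporter
expression by flow cytometry.  For each sample, over live-gated events:

    F = N x MFI / S

where S is the number of live events, N the number of live GFP-positive
events and MFI the mean GFP intensity of those N events.  The relative
expression is the ratio of the treated to the undamaged-plasmid sample,

    %RE = 100 x F_t / F_u.

Events arrive as exported CSV tables (one row per event with viability-dye
and GFP intensities); live gating uses the dye channel and the GFP-positive
threshold is either manual or a high quantile of an untransfected control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GateConfig",
    "SampleStats",
    "HCRResult",
    "gate_live_cells",
    "derive_gfp_threshold",
    "sample_stats",
    "relative_expression",
    "read_events_csv",
]


@dataclass
class GateConfig:
    """Gating thresholds: live iff dye < dye_threshold, GFP+ iff gfp >= gfp_threshold."""

    dye_threshold: float = 1000.0
    gfp_threshold: float = 1000.0

    def __post_init__(self) -> None:
        if self.dye_threshold <= 0 or self.gfp_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class SampleStats:
    """Per-sample gated counts and the F statistic (N x MFI / S)."""

    S: int
    N: int
    MFI: float
    F: float


@dataclass
class HCRResult:
    treated: SampleStats
    untreated: SampleStats
    percent_re: float


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read a flow-event CSV (columns event_id, dye, gfp, fsc, ssc)."""
    df = pd.read_csv(path)
    for col in ("dye", "gfp"):
        if col not in df.columns:
            raise ValueError(f"event table missing column {col!r}")
    return df


def gate_live_cells(events: pd.DataFrame, cfg: GateConfig) -> pd.DataFrame:
    """Live gate on the viability-dye channel: keep events with dye < threshold."""
    if len(events) == 0:
        raise ValueError("event table is empty")
    live = events[events["dye"] < cfg.dye_threshold]
    if len(live) == 0:
        warnings.warn("no events survive the live gate", stacklevel=2)
    return live


def derive_gfp_threshold(control: pd.DataFrame, cfg: GateConfig, q: float = 0.999) -> float:
    """GFP-positive threshold from an untransfected control sample.

    Returns the q-quantile (linear interpolation between order statistics,
    the type-7 convention) of the control's live-gated GFP intensities — a
    reproducible stand-in for a hand-drawn positivity line.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    live = gate_live_cells(control, cfg)
    if len(live) < 1 / (1 - q):
        warnings.warn("control sample too small for a stable quantile", stacklevel=2)
    return float(np.quantile(live["gfp"].to_numpy(), q, method="linear"))


def sample_stats(events: pd.DataFrame, cfg: GateConfig) -> SampleStats:
    """Gate one sample and compute S, N, MFI and F = N x MFI / S.

    With N = 0, MFI is undefined (NaN) but F is defined as 0.
    """
    live = gate_live_cells(events, cfg)
    S = len(live)
    if S == 0:
        return SampleStats(S=0, N=0, MFI=float("nan"), F=float("nan"))
    pos = live[live["gfp"] >= cfg.gfp_threshold]
    N = len(pos)
    if N == 0:
        return SampleStats(S=S, N=0, MFI=float("nan"), F=0.0)
    mfi = float(pos["gfp"].mean())
    return SampleStats(S=S, N=N, MFI=mfi, F=N * mfi / S)


def relative_expression(
    treated: pd.DataFrame, untreated: pd.DataFrame, cfg: GateConfig
) -> HCRResult:
    """%RE = 100 x F_treated / F_untreated with both samples gated identically.

    F_u = 0 (or undefined) leaves %RE missing (NaN) with a warning rather
    than raising, so batch processing can continue.
    """
    st_t = sample_stats(treated, cfg)
    st_u = sample_stats(untreated, cfg)
    if not st_u.F or np.isnan(st_u.F) or np.isnan(st_t.F):
        warnings.warn("F of the undamaged sample is zero or undefined; %RE missing", stacklevel=2)
        pct = float("nan")
    else:
        pct = 100.0 * st_t.F / st_u.F
    return HCRResult(treated=st_t, untreated=st_u, percent_re=pct)
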