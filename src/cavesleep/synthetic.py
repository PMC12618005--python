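"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (sleep scoring, flow-cytometry %RE,
fluorescence quantification, expression-response classification) is testable
without any raw recording: this module generates all four input kinds from
explicit stochastic models with fixed seeds and retains the generating truth
(hidden behavioural states, live/GFP+ labels, planted responder categories,
planted nucleus intensities) alongside the observable data.

The locomotor model is a two-state Markov chain on 1-s epochs — active vs
quiescent, with per-epoch transition probabilities p_doze (active→quiescent)
and p_wake (quiescent→active) — expanded to the frame grid, with velocity
emitted from a state-specific normal truncated at zero.  Dwell times in each
state are therefore geometric, and the long-run quiescent fraction is
p_doze/(p_doze+p_wake).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .sleep import VelocityTrace

__all__ = [
    "LocomotorParams",
    "FlowSimParams",
    "DESimParams",
    "ImageSimParams",
    "simulate_state_epochs",
    "simulate_locomotor_trace",
    "simulate_cohort",
    "simulate_flow_events",
    "simulate_de_tables",
    "simulate_image_stack",
]

#: mobility cut-off (mm/s) used only for the well-posedness warning
MOBILITY_THRESHOLD = 6.0


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass
class LocomotorParams:
    """Two-state locomotor model parameters.

    Transition probabilities are per 1-s epoch, so they are frame-rate
    independent; emissions are truncated-normal velocities in mm/s.
    """

    frame_rate: float = 1.0
    duration: float = 86400.0
    p_doze_true: float = 0.01
    p_wake_true: float = 0.05
    v_active_mean: float = 20.0
    v_active_sd: float = 4.0
    v_quiescent_mean: float = 1.0
    v_quiescent_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        if not (0 <= self.p_doze_true <= 1 and 0 <= self.p_wake_true <= 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if self.v_active_sd < 0 or self.v_quiescent_sd < 0:
            raise ValueError("emission sds must be non-negative")
        if not (self.v_quiescent_mean < MOBILITY_THRESHOLD < self.v_active_mean):
            warnings.warn(
                "emission means do not straddle the 6 mm/s mobility cut-off; "
                "the scenario may be ill-posed for sleep scoring",
                stacklevel=2,
            )


@dataclass
class FlowSimParams:
    """Flow-cytometry event mixture parameters.

    Intensity components are log-normal: each *_mean is the component median
    in arbitrary units, each *_sd the log-scale sigma.  live_fraction of
    events are live (low viability-dye signal); transfection_efficiency of
    live events are GFP+.
    """

    n_events: int = 50_000
    live_fraction: float = 0.9
    transfection_efficiency: float = 0.3
    gfp_pos_mean: float = 10_000.0
    gfp_pos_sd: float = 0.4
    gfp_neg_mean: float = 100.0
    gfp_neg_sd: float = 0.4
    dye_live_mean: float = 100.0
    dye_dead_mean: float = 10_000.0
    dye_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not (0 <= self.live_fraction <= 1):
            raise ValueError("live_fraction must lie in [0, 1]")
        if not (0 <= self.transfection_efficiency <= 1):
            raise ValueError("transfection_efficiency must lie in [0, 1]")
        if min(self.gfp_pos_sd, self.gfp_neg_sd, self.dye_sd) <= 0:
            raise ValueError("all sds must be positive")


@dataclass
class DESimParams:
    """Planted-responder differential-expression table parameters.

    Each gene's observed log2 fold change is effect + N(0, lfc_se) for
    responders (sign split evenly) and N(0, lfc_se) for nulls; the p-value is
    the two-sided normal tail of log2fc/lfc_se, so null p-values are
    uniform(0,1).  Shared responders respond in both populations;
    surface-only / cave-only respond in one.
    """

    n_genes: int = 2000
    n_shared: int = 0
    n_surface_only: int = 100
    n_cave_only: int = 0
    effect_size_log2fc: float = 2.0
    lfc_se: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_shared, self.n_surface_only, self.n_cave_only) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_shared + self.n_surface_only + self.n_cave_only > self.n_genes:
            raise ValueError("planted responder counts exceed n_genes")
        if self.lfc_se <= 0:
            raise ValueError("lfc_se must be positive")


@dataclass
class ImageSimParams:
    """Synthetic fluorescence stack parameters.

    Nuclei are uniform-intensity disks placed without overlap on a constant
    background; each slice carries the same signal plus independent Gaussian
    read noise, emulating a confocal stack destined for an average-intensity
    z-projection.
    """

    width: int = 128
    height: int = 128
    n_slices: int = 5
    n_nuclei: int = 4
    nucleus_radius: float = 6.0
    per_nucleus_intensity: Sequence[float] = (100.0, 100.0, 100.0, 100.0)
    background: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei != len(self.per_nucleus_intensity):
            raise ValueError("per_nucleus_intensity must have one value per nucleus")
        if any(i < 0 for i in self.per_nucleus_intensity) or self.background < 0:
            raise ValueError("intensities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_slices < 1 or self.width < 1 or self.height < 1:
            raise ValueError("stack dimensions must be positive")


# ---------------------------------------------------------------------------
# Locomotor traces
# ---------------------------------------------------------------------------

def simulate_state_epochs(
    n_epochs: int,
    p_doze: float,
    p_wake: float,
    rng: np.random.Generator,
    initial_quiescent: bool = False,
) -> np.ndarray:
    """Simulate the hidden two-state chain on the epoch grid.

    Returns a boolean array (True = quiescent).  Dwell times are geometric
    with the state's exit probability; a zero exit probability makes the
    state absorbing.
    """
    if n_epochs <= 0:
        raise ValueError("n_epochs must be positive")
    states = np.empty(n_epochs, dtype=bool)
    pos = 0
    quiescent = initial_quiescent
    while pos < n_epochs:
        p_exit = p_wake if quiescent else p_doze
        if p_exit == 0.0:
            states[pos:] = quiescent
            break
        dwell = int(rng.geometric(p_exit))
        end = min(pos + dwell, n_epochs)
        states[pos:end] = quiescent
        pos = end
        quiescent = not quiescent
    return states


def _truncnorm_at_zero(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated to [0, inf), via inverse-CDF sampling."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    lo = ndtr(-mean / sd)
    u = lo + (1.0 - lo) * rng.random(size)
    return mean + sd * ndtri(u)


def simulate_locomotor_trace(params: LocomotorParams) -> VelocityTrace:
    """Simulate one subject's velocity trace from the two-state model.

    The hidden state evolves on 1-s epochs and is expanded to the frame grid;
    each frame's velocity is drawn from its state's truncated-normal emission.
    Identical params (including seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_epochs = int(np.ceil(params.duration))
    quiescent = simulate_state_epochs(
        n_epochs, params.p_doze_true, params.p_wake_true, rng
    )
    n_frames = int(round(params.duration * params.frame_rate))
    epoch_of_frame = (np.arange(n_frames) / params.frame_rate).astype(int)
    q = quiescent[epoch_of_frame]
    v = np.empty(n_frames)
    v[~q] = _truncnorm_at_zero(params.v_active_mean, params.v_active_sd, int(np.sum(~q)), rng)
    v[q] = _truncnorm_at_zero(params.v_quiescent_mean, params.v_quiescent_sd, int(np.sum(q)), rng)
    return VelocityTrace(
        subject_id=f"sim_{params.seed}",
        velocity=v,
        frame_rate=params.frame_rate,
        labels={"true_quiescent_fraction": float(np.mean(quiescent))},
    )


def simulate_cohort(
    group_specs: Sequence[tuple[str, LocomotorParams, int]],
    seed: int = 0,
) -> list[VelocityTrace]:
    """Simulate a labelled cohort of traces.

    Per-subject seeds derive deterministically from the master seed and the
    subject's global index, so subject streams are independent and the whole
    cohort is reproducible from one seed.
    """
    traces: list[VelocityTrace] = []
    seen: set[str] = set()
    idx = 0
    for label, params, n_subjects in group_specs:
        if n_subjects < 1:
            raise ValueError("each group needs at least one subject")
        for j in range(n_subjects):
            sub_seed = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % 2**31)
            tr = simulate_locomotor_trace(replace(params, seed=sub_seed))
            tr.subject_id = f"{label}_{j:03d}"
            if tr.subject_id in seen:
                raise ValueError(f"duplicate subject identifier {tr.subject_id}")
            seen.add(tr.subject_id)
            tr.labels["group"] = label
            traces.append(tr)
            idx += 1
    return traces


# ---------------------------------------------------------------------------
# Flow-cytometry events
# ---------------------------------------------------------------------------

def simulate_flow_events(params: FlowSimParams) -> pd.DataFrame:
    """Simulate a flow-cytometry event table.

    Columns: event_id, dye, gfp, fsc, ssc, plus ground-truth booleans
    true_live and true_gfp_pos for downstream gate validation.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    live = rng.random(n) < params.live_fraction
    gfp_pos = live & (rng.random(n) < params.transfection_efficiency)

    def lognorm(median: float, sigma: float, size: int) -> np.ndarray:
        return np.exp(np.log(median) + sigma * rng.standard_normal(size))

    dye = np.where(
        live,
        lognorm(params.dye_live_mean, params.dye_sd, n),
        lognorm(params.dye_dead_mean, params.dye_sd, n),
    )
    gfp = np.where(
        gfp_pos,
        lognorm(params.gfp_pos_mean, params.gfp_pos_sd, n),
        lognorm(params.gfp_neg_mean, params.gfp_neg_sd, n),
    )
    # scatter channels carry no downstream signal; dead cells shrink slightly
    fsc = lognorm(1e5, 0.2, n) * np.where(live, 1.0, 0.7)
    ssc = lognorm(5e4, 0.25, n) * np.where(live, 1.0, 1.3)
    return pd.DataFrame(
        {
            "event_id": np.arange(n),
            "dye": dye,
            "gfp": gfp,
            "fsc": fsc,
            "ssc": ssc,
            "true_live": live,
            "true_gfp_pos": gfp_pos,
        }
    )


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def _de_table(
    responder: np.ndarray,
    effect: float,
    lfc_se: float,
    genes: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    from .expression import bh_adjust  # local import to avoid a cycle at import time

    n = genes.size
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    mean_lfc = np.where(responder, signs * effect, 0.0)
    lfc = mean_lfc + lfc_se * rng.standard_normal(n)
    z = lfc / lfc_se
    pval = 2.0 * ndtr(-np.abs(z))
    return pd.DataFrame(
        {"gene": genes, "log2fc": lfc, "pvalue": pval, "padj": bh_adjust(pval)}
    )


def simulate_de_tables(params: DESimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired surface/cave DE summary tables with planted truth.

    Returns (surface, cave) DataFrames with columns gene, log2fc, pvalue,
    padj and a shared true_category column in {shared, surface_only,
    cave_only, null}.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = np.array([f"g{i:05d}" for i in range(params.n_genes)])
    category = np.full(params.n_genes, "null", dtype=object)
    k = 0
    for name, cnt in (
        ("shared", params.n_shared),
        ("surface_only", params.n_surface_only),
        ("cave_only", params.n_cave_only),
    ):
        category[k : k + cnt] = name
        k += cnt
    surf_resp = np.isin(category, ["shared", "surface_only"])
    cave_resp = np.isin(category, ["shared", "cave_only"])
    surface = _de_table(surf_resp, params.effect_size_log2fc, params.lfc_se, genes, rng)
    cave = _de_table(cave_resp, params.effect_size_log2fc, params.lfc_se, genes, rng)
    surface["true_category"] = category
    cave["true_category"] = category
    return surface, cave


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def simulate_image_stack(params: ImageSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a fluorescence stack and its matching nucleus label mask.

    Nuclei are uniform-intensity disks (value = background + planted
    intensity inside the disk) placed without overlap; each slice adds
    independent N(0, noise_sd) read noise, clipped at zero.  Returns
    (stack[n_slices, h, w] float, mask[h, w] int) with mask label k marking
    nucleus k (1-based).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w, r = params.height, params.width, params.nucleus_radius
    margin = r + 1
    if params.n_nuclei > 0 and (w <= 2 * margin or h <= 2 * margin):
        raise ValueError("frame too small for the requested nucleus radius")
    centers: list[tuple[float, float]] = []
    tries = 0
    max_tries = 1000 * max(params.n_nuclei, 1)
    while len(centers) < params.n_nuclei:
        if tries >= max_tries:
            raise ValueError("could not place non-overlapping nuclei (infeasible packing)")
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        tries += 1
        if all((cy - y) ** 2 + (cx - x) ** 2 > (2 * r + 1) ** 2 for y, x in centers):
            centers.append((cy, cx))

    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int32)
    signal = np.full((h, w), params.background, dtype=float)
    for k, ((cy, cx), inten) in enumerate(zip(centers, params.per_nucleus_intensity), start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        mask[disk] = k
        signal[disk] += inten
    stack = signal[None, :, :] + params.noise_sd * rng.standard_normal(
        (params.n_slices, h, w)
    )
    return np.clip(stack, 0.0, None), mask
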