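"""Synthetic single-cell cohorts and expression panels with known truth.

Cell-to-cell heterogeneity is emulated the same way the stability scans
probe parameter uncertainty: each cell's rates are the baseline times
10^u with u uniform in ±D_cell per parameter (default D_cell = 0.15, a
modest jitter attributing the observed variety of damped phenotypes to
parameter variation).  Measurement noise on NCI is multiplicative
log-normal — NCI is a ratio of intensities, so its error scales with
its magnitude — and tracking loss truncates each trace geometrically.

Expression panels are generated from the gene module itself (plus
NF-κB-independent exponential-decay archetypes emulating down-regulated
genes), with log-normal noise, so every generated dataset carries exact
ground-truth labels for benchmarking the detection, fitting and
clustering stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_patterns import ExpressionMatrix
from .fitting import fold_change_series, _core_dense
from .model_core import (
    BASELINE,
    ForcingSignal,
    GeneParameters,
    KineticParameters,
    nci_of,
    simulate,
)
from .stability import ParameterPrior, randomize_parameters
from .trace_analysis import TraceSet, detect_peaks

__all__ = [
    "CohortSpec", "PanelSpec", "DEFAULT_ARCHETYPES", "generate_cohort",
    "generate_expression_panel", "generate_phase_samples", "pulse_sampling_times",
]

#: per-cell jitter applied to every rate when building a cohort
DEFAULT_CELL_DEGREE = 0.15


@dataclass
class CohortSpec:
    """Recipe for a synthetic single-cell NCI cohort."""

    n_cells: int = 100
    forcing: ForcingSignal = field(default_factory=lambda: ForcingSignal(kind="constant", S_high=2.0))
    base_params: KineticParameters = BASELINE
    cell_degree: float = DEFAULT_CELL_DEGREE
    degrees: dict[str, float] | None = None       # per-parameter override
    sampling_interval: float = 6.0
    duration_min: float = 12.0 * 60.0
    noise_sd: float = 0.05
    track_loss: float = 0.002                     # per-frame dropout probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd < 0 or not (0 <= self.track_loss < 1):
            raise ValueError("invalid noise or dropout settings")

    def prior(self) -> ParameterPrior:
        degrees = self.degrees
        if degrees is None:
            degrees = {name: self.cell_degree for name in KineticParameters.RATE_NAMES}
        return ParameterPrior(self.base_params, degrees)


def generate_cohort(spec: CohortSpec) -> tuple[TraceSet, dict]:
    """Simulate a heterogeneous cohort and return traces plus ground truth.

    Each cell: draw rates from the per-cell prior, integrate under the
    requested forcing, sample NCI on the uniform grid, multiply by
    log-normal noise exp(σZ), and truncate the track at the first
    dropout frame (geometric attrition).  The returned truth maps each
    cell to the significant peak times of its noiseless trace — the
    reference for detector benchmarking.
    """
    rng_master = np.random.SeedSequence(spec.seed)
    prior = spec.prior()
    t_grid = np.arange(0.0, spec.duration_min + spec.sampling_interval / 2,
                       spec.sampling_interval)
    cells: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    truth: dict = {"peak_times": {}, "params": {}, "clean_nci": {}}
    for i, child in enumerate(rng_master.spawn(spec.n_cells)):
        rng = np.random.default_rng(child)
        params = randomize_parameters(prior, rng)
        traj = simulate(params, spec.forcing, t_grid, rtol=1e-6, atol=1e-9)
        clean = traj.nci
        noisy = clean * np.exp(spec.noise_sd * rng.standard_normal(len(clean))) \
            if spec.noise_sd > 0 else clean.copy()
        if spec.track_loss > 0:
            n_keep = int(rng.geometric(spec.track_loss))
            n_keep = max(n_keep, 3)               # keep analyzable stubs
        else:
            n_keep = len(t_grid)
        n_keep = min(n_keep, len(t_grid))
        cid = f"cell_{i:04d}"
        cells[cid] = (t_grid[:n_keep], noisy[:n_keep])
        clean_peaks = detect_peaks(t_grid[:n_keep], clean[:n_keep],
                                   min_track_min=0.0)
        truth["peak_times"][cid] = clean_peaks.significant_times()
        truth["params"][cid] = params
        truth["clean_nci"][cid] = clean[:n_keep]
    traces = TraceSet(cells, sampling_interval=spec.sampling_interval,
                      metadata={"forcing_kind": spec.forcing.kind,
                                "T_f": spec.forcing.period,
                                "seed": spec.seed})
    return traces, truth


def pulse_sampling_times(forcing: ForcingSignal, duration_min: float,
                         offsets: tuple[float, ...] = (20.0, 40.0, 60.0)) -> np.ndarray:
    """Sampling schedule 0 plus fixed offsets after each stimulation pulse."""
    starts = forcing.cycle_starts(duration_min)
    times = {0.0}
    for s in starts:
        for off in offsets:
            t = s + off
            if t <= duration_min:
                times.add(float(t))
    return np.array(sorted(times))


@dataclass(frozen=True)
class Archetype:
    """Ground-truth generator for one expression profile class.

    Decay archetypes follow floor + (1−floor)·exp(−k·(t−delay)⁺): pure
    exponentials of different rates standardize to the same shape (their
    log profile is linear in t), so distinguishable decay classes must
    differ in the shape of the log profile — an early drop to a plateau,
    a gradual decline, or a delayed onset.
    """

    label: str
    kind: str                        # "gene" | "decay"
    gene: GeneParameters | None = None
    decay_rate: float = 0.0          # h⁻¹, for kind="decay"
    delay_min: float = 0.0           # onset delay for decay archetypes
    floor: float = 0.0               # residual expression level


#: six archetypes emulating the canonical cluster shapes: an oscillating
#: high-turnover early gene, a fast-rising intermediate gene, a slowly
#: accumulating low-turnover late gene, and three decaying profiles
#: (fast, slow and delayed) independent of NF-κB.
DEFAULT_ARCHETYPES: tuple[Archetype, ...] = (
    Archetype("oscillating", "gene",
              GeneParameters(k_on_G=5.0, k_on0_G=0.05, k_off_G=1.0, k_off0_G=0.3, d_R_G=3.0)),
    Archetype("fast_up", "gene",
              GeneParameters(k_on_G=5.0, k_on0_G=0.05, k_off_G=1.0, k_off0_G=0.3, d_R_G=0.25)),
    Archetype("slow_up", "gene",
              GeneParameters(k_on_G=5.0, k_on0_G=0.01, k_off_G=1.0, k_off0_G=0.3, d_R_G=0.03)),
    Archetype("fast_down", "decay", decay_rate=1.5, floor=0.25),
    Archetype("slow_down", "decay", decay_rate=0.12),
    Archetype("late_down", "decay", decay_rate=0.6, delay_min=240.0),
)


@dataclass
class PanelSpec:
    """Recipe for a synthetic gene-expression panel."""

    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    genes_per_archetype: int = 12
    forcing: ForcingSignal = field(default_factory=lambda: ForcingSignal(
        kind="square", S_high=2.0, S_low=0.0, T1=30.0, T2=150.0))
    params: KineticParameters = BASELINE
    duration_min: float = 12.0 * 60.0
    timepoints_min: np.ndarray | None = None      # default: pulse schedule
    noise_sd: float = 0.1                         # log-normal sd on values
    seed: int = 0


def generate_expression_panel(spec: PanelSpec) -> tuple[ExpressionMatrix, pd.Series]:
    """Fold-change panel with per-gene archetype labels as ground truth.

    Gene archetypes run through the transcription module driven by the
    shared core trajectory; decay archetypes are pure exponentials
    (optionally delayed) emulating NF-κB-independent down-regulation.
    Values are multiplied by log-normal noise exp(σZ) per measurement.
    """
    times = spec.timepoints_min
    if times is None:
        times = pulse_sampling_times(spec.forcing, spec.duration_min)
    times = np.asarray(times, dtype=float)
    core = _core_dense(spec.params, spec.forcing, times[-1])
    rng = np.random.default_rng(spec.seed)
    rows, labels, index = [], [], []
    for arch in spec.archetypes:
        if arch.kind == "gene":
            clean = fold_change_series(spec.params, arch.gene, spec.forcing,
                                       times, core=core)
        elif arch.kind == "decay":
            t_eff = np.maximum(times - arch.delay_min, 0.0)
            clean = arch.floor + (1.0 - arch.floor) * np.exp(-arch.decay_rate * t_eff / 60.0)
        else:
            raise ValueError(f"unknown archetype kind {arch.kind!r}")
        for j in range(spec.genes_per_archetype):
            noisy = clean * np.exp(spec.noise_sd * rng.standard_normal(len(times))) \
                if spec.noise_sd > 0 else clean.copy()
            gene_id = f"{arch.label}_{j:03d}"
            rows.append(noisy)
            labels.append(arch.label)
            index.append(gene_id)
    values = pd.DataFrame(np.asarray(rows), index=index,
                          columns=[f"{t:g}" for t in times])
    matrix = ExpressionMatrix(values, times,
                              metadata={"seed": spec.seed,
                                        "forcing_kind": spec.forcing.kind,
                                        "T_f": spec.forcing.period})
    return matrix, pd.Series(labels, index=index, name="archetype")


def generate_phase_samples(kind: str, n: int, seed: int | None = 0,
                           kappa: float = 4.0, center: float = np.pi) -> np.ndarray:
    """Phase-difference samples for synchrony-statistic benchmarking.

    ``flat``: Uniform[0, 2π) (asynchronous limit, η → 0);
    ``delta``: all values identical (perfect locking, η = 1);
    ``concentrated``: von Mises around ``center`` with concentration κ.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "flat":
        return rng.uniform(0.0, 2.0 * np.pi, n)
    if kind == "delta":
        return np.full(n, center % (2.0 * np.pi))
    if kind == "concentrated":
        return np.mod(rng.vonmises(center - np.pi, kappa, n) + np.pi, 2.0 * np.pi)
    raise ValueError(f"unknown sample kind {kind!r}")
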