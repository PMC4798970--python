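"""Normalized ODE model of NF-κB dynamics with IκBα and A20 negative feedbacks.

The model tracks eight adimensional variables:

====  =============================================================
K     active IKK kinase (fraction of a reference amount)
N     free (nuclear) NF-κB fraction
G_I   fraction of active IκBα gene copies
R_I   IκBα mature mRNA (normalized to its asymptotic maximum)
I     free IκBα protein
G_A   fraction of active A20 gene copies
R_A   A20 mature mRNA
A     A20 protein
====  =============================================================

TNF-α enters as a time-dependent IKK activation rate ``S(t)`` that is
attenuated by A20 through a Hill term ``S(t)/(1 + A**n)``.  Free NF-κB
drives transcription of both feedback genes; IκBα re-sequesters NF-κB in
the cytoplasm and (optionally) acts as a transcriptional repressor on
the gene-inactivation side.  An arbitrary NF-κB controlled gene is a
two-variable telegraph-style module (active-gene fraction G, mature RNA
R) slaved to N(t) and I(t).

All rates are per hour; every public interface that speaks about time
does so in minutes (the sampling unit of the live-imaging data the model
is matched to).  The observable compared to microscopy is the nuclear-
to-cytoplasmic intensity ratio NCI = r·N/(1−N) with an area ratio r≈1/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

MIN_PER_HOUR = 60.0

#: names of the 8 core state variables, in vector order
STATE_NAMES = ("K", "N", "G_I", "R_I", "I", "G_A", "R_A", "A")

#: indices of variables constrained to [0, 1]
_UNIT_BOUNDED = {1, 2, 3, 5, 6}  # N, G_I, R_I, G_A, R_A


class ConfigurationError(ValueError):
    """Raised when a forcing protocol or parameter set is ill-formed."""


class SimulationError(RuntimeError):
    """Raised when integration fails or produces an invalid state."""


# ---------------------------------------------------------------------------
# Forcing signals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForcingSignal:
    """Time-dependent IKK activation rate S(t) encoding the TNF-α protocol.

    ``square`` alternates a high dose (rate ``S_high``, duration ``T1``
    minutes) with a low dose (``S_low``, ``T2`` minutes); the forcing
    period is ``T_f = T1 + T2``.  ``sawtooth`` emulates a microfluidic
    protocol in which the medium is replaced for ``pulse_len`` minutes at
    the start of each period and the ligand is then cleared with an
    exponential ``decay_halflife``.  ``constant`` holds ``S_high`` inside
    the active window.
    """

    kind: str = "constant"
    S_high: float = 2.0
    S_low: float = 0.0
    T1: float = 45.0
    T2: float = 45.0
    pulse_len: float = 15.0
    decay_halflife: float = 30.0
    t_start: float = 0.0
    t_end: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "square", "sawtooth"):
            raise ConfigurationError(f"unknown forcing kind {self.kind!r}")
        if self.S_high < self.S_low or self.S_low < 0:
            raise ConfigurationError("need S_high >= S_low >= 0")
        if self.kind in ("square", "sawtooth"):
            if self.T1 < 0 or self.T2 < 0 or self.T1 + self.T2 <= 0:
                raise ConfigurationError("need T1, T2 >= 0 and T1 + T2 > 0")
        if self.kind == "sawtooth" and self.decay_halflife <= 0:
            raise ConfigurationError("decay_halflife must be positive")

    @property
    def period(self) -> float:
        """Forcing period T_f = T1 + T2 in minutes."""
        return self.T1 + self.T2

    def cycle_starts(self, t_max: float) -> np.ndarray:
        """Start times (min) of forcing cycles in [t_start, min(t_end, t_max)]."""
        if self.kind == "constant":
            return np.array([self.t_start])
        stop = min(self.t_end, t_max)
        n = int(np.floor((stop - self.t_start) / self.period)) + 1
        starts = self.t_start + self.period * np.arange(max(n, 0))
        return starts[starts <= stop]

    def switch_times(self, t0: float, t1: float) -> np.ndarray:
        """Discontinuity times of S(t) within (t0, t1), in minutes."""
        pts: list[float] = []
        if np.isfinite(self.t_start):
            pts.append(self.t_start)
        if np.isfinite(self.t_end):
            pts.append(self.t_end)
        if self.kind in ("square", "sawtooth"):
            k0 = int(np.floor((t0 - self.t_start) / self.period)) - 1
            k1 = int(np.ceil((t1 - self.t_start) / self.period)) + 1
            width = self.T1 if self.kind == "square" else self.pulse_len
            for k in range(k0, k1 + 1):
                base = self.t_start + k * self.period
                pts.extend((base, base + width))
        arr = np.array([p for p in pts if t0 < p < t1])
        return np.unique(arr)

    def evaluate(self, t: float | np.ndarray) -> float | np.ndarray:
        """S(t) in h⁻¹ for time(s) ``t`` in minutes."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("time must be finite")
        out = np.full(t.shape, self.S_low)
        active = (t >= self.t_start) & (t < self.t_end)
        if self.kind == "constant":
            out[active] = self.S_high
        else:
            phase = np.mod(t - self.t_start, self.period)
            if self.kind == "square":
                out[active & (phase < self.T1)] = self.S_high
            else:  # sawtooth
                in_pulse = phase < self.pulse_len
                out[active & in_pulse] = self.S_high
                tail = active & ~in_pulse
                dt = phase[tail] - self.pulse_len
                decayed = self.S_high * np.exp2(-dt / self.decay_halflife)
                out[tail] = np.maximum(decayed, self.S_low)
        return out if out.shape else float(out)


def evaluate_forcing(signal: ForcingSignal, t: float) -> float:
    """S(t) in h⁻¹ for time ``t`` in minutes (module-level convenience)."""
    return signal.evaluate(t)


def dose_to_rate(dose: float, rate_per_ng_ml: float = 0.2) -> float:
    """Map a TNF-α dose (ng/ml) to an IKK activation rate S (h⁻¹).

    Linear by default, anchored so that the saturating reference dose of
    10 ng/ml corresponds to S = 2 h⁻¹.  The linear shape is a modelling
    choice; only the anchor is constrained by the calibration data.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return rate_per_ng_ml * dose


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParameters:
    """The 21 normalized rates of the core network (h⁻¹; ``n`` adimensional).

    ``repressor_active`` controls whether free IκBα contributes to gene
    inactivation (the ``k_off_* · I`` terms); with the flag off only the
    basal ``k_off0_*`` inactivation remains, giving the no-repressor
    model variant.
    """

    d_K: float      # IKK spontaneous inactivation
    n: float        # Hill exponent of A20 inhibition of IKK activation
    d: float        # spontaneous NF-κB:IκBα complex dissociation
    gamma: float    # IκBα degradation in complex, relative to free d_I
    d_I: float      # free IκBα degradation
    p: float        # IKK-mediated IκBα degradation in complex
    a: float        # NF-κB + IκBα association
    kappa: float    # IKK action on free IκBα, relative to p
    k_I: float      # IκBα translation (lumped with transcription scale)
    d_RI: float     # IκBα mRNA degradation
    k_on_I: float   # NF-κB driven IκBα gene activation
    k_on0_I: float  # basal IκBα gene activation
    k_off_I: float  # IκBα-repressed gene inactivation
    k_off0_I: float # basal IκBα gene inactivation
    k_on_A: float
    k_on0_A: float
    k_off_A: float
    k_off0_A: float
    d_RA: float     # A20 mRNA degradation
    k_A: float      # A20 translation
    d_A: float      # A20 protein degradation
    repressor_active: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "repressor_active":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"parameter {f.name} must be a finite non-negative number")
        if self.n < 1:
            raise ConfigurationError("Hill exponent n must be >= 1")

    RATE_NAMES = (
        "d_K", "n", "d", "gamma", "d_I", "p", "a", "kappa", "k_I", "d_RI",
        "k_on_I", "k_on0_I", "k_off_I", "k_off0_I",
        "k_on_A", "k_on0_A", "k_off_A", "k_off0_A",
        "d_RA", "k_A", "d_A",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.RATE_NAMES}

    def with_values(self, **updates: float) -> "KineticParameters":
        return replace(self, **updates)


@dataclass(frozen=True)
class GeneParameters:
    """Telegraph-module rates for one NF-κB controlled gene (h⁻¹)."""

    k_on_G: float
    k_on0_G: float
    k_off_G: float
    k_off0_G: float
    d_R_G: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"gene parameter {f.name} must be non-negative")

    RATE_NAMES = ("k_on_G", "k_on0_G", "k_off_G", "k_off0_G", "d_R_G")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.RATE_NAMES}

    def with_values(self, **updates: float) -> "GeneParameters":
        return replace(self, **updates)


#: Baseline parameter set used throughout as the starting point of scans
#: and fits.  Calibrated (scripts/calibrate_baseline.py) so that under a
#: constant saturating stimulus S = 2 h⁻¹ the response is a damped
#: oscillation (stable spiral fixed point) with the first nuclear peak
#: within ~30 min and an intrinsic inter-peak interval close to the
#: 90-min natural period of NF-κB.
BASELINE = KineticParameters(
    d_K=10.67, n=1.0, d=0.008, gamma=0.179, d_I=0.0196, p=60.0, a=71.1,
    kappa=0.60, k_I=16.6, d_RI=2.98,
    k_on_I=4.14, k_on0_I=3e-4, k_off_I=6.43, k_off0_I=0.0407,
    k_on_A=7.81, k_on0_A=3e-4, k_off_A=10.1, k_off0_A=0.0228,
    d_RA=25.5, k_A=0.9, d_A=4.0,
)

#: Per-parameter uncertainty degrees D used by the randomized scans:
#: D = 1 for manually fitted rates and for the coarse-grained A20/IKK
#: module, D = 0.3 for degradation and binding rates taken from the
#: literature.  Randomization multiplies a rate by 10**u, u~U(−D, D).
DEFAULT_DEGREES: dict[str, float] = {
    "d_K": 0.3, "n": 1.0, "d": 0.3, "gamma": 0.3, "d_I": 0.3, "p": 0.3,
    "a": 0.3, "kappa": 0.3, "k_I": 0.3, "d_RI": 0.3,
    "k_on_I": 1.0, "k_on0_I": 1.0, "k_off_I": 1.0, "k_off0_I": 1.0,
    "k_on_A": 1.0, "k_on0_A": 1.0, "k_off_A": 1.0, "k_off0_A": 1.0,
    "d_RA": 1.0, "k_A": 1.0, "d_A": 1.0,
}

#: A default early-response gene: fast mRNA turnover tracking the pulses
#: (IκBα-like).  Lowering d_R_G by two orders of magnitude turns the fold
#: change into a slow monotone accumulation (Ccl5-like).
DEFAULT_GENE = GeneParameters(k_on_G=5.0, k_on0_G=0.05, k_off_G=1.0, k_off0_G=0.3, d_R_G=2.0)


# ---------------------------------------------------------------------------
# State and trajectory containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelState:
    """One point of the normalized state space (core 8 variables + genes)."""

    K: float
    N: float
    G_I: float
    R_I: float
    I: float
    G_A: float
    R_A: float
    A: float
    genes: tuple[tuple[float, float], ...] = ()  # (G, R) per gene

    def to_array(self) -> np.ndarray:
        core = [self.K, self.N, self.G_I, self.R_I, self.I, self.G_A, self.R_A, self.A]
        for g, r in self.genes:
            core.extend((g, r))
        return np.array(core, dtype=float)

    @staticmethod
    def from_array(y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        n_genes = (y.size - 8) // 2
        genes = tuple((float(y[8 + 2 * i]), float(y[9 + 2 * i])) for i in range(n_genes))
        return ModelState(*map(float, y[:8]), genes=genes)


@dataclass
class Trajectory:
    """A sampled solution of the model on a uniform-or-not minute grid."""

    times_min: np.ndarray
    states: np.ndarray             # shape (T, 8 + 2·n_genes)
    params: KineticParameters
    forcing: ForcingSignal
    gene_params: tuple[GeneParameters, ...] = ()
    area_ratio: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.states) != len(self.times_min):
            raise ValueError("states and times length mismatch")

    def __len__(self) -> int:
        return len(self.times_min)

    @property
    def n_genes(self) -> int:
        return (self.states.shape[1] - 8) // 2

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def nci(self) -> np.ndarray:
        return nci_of(self.N, self.area_ratio)

    def gene_series(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(G, R) series of the i-th attached gene."""
        return self.states[:, 8 + 2 * i], self.states[:, 9 + 2 * i]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_min": self.times_min}
        for j, name in enumerate(STATE_NAMES):
            cols[name] = self.states[:, j]
        cols["nci"] = self.nci
        for i in range(self.n_genes):
            g, r = self.gene_series(i)
            cols[f"gene_{i}_G"] = g
            cols[f"gene_{i}_R"] = r
        return pd.DataFrame(cols)


def nci_of(N: float | np.ndarray, area_ratio: float = 1.0 / 3.0) -> float | np.ndarray:
    """Nuclear-to-cytoplasmic intensity NCI = r · N/(1−N).

    The map is a strictly increasing bijection of [0, 1) onto [0, ∞), so
    NCI peaks exactly where N peaks and ordering of nuclear amounts is
    preserved — the property that makes NCI a faithful oscillation
    quantifier.
    """
    arr = np.asarray(N, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError("N must lie in [0, 1)")
    out = area_ratio * arr / (1.0 - arr)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _make_rhs(params: KineticParameters,
              s_of_t_min: Callable[[float], float],
              genes: Sequence[GeneParameters] = ()) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build an ODE right-hand side f(t_min, y) -> dy/dt in h⁻¹ units of min time.

    Time flows in minutes at the interface (so solver output aligns with
    the data); rates are per hour, hence the global 1/60 factor.
    """
    P = params
    koffI = P.k_off_I if P.repressor_active else 0.0
    koffA = P.k_off_A if P.repressor_active else 0.0
    gene_rates = [
        (g.k_on_G, g.k_on0_G, (g.k_off_G if P.repressor_active else 0.0), g.k_off0_G, g.d_R_G)
        for g in genes
    ]
    d_K, n, d, gamma, d_I, p, a, kappa, k_I, d_RI = (
        P.d_K, P.n, P.d, P.gamma, P.d_I, P.p, P.a, P.kappa, P.k_I, P.d_RI)
    k_on_I, k_on0_I, k_off0_I = P.k_on_I, P.k_on0_I, P.k_off0_I
    k_on_A, k_on0_A, k_off0_A = P.k_on_A, P.k_on0_A, P.k_off0_A
    d_RA, k_A, d_A = P.d_RA, P.k_A, P.d_A
    inv_min = 1.0 / MIN_PER_HOUR

    def f(t: float, y: np.ndarray) -> np.ndarray:
        K, N, G_I, R_I, I, G_A, R_A, A = y[:8]
        S = s_of_t_min(t)
        one_m_N = 1.0 - N
        A_pos = A if A > 0.0 else 0.0  # solver may probe tiny negatives
        dy = np.empty_like(y)
        dy[0] = -d_K * K + S / (1.0 + A_pos ** n)
        dy[1] = d * one_m_N + gamma * d_I * one_m_N + p * K * one_m_N - a * I * N
        dy[2] = (k_on_I * N + k_on0_I) * (1.0 - G_I) - (koffI * I + k_off0_I) * G_I
        dy[3] = d_RI * (G_I - R_I)
        dy[4] = d * one_m_N - kappa * p * K * I - a * I * N + k_I * R_I - d_I * I
        dy[5] = (k_on_A * N + k_on0_A) * (1.0 - G_A) - (koffA * I + k_off0_A) * G_A
        dy[6] = d_RA * (G_A - R_A)
        dy[7] = k_A * R_A - d_A * A
        for i, (kon, kon0, koff, koff0, dR) in enumerate(gene_rates):
            G = y[8 + 2 * i]
            R = y[9 + 2 * i]
            dy[8 + 2 * i] = (kon * N + kon0) * (1.0 - G) - (koff * I + koff0) * G
            dy[9 + 2 * i] = dR * (G - R)
        dy *= inv_min
        return dy

    return f


def rhs(state: ModelState | np.ndarray, t: float, params: KineticParameters,
        forcing: ForcingSignal, genes: Sequence[GeneParameters] = ()) -> np.ndarray:
    """Time derivative of the state in h⁻¹ (t in minutes)."""
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    f = _make_rhs(params, forcing.evaluate, genes)
    return f(t, y) * MIN_PER_HOUR


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _integrate_piecewise(f, y0: np.ndarray, t_grid: np.ndarray,
                         switch_times: np.ndarray,
                         rtol: float, atol: float) -> np.ndarray:
    """LSODA integration restarted at forcing discontinuities.

    Splitting at switch times keeps each sub-interval smooth so square
    and sawtooth edges are resolved exactly instead of being smeared by
    the step controller.
    """
    t0, t1 = t_grid[0], t_grid[-1]
    edges = np.concatenate(([t0], switch_times[(switch_times > t0) & (switch_times < t1)], [t1]))
    ys = np.empty((len(t_grid), y0.size))
    y = y0.copy()
    filled = 0
    if t_grid[0] == t0:
        ys[0] = y
        filled = 1
    for a, b in zip(edges[:-1], edges[1:]):
        # evaluate just inside the piece so the solver sees one smooth branch
        mask = (t_grid > a) & (t_grid <= b)
        t_eval = t_grid[mask]
        sol = solve_ivp(f, (a, b), y, method="LSODA", t_eval=t_eval if t_eval.size else None,
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise SimulationError(f"integration failed on [{a:.3f}, {b:.3f}] min: {sol.message}")
        if t_eval.size:
            ys[filled:filled + t_eval.size] = sol.y.T
            filled += t_eval.size
        y = sol.y[:, -1] if sol.y.size else y
        if t_eval.size == 0 or t_eval[-1] < b:
            # advance the carried state to the edge
            sol2 = solve_ivp(f, (t_eval[-1] if t_eval.size else a, b), y, method="LSODA",
                             rtol=rtol, atol=atol)
            if not sol2.success:
                raise SimulationError(f"integration failed approaching t={b:.3f} min")
            y = sol2.y[:, -1]
    return ys


def _repair_bounds(ys: np.ndarray, n_genes: int, tol: float = 1e-6) -> np.ndarray:
    """Clip tiny solver-tolerance excursions outside the invariant region."""
    low = ys.min(initial=0.0)
    if low < -tol:
        raise SimulationError(f"state went negative beyond tolerance (min {low:.3e})")
    unit_cols = sorted(_UNIT_BOUNDED) + [8 + 2 * i for i in range(n_genes)] + \
        [9 + 2 * i for i in range(n_genes)]
    over = ys[:, unit_cols].max(initial=0.0) - 1.0
    if over > tol:
        raise SimulationError(f"unit-bounded state exceeded 1 beyond tolerance (+{over:.3e})")
    ys = np.clip(ys, 0.0, None)
    ys[:, unit_cols] = np.clip(ys[:, unit_cols], 0.0, 1.0)
    return ys


def resting_state(params: KineticParameters, genes: Sequence[GeneParameters] = (),
                  tol: float = 1e-8, max_hours: float = 1000.0) -> ModelState:
    """Unstimulated steady state (S ≡ 0), the initial condition of all runs.

    Integrates the model without stimulus in 50 h blocks until the
    largest derivative component falls below ``tol`` (h⁻¹).
    """
    zero = ForcingSignal(kind="constant", S_high=0.0, S_low=0.0)
    f = _make_rhs(params, zero.evaluate, genes)
    y = np.zeros(8 + 2 * len(genes))
    y[1] = 0.01  # small nuclear seed; basin is global for S = 0
    elapsed = 0.0
    block = 50.0 * MIN_PER_HOUR
    while elapsed < max_hours * MIN_PER_HOUR:
        sol = solve_ivp(f, (0.0, block), y, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise SimulationError("resting-state integration failed")
        y = sol.y[:, -1]
        elapsed += block
        resid = np.max(np.abs(f(0.0, y))) * MIN_PER_HOUR
        if resid < tol:
            y = np.clip(y, 0.0, None)
            return ModelState.from_array(y)
    raise SimulationError(f"no resting state within {max_hours} h (residual {resid:.2e} h⁻¹)")


def gene_resting(params: KineticParameters, gene: GeneParameters,
                 core_rest: ModelState) -> tuple[float, float]:
    """Steady (G, R) of a gene module given the resting core state."""
    alpha = gene.k_on_G * core_rest.N + gene.k_on0_G
    koff = gene.k_off_G if params.repressor_active else 0.0
    beta = koff * core_rest.I + gene.k_off0_G
    if alpha + beta <= 0:
        return 0.0, 0.0
    g = alpha / (alpha + beta)
    return g, g


def simulate(params: KineticParameters, forcing: ForcingSignal,
             t_grid: np.ndarray, genes: Sequence[GeneParameters] = (),
             initial: ModelState | str = "resting",
             rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the model on a minute grid with a stiff-capable solver.

    ``initial`` may be a :class:`ModelState` or the string ``"resting"``
    (default), in which case the unstimulated steady state is computed
    first; gene modules are then initialized at their own resting point.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be an increasing 1-D array with >= 2 points")
    genes = tuple(genes)
    if isinstance(initial, str):
        if initial != "resting":
            raise ValueError("initial must be a ModelState or 'resting'")
        core = resting_state(params)
        y0 = np.concatenate([core.to_array()[:8],
                             np.ravel([gene_resting(params, g, core) for g in genes])
                             if genes else np.empty(0)])
    else:
        y0 = initial.to_array()
        if y0.size != 8 + 2 * len(genes):
            raise ValueError("initial state does not match the number of genes")
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial state contains non-finite values")
    f = _make_rhs(params, forcing.evaluate, genes)
    switches = forcing.switch_times(t_grid[0], t_grid[-1])
    ys = _integrate_piecewise(f, y0, t_grid, switches, rtol, atol)
    ys = _repair_bounds(ys, len(genes))
    return Trajectory(t_grid, ys, params, forcing, genes)
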