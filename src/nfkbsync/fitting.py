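"""Model fitting to NCI and gene-expression time courses.

The objective is the mean relative error per timepoint,

    d(X, x) = (1/N) Σ_k |X(t_k) − x(t_k)| / max(X(t_k), x(t_k)),

summed over datasets when several are fitted together.  Optimization is
two-stage: a Metropolis random walk in log10-parameter space explores
the uncertainty box (each free parameter may move within ±D decades of
its base value), then a Levenberg–Marquardt refinement of the relative
residuals polishes the best state.  LM steps are only accepted when the
actual distance decreases, so the refinement can never worsen the
objective it started from.

Gene-panel fits hold the shared network parameters P_NF-κB fixed and fit
the per-gene telegraph-module parameters P_G against fold-change
profiles; because the gene module is slaved to N(t) and I(t), the core
trajectory is simulated once and each proposal only integrates the
two-variable gene ODE on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    ForcingSignal,
    GeneParameters,
    KineticParameters,
    Trajectory,
    gene_resting,
    nci_of,
    simulate,
)

__all__ = [
    "FitProblem", "FitResult", "Dataset", "distance", "model_nci_series",
    "fold_change_series", "simulate_gene_on", "fit", "fit_gene_panel",
]

AREA_RATIO = 1.0 / 3.0


def distance(X: np.ndarray, x: np.ndarray) -> float:
    """Mean relative error per timepoint; symmetric; 0 iff identical.

    Terms where both series are exactly zero are defined as 0 (the
    0/0 convention needed e.g. for pre-stimulus fold-change baselines).
    """
    X = np.asarray(X, dtype=float)
    x = np.asarray(x, dtype=float)
    if X.shape != x.shape or X.ndim != 1 or X.size == 0:
        raise ValueError("series must be 1-D, non-empty and of equal length")
    if np.any(X < 0) or np.any(x < 0):
        raise ValueError("distance is defined for non-negative series")
    denom = np.maximum(X, x)
    terms = np.zeros_like(denom)
    nz = denom > 0
    terms[nz] = np.abs(X[nz] - x[nz]) / denom[nz]
    return float(terms.mean())


def _relative_residuals(X: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Signed per-point relative residuals (X−x)/max(X,x), 0/0 → 0."""
    denom = np.maximum(X, x)
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = (X[nz] - x[nz]) / denom[nz]
    return out


def model_nci_series(params: KineticParameters, forcing: ForcingSignal,
                     times_min: np.ndarray,
                     area_ratio: float = AREA_RATIO) -> np.ndarray:
    """Theoretical NCI profile r·N/(1−N) at the requested times."""
    times_min = np.asarray(times_min, dtype=float)
    t0 = min(0.0, times_min[0])
    grid = np.union1d(np.arange(t0, times_min[-1] + 3.0, 3.0), times_min)
    traj = simulate(params, forcing, grid)
    idx = np.searchsorted(grid, times_min)
    return nci_of(traj.N[idx], area_ratio)


def _core_dense(params: KineticParameters, forcing: ForcingSignal,
                t_end_min: float, dt_min: float = 1.0) -> Trajectory:
    grid = np.arange(0.0, t_end_min + dt_min, dt_min)
    return simulate(params, forcing, grid)


def simulate_gene_on(core: Trajectory, gene: GeneParameters,
                     dt_min: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one gene module driven by a precomputed core trajectory.

    The gene ODE is linear in (G, R) given N(t) and I(t); a fixed-step
    RK4 on the core's (interpolated) drive is accurate and much cheaper
    than re-integrating the full system for every fit proposal.
    Returns (times of the core grid, R series).
    """
    p = core.params
    koff = gene.k_off_G if p.repressor_active else 0.0
    tc = core.times_min
    alpha_c = gene.k_on_G * core.N + gene.k_on0_G
    beta_c = koff * core.column("I") + gene.k_off0_G
    t = np.arange(tc[0], tc[-1] + dt_min / 2, dt_min)
    alpha = np.interp(t, tc, alpha_c) / 60.0     # per minute
    beta = np.interp(t, tc, beta_c) / 60.0
    dR = gene.d_R_G / 60.0
    g0 = alpha[0] / (alpha[0] + beta[0]) if alpha[0] + beta[0] > 0 else 0.0
    G, R = g0, g0
    Gs = np.empty(len(t))
    Rs = np.empty(len(t))
    Gs[0], Rs[0] = G, R
    h = dt_min
    for i in range(len(t) - 1):
        a0, b0 = alpha[i], beta[i]
        a1, b1 = alpha[i + 1], beta[i + 1]
        am, bm = 0.5 * (a0 + a1), 0.5 * (b0 + b1)

        def fG(G, a, b):
            return a * (1.0 - G) - b * G

        k1G = fG(G, a0, b0);            k1R = dR * (G - R)
        k2G = fG(G + 0.5 * h * k1G, am, bm); k2R = dR * (G + 0.5 * h * k1G - (R + 0.5 * h * k1R))
        k3G = fG(G + 0.5 * h * k2G, am, bm); k3R = dR * (G + 0.5 * h * k2G - (R + 0.5 * h * k2R))
        k4G = fG(G + h * k3G, a1, b1);  k4R = dR * (G + h * k3G - (R + h * k3R))
        G += h / 6.0 * (k1G + 2 * k2G + 2 * k3G + k4G)
        R += h / 6.0 * (k1R + 2 * k2R + 2 * k3R + k4R)
        Gs[i + 1], Rs[i + 1] = G, R
    return t, Rs


def fold_change_series(params: KineticParameters, gene: GeneParameters,
                       forcing: ForcingSignal, times_min: np.ndarray,
                       core: Trajectory | None = None,
                       baseline_floor: float = 1e-6) -> np.ndarray:
    """Mature-RNA fold change R(t)/R(0) for one gene.

    R(0) is the resting expression before stimulation; genes without a
    basal activation floor (k_on0_G = 0 and negligible resting N drive)
    have no defined baseline and raise.
    """
    times_min = np.asarray(times_min, dtype=float)
    if core is None:
        core = _core_dense(params, forcing, times_min[-1])
    # the core run starts from the unstimulated steady state, so its first
    # sample is the resting point — no need to re-converge it
    from .model_core import ModelState
    rest = ModelState.from_array(core.states[0, :8])
    g0, r0 = gene_resting(params, gene, rest)
    if r0 <= baseline_floor:
        raise ValueError(
            "resting gene expression is ~0; a basal activation floor "
            "(k_on0_G > 0) is needed for a defined fold change")
    t, R = simulate_gene_on(core, gene)
    # the core run starts from rest, so R(0)=r0 up to roundoff
    return np.interp(times_min, t, R) / r0


# ---------------------------------------------------------------------------
# Fit problem definition
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """One observed series: NCI or a gene's fold change."""

    kind: str                   # "nci" | "fold_change"
    times_min: np.ndarray
    values: np.ndarray
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("nci", "fold_change"):
            raise ValueError("dataset kind must be 'nci' or 'fold_change'")
        if self.values.size == 0:
            raise ValueError("empty dataset")
        if self.kind == "fold_change" and self.gene_id is None:
            raise ValueError("fold_change dataset needs a gene_id")
        if np.ptp(self.values) == 0:
            raise ValueError("degenerate (constant) dataset")


@dataclass
class FitProblem:
    """Datasets plus the free-parameter specification.

    ``free`` maps parameter keys to uncertainty degrees D: the key is a
    core rate name (e.g. "p") or "<gene_id>:<rate>" for gene-module
    rates.  Bounds are base·10^±D; proposals and refinement act on
    log10 values inside that box.
    """

    params: KineticParameters
    forcing: ForcingSignal
    datasets: list[Dataset]
    free: dict[str, float]
    genes: dict[str, GeneParameters] = field(default_factory=dict)
    area_ratio: float = AREA_RATIO

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("no datasets")
        for key in self.free:
            self._locate(key)
        for ds in self.datasets:
            if ds.gene_id is not None and ds.gene_id not in self.genes:
                raise ValueError(f"dataset references unknown gene {ds.gene_id!r}")

    def _locate(self, key: str):
        if ":" in key:
            gid, rate = key.split(":", 1)
            if gid not in self.genes or rate not in GeneParameters.RATE_NAMES:
                raise ValueError(f"unknown free parameter {key!r}")
            return gid, rate
        if key not in KineticParameters.RATE_NAMES:
            raise ValueError(f"unknown free parameter {key!r}")
        return None, key

    @property
    def core_free(self) -> bool:
        return any(":" not in k for k in self.free)


@dataclass
class FitResult:
    params: KineticParameters
    genes: dict[str, GeneParameters]
    distances: list[float]
    total_distance: float
    seed: int | None
    n_mcmc_accepted: int
    mcmc_trace: list[tuple[int, float]]        # (step, best-so-far distance)
    lm_converged: bool
    warning: str | None = None


class _Objective:
    """Evaluate total distance for a log10 free-parameter vector."""

    def __init__(self, problem: FitProblem):
        self.problem = problem
        self.keys = list(problem.free)
        base = [self._get(k) for k in self.keys]
        if any(b <= 0 for b in base):
            raise ValueError("free parameters must be positive to fit on a log scale")
        self.x0 = np.log10(base)
        D = np.array([problem.free[k] for k in self.keys])
        self.lo = self.x0 - D
        self.hi = self.x0 + D
        self.t_end = max(ds.times_min[-1] for ds in problem.datasets)
        self._core_cache: Trajectory | None = None
        if not problem.core_free:
            self._core_cache = _core_dense(problem.params, problem.forcing, self.t_end)

    def _get(self, key: str) -> float:
        gid, rate = self.problem._locate(key)
        obj = self.problem.genes[gid] if gid else self.problem.params
        return getattr(obj, rate)

    def build(self, x: np.ndarray) -> tuple[KineticParameters, dict[str, GeneParameters]]:
        params = self.problem.params
        genes = dict(self.problem.genes)
        core_updates: dict[str, float] = {}
        gene_updates: dict[str, dict[str, float]] = {}
        for key, xi in zip(self.keys, x):
            gid, rate = self.problem._locate(key)
            val = 10.0 ** xi
            if gid is None:
                core_updates[rate] = val
            else:
                gene_updates.setdefault(gid, {})[rate] = val
        if core_updates:
            params = params.with_values(**core_updates)
        for gid, upd in gene_updates.items():
            genes[gid] = genes[gid].with_values(**upd)
        return params, genes

    def predictions(self, x: np.ndarray) -> list[np.ndarray]:
        params, genes = self.build(x)
        if self.problem.core_free:
            core = _core_dense(params, self.problem.forcing, self.t_end)
        else:
            core = self._core_cache
        preds = []
        for ds in self.problem.datasets:
            if ds.kind == "nci":
                idx_t = ds.times_min
                pred = np.interp(idx_t, core.times_min,
                                 nci_of(core.N, self.problem.area_ratio))
            else:
                pred = fold_change_series(params, genes[ds.gene_id],
                                          self.problem.forcing, ds.times_min, core=core)
            preds.append(pred)
        return preds

    def distances(self, x: np.ndarray) -> list[float]:
        return [distance(ds.values, pred)
                for ds, pred in zip(self.problem.datasets, self.predictions(x))]

    def total(self, x: np.ndarray) -> float:
        try:
            return float(sum(self.distances(x)))
        except Exception:
            return np.inf

    def residuals(self, x: np.ndarray) -> np.ndarray:
        out = []
        for ds, pred in zip(self.problem.datasets, self.predictions(x)):
            out.append(_relative_residuals(ds.values, pred) / len(ds.values))
        return np.concatenate(out)


def _lm_refine(obj: _Objective, x: np.ndarray, max_iter: int = 40,
               tol: float = 1e-8, fd_step: float = 1e-4) -> tuple[np.ndarray, bool]:
    """Levenberg–Marquardt on log10 parameters with box projection.

    A step is kept only if the actual (L1) distance improves, which
    guarantees monotone refinement even though the LM model works on
    squared relative residuals.
    """
    lam = 1e-2
    best_d = obj.total(x)
    converged = False
    for _ in range(max_iter):
        try:
            r = obj.residuals(x)
        except Exception:
            break
        J = np.empty((len(r), len(x)))
        for j in range(len(x)):
            xp = x.copy()
            xp[j] = min(xp[j] + fd_step, obj.hi[j])
            h = xp[j] - x[j]
            if h == 0:
                xp[j] = x[j] - fd_step
                h = -fd_step
            J[:, j] = (obj.residuals(xp) - r) / h
        g = J.T @ r
        H = J.T @ J
        improved = False
        for _try in range(8):
            try:
                step = np.linalg.solve(H + lam * np.diag(np.maximum(np.diag(H), 1e-12)), -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            x_new = np.clip(x + step, obj.lo, obj.hi)
            d_new = obj.total(x_new)
            if d_new < best_d - tol:
                x, best_d = x_new, d_new
                lam = max(lam / 3, 1e-10)
                improved = True
                break
            lam *= 10
        if not improved:
            converged = True
            break
    return x, converged


def fit(problem: FitProblem,
        n_steps: int = 5000, step_scale: float = 0.25, temperature: float = 0.02,
        seed: int | None = 0,
        lm_max_iter: int = 40, lm_tol: float = 1e-8) -> FitResult:
    """Two-stage fit: Metropolis exploration then LM refinement.

    The Metropolis walk proposes Gaussian moves in log10 space with
    per-parameter σ = step_scale·D, rejects moves outside the
    uncertainty box, and accepts uphill moves with probability
    exp(−Δd/temperature).  The final distance never exceeds the best
    distance seen during exploration.
    """
    if seed is None:
        raise ValueError("fits require an explicit seed for reproducibility")
    obj = _Objective(problem)
    rng = np.random.default_rng(seed)
    sigma = step_scale * np.array([problem.free[k] for k in obj.keys])
    x = obj.x0.copy()
    d = obj.total(x)
    best_x, best_d = x.copy(), d
    n_acc = 0
    trace = [(0, best_d)]
    for step in range(1, n_steps + 1):
        prop = x + rng.normal(0.0, sigma)
        if np.any(prop < obj.lo) or np.any(prop > obj.hi):
            continue
        d_prop = obj.total(prop)
        if d_prop <= d or rng.random() < np.exp(-(d_prop - d) / temperature):
            x, d = prop, d_prop
            n_acc += 1
            if d < best_d:
                best_x, best_d = x.copy(), d
                trace.append((step, best_d))
    x_ref, converged = _lm_refine(obj, best_x.copy(), max_iter=lm_max_iter, tol=lm_tol)
    d_ref = obj.total(x_ref)
    warning = None
    if d_ref > best_d:       # cannot happen by construction; belt and braces
        x_ref, d_ref = best_x, best_d
        warning = "LM refinement did not improve; returning MCMC best"
    if not converged and warning is None:
        warning = "LM stopped at max_iter without meeting tolerance"
    params, genes = obj.build(x_ref)
    dists = obj.distances(x_ref)
    return FitResult(params=params, genes=genes, distances=dists,
                     total_distance=float(sum(dists)), seed=seed,
                     n_mcmc_accepted=n_acc, mcmc_trace=trace,
                     lm_converged=converged, warning=warning)


#: default uncertainty degrees for a per-gene fit: two decades for the
#: mRNA degradation rate (the clusters span high- vs low-turnover genes
#: two orders of magnitude apart) and one decade for the on/off rates.
GENE_FIT_DEGREES = {"k_on_G": 1.0, "k_on0_G": 1.0, "k_off_G": 1.0,
                    "k_off0_G": 1.0, "d_R_G": 2.0}


def fit_gene_panel(expression, params: KineticParameters, forcing: ForcingSignal,
                   gene_init: GeneParameters | None = None,
                   degrees: dict[str, float] | None = None,
                   n_steps: int = 400, seed: int | None = 0,
                   **fit_kwargs) -> pd.DataFrame:
    """Independent P_G fits for each gene of a fold-change matrix.

    ``expression`` is an :class:`~nfkbsync.expression_patterns.ExpressionMatrix`
    or a genes × timepoints DataFrame of fold changes with time (min)
    column labels.  P_NF-κB stays fixed at ``params``.  Returns one row
    per gene with fitted rates and the fit distance (the mean relative
    error per timepoint); per-gene failures are recorded, not raised.
    """
    from .expression_patterns import ExpressionMatrix

    if isinstance(expression, ExpressionMatrix):
        frame = expression.values
        times = expression.timepoints_min
    else:
        frame = expression
        times = np.asarray([float(c) for c in frame.columns])
    init = gene_init if gene_init is not None else GeneParameters(
        k_on_G=5.0, k_on0_G=0.05, k_off_G=1.0, k_off0_G=0.3, d_R_G=0.5)
    degrees = dict(GENE_FIT_DEGREES if degrees is None else degrees)
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(len(frame)) % (2 ** 31)
    for (gene_id, series), gseed in zip(frame.iterrows(), seeds):
        rec: dict = {"gene_id": gene_id}
        try:
            ds = Dataset(kind="fold_change", times_min=times,
                         values=series.to_numpy(float), gene_id=str(gene_id))
            problem = FitProblem(
                params=params, forcing=forcing, datasets=[ds],
                free={f"{gene_id}:{rate}": D for rate, D in degrees.items()},
                genes={str(gene_id): init})
            res = fit(problem, n_steps=n_steps, seed=int(gseed), **fit_kwargs)
            fitted = res.genes[str(gene_id)]
            rec.update(fitted.as_dict())
            rec["distance"] = res.total_distance
            rec["error"] = None
        except Exception as exc:
            rec["distance"] = np.nan
            rec["error"] = str(exc)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id")
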