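"""Synthetic fed-batch fermentation data generator.

Emulates the data structure of a pilot-scale *Pichia pastoris* fed-batch
run: a ~90 h fermentation sampled every 15 min on 16 online auxiliary
(environmental) channels, with the two hard-to-measure dominant variables
— cell concentration ``X`` (g/L dry cell weight) and product concentration
``P`` (arbitrary product units) — assayed offline on a much sparser,
phase-dependent schedule and aligned to the auxiliary grid by
interpolation.

Biomass follows logistic growth ``dX/dt = mu * X * (1 - X/X_max)`` with a
phase-dependent multiplier on the specific growth rate (lag, exponential
fed-batch, transition, induction), and product formation follows the
Luedeking–Piret model ``dP/dt = alpha * dX/dt + beta * X``.  Both ODEs are
propagated with their per-phase closed-form solutions, so trajectories are
exact to floating point.

Auxiliary channels are deterministic functions of the state plus
multiplicative noise.  By construction at least six channels are strongly
coupled to (X, P) — dissolved oxygen, exhaust CO2, fermentation time, the
phase-gated substrate feeds, the condensate/cooling flow — and at least
four (tank pressure, air flow, stirring speed, peptone feed, temperature)
are controlled setpoints carrying noise only, so that relevance-based
variable screening has real signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical auxiliary-channel order used everywhere downstream (CSV
#: columns, mutual-information tie-breaks, model signatures).
AUX_NAMES = [
    "DO", "eta_CO2", "pH", "f_b", "P_tank", "l", "t_ferm", "f_w",
    "f_a", "f_f", "f_c", "T", "r", "f_e", "f_d", "V",
]

DOMINANT_NAMES = ["X", "P"]

#: Channels driven only by their setpoint + noise (no state coupling).
WEAK_CHANNELS = ["P_tank", "l", "T", "r", "f_d"]


@dataclass(frozen=True)
class SimulatorConfig:
    """Parameters of the synthetic fermentation.

    Defaults describe a high-cell-density run: X climbs a sigmoid toward
    ``X_max`` ~ 85 g/L over 90 h, product accumulates to a few thousand
    units so that P is roughly 10-100x X in magnitude.
    """

    mu_max: float = 0.18            # max specific growth rate, 1/h
    X_max: float = 85.0             # carrying capacity, g/L
    X0: float = 1.5                 # inoculum, g/L
    alpha: float = 30.0             # growth-associated product yield, units/g
    beta: float = 0.5               # non-growth-associated rate, units/(g h)
    phase_boundaries: tuple = (12.0, 40.0, 65.0)   # h, splits run into 4 phases
    phase_mu_factors: tuple = (0.55, 1.0, 0.45, 0.18)
    noise_sd_aux: float = 0.02      # relative noise per auxiliary channel
    noise_sd_dom: float = 0.02      # relative assay noise on X and P
    batch_jitter_sd: float = 0.04   # relative batch-to-batch parameter jitter
    duration: float = 90.0          # h
    aux_period: float = 0.25        # h (15 min)
    dom_period_exp: float = 1.0     # h, offline assay interval in exponential phase
    dom_period_other: float = 2.0   # h, elsewhere
    seed: int = 0

    def __post_init__(self):
        if self.mu_max <= 0:
            raise ValueError("mu_max must be > 0")
        if self.X_max <= 0:
            raise ValueError("X_max must be > 0")
        if self.aux_period <= 0:
            raise ValueError("aux_period must be > 0")
        b = np.asarray(self.phase_boundaries, dtype=float)
        if b.size and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= self.duration):
            raise ValueError(
                "phase_boundaries must be strictly increasing within (0, duration)"
            )
        if len(self.phase_mu_factors) != len(self.phase_boundaries) + 1:
            raise ValueError("need one phase_mu_factor per phase")


@dataclass
class FermentationBatch:
    """One simulated batch: dense auxiliary grid + sparse offline assays."""

    batch_id: int
    times: np.ndarray               # auxiliary grid, h
    aux: pd.DataFrame               # n_times x 16, columns AUX_NAMES
    dom_times: np.ndarray           # sparse assay times, h
    dom_values: np.ndarray          # n_dom x 2, columns (X, P)
    config: SimulatorConfig = field(repr=False, default=None)


def _phase_edges(config: SimulatorConfig) -> np.ndarray:
    return np.concatenate([[0.0], np.asarray(config.phase_boundaries, float),
                           [config.duration]])


def _phase_index(t: np.ndarray, config: SimulatorConfig) -> np.ndarray:
    edges = _phase_edges(config)
    # right-closed last bin so t == duration lands in the final phase
    idx = np.searchsorted(edges, t, side="right") - 1
    return np.clip(idx, 0, len(config.phase_mu_factors) - 1)


def _logistic_segment(X0, mu, X_max, dt):
    """Closed-form logistic state after time dt, plus the integral of X."""
    if mu == 0.0:
        return X0, X0 * dt
    e = np.exp(mu * dt)
    X1 = X0 * X_max * e / (X_max + X0 * (e - 1.0))
    # int_0^dt X ds = (X_max/mu) * ln((X_max + X0(e^{mu dt} - 1))/X_max)
    intX = (X_max / mu) * np.log((X_max + X0 * (e - 1.0)) / X_max)
    return X1, intX


def _trajectory(times: np.ndarray, cfg: SimulatorConfig):
    """Exact (X, P, dX/dt) on an arbitrary increasing time grid."""
    edges = _phase_edges(cfg)
    factors = np.asarray(cfg.phase_mu_factors, float)
    X = np.empty_like(times)
    P = np.empty_like(times)
    # propagate segment by segment from t=0 through phase edges + grid points
    Xc, Pc, tc = cfg.X0, 0.0, 0.0
    phase_of = _phase_index(times, cfg)
    for i, t in enumerate(times):
        while True:
            ph = int(_phase_index(np.array([tc]), cfg)[0])
            seg_end = min(t, edges[ph + 1]) if tc < edges[ph + 1] else t
            mu = cfg.mu_max * factors[ph]
            dt = seg_end - tc
            if dt > 0:
                X1, intX = _logistic_segment(Xc, mu, cfg.X_max, dt)
                Pc = Pc + cfg.alpha * (X1 - Xc) + cfg.beta * intX
                Xc, tc = X1, seg_end
            if tc >= t - 1e-12:
                break
        X[i], P[i] = Xc, Pc
    mu_t = cfg.mu_max * factors[phase_of]
    dXdt = mu_t * X * (1.0 - X / cfg.X_max)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(P))):
        raise ValueError(
            f"non-finite fermentation state for parameters mu_max={cfg.mu_max}, "
            f"X_max={cfg.X_max}, alpha={cfg.alpha}, beta={cfg.beta}"
        )
    return X, P, dXdt


def _aux_channels(times, X, P, dXdt, cfg: SimulatorConfig) -> pd.DataFrame:
    """Deterministic auxiliary channel values (noise added separately)."""
    x = X / cfg.X_max
    g_scale = cfg.mu_max * cfg.X_max / 4.0        # peak logistic rate
    g = dXdt / g_scale
    ph = _phase_index(times, cfg)
    n_ph = len(cfg.phase_mu_factors)
    gate = lambda *phases: np.isin(ph, phases).astype(float)

    # stepped per-phase feed setpoints (operator recipe) on top of the
    # state-coupled terms; the recipe steps are what make the operating
    # phases separable regimes in auxiliary space
    def stepped(setpoints):
        table = np.resize(np.asarray(setpoints, float), n_ph)
        return table[ph]

    aux = pd.DataFrame(index=np.arange(len(times)), columns=AUX_NAMES, dtype=float)
    aux["DO"] = np.clip(100.0 * (1.0 - 0.85 * x) - 12.0 * g, 2.0, None)
    aux["eta_CO2"] = 0.8 + 4.5 * g + 1.2 * x
    aux["pH"] = stepped([6.1, 5.8, 6.0, 6.3]) - 0.1 * g
    aux["f_b"] = stepped([0.05, 0.3, 0.6, 0.9]) + 0.05 * x
    aux["P_tank"] = 1.25
    aux["l"] = 30.0
    aux["t_ferm"] = times
    aux["f_w"] = 0.5 + 3.0 * x
    aux["f_a"] = stepped([0.05, 0.5, 0.3, 0.1]) + 0.4 * g
    aux["f_f"] = stepped([0.01, 0.01, 1.0, 2.0]) + gate(n_ph - 2, n_ph - 1) * 0.1 * x
    aux["f_c"] = 0.02 + gate(0) * (0.6 + 1.5 * g)
    aux["T"] = 30.0
    aux["r"] = 600.0
    aux["f_e"] = 0.02 + gate(1) * (0.4 + 2.0 * g)
    aux["f_d"] = 0.1
    feeds = aux[["f_b", "f_a", "f_f", "f_c", "f_e"]].sum(axis=1).to_numpy()
    dt = np.diff(times, prepend=times[0] if len(times) else 0.0)
    aux["V"] = 180.0 + 1.1 * np.cumsum(feeds * dt)
    return aux


def _dom_schedule(cfg: SimulatorConfig) -> np.ndarray:
    """Offline assay times: 1 h apart in the exponential phase, 2 h elsewhere."""
    exp_phase = int(np.argmax(cfg.phase_mu_factors))
    ts, t = [], 0.0
    while t <= cfg.duration + 1e-9:
        ts.append(min(t, cfg.duration))
        ph = int(_phase_index(np.array([t]), cfg)[0])
        t += cfg.dom_period_exp if ph == exp_phase else cfg.dom_period_other
    ts = np.array(ts)
    if ts[-1] < cfg.duration - 1e-9:
        ts = np.append(ts, cfg.duration)
    return np.unique(ts)


def _jittered(cfg: SimulatorConfig, rng: np.random.Generator) -> SimulatorConfig:
    if cfg.batch_jitter_sd == 0:
        return cfg
    j = lambda v: float(v * (1.0 + cfg.batch_jitter_sd * rng.standard_normal()))
    return replace(cfg, mu_max=max(j(cfg.mu_max), 1e-3),
                   X_max=max(j(cfg.X_max), 1.0),
                   alpha=max(j(cfg.alpha), 0.0), beta=max(j(cfg.beta), 0.0))


def simulate_batch(config: SimulatorConfig, batch_id: int) -> FermentationBatch:
    """Simulate one fed-batch run on the auxiliary sampling grid.

    Batch-to-batch kinetic jitter and measurement noise are drawn from an
    RNG seeded by ``(config.seed, batch_id)``, so the same config and
    batch_id always reproduce the same batch bit for bit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, batch_id]))
    cfg = _jittered(config, rng)

    n_steps = int(round(config.duration / config.aux_period))
    times = np.linspace(0.0, config.duration, n_steps + 1)
    X, P, dXdt = _trajectory(times, cfg)
    aux = _aux_channels(times, X, P, dXdt, cfg)
    if config.noise_sd_aux > 0:
        noisy = [c for c in AUX_NAMES if c != "t_ferm"]
        aux[noisy] = aux[noisy] * (
            1.0 + config.noise_sd_aux * rng.standard_normal((len(times), len(noisy)))
        )
    aux[[c for c in AUX_NAMES if c != "pH"]] = aux[
        [c for c in AUX_NAMES if c != "pH"]].clip(lower=0.0)

    dom_times = _dom_schedule(config)
    Xd, Pd, _ = _trajectory(dom_times, cfg)
    dom = np.column_stack([Xd, Pd])
    if config.noise_sd_dom > 0:
        dom = dom * (1.0 + config.noise_sd_dom * rng.standard_normal(dom.shape))
    dom = np.clip(dom, 0.0, None)
    return FermentationBatch(batch_id=batch_id, times=times, aux=aux,
                             dom_times=dom_times, dom_values=dom, config=config)


def interpolate_dominant(batch: FermentationBatch) -> pd.DataFrame:
    """Align sparse offline assays to the auxiliary grid.

    X and P are linearly interpolated onto the auxiliary time grid; grid
    rows outside the assayed interval [first, last] are dropped (no
    extrapolation).  Returns one row per retained grid point with all 16
    auxiliary channels, X, P, batch id and time.
    """
    if len(batch.dom_times) < 2:
        raise ValueError("need at least 2 dominant-variable samples to interpolate")
    t0, t1 = batch.dom_times[0], batch.dom_times[-1]
    keep = (batch.times >= t0) & (batch.times <= t1)
    tk = batch.times[keep]
    out = pd.DataFrame({"batch": batch.batch_id, "time_h": tk})
    out = pd.concat([out, batch.aux.loc[keep].reset_index(drop=True)], axis=1)
    out["X"] = np.interp(tk, batch.dom_times, batch.dom_values[:, 0])
    out["P"] = np.interp(tk, batch.dom_times, batch.dom_values[:, 1])
    return out


def build_dataset(
    n_batches: int,
    config: SimulatorConfig,
    test_fraction: float = 0.1,
    split: str = "batch",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, interpolate and split a multi-batch dataset.

    split="batch" (default) holds out whole batches (the last
    ``round(test_fraction * n_batches)``, at least one), avoiding temporal
    leakage between train and test; split="row" holds out the latest
    fraction of rows within the concatenated table.  The split is recorded
    in ``DataFrame.attrs``.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if split not in ("batch", "row"):
        raise ValueError("split must be 'batch' or 'row'")
    tables = [interpolate_dominant(simulate_batch(config, b))
              for b in range(n_batches)]
    full = pd.concat(tables, ignore_index=True)
    if split == "batch":
        n_test = max(1, int(round(test_fraction * n_batches)))
        if n_test >= n_batches:
            raise ValueError(
                f"{n_batches} batches cannot support a {test_fraction:.0%} "
                "whole-batch holdout; use split='row'"
            )
        test_ids = list(range(n_batches - n_test, n_batches))
        test = full[full["batch"].isin(test_ids)].reset_index(drop=True)
        train = full[~full["batch"].isin(test_ids)].reset_index(drop=True)
        meta = {"split": "batch", "test_batches": test_ids}
    else:
        n_test = int(round(test_fraction * len(full)))
        if n_test < 1 or n_test >= len(full):
            raise ValueError("row split fraction leaves an empty partition")
        train = full.iloc[:-n_test].reset_index(drop=True)
        test = full.iloc[-n_test:].reset_index(drop=True)
        meta = {"split": "row", "n_test_rows": n_test}
    meta.update({"n_batches": n_batches, "test_fraction": test_fraction,
                 "seed": config.seed})
    train.attrs["split"] = meta
    test.attrs["split"] = meta
    return train, test
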