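"""Mechanistic single-cell simulator of the H2O2 -> PRDX -> {FOXO1, p53} switch.

State per cell (all per hour, see :class:`redoxtf.params.KineticParams`):

``H``  intracellular H2O2 (closed form; linear clearance, bolus or
       continuous production),
``P``  hyperoxidized 2-Cys peroxiredoxin fraction,
       ``dP/dt = k_hyp * H * (1 - P) - k_srx * m_srx * P``,
``D``  oxidative damage integral,
       ``dD/dt = k_dmg * H + k_pdmg * P - k_rep * D``,
``F``  FOXO1 nuclear fraction, first-order relaxation toward ``f_max``
       while ``P > theta_F`` and toward ``f_min`` otherwise,
``x``  p53 above baseline, repressed by MDM2:
       ``dx/dt = beta_p * s - (alpha_p * M + alpha_x) * x``,
``M``  MDM2-like repressor produced cooperatively from *delayed* p53,
       ``dM/dt = gamma_eff * x(t-tau)^4 / (K_m^4 + x(t-tau)^4) - delta_m * M``
       with ``gamma_eff = gamma_m / (1 + (D/d_m)^2)`` -- damage weakens the
       feedback, turning pulsing into a sustained rise in doomed cells,
``s``  activation filter of the p53 drive ``u = (D + w_relay * P) *
       [P <= theta_F]``: rises with time constant ``tau_act`` while
       ``u > theta_p``, decays with ``tau_deact`` otherwise.

While ``P > theta_F`` (hyperoxidation above the FOXO1 threshold) the p53
subsystem is frozen (``dx = dM = 0`` and the drive is gated off): this one
rule produces both the p53 blockade under high bolus doses and the p53
plateau once FOXO1 enters the nucleus under continuous production.  Damage
weakens the MDM2 feedback (``d_m``), so heavily damaged cells show
sustained, non-oscillatory p53 while mildly stressed cells pulse with a
~5.5 h period.

Death is a hazard process on excess damage,
``lambda(t) = lambda_d * min(max(D - D_c, 0), hazard_cap)``;
each cell draws a unit-exponential threshold on its cumulative hazard.

Integration is fixed-step RK4 at 1 min with sample-and-hold for the delay
term.  Cell-level randomness comes from counter-based (Philox) streams
keyed on ``(seed, cell_index)``, so populations are reproducible and
order-independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import (
    ExposureCondition,
    InvalidConditionError,
    KineticParams,
    PerturbationMode,
    SimulationConfig,
)

__all__ = [
    "simulate_h2o2",
    "simulate_prdx",
    "simulate_cell",
    "simulate_population",
    "simulate_snapshot",
    "IntegrationError",
]

# Per-cell lognormal heterogeneity applies to these parameters, in this order.
_HETEROGENEOUS = ("k_hyp", "k_clear", "theta_F", "D_c")


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


def _production_rate(condition: ExposureCondition, params: KineticParams) -> float:
    """Continuous-mode H2O2 production rate v (dose units / h)."""
    dose = condition.dose / (1.0 + params.density_coupling * params.cells_plated)
    return params.gox_rate * dose ** params.gox_exponent if dose > 0 else 0.0


def _effective_dose(condition: ExposureCondition, params: KineticParams) -> float:
    return condition.dose / (1.0 + params.density_coupling * params.cells_plated)


def simulate_h2o2(
    condition: ExposureCondition,
    params: KineticParams,
    t_grid: np.ndarray,
    k_clear=None,
) -> np.ndarray:
    """Closed-form intracellular H2O2 on ``t_grid`` (hours, ascending from 0).

    Bolus: ``H(t0) = dose`` decaying as ``exp(-k_clear * (t - t0))``.
    Continuous: ``dH/dt = v - k_clear * H`` from ``H(t0) = 0``; if
    ``params.gox_dip > 0`` the production rate drops by that fraction one
    hour after exposure begins.  ``k_clear`` may be a scalar or per-cell
    array (broadcast against the leading axis); defaults to
    ``params.k_clear``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid[0] < 0 or (t_grid.size > 1 and np.any(np.diff(t_grid) <= 0)):
        raise ValueError("t_grid must be ascending and start at t >= 0")
    if condition.dose < 0:
        raise InvalidConditionError("dose must be >= 0")
    kc = params.k_clear if k_clear is None else k_clear
    kc = np.asarray(kc, dtype=float)
    t = t_grid - condition.treatment_start
    if kc.ndim > 0:
        t = t[np.newaxis, :]
        kc = kc[:, np.newaxis]
    if condition.mode == "none" or condition.dose == 0:
        return np.zeros(np.broadcast_shapes(np.shape(kc), np.shape(t)))

    if condition.mode == "bolus":
        dose = _effective_dose(condition, params)
        H = dose * np.exp(-kc * np.maximum(t, 0.0))
        return np.where(t >= 0, H, 0.0)

    # continuous production, piecewise-constant rate (optional dip after 1 h)
    v0 = _production_rate(condition, params)
    v1 = v0 * (1.0 - params.gox_dip)
    tp = np.maximum(t, 0.0)
    H = (v0 / kc) * (1.0 - np.exp(-kc * np.minimum(tp, 1.0)))
    t2 = np.maximum(tp - 1.0, 0.0)
    H1 = (v0 / kc) * (1.0 - np.exp(-kc))
    H = np.where(tp > 1.0, (v1 / kc) + (H1 - v1 / kc) * np.exp(-kc * t2), H)
    return np.where(t >= 0, H, 0.0)


def simulate_prdx(
    t_grid: np.ndarray,
    H: np.ndarray,
    params: KineticParams,
    perturbation: PerturbationMode | None = None,
) -> np.ndarray:
    """Hyperoxidized PRDX fraction driven by a given H2O2 series.

    ``dP/dt = k_hyp * H * (1 - P) - k_srx * m * P`` with ``P(0) = 0``,
    integrated by RK4 with linear interpolation of ``H`` between grid
    points, clipped to [0, 1].
    """
    t_grid = np.asarray(t_grid, dtype=float)
    H = np.asarray(H, dtype=float)
    if H.shape != t_grid.shape:
        raise ValueError("H and t_grid must have the same shape")
    if np.any(H < 0):
        raise ValueError("H series must be nonnegative")
    m = 1.0 if perturbation is None else perturbation.srxn1_multiplier
    k_hyp, k_srx = params.k_hyp, params.k_srx * m

    P = np.empty_like(H)
    P[0] = 0.0
    for i in range(len(H) - 1):
        dt = t_grid[i + 1] - t_grid[i]
        n_sub = max(1, int(round(dt / params.dt_int)))
        h = dt / n_sub
        p = P[i]
        for j in range(n_sub):
            frac0 = j / n_sub
            frac1 = (j + 0.5) / n_sub
            frac2 = (j + 1) / n_sub
            H0 = H[i] + (H[i + 1] - H[i]) * frac0
            Hm = H[i] + (H[i + 1] - H[i]) * frac1
            H1 = H[i] + (H[i + 1] - H[i]) * frac2

            def f(Hv, Pv):
                return k_hyp * Hv * (1.0 - Pv) - k_srx * Pv

            k1 = f(H0, p)
            k2 = f(Hm, p + 0.5 * h * k1)
            k3 = f(Hm, p + 0.5 * h * k2)
            k4 = f(H1, p + h * k3)
            p = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        P[i + 1] = min(max(p, 0.0), 1.0)
    return P


def _cell_streams(seed: int, cell_indices: np.ndarray) -> list[np.random.Generator]:
    """Counter-based per-cell RNG streams keyed on (seed, cell_index)."""
    return [
        np.random.Generator(
            np.random.Philox(key=np.array([seed % 2**64, int(i)], dtype=np.uint64))
        )
        for i in cell_indices
    ]


def _draw_cells(config: SimulationConfig, cell_indices: np.ndarray):
    """All per-cell randomness, drawn in a fixed order per cell."""
    p = config.params
    sigma = np.sqrt(np.log1p(p.cv_cell**2))
    n = len(cell_indices)
    mult = np.empty((n, len(_HETEROGENEOUS)))
    death_q = np.empty(n)
    noise = np.empty((n, config.n_samples, 2))
    for row, gen in enumerate(_cell_streams(config.seed, cell_indices)):
        z = gen.standard_normal(len(_HETEROGENEOUS))
        mult[row] = np.exp(sigma * z - 0.5 * sigma**2)
        death_q[row] = gen.standard_exponential()
        noise[row] = gen.standard_normal((config.n_samples, 2))
    return mult, death_q, noise


def _integrate(config: SimulationConfig, cell_indices: np.ndarray) -> dict:
    """Vectorized RK4 integration of the full model for the given cells."""
    p = config.params
    pert = config.perturbation
    cond = config.condition
    n = len(cell_indices)

    mult, death_q, noise = _draw_cells(config, cell_indices)
    k_hyp = p.k_hyp * mult[:, 0]
    k_clear = p.k_clear * mult[:, 1] * pert.prdx_capacity_multiplier
    theta_F = np.minimum(p.theta_F * mult[:, 2], 0.999) * pert.prdx_capacity_multiplier
    D_c = p.D_c * mult[:, 3]
    m_srx = pert.srxn1_multiplier
    # hyperoxidized PRDX is toxic in proportion to how long it stays
    # unrepaired; sulfiredoxin cycling flux detoxifies it (saturable)
    pdmg_eff = p.k_pdmg / (1.0 + m_srx * p.k_srx / p.k_srx_half)

    dt = p.dt_int
    n_steps = int(round(config.t_end / dt))
    stride = int(round(config.dt_sample / dt))
    n_delay = max(1, int(round(p.tau_delay / dt)))

    # closed-form H at step boundaries and midpoints
    t_edges = np.arange(n_steps + 1) * dt
    H_edge = simulate_h2o2(cond, p, t_edges, k_clear=k_clear)
    H_mid = simulate_h2o2(cond, p, t_edges[:-1] + 0.5 * dt, k_clear=k_clear)

    P = np.zeros(n)
    D = np.zeros(n)
    F = np.full(n, p.f_min)
    X = np.zeros(n)
    M = np.zeros(n)
    S = np.zeros(n)
    x_hist = np.zeros((n_steps + 1, n))
    on_hist = np.zeros((n_steps + 1, n), dtype=bool)
    n_sig = int(round(p.tau_sig / dt))

    cum_haz = np.zeros(n)
    lam_prev = np.zeros(n)
    death_time = np.full(n, np.nan)

    n_samp = config.n_samples
    F_samp = np.empty((n_samp, n))
    P53_samp = np.empty((n_samp, n))
    P_samp = np.empty((n_samp, n))
    D_samp = np.empty((n_samp, n))
    F_samp[0], P53_samp[0] = F, p.p53_baseline + X
    P_samp[0], D_samp[0] = P, D

    def rhs(Hv, P_, D_, F_, X_, M_, S_, x_tau, on_tau):
        frozen = P_ > theta_F
        dP = k_hyp * Hv * (1.0 - P_) - p.k_srx * m_srx * P_
        dD = p.k_dmg * Hv + pdmg_eff * P_ - p.k_rep * D_
        # while blocked (frozen) the upstream signal is actively shut off and
        # decays at the fast activation timescale, not the slow persistence one
        decay_tau = np.where(frozen, p.tau_act, p.tau_deact)
        dS = np.where(on_tau & ~frozen, (1.0 - S_) / p.tau_act, -S_ / decay_tau)
        gamma_eff = p.gamma_m / (1.0 + (D_ / p.d_m) ** 2)
        hill = x_tau**4 / (p.K_m**4 + x_tau**4)
        dX = np.where(frozen, 0.0, p.beta_p * S_ - (p.alpha_p * M_ + p.alpha_x) * X_)
        dM = np.where(frozen, 0.0, gamma_eff * hill - p.delta_m * M_)
        # below the hyperoxidation threshold the still-active PRDX relay
        # retains FOXO1 in the cytoplasm (disulfide tethering), pushing the
        # resting nuclear fraction below the untreated baseline
        f_target = np.where(frozen, p.f_max, p.f_min / (1.0 + p.k_retention * P_))
        dF = (f_target - F_) / p.tau_f
        return dP, dD, dF, dX, dM, dS

    for j in range(n_steps):
        H0, Hm, H1 = H_edge[:, j], H_mid[:, j], H_edge[:, j + 1]
        # delayed inputs, sample-and-hold across the RK4 substeps
        x_tau = x_hist[j - n_delay] if j >= n_delay else np.zeros(n)
        on_tau = on_hist[j - n_sig] if j >= n_sig else np.zeros(n, dtype=bool)

        k1 = rhs(H0, P, D, F, X, M, S, x_tau, on_tau)
        y2 = [v + 0.5 * dt * dv for v, dv in zip((P, D, F, X, M, S), k1)]
        k2 = rhs(Hm, *y2, x_tau, on_tau)
        y3 = [v + 0.5 * dt * dv for v, dv in zip((P, D, F, X, M, S), k2)]
        k3 = rhs(Hm, *y3, x_tau, on_tau)
        y4 = [v + dt * dv for v, dv in zip((P, D, F, X, M, S), k3)]
        k4 = rhs(H1, *y4, x_tau, on_tau)

        P, D, F, X, M, S = (
            v + (dt / 6.0) * (a + 2 * b + 2 * c + d)
            for v, a, b, c, d in zip((P, D, F, X, M, S), k1, k2, k3, k4)
        )
        P = np.clip(P, 0.0, 1.0)
        X = np.maximum(X, 0.0)
        M = np.maximum(M, 0.0)
        D = np.maximum(D, 0.0)
        x_hist[j + 1] = X
        on_hist[j + 1] = (P <= theta_F) & (D + p.w_relay * P > p.theta_p)

        lam = p.lambda_d * np.minimum(np.maximum(D - D_c, 0.0), p.hazard_cap)
        new_cum = cum_haz + 0.5 * (lam_prev + lam) * dt
        crossed = (new_cum >= death_q) & np.isnan(death_time)
        if np.any(crossed):
            inc = new_cum - cum_haz
            frac = np.where(inc > 0, (death_q - cum_haz) / np.where(inc > 0, inc, 1.0), 1.0)
            # commitment-to-execution latency: the cell is observed for a
            # while after its hazard threshold is crossed
            death_time[crossed] = (
                (j + np.clip(frac[crossed], 0.0, 1.0)) * dt + p.death_latency
            )
        cum_haz, lam_prev = new_cum, lam

        if (j + 1) % stride == 0:
            i_s = (j + 1) // stride
            F_samp[i_s], P53_samp[i_s] = F, p.p53_baseline + X
            P_samp[i_s], D_samp[i_s] = P, D

    if not (
        np.all(np.isfinite(P)) and np.all(np.isfinite(D)) and np.all(np.isfinite(X))
    ):
        bad = int(cell_indices[
            np.flatnonzero(~(np.isfinite(P) & np.isfinite(D) & np.isfinite(X)))[0]
        ])
        raise IntegrationError(
            f"non-finite state for cell {bad} (seed={config.seed}, "
            f"mode={cond.mode}, dose={cond.dose}, perturbation={pert.label})"
        )

    # deaths executing after the movie ends are never observed
    death_time[death_time > config.t_end] = np.nan

    # measurement noise, then death truncation; severe hyperoxidation mildly
    # suppresses the basal p53 pool (translation attenuation during the
    # blockade), so heavily stressed cells sit at or just below control
    t_samp = config.sample_times()
    foxo = np.clip(F_samp.T * np.exp(p.sigma_meas * noise[:, :, 0]), 0.0, 1.0)
    p53 = (
        P53_samp.T
        * (1.0 - p.p53_suppression * P_samp.T)
        * np.exp(p.sigma_meas * noise[:, :, 1])
    )
    dead_mask = ~np.isnan(death_time)[:, None] & (t_samp[None, :] >= death_time[:, None])
    foxo[dead_mask] = np.nan
    p53[dead_mask] = np.nan

    return {
        "t": t_samp,
        "foxo": foxo,              # (n_cells, n_samples)
        "p53": p53,
        "death_time": death_time,  # NaN for survivors
        "prdx": P_samp.T,          # noiseless latent states (diagnostics)
        "damage": D_samp.T,
    }


def _cell_id(index: int, prefix: str = "") -> str:
    return f"{prefix}c{index:05d}"


def _as_tidy(
    config: SimulationConfig, res: dict, cell_indices: np.ndarray, id_prefix: str = ""
) -> pd.DataFrame:
    n, n_samp = res["foxo"].shape
    t = res["t"]
    dead = ~np.isnan(res["death_time"])[:, None] & (
        t[None, :] >= np.where(np.isnan(res["death_time"]), np.inf, res["death_time"])[:, None]
    )
    return pd.DataFrame(
        {
            "cell_id": np.repeat([_cell_id(i, id_prefix) for i in cell_indices], n_samp),
            "mode": config.condition.mode,
            "dose": config.condition.dose,
            "perturbation": config.perturbation.label,
            "t_h": np.tile(t, n),
            "foxo1_nuc_frac": res["foxo"].ravel(),
            "p53_nuc": res["p53"].ravel(),
            "dead": dead.ravel().astype(int),
        }
    )


def simulate_cell(config: SimulationConfig, cell_index: int):
    """One cell's trace; identical to the matching row block of the population."""
    from .trace_io import CellTrace

    if not 0 <= cell_index:
        raise ValueError("cell_index must be >= 0")
    res = _integrate(config, np.array([cell_index]))
    dt_death = res["death_time"][0]
    return CellTrace(
        cell_id=_cell_id(cell_index),
        mode=config.condition.mode,
        dose=config.condition.dose,
        perturbation=config.perturbation.label,
        t=res["t"],
        foxo1_nuc_frac=res["foxo"][0],
        p53_nuc=res["p53"][0],
        death_time=None if np.isnan(dt_death) else float(dt_death),
    )


def simulate_population(config: SimulationConfig, id_prefix: str = "") -> pd.DataFrame:
    """Simulate ``config.n_cells`` cells; returns the tidy trace table.

    Deterministic: identical configs give identical tables.  ``id_prefix``
    namespaces the cell ids so tables from different conditions can be
    pooled without collisions.
    """
    idx = np.arange(config.n_cells)
    res = _integrate(config, idx)
    return _as_tidy(config, res, idx, id_prefix)


def simulate_snapshot(
    config: SimulationConfig, t_fix: float = 5.0, id_prefix: str = ""
) -> pd.DataFrame:
    """Fixed-timepoint (immunofluorescence-like) readout at ``t_fix`` hours.

    Returns one row per cell still alive at ``t_fix`` with the noisy FOXO1
    nuclear fraction and the natural log of noisy nuclear p53.
    """
    if not 0 < t_fix <= config.t_end:
        raise ValueError(f"t_fix must lie in (0, {config.t_end}], got {t_fix}")
    ratio = t_fix / config.dt_sample
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("t_fix must fall on the sampling grid")
    i_fix = int(round(ratio))
    idx = np.arange(config.n_cells)
    res = _integrate(config, idx)
    alive = np.isnan(res["death_time"]) | (res["death_time"] > t_fix)
    return pd.DataFrame(
        {
            "cell_id": [_cell_id(i, id_prefix) for i in idx[alive]],
            "mode": config.condition.mode,
            "dose": config.condition.dose,
            "perturbation": config.perturbation.label,
            "foxo1_nuc_frac": res["foxo"][alive, i_fix],
            "log_p53": np.log(res["p53"][alive, i_fix]),
        }
    )
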