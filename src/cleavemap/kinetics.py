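"""Equilibrium occupancy, binding fits, and the kinetic-trap cleavage model.

The enzyme binds DNA tightly as a monomer but cuts only as a dimer. Three
levels of description are implemented:

1. Closed-form equilibrium occupancy of a cleavable site with two
   independent monomer binding sites (``fraction_single_bound``,
   ``fraction_dimer_bound``) and the hyperbolic Kd fit used for band-shift
   titrations.
2. Descriptive two-phase association fits of substrate-utilization time
   courses, Y(t) = A1*(1 - exp(-k1 t)) + A2*(1 - exp(-k2 t)). These
   visualize biphasic trends; they are not estimates of mechanistic rate
   parameters.
3. A minimal mass-action scheme for the kinetic trap: cleavable sites S
   assemble a dimer sequentially (S + P <-> SP <-> SP2 -> cleaved) while a
   large pool of decoy monomer sites D soaks up protein (D + P <-> DP).
   Statistical factors (2*k_on for the first binding, 2*k_off for the loss
   of one protomer from the dimer) make the k_cut = 0 equilibrium of the
   scheme coincide exactly with the independent-two-site closed form.
   Cleaved product keeps its two protomers covalently attached, so with
   slow off-rates protein that commits early is not recycled — the trap
   that produces biphasic kinetics and order-of-addition asymmetry when
   substrates are staged.

Units: concentrations in nM, time in minutes, k_on in /nM/min, k_off and
k_cut in /min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from cleavemap.errors import CleavemapError, DataError


@dataclass(frozen=True)
class OccupancyModel:
    """Equilibrium monomer binding: dissociation constant and free protein (nM)."""

    kd: float
    p_free: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise DataError("Kd must be > 0")
        if self.p_free < 0:
            raise DataError("free protein concentration must be >= 0")


def fraction_single_bound(model: OccupancyModel) -> float:
    """Occupancy of one monomer site: P / (Kd + P)."""
    return model.p_free / (model.kd + model.p_free)


def fraction_dimer_bound(model: OccupancyModel) -> float:
    """Both of two independent monomer sites occupied: (P / (Kd + P))^2."""
    return fraction_single_bound(model) ** 2


@dataclass(frozen=True)
class KdFit:
    """Apparent Kd from a binding titration, with its standard error."""

    kd: float
    kd_se: float
    model: str  # "hyperbola" or "quadratic"
    residual_ss: float

    def predict(self, conc: np.ndarray, dna_conc: float | None = None) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if self.model == "hyperbola":
            return conc / (self.kd + conc)
        return _quadratic_bound(conc, self.kd, dna_conc)


def _quadratic_bound(p_total: np.ndarray, kd: float, dna_conc: float) -> np.ndarray:
    """Ligand-depletion fraction bound for total protein and DNA concentrations."""
    s = p_total + dna_conc + kd
    return (s - np.sqrt(s * s - 4.0 * p_total * dna_conc)) / (2.0 * dna_conc)


def fit_kd(
    concentrations: Sequence[float],
    fraction_bound: Sequence[float],
    model: str = "hyperbola",
    dna_conc: float | None = None,
) -> KdFit:
    """Least-squares apparent-Kd estimate from fraction bound vs protein.

    The default is the simple hyperbola f = P / (Kd + P), the standard
    "apparent Kd" convention for band-shift titrations. ``model="quadratic"``
    fits the ligand-depletion closed form instead and requires ``dna_conc``
    (total labeled DNA, nM) — relevant when the probe concentration is not
    far below Kd.
    """
    conc = np.asarray(concentrations, dtype=float)
    frac = np.asarray(fraction_bound, dtype=float)
    if conc.size < 3:
        raise DataError("at least 3 titration points are required")
    if conc.size != frac.size:
        raise DataError("concentration and fraction arrays differ in length")
    if len(np.unique(conc)) != conc.size:
        raise DataError("concentrations must be distinct")
    if np.all(frac <= 0):
        raise DataError("all fractions are zero: Kd is unidentifiable")
    if model == "hyperbola":
        fun = lambda p, kd: p / (kd + p)
    elif model == "quadratic":
        if dna_conc is None or dna_conc <= 0:
            raise DataError("quadratic model requires a positive dna_conc")
        fun = lambda p, kd: _quadratic_bound(p, kd, dna_conc)
    else:
        raise DataError(f"unknown binding model {model!r}")
    p0 = float(np.median(conc))
    try:
        popt, pcov = curve_fit(fun, conc, frac, p0=[p0], bounds=(1e-12, np.inf), maxfev=10000)
    except RuntimeError as exc:
        raise CleavemapError(f"Kd fit did not converge: {exc}") from exc
    resid = frac - fun(conc, popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return KdFit(kd=float(popt[0]), kd_se=se, model=model, residual_ss=float(resid @ resid))


def breaks_to_protein_fraction(breaks_fmol: float, protein_nm: float, volume_ul: float) -> float:
    """Percent of protein molecules accounted for by the observed strand breaks.

    Uses 1 nM x 1 uL = 1 fmol, so the result is
    100 * breaks / (protein_conc * volume). With one break per protomer this
    is the per-protein utilization of the preparation.
    """
    if protein_nm <= 0 or volume_ul <= 0:
        raise DataError("protein concentration and volume must be > 0")
    if breaks_fmol < 0:
        raise DataError("breaks must be >= 0")
    return 100.0 * breaks_fmol / (protein_nm * volume_ul)


def one_significant_figure(percent: float) -> str:
    """Render a percentage at one significant figure, e.g. 4.3 -> '~4%'."""
    if percent == 0:
        return "~0%"
    rounded = float(f"{percent:.1g}")
    rounded_str = f"{rounded:g}"
    return f"~{rounded_str}%"


@dataclass(frozen=True)
class TwoPhaseFit:
    """Descriptive two-phase association fit (amplitudes %, rates /min)."""

    a1: float
    k1: float
    a2: float
    k2: float
    residual_ss: float
    degenerate: bool  # phases not separable (k1 ~ k2 or one amplitude ~ 0)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a1 * (1 - np.exp(-self.k1 * t)) + self.a2 * (1 - np.exp(-self.k2 * t))


def two_phase_fit(
    times: Sequence[float],
    utilization: Sequence[float],
    degenerate_rate_ratio: float = 3.0,
    degenerate_amplitude_fraction: float = 0.02,
) -> TwoPhaseFit:
    """Fit Y(t) = A1*(1-exp(-k1 t)) + A2*(1-exp(-k2 t)) to a utilization course.

    Multi-start nonlinear least squares; the returned fit has k1 >= k2. The
    ``degenerate`` flag is raised when the two phases are not separable
    (rate ratio below ``degenerate_rate_ratio`` or either amplitude below
    ``degenerate_amplitude_fraction`` of the total), signalling that a
    single exponential describes the data as well.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(utilization, dtype=float)
    if t.size < 5:
        raise DataError("at least 5 time points are required")
    if t.size != y.size:
        raise DataError("times and utilization differ in length")
    if np.any(y < 0) or np.any(y > 100):
        raise DataError("utilization must be a percentage in [0, 100]")
    if np.all(y == 0):
        raise DataError("all-zero utilization: rates unidentifiable")

    def fun(tt, a1, k1, a2, k2):
        return a1 * (1 - np.exp(-k1 * tt)) + a2 * (1 - np.exp(-k2 * tt))

    span = max(y.max(), 1.0)
    tmax = max(t.max(), 1e-6)
    starts = []
    for fast in (10.0 / tmax, 2.0 / tmax):
        for slow_frac in (0.1, 0.01):
            starts.append([span / 2, fast, span / 2, fast * slow_frac])
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                fun, t, y, p0=p0,
                bounds=([0, 1e-9, 0, 1e-9], [200, np.inf, 200, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        ss = float(np.sum((y - fun(t, *popt)) ** 2))
        if best is None or ss < best[1]:
            best = (popt, ss)
    if best is None:
        raise CleavemapError("two-phase fit did not converge from any start")
    (a1, k1, a2, k2), ss = best
    if k2 > k1:
        a1, k1, a2, k2 = a2, k2, a1, k1
    total = a1 + a2
    degenerate = (
        k1 / max(k2, 1e-12) < degenerate_rate_ratio
        or min(a1, a2) < degenerate_amplitude_fraction * max(total, 1e-12)
    )
    return TwoPhaseFit(
        a1=float(a1), k1=float(k1), a2=float(a2), k2=float(k2),
        residual_ss=ss, degenerate=bool(degenerate),
    )


@dataclass(frozen=True)
class SubstratePool:
    """A cleavable-substrate pool with an addition time (min; < 0 = on ice)."""

    name: str
    s0: float  # nM of cleavable sites
    add_time: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise DataError("substrate amount must be >= 0")


@dataclass(frozen=True)
class KineticScheme:
    """Mass-action kinetic-trap scheme.

    Reactions (per substrate pool i):

        S_i + P  -> SP_i     rate 2*k_on*S_i*P
        SP_i     -> S_i + P  rate k_off*SP_i
        SP_i + P -> SP2_i    rate dimer_boost*k_on*SP_i*P
        SP2_i    -> SP_i + P rate 2*k_off*SP2_i
        SP2_i    -> C_i      rate k_cut*SP2_i      (only for t >= 0)
        D + P   <-> DP       rates k_on / k_off

    Substrate pools are injected at their ``add_time``; negative times model
    pre-equilibration on ice, during which no cutting occurs. ``dimer_boost``
    multiplies the second-binding on-rate, the knob emulating an artificial
    dimerization module.
    """

    k_on: float  # /nM/min
    k_off: float  # /min
    k_cut: float  # /min
    p0: float  # nM total protein
    d0: float = 0.0  # nM decoy monomer sites, present from the start
    substrates: tuple[SubstratePool, ...] = ()
    dimer_boost: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_cut", "p0", "d0"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.dimer_boost <= 0:
            raise DataError("dimer_boost must be > 0")
        if not self.substrates:
            raise DataError("scheme needs at least one substrate pool")
        object.__setattr__(self, "substrates", tuple(self.substrates))


@dataclass(frozen=True)
class KineticTrajectory:
    """Deterministic trajectory of all species, with per-pool initial totals."""

    frame: pd.DataFrame  # index: time (min); columns: P, D, DP, then per-pool S/SP/SP2/cleaved
    scheme: KineticScheme

    def pool_columns(self, name: str) -> list[str]:
        return [f"S[{name}]", f"SP[{name}]", f"SP2[{name}]", f"cleaved[{name}]"]

    def protein_total(self) -> pd.Series:
        """Total protein across free, decoy-bound, site-bound and covalent states."""
        total = self.frame["P"] + self.frame["DP"]
        for pool in self.scheme.substrates:
            total = (
                total
                + self.frame[f"SP[{pool.name}]"]
                + 2 * self.frame[f"SP2[{pool.name}]"]
                + 2 * self.frame[f"cleaved[{pool.name}]"]
            )
        return total

    def dna_total(self, name: str) -> pd.Series:
        cols = self.pool_columns(name)
        return self.frame[cols].sum(axis=1)


def simulate_cleavage_kinetics(
    scheme: KineticScheme,
    t_grid: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> KineticTrajectory:
    """Integrate the mass-action scheme over ``t_grid`` (must start at >= 0).

    Pools with negative ``add_time`` are pre-equilibrated (k_cut forced to 0
    before t = 0); staged additions at positive times inject fresh substrate
    mid-course. Protein and per-pool DNA totals are conserved by
    construction and integrated tightly enough to hold to ~1e-8 relative.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise DataError("t_grid must be an increasing 1-D array")
    if t_grid[0] < 0:
        raise DataError("t_grid must start at time >= 0 (negative times are add_times)")

    pools = scheme.substrates
    n_pools = len(pools)
    # state: [P, D, DP, (S, SP, SP2, C) per pool]
    def rhs(t, y, cutting):
        P, D, DP = y[0], y[1], y[2]
        dP = -scheme.k_on * D * P + scheme.k_off * DP
        dD = -scheme.k_on * D * P + scheme.k_off * DP
        dDP = scheme.k_on * D * P - scheme.k_off * DP
        out = np.empty_like(y)
        for i in range(n_pools):
            S, SP, SP2, C = y[3 + 4 * i : 7 + 4 * i]
            bind1 = 2.0 * scheme.k_on * S * P
            unbind1 = scheme.k_off * SP
            bind2 = scheme.dimer_boost * scheme.k_on * SP * P
            unbind2 = 2.0 * scheme.k_off * SP2
            cut = scheme.k_cut * SP2 if cutting else 0.0
            out[3 + 4 * i] = -bind1 + unbind1
            out[4 + 4 * i] = bind1 - unbind1 - bind2 + unbind2
            out[5 + 4 * i] = bind2 - unbind2 - cut
            out[6 + 4 * i] = cut
            dP += -bind1 + unbind1 - bind2 + unbind2
        out[0], out[1], out[2] = dP, dD, dDP
        return out

    add_times = sorted({p.add_time for p in pools})
    t_start = min(add_times[0], 0.0)
    y = np.zeros(3 + 4 * n_pools)
    y[0], y[1] = scheme.p0, scheme.d0

    # breakpoints: every addition time, t=0 (cutting switches on), grid end
    breakpoints = sorted(
        b for b in set(add_times) | {0.0, float(t_grid[-1])} if t_start < b <= float(t_grid[-1])
    )

    applied = [False] * n_pools

    def apply_additions(t: float) -> None:
        for i, pool in enumerate(pools):
            if not applied[i] and pool.add_time <= t:
                y[3 + 4 * i] += pool.s0
                applied[i] = True

    rec_times: list[float] = []
    rec_states: list[np.ndarray] = []
    t_cur = t_start
    apply_additions(t_cur)
    if t_grid[0] == t_cur:
        rec_times.append(t_cur)
        rec_states.append(y.copy())

    for b in breakpoints:
        cutting = t_cur >= 0.0
        inner = t_grid[(t_grid > t_cur) & (t_grid < b)]
        t_eval = np.append(inner, b)
        sol = solve_ivp(
            rhs, (t_cur, b), y, method="LSODA", t_eval=t_eval,
            rtol=rtol, atol=atol, args=(cutting,),
        )
        if not sol.success:
            raise CleavemapError(f"integration failed: {sol.message}")
        for tt, yy in zip(sol.t[:-1], sol.y.T[:-1]):
            rec_times.append(float(tt))
            rec_states.append(yy.copy())
        y = sol.y[:, -1].copy()
        t_cur = b
        apply_additions(t_cur)
        if b in t_grid:  # record the post-addition state at grid breakpoints
            rec_times.append(float(b))
            rec_states.append(y.copy())
    if np.any(y < -1e-6):
        raise CleavemapError("integration produced negative concentrations")

    times = np.asarray(rec_times)
    states = np.vstack(rec_states) if rec_states else np.empty((0, y.size))
    columns = ["P", "D", "DP"]
    for pool in pools:
        columns += [f"S[{pool.name}]", f"SP[{pool.name}]", f"SP2[{pool.name}]", f"cleaved[{pool.name}]"]
    frame = pd.DataFrame(states, index=pd.Index(times, name="time_min"), columns=columns)
    return KineticTrajectory(frame=frame, scheme=scheme)


def substrate_utilization(traj: KineticTrajectory, pool_name: str | None = None) -> pd.Series:
    """Percent of a substrate pool cleaved over time (monotone non-decreasing)."""
    pools = traj.scheme.substrates
    if pool_name is None:
        if len(pools) != 1:
            raise DataError("pool_name required when the scheme has several pools")
        pool = pools[0]
    else:
        match = [p for p in pools if p.name == pool_name]
        if not match:
            raise DataError(f"no substrate pool named {pool_name!r}")
        pool = match[0]
    if pool.s0 <= 0:
        raise DataError(f"pool {pool.name!r} has zero substrate")
    cleaved = traj.frame[f"cleaved[{pool.name}]"]
    out = 100.0 * cleaved / pool.s0
    return out.rename(f"utilization[{pool.name}]")
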