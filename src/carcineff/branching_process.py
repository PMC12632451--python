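"""Birth-death branching process of somatic evolution with carcinogenesis.

A normal tissue holds a constant pool of N0 wild-type cells.  Cells acquire
a focal mutation z at per-cell rate v; the mutant count N1 then follows a
linear birth-death process with division rate a1 and loss rate b1
(selective effect s = a1 - b1).  At age t, a wild-type cell initiates
cancer at baseline rate r0(t) and a mutant cell at rate r1(t) = w * r0(t),
where w is the mutation's carcinogenic effect.

Writing p_k(t, T) for the probability that no mutant-initiated cancer
occurs in (t, T) given N1(t) = k, the backward Kolmogorov equations are

    dp0/dt = -N0 v (p1 - p0)
    dp1/dt = (N0 v + a1 + b1 + r1) p1 - (N0 v + a1) p1^2/p0 - b1 p0

with p_k(T, T) = 1.  The closure p2 = p1^2/p0 follows from the branching
structure: mutant families evolve independently over a shared influx
background, so p_k = p0 (p1/p0)^k.  The system differentiated in T
(q_k = dp_k/dT) is

    dq0/dt = -N0 v (q1 - q0)
    dq1/dt = (N0 v + a1 + b1 + r1) q1
             - (N0 v + a1) (2 (p1/p0) q1 - (p1/p0)^2 q0) - b1 q0

with q0(T, T) = 0 and q1(T, T) = -r1(T).  These are solved backward in t
by the Euler method.  For cancer arising at age T, the odds it carries mutation z is
[-q0(0,T)/p0(0,T)] / [N0 r0(T)]; the odds a normal cell carries z at T
(conditional on no cancer) is [-q0(0,T)/r1(T)] / [N0 p0(0,T)]; their ratio
is exactly w.

An exact Gillespie simulator (:func:`simulate_trajectories`) serves as an
independent stochastic oracle, and a family of deterministic
sub-exponential clonal growth curves (:class:`GrowthCurveNull`) expresses
the null hypothesis of no carcinogenicity for solid-tissue-like dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BaselineHazard", "BranchingModel", "KolmogorovSolution", "GrowthCurveNull",
    "AgeProfile", "solve_backward", "cancer_mutation_odds", "normal_tissue_odds",
    "simulate_trajectories", "age_profile", "null_family_age_shift",
]


class StepSizeError(RuntimeError):
    """Euler integration left [0, 1]; retry with a smaller dt."""


@dataclass
class BaselineHazard:
    """Baseline carcinogenesis hazard r0(t) = coef * t^exponent per cell.

    ``constant`` form: r0(t) = rate (exponent 0).  ``power_law`` form:
    coef = 10^u, exponent p (default 3, a textbook age-incidence slope).
    ``power_law_mixture``: u varies between people, uniform on
    (u_lo, u_hi); the mixture is integrated deterministically by midpoint
    quadrature with ``n_nodes`` nodes.
    """

    form: str = "power_law_mixture"
    rate: float = 1e-12
    exponent: float = 3.0
    u: float = -14.5
    u_lo: float = -16.0
    u_hi: float = -13.0
    n_nodes: int = 64

    def components(self):
        """(coefs, exponent, weights) of the hazard mixture."""
        if self.form == "constant":
            return np.array([self.rate]), 0.0, np.array([1.0])
        if self.form == "power_law":
            return np.array([10.0 ** self.u]), self.exponent, np.array([1.0])
        if self.form == "power_law_mixture":
            edges = np.linspace(self.u_lo, self.u_hi, self.n_nodes + 1)
            mids = 0.5 * (edges[:-1] + edges[1:])
            wts = np.full(self.n_nodes, 1.0 / self.n_nodes)
            return 10.0 ** mids, self.exponent, wts
        raise ValueError(f"unknown hazard form: {self.form}")

    def at(self, t, coef=None):
        """Hazard value; ``coef`` picks a mixture component (default: the
        single component of constant / fixed power-law forms)."""
        coefs, p, _ = self.components()
        c = coefs[0] if coef is None else coef
        return c * np.asarray(t, dtype=float) ** p


@dataclass
class BranchingModel:
    """Parameters of the branching process with carcinogenesis."""

    N0: float = 1e5
    v: float = 1e-8
    a1: float = 1.0
    b1: float = 1.0
    w: float = 1.0
    hazard: BaselineHazard = field(default_factory=BaselineHazard)
    lifespan: float = 80.0

    def __post_init__(self):
        if min(self.N0, self.v, self.a1, self.b1) < 0:
            raise ValueError("rates must be non-negative")
        if self.w <= 0:
            raise ValueError("carcinogenic effect w must be positive")

    @property
    def s(self) -> float:
        """Selective effect in normal tissue, a1 - b1 (per year)."""
        return self.a1 - self.b1

    def neutral_reference(self) -> "BranchingModel":
        """Same acquisition rate, no selection (s=0), no causation (w=1)."""
        return replace(self, a1=self.b1, w=1.0)


@dataclass
class KolmogorovSolution:
    """Backward solution on the age grid t in [0, T] (descending from T)."""

    t: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    dp0: np.ndarray
    dp1: np.ndarray
    T: float
    dt: float
    hazard_coef: float
    hazard_exponent: float


def _euler_backward(T, coef, N0, v, a1, b1, w, p_exp, dt, record=False):
    """Vectorised backward Euler integration of (p0, p1, q0, q1).

    ``T`` and ``coef`` are broadcast arrays of horizons and hazard
    coefficients (one column per (T, component) pair).  Returns values at
    t = 0; with ``record`` (scalar input only) also the full trajectory.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    coef = np.broadcast_to(np.asarray(coef, dtype=float), T.shape).copy()
    t = T.copy()
    p0 = np.ones_like(T)
    p1 = np.ones_like(T)
    q0 = np.zeros_like(T)
    q1 = -w * coef * T ** p_exp
    influx = N0 * v
    rate_sum = influx + a1 + b1
    gain = influx + a1
    traj = [] if record else None
    active = t > 0
    while active.any():
        h = np.where(active, np.minimum(dt, t), 0.0)
        r1 = w * coef * t ** p_exp
        # two-mutant closure: p2 = p1^2 / p0 (independent mutant families
        # over a shared influx background), so the quadratic term is
        # p1^2/p0 and its T-derivative brings in q0 with an O(1) weight
        phi = p1 / p0
        dp0 = -influx * (p1 - p0)
        dp1 = (rate_sum + r1) * p1 - gain * phi * p1 - b1 * p0
        dq0 = -influx * (q1 - q0)
        dq1 = (rate_sum + r1) * q1 - gain * (2.0 * phi * q1 - phi * phi * q0) \
            - b1 * q0
        p0 = p0 - h * dp0
        p1 = p1 - h * dp1
        q0 = q0 - h * dq0
        q1 = q1 - h * dq1
        t = t - h
        if record:
            traj.append((t[0], p0[0], p1[0], q0[0], q1[0]))
        active = t > 0
        if (p0 < -1e-9).any() or (p0 > 1 + 1e-9).any() \
                or (p1 < -1e-9).any() or (p1 > 1 + 1e-9).any():
            raise StepSizeError(
                "survival probability left [0, 1]; decrease dt "
                f"(dt={dt}) or the hazard scale"
            )
    return p0, p1, q0, q1, traj


def solve_backward(
    model: BranchingModel, T: float, dt: float = 1e-3, hazard_coef: float | None = None
) -> KolmogorovSolution:
    """Solve the backward Kolmogorov system from age T down to 0.

    ``hazard_coef`` selects a single hazard-mixture component; by default
    the first (only) component of the model's hazard is used.  A Richardson
    self-check is available by re-solving with dt/2.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    coefs, p_exp, _ = model.hazard.components()
    c = coefs[0] if hazard_coef is None else hazard_coef
    p0, p1, q0, q1, traj = _euler_backward(
        np.array([T]), np.array([c]), model.N0, model.v, model.a1, model.b1,
        model.w, p_exp, dt, record=True,
    )
    rows = np.array(traj) if traj else np.empty((0, 5))
    t_grid = np.concatenate([[T], rows[:, 0]]) if len(rows) else np.array([T])
    return KolmogorovSolution(
        t=t_grid,
        p0=np.concatenate([[1.0], rows[:, 1]]) if len(rows) else np.array([1.0]),
        p1=np.concatenate([[1.0], rows[:, 2]]) if len(rows) else np.array([1.0]),
        dp0=np.concatenate([[0.0], rows[:, 3]]) if len(rows) else np.array([0.0]),
        dp1=np.concatenate(
            [[-model.w * c * T ** p_exp], rows[:, 4]]
        ) if len(rows) else np.array([-model.w * c * T ** p_exp]),
        T=float(T), dt=dt, hazard_coef=float(c), hazard_exponent=p_exp,
    )


def _final(sol: KolmogorovSolution):
    return sol.p0[-1], sol.dp0[-1]


def cancer_mutation_odds(sol: KolmogorovSolution, model: BranchingModel, T: float):
    """Odds that a cancer arising at age T carries mutation z."""
    p0, q0 = _final(sol)
    if p0 <= 1e-300:
        raise FloatingPointError("p0 underflow: hazard too large for this model")
    r0_T = sol.hazard_coef * T ** sol.hazard_exponent
    if r0_T == 0.0:
        raise ZeroDivisionError("baseline hazard is zero at T")
    return float((-q0 / p0) / (model.N0 * r0_T))


def normal_tissue_odds(sol: KolmogorovSolution, model: BranchingModel, T: float):
    """Odds that a normal-tissue cell at age T carries mutation z,
    conditional on no cancer by T."""
    p0, q0 = _final(sol)
    if p0 <= 1e-300:
        raise FloatingPointError("p0 underflow: hazard too large for this model")
    r1_T = model.w * sol.hazard_coef * T ** sol.hazard_exponent
    if r1_T == 0.0:
        raise ZeroDivisionError("mutant hazard is zero at T")
    return float((-q0 / r1_T) / (model.N0 * p0))


def odds_profile(model: BranchingModel, T_grid, dt: float = 1e-3,
                 hazard_coef: float | None = None) -> "pd.DataFrame":
    """Cancer and normal odds over a grid of ages in one vectorised solve.

    Uses a single hazard component (default: the first); returns a
    DataFrame with columns T, normal_odds, cancer_odds (NaN at T = 0).
    """
    import pandas as pd

    T_grid = np.asarray(T_grid, dtype=float)
    coefs, p_exp, _ = model.hazard.components()
    c = float(coefs[0] if hazard_coef is None else hazard_coef)
    p0, _, q0, _, _ = _euler_backward(
        T_grid, np.full_like(T_grid, c), model.N0, model.v, model.a1,
        model.b1, model.w, p_exp, dt,
    )
    r0_T = c * T_grid ** p_exp
    r1_T = model.w * r0_T
    with np.errstate(invalid="ignore", divide="ignore"):
        cancer = (-q0 / p0) / (model.N0 * r0_T)
        normal = (-q0 / r1_T) / (model.N0 * p0)
    return pd.DataFrame({"T": T_grid, "normal_odds": normal, "cancer_odds": cancer})


# ---------------------------------------------------------------------------
# exact stochastic oracle


@dataclass
class TrajectorySample:
    """Monte-Carlo sample of the branching process with carcinogenesis."""

    t_cancer: np.ndarray        # NaN where no cancer by the horizon
    founder_is_mutant: np.ndarray
    n1_grid: np.ndarray | None  # (n, len(grid)) mutant counts, or None
    grid: np.ndarray | None
    horizon: float

    @property
    def got_cancer(self) -> np.ndarray:
        return ~np.isnan(self.t_cancer)


def simulate_trajectories(
    model: BranchingModel,
    n: int,
    seed: int | None = None,
    horizon: float | None = None,
    grid=None,
    hazard_coef: float | None = None,
) -> TrajectorySample:
    """Exact Gillespie simulation of the mutant-count process with cancer.

    Demographic events (mutation influx, mutant division/loss) are drawn
    from their exponential clocks; between events the cancer intensity
    (N0 + w N1) r0(t) has a closed-form time integral (r0 is a power law
    or constant), so cancer times are drawn exactly by inversion of the
    cumulative hazard — no time discretisation anywhere.

    Intended for reduced-scale parameters (small N0, inflated v); records
    mutant counts on ``grid`` if given and attributes the first cancer to
    a mutant or wild-type founder.
    """
    rng = np.random.default_rng(seed)
    horizon = model.lifespan if horizon is None else float(horizon)
    coefs, p_exp, _ = model.hazard.components()
    c = float(coefs[0] if hazard_coef is None else hazard_coef)
    pp = p_exp + 1.0
    N0, v, a1, b1, w = model.N0, model.v, model.a1, model.b1, model.w
    influx = N0 * v
    grid = None if grid is None else np.asarray(grid, dtype=float)
    n1_grid = None if grid is None else np.zeros((n, len(grid)))
    t_cancer = np.full(n, np.nan)
    founder = np.zeros(n, dtype=bool)

    for i in range(n):
        t, N1, acc = 0.0, 0, 0.0
        threshold = rng.exponential()
        times, counts = [0.0], [0]
        while t < horizon:
            rate = influx + N1 * (a1 + b1)
            tau = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            t_next = min(t + tau, horizon)
            intensity = (N0 + w * N1) * c
            seg = intensity * (t_next ** pp - t ** pp) / pp
            if acc + seg >= threshold and intensity > 0:
                need = threshold - acc
                t_star = (t ** pp + need * pp / intensity) ** (1.0 / pp)
                t_cancer[i] = t_star
                founder[i] = rng.random() < (w * N1) / (N0 + w * N1)
                break
            acc += seg
            if t + tau >= horizon:
                break
            t = t + tau
            if rng.random() < (influx + N1 * a1) / rate:
                N1 += 1
            else:
                N1 -= 1
            times.append(t)
            counts.append(N1)
        if grid is not None:
            idx = np.searchsorted(times, grid, side="right") - 1
            stop = t_cancer[i] if not np.isnan(t_cancer[i]) else horizon
            vals = np.array(counts, dtype=float)[idx]
            vals[grid > stop] = np.nan
            n1_grid[i] = vals
    return TrajectorySample(t_cancer, founder, n1_grid, grid, horizon)


def expected_mutant_count(model: BranchingModel, T: float) -> float:
    """Closed-form E N1(T) of the linear birth-death process with influx:
    N0 v T for s = 0 and N0 v (e^{sT} - 1)/s otherwise."""
    s = model.s
    if s == 0.0:
        return model.N0 * model.v * T
    return model.N0 * model.v * (np.exp(s * T) - 1.0) / s


# ---------------------------------------------------------------------------
# age profiles


@dataclass
class AgeProfile:
    """Age densities of mutation-z and neutral-mutation cancers."""

    T: np.ndarray
    density_z: np.ndarray
    density_neutral: np.ndarray
    mean_age_z: float
    mean_age_neutral: float
    odds_vs_neutral: float

    @property
    def age_shift(self) -> float:
        return self.mean_age_z - self.mean_age_neutral

    def cdfs(self):
        cz = np.cumsum(self.density_z)
        cn = np.cumsum(self.density_neutral)
        return cz / cz[-1], cn / cn[-1]


def _density_columns(model, T_grid, dt):
    """Mixture-integrated age density of mutation-z cancers on T_grid."""
    coefs, p_exp, wts = model.hazard.components()
    nT, nc = len(T_grid), len(coefs)
    Tcol = np.repeat(T_grid, nc)
    ccol = np.tile(coefs, nT)
    p0, _, q0, _, _ = _euler_backward(
        Tcol, ccol, model.N0, model.v, model.a1, model.b1, model.w, p_exp, dt
    )
    # wild-type survival: exp(-N0 * integral of r0) with closed-form integral
    cum_r0 = ccol * Tcol ** (p_exp + 1.0) / (p_exp + 1.0)
    dens = (-q0) * np.exp(-model.N0 * cum_r0)
    return (dens.reshape(nT, nc) * wts).sum(axis=1)


def _mean_age(T, density):
    num = np.trapezoid(T * density, T)
    den = np.trapezoid(density, T)
    return float(num / den) if den > 0 else np.nan


def age_profile(
    model: BranchingModel, T_grid=None, dt: float = 2e-3
) -> AgeProfile:
    """Age distributions of cancers carrying mutation z vs. a neutral
    mutation with the same acquisition rate (s=0, w=1), and their overall
    frequency ratio.

    The per-person hazard mixture is integrated by midpoint quadrature;
    the density weights each age by survival to that age (hazard times
    survival), which is numerically inert at realistic hazard scales but
    principled.
    """
    if T_grid is None:
        T_grid = np.linspace(0.0, model.lifespan, 81)
    T_grid = np.asarray(T_grid, dtype=float)
    dens_z = _density_columns(model, T_grid, dt)
    dens_n = _density_columns(model.neutral_reference(), T_grid, dt)
    ratio_num = np.trapezoid(dens_z, T_grid)
    ratio_den = np.trapezoid(dens_n, T_grid)
    return AgeProfile(
        T=T_grid,
        density_z=dens_z,
        density_neutral=dens_n,
        mean_age_z=_mean_age(T_grid, dens_z),
        mean_age_neutral=_mean_age(T_grid, dens_n),
        odds_vs_neutral=float(ratio_num / ratio_den) if ratio_den > 0 else np.nan,
    )


# ---------------------------------------------------------------------------
# growth-curve null family


@dataclass
class GrowthCurveNull:
    """Deterministic expected-clone-size curves for the null hypothesis of
    no carcinogenicity (w = 1) with sub-exponential clonal growth.

    ``selection`` is the initial per-year growth rate of a clone;
    ``carrying_capacity`` bounds the Gompertz and logistic curves and
    ``poly_exponent`` sets the polynomial curve's degree.  At zero
    selection every curve is the neutral constant 1.
    """

    curve: str = "exponential"
    selection: float = 0.0
    carrying_capacity: float = 1e4
    poly_exponent: float = 2.0

    def clone_size(self, age):
        """Expected size of a clone of the given age (founder size 1)."""
        a = np.asarray(age, dtype=float)
        s = self.selection
        if s == 0.0:
            return np.ones_like(a)
        if self.curve == "exponential":
            return np.exp(s * a)
        if self.curve == "gompertz":
            lk = np.log(self.carrying_capacity)
            return np.exp(lk * (1.0 - np.exp(-s * a / lk)))
        if self.curve == "logistic":
            K = self.carrying_capacity
            return K / (1.0 + (K - 1.0) * np.exp(-s * a))
        if self.curve == "polynomial":
            return (1.0 + s * a / self.poly_exponent) ** self.poly_exponent
        raise ValueError(f"unknown growth curve: {self.curve}")


@dataclass
class NullAgeShift:
    T: np.ndarray
    density_z: np.ndarray
    density_neutral: np.ndarray
    mean_age_z: float
    mean_age_neutral: float
    frequency_ratio: float

    @property
    def age_shift(self) -> float:
        return self.mean_age_z - self.mean_age_neutral

    def cdfs(self):
        cz = np.cumsum(self.density_z)
        cn = np.cumsum(self.density_neutral)
        return cz / cz[-1], cn / cn[-1]


def null_family_age_shift(
    null: GrowthCurveNull,
    v: float = 1e-8,
    T_grid=None,
    hazard_exponent: float = 3.0,
    lifespan: float = 80.0,
) -> NullAgeShift:
    """Mean-age shift and frequency ratio vs. neutral for a non-carcinogenic
    (w = 1) mutation whose clones follow a deterministic growth curve.

    Clones initiate as a Poisson process in time; the expected mutant cell
    fraction at age t is proportional to the integral of the clone-size
    curve.  Because w = 1, a cancer founder is drawn proportionally to cell
    fractions, so the age density of z-cancers is the cancer incidence
    (a t^p age weighting) times the expected fraction.  The neutral
    reference has constant clone size 1 (fraction proportional to v t).
    """
    if T_grid is None:
        T_grid = np.linspace(0.0, lifespan, 801)
    T = np.asarray(T_grid, dtype=float)
    sizes = null.clone_size(T)
    # expected mutant fraction, up to the common factor (clone initiation
    # rate / N0): cumulative integral of the clone-size curve
    frac_z = v * _cumtrapz(sizes, T)
    frac_neutral = v * T
    incidence = T ** hazard_exponent
    dens_z = incidence * frac_z
    dens_n = incidence * frac_neutral
    num = np.trapezoid(dens_z, T)
    den = np.trapezoid(dens_n, T)
    return NullAgeShift(
        T=T, density_z=dens_z, density_neutral=dens_n,
        mean_age_z=_mean_age(T, dens_z),
        mean_age_neutral=_mean_age(T, dens_n),
        frequency_ratio=float(num / den) if den > 0 else np.nan,
    )


def _cumtrapz(y, x):
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out
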