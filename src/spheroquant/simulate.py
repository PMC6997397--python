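"""Compartmental spheroid growth/death simulator.

A deliberately minimal compartment model of a treated spheroid, built to
produce controllable ground truth with the qualitative dynamics observed in
spheroid assays of radiation (RT) and hyperthermia (HT):

* layered structure — proliferating rim ``P``, quiescent interior ``Q``,
  necrotic core ``C`` — with geometric depth thresholds instead of an
  explicit oxygen field;
* HT kills cells irrespective of position (P, Q and C alike), transiently
  loosens cell packing, and the dead cells are shed quickly, forming a
  corona;
* RT kills proliferating cells only, with a mitosis-linked exponential
  death lag, and the dead cells are shed slowly from the surface
  (outside-in shrinkage);
* regrowing spheroids that cleared their necrotic core may proliferate
  faster than untreated controls of the same size (reoxygenation boost).

Counts are continuous (expected-value dynamics); the trajectory is
deterministic given the configuration, and stochasticity lives in the
frame renderer and in the assay generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose import SurvivalParams, TreatmentSpec, CELL_LINE_PRESETS

__all__ = [
    "PopulationState",
    "SimConfig",
    "simulate",
    "trajectory_table",
    "generate_clonogenic_dataset",
    "generate_viability_dataset",
    "CANONICAL_SCENARIOS",
]

HOURS_PER_STEP = 4.0
DAYS_TOTAL = 21.0
STEPS = int(DAYS_TOTAL * 24 / HOURS_PER_STEP)  # 126 steps -> 127 states


@dataclass
class PopulationState:
    """Cell-count bookkeeping of one time point.

    ``P`` includes radiation-doomed cells that have not yet died
    (``p_doomed``); ``A`` is split internally by death origin because HT-
    and RT-killed cells shed at different rates and stain in different
    spatial patterns.  ``rho`` is the current packing density, so the
    spheroid radius follows from (4/3)·π·r³·rho = P+Q+C+A.
    """

    t: float  # hours post-treatment
    P: float  # proliferating live cells (incl. doomed, see p_doomed)
    Q: float  # quiescent live cells
    C: float  # necrotic-core cells
    A: float  # dead but still attached
    Shed: float  # cumulative shed cells (corona pool)
    rho: float  # packing density, cells/µm³
    p_doomed: float = 0.0
    a_ht: float = 0.0
    a_rt: float = 0.0
    cum_births: float = 0.0

    def __post_init__(self):
        for name in ("P", "Q", "C", "A", "Shed", "rho"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_attached(self) -> float:
        return self.P + self.Q + self.C + self.A

    @property
    def live(self) -> float:
        """Live cells (doomed cells are metabolically alive until death)."""
        return self.P + self.Q

    @property
    def radius_um(self) -> float:
        n = max(self.total_attached, 0.0)
        if n == 0 or self.rho <= 0:
            return 0.0
        return (3.0 * n / (4.0 * math.pi * self.rho)) ** (1.0 / 3.0)

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um

    @property
    def dead_attached_fraction(self) -> float:
        tot = self.total_attached
        return self.A / tot if tot > 0 else 0.0


@dataclass
class SimConfig:
    """Simulator parameters (rates per day, lengths in µm).

    Defaults emulate an HCT116-like spheroid of ~300 µm initial diameter:
    proliferation confined to a ~75 µm rim, necrosis beyond ~220 µm depth
    developing at a finite rate, fast shedding plus transient structural
    loosening after heat, and slow surface shedding with a ~3-day
    mitosis-linked death lag after irradiation.
    """

    initial_diameter: float = 300.0  # µm (~300 small, ~550 large spheroids)
    growth_rate: float = 0.18  # per day, proliferating-rim cells
    rim_depth: float = 75.0  # µm, proliferating rim thickness
    core_onset_depth: float = 220.0  # µm depth beyond which cells necrose
    necrosis_rate: float = 1.0  # per day, relaxation of Q->C to target
    shed_rate_ht: float = 0.35  # per day, heat-killed attached cells
    shed_rate_rt: float = 0.15  # per day, radiation-killed attached cells
    loosening_factor: float = 0.4  # max fractional rho drop after HT
    loosening_onset_days: float = 1.0  # linear ramp-up of loosening
    loosening_recovery_days: float = 4.0  # linear recovery back to baseline
    mitotic_death_lag: float = 3.0  # days, mean doomed-cell survival
    reoxygenation_boost: float = 0.3  # fractional growth_rate increase
    reoxygenation_enabled: bool = True
    packing_density: float = 3.4e-4  # cells/µm³ (~4800 cells per 300 µm)
    survival_params: SurvivalParams = field(
        default_factory=lambda: CELL_LINE_PRESETS["HCT116"]
    )
    seed: int = 0

    def __post_init__(self):
        rates = (
            "growth_rate", "necrosis_rate", "shed_rate_ht", "shed_rate_rt",
            "mitotic_death_lag", "reoxygenation_boost", "rim_depth",
            "core_onset_depth", "packing_density", "initial_diameter",
        )
        for name in rates:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.loosening_factor < 1):
            raise ValueError("loosening_factor must lie in [0, 1)")
        if self.initial_diameter <= 0 or self.packing_density <= 0:
            raise ValueError("initial_diameter and packing_density must be > 0")


def _rim_fraction(r: float, rim_depth: float) -> float:
    """Volume fraction of a sphere within ``rim_depth`` of its surface."""
    if r <= 0:
        return 1.0
    inner = max(r - rim_depth, 0.0)
    return 1.0 - (inner / r) ** 3


def _core_fraction(r: float, core_depth: float) -> float:
    """Volume fraction deeper than ``core_depth`` from the surface."""
    if r <= 0:
        return 0.0
    core = max(r - core_depth, 0.0)
    return (core / r) ** 3


def _loosening_level(t_days: float, cfg: SimConfig) -> float:
    """Unit-height loosening profile: linear onset, then linear recovery."""
    on, rec = cfg.loosening_onset_days, cfg.loosening_recovery_days
    if t_days <= 0:
        return 0.0
    if t_days < on:
        return t_days / on
    if rec <= 0:
        return 0.0
    return max(0.0, 1.0 - (t_days - on) / rec)


def _thermal_survival(h: float, p: SurvivalParams) -> float:
    return math.exp(-(p.a_thermal * h + p.b_thermal * h * h))


def _radiation_survival(d: float, h: float, p: SurvivalParams) -> float:
    return math.exp(-(p.alpha0 * (1.0 + p.c_sens * h) * d + p.beta * d * d))


def _initial_state(cfg: SimConfig) -> PopulationState:
    r = cfg.initial_diameter / 2.0
    n0 = cfg.packing_density * (4.0 / 3.0) * math.pi * r**3
    f_rim = _rim_fraction(r, cfg.rim_depth)
    f_core = _core_fraction(r, cfg.core_onset_depth)
    c = n0 * f_core
    p = n0 * f_rim
    q = max(n0 - p - c, 0.0)
    return PopulationState(
        t=0.0, P=p, Q=q, C=c, A=0.0, Shed=0.0, rho=cfg.packing_density,
    )


def _apply_treatment(
    state: PopulationState, cfg: SimConfig, treatment: TreatmentSpec
) -> tuple[PopulationState, float]:
    """Instantaneous treatment effects at t = 0.

    HT moves the killed fraction of P, Q and C alike into the attached-dead
    pool; RT marks the killed fraction of P as doomed.  Returns the state
    and the effective loosening amplitude (scaled by the heat-killed
    fraction so that a biologically null heat dose leaves the trajectory
    identical to control).
    """
    pars = cfg.survival_params
    h = treatment.thermal.cem43
    d = treatment.radiation_gy
    s_ht = _thermal_survival(h, pars)
    s_rt = _radiation_survival(d, h, pars)

    kill_ht = 1.0 - s_ht
    a_ht = (state.P + state.Q + state.C) * kill_ht
    p = state.P * s_ht
    q = state.Q * s_ht
    c = state.C * s_ht

    doomed = p * (1.0 - s_rt)
    p_live = p - doomed

    loosening = cfg.loosening_factor * kill_ht
    new = replace(
        state,
        P=p_live + doomed, Q=q, C=c, A=a_ht,
        p_doomed=doomed, a_ht=a_ht, a_rt=0.0,
    )
    return new, loosening


def simulate(
    cfg: SimConfig, treatment: TreatmentSpec | None = None
) -> list[PopulationState]:
    """Run the compartment model at 4-hour steps over 21 days.

    Returns the list of states at t = 0, 4, 8, … 504 h.  The state at t = 0
    already reflects the instantaneous treatment kill (which reclassifies
    but does not detach cells, so the day-0 diameter is unchanged);
    structural loosening develops over ``loosening_onset_days`` and then
    recovers linearly, so the diameter transient peaks after day 0.
    """
    treatment = treatment or TreatmentSpec()
    state0 = _initial_state(cfg)
    state, loosening = _apply_treatment(state0, cfg, treatment)

    dt = HOURS_PER_STEP / 24.0  # days
    decay_shed_ht = 1.0 - math.exp(-cfg.shed_rate_ht * dt)
    decay_shed_rt = 1.0 - math.exp(-cfg.shed_rate_rt * dt)
    decay_doom = (
        1.0 - math.exp(-dt / cfg.mitotic_death_lag)
        if cfg.mitotic_death_lag > 0
        else 1.0
    )
    decay_nec = 1.0 - math.exp(-cfg.necrosis_rate * dt)

    p = state.P - state.p_doomed
    pd_ = state.p_doomed
    q, c = state.Q, state.C
    a_ht, a_rt = state.a_ht, state.a_rt
    shed, births = 0.0, 0.0

    def snapshot(t_hours: float) -> PopulationState:
        t_days = t_hours / 24.0
        rho = cfg.packing_density * (1.0 - loosening * _loosening_level(t_days, cfg))
        return PopulationState(
            t=t_hours, P=p + pd_, Q=q, C=c, A=a_ht + a_rt, Shed=shed,
            rho=rho, p_doomed=pd_, a_ht=a_ht, a_rt=a_rt, cum_births=births,
        )

    out = [snapshot(0.0)]
    for step in range(1, STEPS + 1):
        total = p + pd_ + q + c + a_ht + a_rt
        t_days = (step - 1) * dt
        rho = cfg.packing_density * (1.0 - loosening * _loosening_level(t_days, cfg))
        r = (
            (3.0 * total / (4.0 * math.pi * rho)) ** (1.0 / 3.0)
            if total > 0
            else 0.0
        )

        # (1) proliferation, boosted when the necrotic core is depleted
        # relative to an untreated spheroid of the same size
        c_target = _core_fraction(r, cfg.core_onset_depth) * total
        lam = cfg.growth_rate
        if (
            cfg.reoxygenation_enabled
            and c_target > 0
            and c < 0.5 * c_target
        ):
            lam *= 1.0 + cfg.reoxygenation_boost
        born = p * (math.exp(lam * dt) - 1.0)
        p += born
        births += born

        # (2) geometric reclassification: excess P beyond the rim -> Q,
        # Q relaxes toward the necrotic target
        total = p + pd_ + q + c + a_ht + a_rt
        p_target = _rim_fraction(r, cfg.rim_depth) * total
        excess = max((p + pd_) - p_target, 0.0)
        move_pq = min(p, excess)
        p -= move_pq
        q += move_pq
        deficit = max(c_target - c, 0.0)
        move_qc = min(q, deficit * decay_nec)
        q -= move_qc
        c += move_qc

        # (4) mitosis-linked death of doomed cells
        dies = pd_ * decay_doom
        pd_ -= dies
        a_rt += dies

        # (5) shedding into the corona pool
        shed_ht = a_ht * decay_shed_ht
        shed_rt = a_rt * decay_shed_rt
        a_ht -= shed_ht
        a_rt -= shed_rt
        shed += shed_ht + shed_rt

        out.append(snapshot(step * HOURS_PER_STEP))
    return out


def trajectory_table(states: list[PopulationState]) -> pd.DataFrame:
    """Ground-truth table of a simulated trajectory."""
    return pd.DataFrame(
        {
            "time_h": [s.t for s in states],
            "day": [s.t / 24.0 for s in states],
            "diameter_um": [s.diameter_um for s in states],
            "P": [s.P for s in states],
            "Q": [s.Q for s in states],
            "C": [s.C for s in states],
            "A": [s.A for s in states],
            "Shed": [s.Shed for s in states],
            "rho": [s.rho for s in states],
            "dead_attached_fraction": [s.dead_attached_fraction for s in states],
        }
    )


#: The four canonical treatment scenarios used throughout testing: an
#: untreated control, a high thermal dose (isoeffective with 10 Gy for the
#: HCT116 parameter preset), a high radiation dose, and an intermediate
#: radiation dose from which spheroids regrow.
CANONICAL_SCENARIOS: dict[str, TreatmentSpec] = {
    "control": TreatmentSpec(),
    "high_ht": TreatmentSpec.heat(240.0),
    "high_rt": TreatmentSpec.radiation(10.0),
    "intermediate_rt": TreatmentSpec.radiation(5.0),
}

#: Regime label expected for each canonical scenario.
CANONICAL_REGIMES: dict[str, str] = {
    "control": "control-like growth",
    "high_ht": "transient-swelling-then-shrinkage",
    "high_rt": "monotone-shrinkage",
    "intermediate_rt": "shrinkage-then-regrowth",
}


# ---------------------------------------------------------------------------
# assay generators


def generate_clonogenic_dataset(
    params: SurvivalParams,
    treatments: list[TreatmentSpec],
    n_plated: int = 100_000,
    plating_efficiency: float = 0.8,
    n_reps: int = 3,
    seed: int = 0,
):
    """Noisy colony counts from the survival model.

    Each replicate draws n_colonies ~ Binomial(n_plated, PE · S(treatment)):
    every plated cell independently forms a colony with the model's
    survival probability, so the count never exceeds n_plated, its mean is
    n_plated · PE · S, and in the sparse regime of a real assay the counting
    noise is indistinguishable from Poisson.  Deterministic per seed.
    """
    from .dose import ClonogenicRecord, survival as _survival

    if n_plated <= 0:
        raise ValueError("n_plated must be > 0")
    if not (0 < plating_efficiency <= 1):
        raise ValueError("plating_efficiency must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for t in treatments:
        p_col = plating_efficiency * _survival(t, params)
        for _ in range(n_reps):
            n_col = int(rng.binomial(n_plated, min(p_col, 1.0)))
            records.append(
                ClonogenicRecord(
                    treatment=t,
                    n_plated=n_plated,
                    n_colonies=n_col,
                    plating_efficiency=plating_efficiency,
                )
            )
    return records


def generate_viability_dataset(
    treated: dict[str, PopulationState],
    control: PopulationState,
    noise_cv: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative-viability table: live cells of each treated state over the
    control's, with multiplicative lognormal noise of the given CV."""
    if control.live <= 0:
        raise ValueError("control state has no live cells")
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean lognormal
    rows = []
    for label, state in treated.items():
        ratio = state.live / control.live
        for rep in range(n_reps):
            noise = rng.lognormal(mu, sigma) if noise_cv > 0 else 1.0
            rows.append(
                {"treatment": label, "repeat": rep,
                 "relative_viability": ratio * noise}
            )
    return pd.DataFrame(rows)
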