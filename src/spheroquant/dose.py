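"""Thermal dose (CEM43), combined clonogenic survival and isoeffect solving.

Treatments are described by a radiation dose ``D`` (Gy) and a thermal dose
``H`` (CEM43 — cumulative equivalent minutes at 43 °C).  Clonogenic survival
under the combined treatment is modelled by the parametric family

    S(D, H) = exp(-(a·H + b·H²) - (α₀·(1 + c·H)·D + β·D²))

i.e. a linear-quadratic thermal-kill term, the linear-quadratic (LQ)
radiation term, and a linear heat-sensitization of the radiation α.  The
biological effect is E = −ln S, the additive scale on which isoeffective
treatments are matched; the biologically equivalent dose (BEQD) of any
treatment is the radiation-only dose producing the same effect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ThermalExposure",
    "ThermalDose",
    "TreatmentSpec",
    "SapareroBreakpoints",
    "SurvivalParams",
    "ClonogenicRecord",
    "FitResult",
    "compute_cem43",
    "survival",
    "biological_effect",
    "fit_survival_params",
    "beqd",
    "isoeffect_combinations",
    "read_clonogenic_csv",
    "write_clonogenic_csv",
    "CELL_LINE_PRESETS",
]

#: Validity range of the CEM43 concept (°C).  The thermal-dose conversion is
#: established for mild-to-ablative hyperthermia; outside this range the
#: per-degree factor R is not considered meaningful.
TEMPERATURE_RANGE = (20.0, 50.0)

#: Reference temperature of the CEM43 scale (°C).
T_REF = 43.0


@dataclass(frozen=True)
class ThermalExposure:
    """A heating protocol: ordered (temperature °C, duration min) segments."""

    segments: tuple[tuple[float, float], ...]

    def __init__(self, segments: Iterable[Sequence[float]]):
        segs = tuple((float(t), float(d)) for t, d in segments)
        for temp, dur in segs:
            if dur <= 0:
                raise ValueError(f"segment duration must be > 0, got {dur}")
            lo, hi = TEMPERATURE_RANGE
            if not (lo <= temp <= hi):
                raise ValueError(
                    f"temperature {temp} °C outside the validity range "
                    f"[{lo}, {hi}] °C of the CEM43 thermal-dose concept"
                )
        object.__setattr__(self, "segments", segs)

    def __add__(self, other: "ThermalExposure") -> "ThermalExposure":
        return ThermalExposure(self.segments + other.segments)


@dataclass(frozen=True)
class ThermalDose:
    """Thermal dose in CEM43 (equivalent minutes at 43 °C)."""

    cem43: float = 0.0

    def __post_init__(self):
        if self.cem43 < 0:
            raise ValueError(f"cem43 must be >= 0, got {self.cem43}")


@dataclass(frozen=True)
class SapareroBreakpoints:
    """Per-degree factors R of the CEM43 conversion.

    ``r_above`` applies for segment temperatures above 43 °C, ``r_below`` at
    or below it.  Defaults are the classic convention (0.5 / 0.25); both are
    exposed so cell-line-specific conversions can be emulated.
    """

    r_above: float = 0.5
    r_below: float = 0.25

    def __post_init__(self):
        for name in ("r_above", "r_below"):
            r = getattr(self, name)
            if not (0 < r <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {r}")

    def factor(self, temperature: float) -> float:
        return self.r_above if temperature > T_REF else self.r_below


@dataclass(frozen=True)
class TreatmentSpec:
    """A single-fraction treatment: radiation dose plus thermal dose.

    The sequencing of the two modalities (gap, order) is informational
    metadata only and does not enter the survival model.
    """

    radiation_gy: float = 0.0
    thermal: ThermalDose = field(default_factory=ThermalDose)
    metadata: Mapping[str, object] | None = None

    def __post_init__(self):
        if self.radiation_gy < 0:
            raise ValueError(f"radiation_gy must be >= 0, got {self.radiation_gy}")

    @classmethod
    def radiation(cls, dose_gy: float) -> "TreatmentSpec":
        return cls(radiation_gy=dose_gy)

    @classmethod
    def heat(cls, cem43: float) -> "TreatmentSpec":
        return cls(thermal=ThermalDose(cem43))

    @classmethod
    def combined(cls, dose_gy: float, cem43: float) -> "TreatmentSpec":
        return cls(radiation_gy=dose_gy, thermal=ThermalDose(cem43))

    def label(self) -> str:
        parts = []
        if self.radiation_gy:
            parts.append(f"{self.radiation_gy:g}Gy")
        if self.thermal.cem43:
            parts.append(f"{self.thermal.cem43:g}CEM43")
        return "+".join(parts) if parts else "control"


PARAM_NAMES = ("alpha0", "beta", "a_thermal", "b_thermal", "c_sens")


@dataclass(frozen=True)
class SurvivalParams:
    """Parameters of the combined radiation + heat survival model.

    alpha0 : Gy⁻¹
        LQ linear radiation coefficient at zero thermal dose.
    beta : Gy⁻²
        LQ quadratic radiation coefficient.
    a_thermal : CEM43⁻¹
        Linear thermal-kill coefficient.
    b_thermal : CEM43⁻²
        Quadratic thermal-kill coefficient.
    c_sens : CEM43⁻¹
        Fractional increase of alpha0 per unit thermal dose
        (heat-induced radiosensitization).
    """

    alpha0: float = 0.0
    beta: float = 0.0
    a_thermal: float = 0.0
    b_thermal: float = 0.0
    c_sens: float = 0.0
    cell_line: str = ""

    def __post_init__(self):
        for name in PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}


#: Presets calibrated so that the model reproduces the experimental
#: isoeffective treatment sets of the two cell lines: for HCT116 the
#: combinations {10 Gy, 2 Gy + 120 CEM43, 5 Gy + 60 CEM43, 240 CEM43} share
#: a survival level near 1e-4, for CAL27 {10 Gy, 2 Gy + 220 CEM43,
#: 5 Gy + 110 CEM43, 350 CEM43} share a level near 6e-4.
CELL_LINE_PRESETS: dict[str, SurvivalParams] = {
    "HCT116": SurvivalParams(
        alpha0=0.55, beta=0.036, a_thermal=0.0384, b_thermal=0.0,
        c_sens=0.022, cell_line="HCT116",
    ),
    "CAL27": SurvivalParams(
        alpha0=0.43, beta=0.031, a_thermal=0.0212, b_thermal=0.0,
        c_sens=0.0093, cell_line="CAL27",
    ),
}


@dataclass(frozen=True)
class ClonogenicRecord:
    """One colony-forming-assay observation."""

    treatment: TreatmentSpec
    n_plated: int
    n_colonies: int
    plating_efficiency: float = 1.0

    def __post_init__(self):
        if self.n_plated <= 0:
            raise ValueError("n_plated must be > 0")
        if not (0 <= self.n_colonies <= self.n_plated):
            raise ValueError("n_colonies must lie in [0, n_plated]")
        if not (0 < self.plating_efficiency <= 1):
            raise ValueError("plating_efficiency must lie in (0, 1]")

    @property
    def surviving_fraction(self) -> float:
        s = self.n_colonies / (self.n_plated * self.plating_efficiency)
        return min(s, 1.0)


# ---------------------------------------------------------------------------
# thermal dose


def compute_cem43(
    exposure: ThermalExposure,
    breakpoints: SapareroBreakpoints = SapareroBreakpoints(),
) -> ThermalDose:
    """Convert a time–temperature exposure to CEM43.

    Each segment of ``duration`` minutes at temperature ``T`` contributes
    ``duration · R^(43 − T)`` equivalent minutes, with R chosen per segment
    by the breakpoint rule; the total is the sum over segments (additive
    over concatenation by construction).
    """
    if not exposure.segments:
        raise ValueError("exposure must contain at least one segment")
    total = 0.0
    for temp, dur in exposure.segments:
        total += dur * breakpoints.factor(temp) ** (T_REF - temp)
    return ThermalDose(total)


# ---------------------------------------------------------------------------
# survival model


def _effect(d: np.ndarray, h: np.ndarray, p: Sequence[float]) -> np.ndarray:
    alpha0, beta, a, b, c = p
    return a * h + b * h**2 + alpha0 * (1.0 + c * h) * d + beta * d**2


def survival(treatment: TreatmentSpec, params: SurvivalParams) -> float:
    """Surviving fraction S(D, H) under the combined model; S(0, 0) = 1."""
    d = treatment.radiation_gy
    h = treatment.thermal.cem43
    e = _effect(np.asarray(d), np.asarray(h), tuple(params.as_dict().values()))
    return float(np.exp(-e))


def biological_effect(s: float) -> float:
    """Biological effect E = −ln(S) of a surviving fraction ``s`` ∈ (0, 1]."""
    if not (0 < s <= 1):
        raise ValueError(f"surviving fraction must lie in (0, 1], got {s}")
    return -math.log(s)


def treatment_effect(treatment: TreatmentSpec, params: SurvivalParams) -> float:
    """E = −ln S(treatment) evaluated directly from the model."""
    d = treatment.radiation_gy
    h = treatment.thermal.cem43
    return float(_effect(np.asarray(d), np.asarray(h),
                         tuple(params.as_dict().values())))


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a weighted least-squares survival fit."""

    params: SurvivalParams
    rss: float
    stderr: dict[str, float]
    converged: bool
    message: str = ""
    n_records: int = 0

    def to_json(self) -> str:
        payload = {
            "params": self.params.as_dict(),
            "units": {
                "alpha0": "1/Gy", "beta": "1/Gy^2",
                "a_thermal": "1/CEM43", "b_thermal": "1/CEM43^2",
                "c_sens": "1/CEM43",
            },
            "cell_line": self.params.cell_line,
            "rss": self.rss,
            "stderr": self.stderr,
            "converged": self.converged,
            "message": self.message,
            "n_records": self.n_records,
        }
        return json.dumps(payload, indent=2)


def fit_survival_params(
    records: Sequence[ClonogenicRecord],
    fixed: Mapping[str, float] | None = None,
    cell_line: str = "",
) -> FitResult:
    """Fit the survival model to colony counts by weighted least squares.

    The fit is performed on ln S with inverse-variance weights from the
    Poisson counting statistics of the colonies, Var(ln S) ≈ 1/n_colonies.
    Zero-colony records receive a +0.5 continuity correction before the log
    transform.  Parameters named in ``fixed`` are held at the given values;
    the rest are estimated subject to non-negativity.

    Raises ``ValueError`` for a degenerate design (no dose variation).
    """
    fixed = dict(fixed or {})
    free_names = [n for n in PARAM_NAMES if n not in fixed]
    if not records:
        raise ValueError("no records to fit")

    d = np.array([r.treatment.radiation_gy for r in records])
    h = np.array([r.treatment.thermal.cem43 for r in records])
    if np.ptp(d) == 0 and np.ptp(h) == 0:
        raise ValueError("degenerate design: all records share one treatment")
    if len(records) < len(free_names):
        raise ValueError(
            f"{len(records)} records cannot constrain {len(free_names)} free parameters"
        )

    counts = np.array([r.n_colonies for r in records], dtype=float)
    expected = np.array(
        [r.n_plated * r.plating_efficiency for r in records], dtype=float
    )
    counts_corr = np.where(counts == 0, 0.5, counts)
    log_s = np.log(np.minimum(counts_corr / expected, 1.0))
    # Poisson: Var(ln S) ~ 1/n; weight residuals by sqrt(n)
    w = np.sqrt(counts_corr)

    def assemble(theta: np.ndarray) -> tuple[float, ...]:
        vals = dict(zip(free_names, theta))
        vals.update(fixed)
        return tuple(vals[n] for n in PARAM_NAMES)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return w * (log_s + _effect(d, h, assemble(theta)))

    defaults = {"alpha0": 0.3, "beta": 0.03, "a_thermal": 0.01,
                "b_thermal": 1e-5, "c_sens": 0.01}
    x0 = np.array([defaults[n] for n in free_names])
    sol = optimize.least_squares(
        residuals, x0, bounds=(0, np.inf), method="trf", xtol=1e-14,
        ftol=1e-14, gtol=1e-14,
    )

    estimates = dict(zip(PARAM_NAMES, assemble(sol.x)))
    rss = float(np.sum(sol.fun**2))
    dof = max(len(records) - len(free_names), 1)
    stderr: dict[str, float] = {}
    if free_names:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * rss / dof
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            stderr = dict(zip(free_names, se.tolist()))
        except np.linalg.LinAlgError:
            stderr = {n: float("nan") for n in free_names}

    params = SurvivalParams(cell_line=cell_line, **estimates)
    return FitResult(
        params=params,
        rss=rss,
        stderr=stderr,
        converged=bool(sol.success),
        message=str(sol.message),
        n_records=len(records),
    )


# ---------------------------------------------------------------------------
# BEQD and isoeffect


def beqd(treatment: TreatmentSpec, params: SurvivalParams) -> float:
    """Biologically equivalent radiation dose (Gy) of a treatment.

    Solves alpha0·x + beta·x² = E(treatment) on the physical branch.  A pure
    radiation treatment maps to its own dose by construction.
    """
    if params.alpha0 == 0 and params.beta == 0:
        raise ValueError("no radiation response defined (alpha0 = beta = 0)")
    e = treatment_effect(treatment, params)
    if e == 0:
        return 0.0
    if params.beta > 0:
        a, b = params.alpha0, params.beta
        return (-a + math.sqrt(a * a + 4 * b * e)) / (2 * b)
    return e / params.alpha0


def isoeffect_combinations(
    target_effect: float,
    params: SurvivalParams,
    radiation_grid: Sequence[float],
    h_max: float = 1e5,
    tol: float = 1e-9,
) -> list[tuple[float, float]]:
    """Radiation/thermal dose pairs sharing one biological effect level.

    For every grid dose D whose radiation-only effect does not exceed
    ``target_effect``, the unique thermal dose H ≥ 0 with
    −ln S(D, H) = target_effect is found by bisection on [0, h_max]
    (survival is monotone in H, so the root is unique).  Grid doses whose
    radiation-only effect already exceeds the target are omitted.
    """
    if target_effect <= 0:
        raise ValueError("target_effect must be > 0")
    pairs: list[tuple[float, float]] = []
    for d in radiation_grid:
        t0 = TreatmentSpec.radiation(d)
        e0 = treatment_effect(t0, params)
        if e0 > target_effect + tol:
            continue

        def f(hval: float, d=d) -> float:
            return treatment_effect(TreatmentSpec.combined(d, hval), params) - target_effect

        if abs(f(0.0)) <= tol:
            pairs.append((float(d), 0.0))
            continue
        if f(h_max) < 0:
            raise ValueError(
                f"target effect {target_effect} unreachable within "
                f"{h_max} CEM43 at D={d} Gy"
            )
        h = optimize.brentq(f, 0.0, h_max, xtol=1e-15, rtol=8.9e-16, maxiter=500)
        # polish until the effect residual meets the tolerance
        if abs(f(h)) > tol:
            lo, hi = max(h - 1e-6, 0.0), h + 1e-6
            while f(lo) > 0:
                lo = max(lo - 1e-3, 0.0)
            while f(hi) < 0:
                hi += 1e-3
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if f(mid) < 0:
                    lo = mid
                else:
                    hi = mid
                if abs(f(mid)) <= tol:
                    h = mid
                    break
        pairs.append((float(d), float(h)))
    return pairs


# ---------------------------------------------------------------------------
# CSV interface

_CSV_COLUMNS = ["cell_line", "dose_gy", "cem43", "n_plated", "n_colonies",
                "plating_efficiency"]


def read_clonogenic_csv(path) -> list[ClonogenicRecord]:
    """Read clonogenic records from CSV (header required, '.' decimal)."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clonogenic CSV missing columns: {sorted(missing)}")
    return [
        ClonogenicRecord(
            treatment=TreatmentSpec.combined(row.dose_gy, row.cem43),
            n_plated=int(row.n_plated),
            n_colonies=int(row.n_colonies),
            plating_efficiency=float(row.plating_efficiency),
        )
        for row in df.itertuples()
    ]


def write_clonogenic_csv(records: Sequence[ClonogenicRecord], path,
                         cell_line: str = "") -> None:
    rows = [
        {
            "cell_line": cell_line,
            "dose_gy": r.treatment.radiation_gy,
            "cem43": r.treatment.thermal.cem43,
            "n_plated": r.n_plated,
            "n_colonies": r.n_colonies,
            "plating_efficiency": r.plating_efficiency,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
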