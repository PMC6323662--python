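"""Study-design data model for ascending-dose cohorts.

A first-in-human dose-escalation trial of a long-half-life biologic is
organised as a sequence of cohorts, each with a fixed dose level, route
(subcutaneous or intravenous), active:placebo allocation, and sampling
calendar.  The default design mirrors a single-ascending-dose part
(five single-dose cohorts, 30--750 mg) followed by a multiple-ascending-dose
part (three cohorts dosed every four weeks for three doses), each enrolling
six active and two placebo subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "CohortSpec",
    "PKModelParams",
    "SubjectRecord",
    "InvalidDesignError",
    "PART_A_PK_DAYS",
    "PART_B_PK_DAYS",
    "PART_A_ADA_DAYS",
    "PART_B_ADA_DAYS",
    "default_study_design",
]

# Serum PK sampling calendars (1-based study days).  The single-dose part
# samples through Day 85; the multiple-dose part doses on Days 1/29/57 and
# samples through Day 141.
PART_A_PK_DAYS = [1, 2, 5, 8, 15, 29, 43, 57, 85]
PART_B_PK_DAYS = [1, 5, 8, 15, 29, 43, 57, 61, 71, 85, 113, 141]

# Anti-drug-antibody sampling calendars.
PART_A_ADA_DAYS = [1, 29, 57, 85]
PART_B_ADA_DAYS = [1, 29, 43, 57, 113, 141]


class InvalidDesignError(ValueError):
    """Raised when a cohort or study design violates its invariants."""


def _check_strictly_increasing(name: str, days) -> None:
    if any(b <= a for a, b in zip(days, days[1:])):
        raise InvalidDesignError(f"{name} must be strictly increasing, got {days}")


@dataclass(frozen=True)
class CohortSpec:
    """One escalation cohort: dose, route, allocation, and calendars.

    ``infusion_duration_h`` applies to IV cohorts only (zero-order infusion);
    subcutaneous cohorts must have it equal to zero.
    """

    label: str
    dose_mg: float
    route: str  # "SC" | "IV"
    n_active: int
    n_placebo: int
    dosing_days: tuple = (1,)
    pk_sampling_days: tuple = tuple(PART_A_PK_DAYS)
    ada_sampling_days: tuple = tuple(PART_A_ADA_DAYS)
    infusion_duration_h: float = 0.0

    def __post_init__(self):
        if self.route not in ("SC", "IV"):
            raise InvalidDesignError(f"route must be 'SC' or 'IV', got {self.route!r}")
        if self.dose_mg <= 0:
            raise InvalidDesignError("dose_mg must be positive")
        if self.n_active < 0 or self.n_placebo < 0 or self.n_active + self.n_placebo < 2:
            raise InvalidDesignError("cohort must plan at least 2 subjects")
        _check_strictly_increasing("dosing_days", list(self.dosing_days))
        _check_strictly_increasing("pk_sampling_days", list(self.pk_sampling_days))
        _check_strictly_increasing("ada_sampling_days", list(self.ada_sampling_days))
        if self.route == "SC" and self.infusion_duration_h != 0.0:
            raise InvalidDesignError("SC cohorts must have infusion_duration_h = 0")
        if self.infusion_duration_h < 0:
            raise InvalidDesignError("infusion_duration_h must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.n_active + self.n_placebo

    @property
    def first_dose_day(self) -> int:
        return self.dosing_days[0]

    @property
    def last_scheduled_day(self) -> int:
        return max(self.pk_sampling_days[-1], self.ada_sampling_days[-1])


@dataclass(frozen=True)
class PKModelParams:
    """One-compartment PK model parameters for an IgG-like biologic.

    CL (L/day) and V (L) give an elimination rate k = CL/V; with the defaults
    (0.2 L/day, 7 L) the terminal half-life is ~24 days, in the range typical
    of an IgG monoclonal antibody.  ``ka`` is the first-order subcutaneous
    absorption rate (1/day); 0.5/day places the SC peak near day 6.
    ``F_abs`` is absolute subcutaneous bioavailability.  ``sigma_prop`` is a
    proportional residual error CV (fraction); ``omega_*`` are between-subject
    log-normal standard deviations.
    """

    CL: float = 0.2
    V: float = 7.0
    ka: float = 0.5
    F_abs: float = 0.9
    sigma_prop: float = 0.20
    omega_cl: float = 0.25
    omega_v: float = 0.15
    omega_ka: float = 0.25

    def __post_init__(self):
        if min(self.CL, self.V, self.ka) <= 0:
            raise ValueError("CL, V, ka must be positive")
        if not (0 < self.F_abs <= 1):
            raise ValueError("F_abs must be in (0, 1]")
        if self.sigma_prop < 0 or min(self.omega_cl, self.omega_v, self.omega_ka) < 0:
            raise ValueError("variability parameters must be nonnegative")

    @property
    def k_elim(self) -> float:
        return self.CL / self.V

    @property
    def t_half(self) -> float:
        return math.log(2) / self.k_elim

    def noiseless(self) -> "PKModelParams":
        """Copy with all between-subject and residual variability removed."""
        return replace(self, sigma_prop=0.0, omega_cl=0.0, omega_v=0.0, omega_ka=0.0)


@dataclass
class SubjectRecord:
    """One enrolled subject; ``arm`` is set only by the randomization step."""

    subject_id: str
    cohort: str
    arm: str  # "active" | "placebo"
    weight_kg: float
    withdrawal_day: int | None = None

    def __post_init__(self):
        if self.arm not in ("active", "placebo"):
            raise ValueError(f"arm must be 'active' or 'placebo', got {self.arm!r}")


def default_study_design(include_asthma_cohort: bool = False) -> list[CohortSpec]:
    """The default eight-cohort escalation design.

    Cohorts A--E are single-dose (30/90/300 mg SC, 300/750 mg IV, Day 1);
    cohorts F--H are multiple-dose (150/300/600 mg SC on Days 1, 29, 57).
    All allocate 6 active : 2 placebo.  With ``include_asthma_cohort`` an
    additional 600-mg SC multiple-dose cohort I (12:4) is appended.
    """
    a_pk, a_ada = tuple(PART_A_PK_DAYS), tuple(PART_A_ADA_DAYS)
    b_pk, b_ada = tuple(PART_B_PK_DAYS), tuple(PART_B_ADA_DAYS)
    mad_days = (1, 29, 57)
    design = [
        CohortSpec("A", 30.0, "SC", 6, 2, (1,), a_pk, a_ada),
        CohortSpec("B", 90.0, "SC", 6, 2, (1,), a_pk, a_ada),
        CohortSpec("C", 300.0, "SC", 6, 2, (1,), a_pk, a_ada),
        CohortSpec("D", 300.0, "IV", 6, 2, (1,), a_pk, a_ada, infusion_duration_h=1.0),
        CohortSpec("E", 750.0, "IV", 6, 2, (1,), a_pk, a_ada, infusion_duration_h=1.0),
        CohortSpec("F", 150.0, "SC", 6, 2, mad_days, b_pk, b_ada),
        CohortSpec("G", 300.0, "SC", 6, 2, mad_days, b_pk, b_ada),
        CohortSpec("H", 600.0, "SC", 6, 2, mad_days, b_pk, b_ada),
    ]
    if include_asthma_cohort:
        design.append(CohortSpec("I", 600.0, "SC", 12, 4, mad_days, b_pk, b_ada))
    return design
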