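"""Synthetic-data generators for every pipeline input.

Each generator takes an explicit integer seed (no global random state)
and emulates the statistical structure its downstream analysis assumes:

* oocyte swelling cohorts — per-oocyte permeabilities drawn lognormal
  around the cohort truth (permeabilities are positive and skewed),
  trajectories from the forward osmotic model, areas recovered through
  the sphere relation A = A0 * (V/V0)^(2/3) and perturbed by
  multiplicative measurement noise;
* qPCR Ct tables — target Ct = baseline - log2(fold) + Gaussian noise,
  reference-gene Ct independent of group;
* blood-fed bug cohorts — ~318 +/- 72% engorgement, exponential
  approach of excretion to a plateau fraction of the meal, excreta urea
  proportional to mass excreted, negative-binomial egg totals;
* urea plates — absorbance = slope*nmol + intercept + read noise.

Zero-noise settings make every generator an exact round-trip oracle for
its estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .osmotic import (
    BathCondition,
    OocyteGeometry,
    apply_mercury,
    simulate_solute_swelling,
    simulate_water_swelling,
)
from .permeability import SwellingTimeCourse
from .phenotype import EXCRETION_HOURS, BugRecord

__all__ = [
    "SwellingSimParams",
    "PhenotypeSimParams",
    "gen_swelling_cohort",
    "gen_ct_table",
    "gen_bug_cohort",
    "gen_urea_plate",
]


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, n: int):
    """n positive draws with the given mean and coefficient of variation."""
    if mean == 0 or cv == 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


@dataclass(frozen=True)
class SwellingSimParams:
    """Design constants of a simulated swelling cohort.

    Defaults reproduce the standard assay: oocytes equilibrated in
    ~200 mOsm medium, challenged in 70 mOsm, recorded for 60 s, at
    least five oocytes per group.
    """

    pf_true: float = 2e-2        # cm/s, cohort-mean water permeability
    ps_true: float = 0.0         # cm/s, solute permeability (0 = water-only)
    osm_in0: float = 200.0       # mOsm
    osm_out: float = 70.0        # mOsm (bath total)
    sol_out: float = 0.0         # mM test solute (0 = water-only)
    solute: str = "water-only"
    duration: float = 60.0       # s
    dt: float = 1.0              # s between frames
    n_oocytes: int = 5
    pf_cv: float = 0.10          # between-oocyte CV of Pf (and Ps)
    area_noise_cv: float = 0.02  # multiplicative area measurement noise
    seed: int = 0
    group: str = "construct"
    hg_treated: bool = False
    reversal: bool = False
    geom: OocyteGeometry = field(default_factory=OocyteGeometry)

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")
        if self.n_oocytes < 1:
            raise ValueError("n_oocytes must be >= 1")
        if self.pf_cv < 0 or self.area_noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.osm_in0 < 0 or self.osm_out < 0 or self.sol_out < 0:
            raise ValueError("osmolarities/concentrations must be >= 0")
        if self.pf_true < 0 or self.ps_true < 0:
            raise ValueError("permeabilities must be >= 0")

    @property
    def bath(self) -> BathCondition:
        solute = self.solute if self.sol_out > 0 else "water-only"
        return BathCondition(
            self.osm_out, self.sol_out, solute, self.hg_treated, self.reversal
        )


def gen_swelling_cohort(params: SwellingSimParams) -> list[SwellingTimeCourse]:
    """Simulate one cohort of oocyte swelling records.

    Each oocyte draws its own Pf (and, for a solute challenge, Ps) from
    a lognormal with mean ``pf_true`` and CV ``pf_cv``; its trajectory
    comes from the forward osmotic model and is converted back to
    cross-sectional areas with multiplicative lognormal noise of CV
    ``area_noise_cv``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    geom = params.geom
    a0 = geom.cross_section
    bath = params.bath
    pf_draws = _lognormal_around(rng, params.pf_true, params.pf_cv, params.n_oocytes)
    ps_draws = _lognormal_around(rng, params.ps_true, params.pf_cv, params.n_oocytes)

    cohort = []
    for i in range(params.n_oocytes):
        pf_eff = apply_mercury(float(pf_draws[i]), bath)
        if params.sol_out > 0:
            traj = simulate_solute_swelling(
                geom, pf_eff, float(ps_draws[i]), params.osm_in0, bath,
                params.duration, params.dt,
            )
        else:
            traj = simulate_water_swelling(
                geom, pf_eff, params.osm_in0, bath, params.duration, params.dt
            )
        areas = a0 * traj.relative_volume ** (2.0 / 3.0)
        if params.area_noise_cv > 0:
            sigma = math.sqrt(math.log1p(params.area_noise_cv**2))
            areas = areas * rng.lognormal(-sigma**2 / 2.0, sigma, areas.size)
        cohort.append(
            SwellingTimeCourse(
                oocyte_id=f"{params.group}-{i + 1:02d}",
                group=params.group,
                times=traj.times,
                areas=areas,
                bath=bath,
            )
        )
    return cohort


def gen_ct_table(
    true_fold_changes: dict,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    target_gene: str = "target",
    reference_gene: str = "RpL18",
    baseline_ct: float = 25.0,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table under a fold-change model.

    ``true_fold_changes`` maps group -> fold relative to the calibrator
    group (which must be present with fold 1).  Target Ct = baseline -
    log2(fold) + noise; the reference gene is drawn around a constant
    Ct in every group.  Deterministic given the seed.
    """
    if not true_fold_changes:
        raise ValueError("need at least one group")
    for g, fold in true_fold_changes.items():
        if not (fold > 0):
            raise ValueError(f"group {g!r}: fold must be > 0, got {fold!r}")
    if not any(math.isclose(f, 1.0) for f in true_fold_changes.values()):
        raise ValueError("a calibrator group with fold 1 must be present")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in true_fold_changes.items():
        for rep in range(1, n_replicates + 1):
            tgt = baseline_ct - math.log2(fold) + rng.normal(0.0, ct_noise_sd)
            ref = reference_ct + rng.normal(0.0, ct_noise_sd)
            sample = f"{group}-r{rep}"
            rows.append((sample, group, target_gene, False, tgt, rep))
            rows.append((sample, group, reference_gene, True, ref, rep))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "gene", "is_reference", "ct", "replicate"],
    )


@dataclass(frozen=True)
class PhenotypeSimParams:
    """Design constants of a simulated blood-feeding phenotype experiment.

    Two groups are generated: a control (dsGFP-like, excretion-rate
    multiplier 1) and a treatment whose excretion rate is scaled by
    ``effect_multiplier`` and whose egg output is scaled by
    ``egg_effect_multiplier``.
    """

    n_bugs_per_group: int = 10
    unfed_weight_mean: float = 4.0      # mg, adult female before the meal
    unfed_weight_cv: float = 0.15
    meal_gain_pct_mean: float = 318.0   # % of unfed weight
    meal_gain_pct_sd: float = 72.0
    excretion_half_time_hr: float = 8.0  # characteristic excretion half-time
    excretion_rate_cv: float = 0.20      # between-bug rate variability
    excretion_plateau_frac: float = 0.5  # fraction of the meal excreted at t->inf
    effect_multiplier: float = 1.0       # treatment excretion-rate factor
    urea_per_mg_excreted: float = 5.0    # nmol/mg
    ct_noise_sd: float = 0.15            # cycles, for companion Ct tables
    weight_noise_sd_mg: float = 0.05     # balance precision
    eggs_mean: float = 12.0              # total eggs per control bug
    eggs_dispersion: float = 8.0         # negative-binomial shape k
    egg_effect_multiplier: float = 1.0
    urea_read_noise_sd: float = 0.005    # absorbance units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bugs_per_group < 1:
            raise ValueError("n_bugs_per_group must be >= 1")
        for name in (
            "unfed_weight_mean", "meal_gain_pct_mean", "excretion_half_time_hr",
            "urea_per_mg_excreted", "eggs_mean", "eggs_dispersion",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.effect_multiplier < 0 or self.egg_effect_multiplier < 0:
            raise ValueError("effect multipliers must be >= 0")
        if not 0 <= self.excretion_plateau_frac <= 1:
            raise ValueError("excretion_plateau_frac must be in [0, 1]")


# default colorimetric curve used when generating bug-level absorbances
_UREA_CURVE_SLOPE = 0.02      # absorbance per nmol in-reaction
_UREA_CURVE_INTERCEPT = 0.05
_UREA_SAMPLE_FRACTION = 20.0 / 100.0  # reaction aliquot / well volume


def _nb_total(rng: np.random.Generator, mean: float, k: float) -> int:
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def gen_bug_cohort(params: PhenotypeSimParams) -> list[BugRecord]:
    """Simulate control and treatment bugs through a feeding/excretion assay.

    Per bug: unfed weight, replete weight (engorgement drawn around
    ``meal_gain_pct_mean``), weights at the standard hours following
    ``plateau * (1 - exp(-rate * t))`` excretion with a per-bug
    lognormal rate, excreta urea proportional to 24-h mass excreted
    (reported as a well absorbance on the default standard curve), and
    a negative-binomial egg total spread over daily counts.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    base_rate = (
        0.0
        if math.isinf(params.excretion_half_time_hr)
        else math.log(2.0) / params.excretion_half_time_hr
    )
    records = []
    for group, rate_mult, egg_mult in (
        ("control", 1.0, 1.0),
        ("treatment", params.effect_multiplier, params.egg_effect_multiplier),
    ):
        for i in range(params.n_bugs_per_group):
            unfed = float(
                _lognormal_around(
                    rng, params.unfed_weight_mean, params.unfed_weight_cv, 1
                )[0]
            )
            gain_pct = max(
                rng.normal(params.meal_gain_pct_mean, params.meal_gain_pct_sd), 20.0
            )
            fed = unfed * (1.0 + gain_pct / 100.0)
            gained = fed - unfed
            rate = base_rate * rate_mult * float(
                _lognormal_around(rng, 1.0, params.excretion_rate_cv, 1)[0]
            )
            weights = {}
            for h in EXCRETION_HOURS:
                frac = params.excretion_plateau_frac * -math.expm1(-rate * h)
                w = fed - gained * frac
                if params.weight_noise_sd_mg > 0:
                    w += rng.normal(0.0, params.weight_noise_sd_mg)
                weights[h] = w
            frac24 = params.excretion_plateau_frac * -math.expm1(-rate * 24.0)
            urea_nmol = params.urea_per_mg_excreted * gained * frac24
            absorbance = (
                _UREA_CURVE_SLOPE * urea_nmol * _UREA_SAMPLE_FRACTION
                + _UREA_CURVE_INTERCEPT
            )
            if params.urea_read_noise_sd > 0:
                absorbance += rng.normal(0.0, params.urea_read_noise_sd)
            total_eggs = _nb_total(rng, params.eggs_mean * egg_mult, params.eggs_dispersion)
            days = np.arange(1, 15)
            day_w = np.exp(-days / 5.0)
            eggs_per_day = rng.multinomial(total_eggs, day_w / day_w.sum()).tolist()
            records.append(
                BugRecord(
                    bug_id=f"{group}-{i + 1:02d}",
                    group=group,
                    w_prefeed=unfed,
                    w_fed=fed,
                    weights=weights,
                    urea_absorbance=float(absorbance),
                    eggs_per_day=eggs_per_day,
                )
            )
    return records


def gen_urea_plate(
    curve_slope: float = _UREA_CURVE_SLOPE,
    curve_intercept: float = _UREA_CURVE_INTERCEPT,
    standards: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    samples: tuple = (),
    read_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a colorimetric plate: standards plus optional samples.

    ``standards`` and ``samples`` are in-reaction nmol amounts;
    absorbance = slope*nmol + intercept + read noise.  Returns a
    long-form frame with columns ``well, role, nmol, absorbance``.
    """
    if curve_slope <= 0:
        raise ValueError("curve slope must be > 0")
    if len(set(standards)) < 2:
        raise ValueError("need >= 2 distinct standard levels")
    if read_noise_sd < 0:
        raise ValueError("read_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i, nmol in enumerate(standards):
        ab = curve_slope * nmol + curve_intercept + rng.normal(0.0, read_noise_sd)
        rows.append((f"S{i + 1}", "standard", float(nmol), float(ab)))
    for i, nmol in enumerate(samples):
        ab = curve_slope * nmol + curve_intercept + rng.normal(0.0, read_noise_sd)
        rows.append((f"U{i + 1}", "sample", float(nmol), float(ab)))
    return pd.DataFrame(rows, columns=["well", "role", "nmol", "absorbance"])
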