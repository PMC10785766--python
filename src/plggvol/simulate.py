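"""Synthetic pLGG cohort generator.

Produces measurement tables with the statistical structure the analysis
pipeline assumes, so every stage can be exercised end-to-end without any
imaging data: growth-model volume trajectories observed on a ~2-month
imaging cadence with 10% multiplicative measurement noise, bidimensional
diameters that are distorted spherical proxies of solid volume, near-static
cysts, a stable edema margin folded into whole-tumor volume, occasional new
lesions in progressing participants, and two simulated BT-RADS readers with
substantial but imperfect agreement.

The default configuration emulates the reference cohort: 43 participants,
each with an early (~6 month) assessment image and a 22-participant subset
with an additional late assessment (65 assessed images in total), with the
assessed-image class mix fixed by stratified assignment at 14 partial
responses, 23 stable, 28 progressive.  Per-class growth-parameter ranges are
a calibration choice (no such ranges are published); they are rejection
sampled so the noiseless trajectory reproduces the assigned class under the
sphere-extrapolated volumetric rules at every assessment time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .growth import GrowthParams, model_volume, time_of_minimum
from .measurements import (
    LesionMeasurement,
    Measure,
    ParticipantSeries,
    TimePoint,
)

#: BT-RADS scores a truthful reader may assign per response class.
_READER1_SCORES = {
    "PR": (("1a",), (1.0,)),
    "SD": (("2", "3a", "3b"), (0.70, 0.20, 0.10)),
    "PD": (("3c", "4"), (0.40, 0.60)),
}
_BTRADS_ORDER = ("1a", "1b", "2", "3a", "3b", "3c", "4")


@dataclass(frozen=True)
class CohortConfig:
    """Generation settings for one synthetic cohort.

    ``class_counts`` are the PR/SD/PD counts over all assessed images
    (early + late) and must sum to ``n_participants + n_late_assessments``.
    ``shape_distortion_cv`` controls how far the per-lesion diameters deviate
    from the equivalent-sphere diameter; a fraction of it is re-drawn per
    visit, which is what makes 2D change a noisy proxy of volume change.
    """

    n_participants: int = 43
    n_late_assessments: int = 22
    cadence_days: float = 61.0
    horizon_days: float = 700.0
    noise_cv: float = 0.10
    class_counts: tuple[int, int, int] = (14, 23, 28)  # PR, SD, PD
    cyst_fraction: float = 0.791
    shape_distortion_cv: float = 0.15
    visit_jitter_frac: float = 1.5
    reader_discordance: float = 11.0 / 65.0
    edema_margin: float = 1.5
    edema_walk_cv: float = 0.08
    cyst_walk_cv: float = 0.04
    new_lesion_rate: float = 0.15
    baseline_solid_median: float = 18.0
    baseline_solid_sigma: float = 1.15
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_counts) != self.n_participants + self.n_late_assessments:
            raise ValueError(
                "class_counts must sum to n_participants + n_late_assessments "
                f"({self.n_participants + self.n_late_assessments}); got "
                f"{sum(self.class_counts)}"
            )
        if self.n_late_assessments > self.n_participants:
            raise ValueError("cannot assess more late images than participants")
        if min(self.noise_cv, self.shape_distortion_cv, self.cyst_walk_cv) < 0:
            raise ValueError("coefficients of variation must be >= 0")


@dataclass
class ParticipantTruth:
    """Latent state behind one simulated participant."""

    participant_id: str
    params: GrowthParams
    t_vmin: float
    assessment_times: list[float]
    true_class: list[str]          # sphere-extrapolated volumetric rule
    model_rule_class: list[str]    # trajectory-rule class on the noiseless curve
    has_cyst: bool
    new_lesion_time: Optional[float] = None


@dataclass
class GroundTruth:
    """Latent classes and parameters behind a simulated cohort."""

    config: CohortConfig
    participants: dict[str, ParticipantTruth] = field(default_factory=dict)

    def assessed_labels(self) -> list[tuple[str, float, str]]:
        """(participant, time, class) for every assessed image, early first."""
        out = []
        for p in self.participants.values():
            for t, c in zip(p.assessment_times, p.true_class):
                out.append((p.participant_id, t, c))
        return out


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def simulate_trajectory(
    p: GrowthParams,
    cadence: float = 61.0,
    horizon: float = 700.0,
    noise_cv: float = 0.10,
    seed: int | np.random.Generator = 0,
    participant_id: str = "SIM-001",
) -> ParticipantSeries:
    """Observe one noiseless growth trajectory on a fixed imaging cadence.

    Observation times are baseline (t = 0, treatment start) then multiples of
    the cadence up to the horizon; each observed solid volume is the
    closed-form model volume times an independent lognormal factor with the
    given coefficient of variation.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times = [0.0]
    t = cadence
    while t <= horizon:
        times.append(t)
        t += cadence
    tps = []
    for tt in times:
        v = float(model_volume(tt, p)) * float(_lognormal_factor(rng, noise_cv))
        tps.append(
            TimePoint(
                participant_id=participant_id,
                t_days=tt,
                lesions=(LesionMeasurement("L1", base_volume=v),),
            )
        )
    return ParticipantSeries(participant_id, tps)


def derive_2d_from_volume(
    volume: float,
    shape_distortion_cv: float = 0.15,
    seed: int | np.random.Generator = 0,
    base_factors: Optional[tuple[float, float]] = None,
    visit_jitter_cv: Optional[float] = None,
) -> tuple[float, float]:
    """Perpendicular diameters as a distorted spherical proxy of a volume.

    The equivalent-sphere diameter is d = (6V/π)^(1/3).  Each reported
    diameter is d times a lognormal distortion factor; ``base_factors`` hold
    a lesion's fixed anatomy (drawn once per lesion when not supplied) while
    a smaller per-visit jitter is always re-drawn, so longitudinal 2D change
    tracks volume change only noisily.  Returns (d1, d2) with d1 >= d2.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    if base_factors is None:
        base_factors = tuple(_lognormal_factor(rng, shape_distortion_cv, size=2))
    jcv = (
        0.5 * shape_distortion_cv if visit_jitter_cv is None else visit_jitter_cv
    )
    jit = _lognormal_factor(rng, jcv, size=2)
    d1 = d * base_factors[0] * jit[0]
    d2 = d * base_factors[1] * jit[1]
    if d1 < d2:
        d1, d2 = d2, d1
    return float(d1), float(d2)


# ---------------------------------------------------------------------------
# class-conditional growth-parameter calibration
# ---------------------------------------------------------------------------
# Ranges are chosen so the noiseless trajectory lands in the intended
# response class at ~6 months under the sphere-extrapolated volumetric rules
# (PD >= +40%, PR group <= -35% with minor response folded in, SD between).
# They are a generator calibration, not published values.

def _draw_class_params(
    cls: str, vb: float, rng: np.random.Generator
) -> GrowthParams:
    if cls == "PR":
        lam = rng.uniform(1e-4, 1.2e-3)
        gamma0 = rng.uniform(0.004, 0.018)
        eps = rng.uniform(5e-4, 2.5e-3)
    elif cls == "SD":
        lam = rng.uniform(1e-4, 1.2e-3)
        gamma0 = lam * rng.uniform(0.2, 1.8)
        eps = rng.uniform(1e-3, 1e-2)
    elif cls == "PD":
        if rng.random() < 0.35:  # monotone growers
            lam = rng.uniform(2e-3, 8e-3)
            gamma0 = lam * rng.uniform(0.0, 0.3)
            eps = rng.uniform(5e-3, 3e-2)
        else:  # dip-then-regrow (resistance-driven progression)
            lam = rng.uniform(3e-3, 6e-3)
            gamma0 = rng.uniform(0.006, 0.02)
            eps = rng.uniform(1.5e-2, 5e-2)
    else:  # pragma: no cover
        raise ValueError(cls)
    return GrowthParams(lam=lam, gamma0=gamma0, eps=max(eps, 1e-6), V_b=vb)


def _volx_class(pct: float) -> str:
    """Three-category class under the sphere-extrapolated volumetric rules
    (minor response grouped with partial response, as in any comparison
    against a visual reference that has no minor-response category)."""
    if pct >= 40.0:
        return "PD"
    if pct <= -35.0:
        return "PR"
    return "SD"


def _model_rule_class(p: GrowthParams, t_eval: float, times: np.ndarray,
                      noise_cv: float) -> str:
    """Trajectory-rule class evaluated on the noiseless curve."""
    tv = time_of_minimum(p)
    if math.isfinite(tv) and t_eval > tv and p.gamma0 > p.lam:
        return "PD"
    if p.gamma0 <= p.lam and t_eval > 0 and tv == 0.0:
        # no shrinkage phase: any eval time is past the (immediate) minimum
        return "PD"
    v0 = float(model_volume(0.0, p))
    mask = times <= t_eval
    pct = 100.0 * (np.asarray(model_volume(times[mask], p)) - v0) / v0
    if np.all(np.abs(pct) <= 100.0 * noise_cv):
        return "SD"
    return "PR"


def _sample_participant_params(
    cls: str,
    vb: float,
    assess_times: Sequence[float],
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> GrowthParams:
    """Rejection-sample class parameters until the noiseless trajectory is in
    the intended class at every assessment time."""
    for _ in range(max_tries):
        p = _draw_class_params(cls, vb, rng)
        v0 = float(model_volume(0.0, p))
        ok = all(
            _volx_class(100.0 * (float(model_volume(t, p)) - v0) / v0) == cls
            for t in assess_times
        )
        if ok:
            return p
    raise RuntimeError(
        f"could not find {cls} parameters consistent with assessment times "
        f"{list(assess_times)}; class mix may be infeasible"
    )


#: Where a discordant second reader lands: a score one *response category*
#: away (subtle changes read as responding/progressing by one reader and
#: stable by the other), mirroring how real discordant reads behave.
_DISCORDANT_MOVES = {
    "1a": ("2",),
    "1b": ("1a", "3c"),
    "2": ("1a", "3c"),
    "3a": ("1a", "3c"),
    "3b": ("1a", "3c"),
    "3c": ("3a",),
    "4": ("3a",),
}


def _perturb_reader(score: str, rng: np.random.Generator) -> str:
    moves = _DISCORDANT_MOVES[score]
    return moves[int(rng.integers(len(moves)))]


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[ParticipantSeries], GroundTruth]:
    """Generate a full synthetic cohort and its latent ground truth.

    Identical configurations (including the seed) produce identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n_pr, n_sd, n_pd = config.class_counts

    # --- allocate early/late classes by largest-remainder apportionment ----
    totals = np.array(config.class_counts, dtype=float)
    quota = totals * config.n_late_assessments / totals.sum()
    late = np.floor(quota).astype(int)
    rem = quota - late
    for i in np.argsort(-rem)[: config.n_late_assessments - late.sum()]:
        late[i] += 1
    early = np.array(config.class_counts) - late
    if (early < 0).any() or early.sum() != config.n_participants:
        raise ValueError("infeasible class mix for this cohort size")

    classes = (["PR"] * early[0] + ["SD"] * early[1] + ["PD"] * early[2])
    late_flags = [False] * len(classes)
    for c, nl in zip(("PR", "SD", "PD"), late):
        idx = [i for i, cc in enumerate(classes) if cc == c]
        for i in rng.choice(idx, size=nl, replace=False):
            late_flags[int(i)] = True
    order = rng.permutation(len(classes))
    classes = [classes[i] for i in order]
    late_flags = [late_flags[i] for i in order]

    series_list: list[ParticipantSeries] = []
    truth = GroundTruth(config=config)

    # follow-up count distributions (median ~4 across the cohort, range 1-10)
    early_counts = (1, 2, 3, 4, 5)
    early_w = (0.15, 0.20, 0.30, 0.20, 0.15)
    late_counts = (4, 5, 6, 7, 8, 9, 10)
    late_w = (0.28, 0.20, 0.16, 0.12, 0.10, 0.08, 0.06)

    for k, (cls, has_late) in enumerate(zip(classes, late_flags)):
        pid = f"SIM{config.seed:03d}-{k + 1:02d}"
        if has_late:
            n_fu = int(rng.choice(late_counts, p=late_w))
        else:
            n_fu = int(rng.choice(early_counts, p=early_w))
        times = np.array([0.0] + [j * config.cadence_days
                                  for j in range(1, n_fu + 1)])
        times = times[times <= config.horizon_days]
        n_fu = len(times) - 1
        # early assessment: follow-up nearest 6 months; late: last follow-up
        fu_times = times[1:]
        early_t = float(fu_times[np.argmin(np.abs(fu_times - 183.0))])
        assess = [early_t]
        if has_late and float(fu_times[-1]) != early_t:
            assess.append(float(fu_times[-1]))
        elif has_late:
            # too few follow-ups to separate late from early: extend by one
            times = np.append(times, times[-1] + config.cadence_days)
            fu_times = times[1:]
            assess.append(float(fu_times[-1]))
            n_fu += 1

        vb = config.baseline_solid_median * math.exp(
            config.baseline_solid_sigma * rng.standard_normal()
        )
        p = _sample_participant_params(cls, vb, assess, rng)

        # latent cyst and new-lesion state
        has_cyst = bool(rng.random() < config.cyst_fraction)
        cyst0 = math.exp(rng.normal(math.log(4.0), 0.9)) if has_cyst else 0.0
        new_lesion_time: Optional[float] = None
        if cls == "PD" and rng.random() < config.new_lesion_rate:
            new_lesion_time = early_t

        base_factors = tuple(
            _lognormal_factor(rng, config.shape_distortion_cv, size=2)
        )
        jitter_cv = config.visit_jitter_frac * config.shape_distortion_cv

        tps = []
        cyst = cyst0
        v0 = float(model_volume(0.0, p))
        # peritumoral edema: a stable absolute margin anchored at the
        # baseline solid volume, drifting slowly and independently of the
        # solid component — this is what dilutes whole-volume change
        edema = (config.edema_margin - 1.0) * v0
        for tt in times:
            v_true = float(model_volume(tt, p))
            v_obs = v_true * float(_lognormal_factor(rng, config.noise_cv))
            d1, d2 = derive_2d_from_volume(
                v_true,
                config.shape_distortion_cv,
                seed=rng,
                base_factors=base_factors,
                visit_jitter_cv=jitter_cv,
            )
            if tt > 0:
                cyst = cyst * float(_lognormal_factor(rng, config.cyst_walk_cv))
                edema = edema * float(_lognormal_factor(rng, config.edema_walk_cv))
            whole_true = v_true + edema + cyst
            whole_obs = whole_true * float(_lognormal_factor(rng, config.noise_cv))
            cyst_obs = (
                min(cyst * float(_lognormal_factor(rng, config.noise_cv)),
                    whole_obs)
                if has_cyst
                else None
            )
            reads: tuple[str, ...] = ()
            if tt in assess:
                scores, w = _READER1_SCORES[cls]
                r1 = str(rng.choice(scores, p=w))
                r2 = (
                    _perturb_reader(r1, rng)
                    if rng.random() < config.reader_discordance
                    else r1
                )
                reads = (r1, r2)
            tps.append(
                TimePoint(
                    participant_id=pid,
                    t_days=float(tt),
                    lesions=(
                        LesionMeasurement("L1", d1=d1, d2=d2, base_volume=v_obs),
                    ),
                    whole_volume=whole_obs,
                    total_cyst_volume=cyst_obs,
                    new_lesion=(
                        new_lesion_time is not None and tt >= new_lesion_time
                    ),
                    btrads_reads=reads,
                )
            )
        series_list.append(ParticipantSeries(pid, tps))
        truth.participants[pid] = ParticipantTruth(
            participant_id=pid,
            params=p,
            t_vmin=time_of_minimum(p),
            assessment_times=list(assess),
            true_class=[cls] * len(assess),
            model_rule_class=[
                _model_rule_class(p, t, times, config.noise_cv) for t in assess
            ],
            has_cyst=has_cyst,
            new_lesion_time=new_lesion_time,
        )
    return series_list, truth
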