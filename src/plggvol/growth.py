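"""Mechanistic longitudinal tumor growth-response model.

The solid-tumor volume trajectory after treatment start is described by a
regression–regrowth ordinary differential equation

    dV/dt = (λ − γ₀ e^(−εt)) V,     V(0) = V_b,

with exponential intrinsic growth at rate λ (day⁻¹), an initial
treatment-induced shrinkage rate γ₀ (day⁻¹) that decays as resistance
develops at rate ε (day⁻¹).  The ODE integrates in closed form to

    V(t) = V_b · exp( λt − (γ₀/ε)(1 − e^(−εt)) ).

When γ₀ > λ the trajectory dips to a minimum at t_Vmin = ln(γ₀/λ)/ε — the
patient-specific pivot of trajectory-based response classification: an image
acquired well past t_Vmin sits on the regrowth limb and is progressive
disease regardless of how its volume compares with baseline.

Fitting is Bayesian: a lognormal observation model (volumes observed with a
fixed coefficient of variation, 10% by default) with affine-invariant
ensemble MCMC (emcee) over (λ, γ₀, ε, V_b), optionally wrapped in a
measurement-noise bootstrap whose refitted posteriors are pooled.  The API
follows the Model / Results convention: build a :class:`TumorGrowthModel`
from a participant's series, call :meth:`~TumorGrowthModel.fit` (or
:meth:`~TumorGrowthModel.fit_bootstrap`), and interrogate the returned
:class:`TumorGrowthResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import emcee
import numpy as np
import pandas as pd

from .measurements import Measure, ParticipantSeries

__all__ = [
    "GrowthParams",
    "GrowthPriors",
    "TumorGrowthModel",
    "TumorGrowthResults",
    "CohortGrowthModel",
    "ModelClassification",
    "model_volume",
    "time_of_minimum",
    "compare_responders",
]

_EPS_TINY = 1e-12


@dataclass(frozen=True)
class GrowthParams:
    """(λ, γ₀, ε, V_b) — growth, initial shrinkage, resistance onset, baseline volume."""

    lam: float
    gamma0: float
    eps: float
    V_b: float

    def __post_init__(self) -> None:
        if self.lam < 0 or self.gamma0 < 0 or self.eps <= 0 or self.V_b <= 0:
            raise ValueError(
                "need lam >= 0, gamma0 >= 0, eps > 0, V_b > 0 "
                f"(got {self.lam}, {self.gamma0}, {self.eps}, {self.V_b})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.lam, self.gamma0, self.eps, self.V_b])


def model_volume(t, p: GrowthParams | Sequence[float]) -> np.ndarray | float:
    """Closed-form trajectory V(t) = V_b exp(λt − (γ₀/ε)(1 − e^(−εt))).

    The ε → 0 limit V_b exp((λ − γ₀)t) is applied below ε = 1e−12 to keep the
    expression numerically stable.
    """
    if isinstance(p, GrowthParams):
        lam, gamma0, eps, vb = p.lam, p.gamma0, p.eps, p.V_b
    else:
        lam, gamma0, eps, vb = p
    t = np.asarray(t, dtype=float)
    if eps < _EPS_TINY:
        out = vb * np.exp((lam - gamma0) * t)
    else:
        out = vb * np.exp(lam * t - (gamma0 / eps) * (1.0 - np.exp(-eps * t)))
    return out if out.ndim else float(out)


def time_of_minimum(p: GrowthParams) -> float:
    """Time of minimal volume: ln(γ₀/λ)/ε when γ₀ > λ, else 0.

    With λ = 0 and γ₀ > 0 the trajectory decreases monotonically and never
    turns; +inf is returned as the "no finite minimum" sentinel.
    """
    if p.gamma0 <= p.lam:
        return 0.0
    if p.lam == 0.0:
        return math.inf
    return math.log(p.gamma0 / p.lam) / p.eps


def _t_vmin_vec(lam: np.ndarray, gamma0: np.ndarray, eps: np.ndarray) -> np.ndarray:
    out = np.zeros_like(lam)
    shrink = gamma0 > lam
    with np.errstate(divide="ignore"):
        out[shrink] = np.where(
            lam[shrink] > 0,
            np.log(gamma0[shrink] / np.maximum(lam[shrink], 1e-300)) / eps[shrink],
            np.inf,
        )
    return out


@dataclass(frozen=True)
class GrowthPriors:
    """Prior support for the single-series fit.

    λ and ε are log-uniform over physically plausible decades, γ₀ is uniform,
    and log V_b is normal centred on the log of the first observed volume
    with a relative spread ``vb_cv``.
    """

    lam_bounds: tuple[float, float] = (1e-5, 0.05)
    gamma0_bounds: tuple[float, float] = (0.0, 0.2)
    eps_bounds: tuple[float, float] = (1e-4, 0.1)
    vb_cv: float = 0.2


@dataclass(frozen=True)
class ModelClassification:
    """Trajectory-based response label for one evaluation image."""

    label: str  # "PR" | "SD" | "PD"
    t_eval: float
    t_vmin_q75: float
    sd_band: float  # fractional no-change band (= assumed measurement CV)


class TumorGrowthModel:
    """Single-participant growth-response model.

    Parameters
    ----------
    series
        Longitudinal record; only time points carrying the chosen measure are
        used.  At least 4 observed volumes (baseline + 3 priors) are required
        before a fit at a later evaluation time is meaningful.
    measure
        Which volume stream to fit (solid volume by default).
    noise_cv
        Assumed multiplicative measurement uncertainty; enters the lognormal
        likelihood as σ of log-volume and defines the stable-disease band.
    fix_lam
        If given, λ is frozen at this value (used when a shared cohort-level
        growth rate has been estimated) and only (γ₀, ε, V_b) are sampled.
    """

    def __init__(
        self,
        series: ParticipantSeries,
        measure: Measure = Measure.SOLID_VOLUME,
        noise_cv: float = 0.10,
        priors: Optional[GrowthPriors] = None,
        fix_lam: Optional[float] = None,
    ) -> None:
        self.series = series
        self.measure = measure
        self.noise_cv = float(noise_cv)
        self.priors = priors or GrowthPriors()
        self.fix_lam = fix_lam
        t, v = [], []
        for tp in series.timepoints:
            val = tp.value(measure)
            if val is not None:
                if val <= 0:
                    raise ValueError(
                        f"non-positive observed volume at t={tp.t_days} d"
                    )
                t.append(tp.t_days)
                v.append(val)
        self.t = np.asarray(t, dtype=float)
        self.v = np.asarray(v, dtype=float)
        if len(self.t) < 2:
            raise ValueError("need at least two observed volumes to fit")
        # model time is measured from treatment start; pretreatment images
        # (t<=0) anchor V_b through the likelihood at their actual times
        self._log_vb0 = math.log(self.v[0])

    # -- log-posterior ---------------------------------------------------

    @property
    def n_free(self) -> int:
        return 3 if self.fix_lam is not None else 4

    def _unpack(self, theta: np.ndarray) -> tuple[float, float, float, float]:
        """theta is (log λ, γ₀, log ε, log V_b), minus log λ when frozen."""
        if self.fix_lam is not None:
            lam = self.fix_lam
            gamma0, log_eps, log_vb = theta
        else:
            log_lam, gamma0, log_eps, log_vb = theta
            lam = math.exp(log_lam)
        return lam, gamma0, math.exp(log_eps), math.exp(log_vb)

    def log_prior(self, theta: np.ndarray) -> float:
        pri = self.priors
        lam, gamma0, eps, vb = self._unpack(theta)
        if not (pri.lam_bounds[0] <= lam <= pri.lam_bounds[1]) and self.fix_lam is None:
            return -math.inf
        if not (pri.gamma0_bounds[0] <= gamma0 <= pri.gamma0_bounds[1]):
            return -math.inf
        if not (pri.eps_bounds[0] <= eps <= pri.eps_bounds[1]):
            return -math.inf
        # lognormal prior on V_b centred on the first observed volume
        z = (math.log(vb) - self._log_vb0) / pri.vb_cv
        return -0.5 * z * z

    def log_likelihood(self, theta: np.ndarray, v_obs: Optional[np.ndarray] = None) -> float:
        lam, gamma0, eps, vb = self._unpack(theta)
        v_obs = self.v if v_obs is None else v_obs
        mu = np.log(model_volume(self.t, (lam, gamma0, eps, vb)))
        resid = (np.log(v_obs) - mu) / self.noise_cv
        return float(-0.5 * np.dot(resid, resid))

    def log_posterior(self, theta: np.ndarray, v_obs: Optional[np.ndarray] = None) -> float:
        lp = self.log_prior(theta)
        if not math.isfinite(lp):
            return -math.inf
        return lp + self.log_likelihood(theta, v_obs)

    # -- fitting ---------------------------------------------------------

    def _initial_walkers(self, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
        pri = self.priors
        cols = []
        if self.fix_lam is None:
            cols.append(rng.uniform(np.log(pri.lam_bounds[0]),
                                    np.log(pri.lam_bounds[1]), n_walkers))
        cols.append(rng.uniform(pri.gamma0_bounds[0], pri.gamma0_bounds[1], n_walkers))
        cols.append(rng.uniform(np.log(pri.eps_bounds[0]),
                                np.log(pri.eps_bounds[1]), n_walkers))
        cols.append(self._log_vb0 + pri.vb_cv * rng.standard_normal(n_walkers))
        return np.column_stack(cols)

    def fit(
        self,
        n_walkers: int = 32,
        n_steps: int = 2000,
        seed: int = 0,
        _v_obs: Optional[np.ndarray] = None,
        prior_only: bool = False,
    ) -> "TumorGrowthResults":
        """Sample the posterior with an affine-invariant ensemble sampler.

        The first half of each chain is discarded as burn-in.  Identical
        seeds give identical sample arrays.  ``prior_only=True`` samples the
        prior alone (a null-data diagnostic).
        """
        rng = np.random.default_rng(seed)
        p0 = self._initial_walkers(n_walkers, rng)
        if prior_only:
            def logp(th):
                return self.log_prior(th)
        else:
            def logp(th):
                return self.log_posterior(th, _v_obs)
        sampler = emcee.EnsembleSampler(n_walkers, self.n_free, logp)
        state = np.random.RandomState(int(rng.integers(0, 2**31 - 1)))
        sampler.random_state = state.get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        burn = n_steps // 2
        chain = sampler.get_chain(discard=burn, flat=True)
        accept = float(np.mean(sampler.acceptance_fraction))
        return TumorGrowthResults._from_chain(
            self, chain, accept, n_steps, n_boot=1, seed=seed
        )

    def fit_bootstrap(
        self,
        n_boot: int = 200,
        noise_cv: Optional[float] = None,
        n_walkers: int = 32,
        n_steps: int = 2000,
        seed: int = 0,
    ) -> "TumorGrowthResults":
        """Measurement-noise bootstrap around the MCMC fit.

        Each replicate multiplies every observed volume by an independent
        lognormal factor with the given coefficient of variation (defaults to
        the model's ``noise_cv``), refits, and the post-burn-in posteriors of
        all replicates are pooled into one results object.
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        cv = self.noise_cv if noise_cv is None else float(noise_cv)
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        chains = []
        accepts = []
        for b in range(n_boot):
            factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(self.v)))
            v_b = self.v * factors
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = self.fit(n_walkers=n_walkers, n_steps=n_steps, seed=sub_seed,
                           _v_obs=v_b)
            chains.append(res._chain)
            accepts.append(res.acceptance_fraction)
        pooled = np.concatenate(chains, axis=0)
        return TumorGrowthResults._from_chain(
            self, pooled, float(np.mean(accepts)), n_steps,
            n_boot=n_boot, seed=seed, noise_cv=cv,
        )


class TumorGrowthResults:
    """Posterior (possibly bootstrap-pooled) of one participant's growth fit.

    Exposes the parameter samples on the natural scale, the derived t_Vmin
    and V_min distributions, a summary table, trajectory prediction bands,
    and the trajectory-based response classification.
    """

    PARAM_NAMES = ("lam", "gamma0", "eps", "V_b")

    def __init__(
        self,
        model: TumorGrowthModel,
        params: np.ndarray,
        acceptance_fraction: float,
        n_steps: int,
        n_boot: int,
        seed: int,
        noise_cv: Optional[float] = None,
        chain: Optional[np.ndarray] = None,
    ) -> None:
        self.model = model
        self.params = params  # (n_samples, 4) on natural scale
        self.acceptance_fraction = acceptance_fraction
        self.n_steps = n_steps
        self.n_boot = n_boot
        self.seed = seed
        self.noise_cv = model.noise_cv if noise_cv is None else noise_cv
        self._chain = chain if chain is not None else params
        self.t_vmin_samples = _t_vmin_vec(
            params[:, 0], params[:, 1], params[:, 2]
        )
        finite = np.where(np.isfinite(self.t_vmin_samples),
                          self.t_vmin_samples, 0.0)
        self.v_min_samples = np.array([
            model_volume(tv, p) for tv, p in zip(finite, params)
        ])
        self.converged = 0.1 <= acceptance_fraction <= 0.9
        if not self.converged:
            import warnings

            warnings.warn(
                f"MCMC acceptance fraction {acceptance_fraction:.2f} outside "
                "[0.1, 0.9]; treat posterior with caution",
                stacklevel=3,
            )

    @classmethod
    def _from_chain(
        cls,
        model: TumorGrowthModel,
        chain: np.ndarray,
        accept: float,
        n_steps: int,
        n_boot: int,
        seed: int,
        noise_cv: Optional[float] = None,
    ) -> "TumorGrowthResults":
        cols = []
        j = 0
        if model.fix_lam is not None:
            cols.append(np.full(len(chain), model.fix_lam))
        else:
            cols.append(np.exp(chain[:, j])); j += 1
        cols.append(chain[:, j]); j += 1          # gamma0 (natural scale)
        cols.append(np.exp(chain[:, j])); j += 1  # eps
        cols.append(np.exp(chain[:, j]))          # V_b
        params = np.column_stack(cols)
        return cls(model, params, accept, n_steps, n_boot, seed,
                   noise_cv=noise_cv, chain=chain)

    # -- posterior summaries --------------------------------------------

    def median_params(self) -> GrowthParams:
        med = np.median(self.params, axis=0)
        return GrowthParams(*med)

    @property
    def t_vmin_median(self) -> float:
        return float(np.median(self.t_vmin_samples))

    def t_vmin_percentile(self, q: float = 75.0) -> float:
        return float(np.percentile(self.t_vmin_samples, q))

    def summary(self) -> pd.DataFrame:
        """Posterior quantile table for the four parameters and t_Vmin."""
        rows = {}
        arr = np.column_stack([self.params, self.t_vmin_samples])
        for i, name in enumerate(self.PARAM_NAMES + ("t_vmin",)):
            col = arr[:, i]
            col = col[np.isfinite(col)]
            if len(col) == 0:
                rows[name] = dict.fromkeys(
                    ["median", "q2.5", "q25", "q75", "q97.5"], math.inf
                )
                continue
            q = np.percentile(col, [50, 2.5, 25, 75, 97.5])
            rows[name] = dict(zip(["median", "q2.5", "q25", "q75", "q97.5"], q))
        df = pd.DataFrame(rows).T
        df.attrs["acceptance_fraction"] = self.acceptance_fraction
        df.attrs["n_samples"] = len(self.params)
        df.attrs["n_boot"] = self.n_boot
        return df

    def predict(self, t, q: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
        """Posterior median trajectory and credible band at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        sub = self.params
        if len(sub) > 2000:  # prediction band needs no more than ~2k draws
            idx = np.linspace(0, len(sub) - 1, 2000).astype(int)
            sub = sub[idx]
        curves = np.array([model_volume(t, p) for p in sub])
        lo, med, hi = np.percentile(curves, [q[0], 50, q[1]], axis=0)
        return pd.DataFrame({"t_days": t, "median": med, "lo": lo, "hi": hi})

    # -- classification ---------------------------------------------------

    def classify(self, t_eval: float) -> ModelClassification:
        """Trajectory-based response label at an observed evaluation time.

        PD if t_eval lies beyond the 75th percentile of the t_Vmin posterior
        (the tumor has clearly passed its minimum and is regrowing); else SD
        if every observed volume up to t_eval stays within the measurement
        uncertainty band around the pretreatment volume; else PR.
        """
        q75 = self.t_vmin_percentile(75.0)
        band = 100.0 * self.noise_cv
        if t_eval > q75:
            label = "PD"
        else:
            base = self.model.v[0]
            mask = self.model.t <= t_eval
            pct = 100.0 * (self.model.v[mask] - base) / base
            if np.all(np.abs(pct) <= band):
                label = "SD"
            else:
                label = "PR"
        return ModelClassification(label=label, t_eval=t_eval,
                                   t_vmin_q75=q75, sd_band=self.noise_cv)

    def plot_fit(self, ax=None, horizon: Optional[float] = None):
        """Observed volumes with the posterior median curve and 95% band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tmax = horizon or float(self.model.t.max()) * 1.1
        grid = np.linspace(min(0.0, self.model.t.min()), tmax, 200)
        band = self.predict(grid)
        ax.fill_between(band.t_days, band.lo, band.hi, alpha=0.25,
                        label="95% band")
        ax.plot(band.t_days, band["median"], label="posterior median")
        ax.plot(self.model.t, self.model.v, "o", label="observed")
        ax.set_xlabel("days from treatment start")
        ax.set_ylabel(f"{self.model.measure.value} (cm³)")
        ax.legend()
        return ax


class CohortGrowthModel:
    """Joint cohort fit with a single shared growth rate λ.

    Low-grade gliomas grow slowly and at broadly similar intrinsic rates, so
    λ is treated as common to all participants while the treatment response
    (γ₀), resistance onset (ε) and baseline volume are participant-specific.
    The sampled vector is (log λ, γ₀⁽¹⁾, log ε⁽¹⁾, log V_b⁽¹⁾, γ₀⁽²⁾, …).
    """

    def __init__(
        self,
        series_list: Sequence[ParticipantSeries],
        measure: Measure = Measure.SOLID_VOLUME,
        noise_cv: float = 0.10,
        priors: Optional[GrowthPriors] = None,
    ) -> None:
        if len(series_list) == 0:
            raise ValueError("empty cohort")
        self.priors = priors or GrowthPriors()
        self.noise_cv = float(noise_cv)
        # sub-models do the per-series bookkeeping; λ injected per call
        self.submodels = [
            TumorGrowthModel(s, measure=measure, noise_cv=noise_cv,
                             priors=self.priors, fix_lam=None)
            for s in series_list
        ]
        self.n_dim = 1 + 3 * len(self.submodels)

    def log_posterior(self, theta: np.ndarray) -> float:
        pri = self.priors
        log_lam = theta[0]
        lam = math.exp(log_lam)
        if not (pri.lam_bounds[0] <= lam <= pri.lam_bounds[1]):
            return -math.inf
        total = 0.0
        for i, m in enumerate(self.submodels):
            sub = theta[1 + 3 * i: 4 + 3 * i]
            m_fixed = m.fix_lam
            m.fix_lam = lam
            try:
                lp = m.log_posterior(sub)
            finally:
                m.fix_lam = m_fixed
            if not math.isfinite(lp):
                return -math.inf
            total += lp
        return total

    def fit(
        self, n_walkers: Optional[int] = None, n_steps: int = 1500, seed: int = 0
    ) -> "CohortGrowthResults":
        rng = np.random.default_rng(seed)
        n_walkers = n_walkers or max(2 * self.n_dim + 2, 16)
        pri = self.priors
        cols = [rng.uniform(np.log(pri.lam_bounds[0]), np.log(pri.lam_bounds[1]),
                            n_walkers)]
        for m in self.submodels:
            cols.append(rng.uniform(*pri.gamma0_bounds, n_walkers))
            cols.append(rng.uniform(np.log(pri.eps_bounds[0]),
                                    np.log(pri.eps_bounds[1]), n_walkers))
            cols.append(m._log_vb0 + pri.vb_cv * rng.standard_normal(n_walkers))
        p0 = np.column_stack(cols)
        sampler = emcee.EnsembleSampler(n_walkers, self.n_dim, self.log_posterior)
        state = np.random.RandomState(int(rng.integers(0, 2**31 - 1)))
        sampler.random_state = state.get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        chain = sampler.get_chain(discard=n_steps // 2, flat=True)
        return CohortGrowthResults(self, chain,
                                   float(np.mean(sampler.acceptance_fraction)))


class CohortGrowthResults:
    """Posterior of the joint shared-λ cohort fit."""

    def __init__(self, model: CohortGrowthModel, chain: np.ndarray,
                 acceptance_fraction: float) -> None:
        self.model = model
        self.chain = chain
        self.acceptance_fraction = acceptance_fraction
        self.lam_samples = np.exp(chain[:, 0])

    @property
    def lam_median(self) -> float:
        return float(np.median(self.lam_samples))

    def participant_results(self, i: int) -> TumorGrowthResults:
        """Per-participant results with λ taken from the joint posterior."""
        sub = self.chain[:, 1 + 3 * i: 4 + 3 * i]
        m = self.model.submodels[i]
        params = np.column_stack([
            self.lam_samples,
            sub[:, 0],
            np.exp(sub[:, 1]),
            np.exp(sub[:, 2]),
        ])
        return TumorGrowthResults(m, params, self.acceptance_fraction,
                                  n_steps=0, n_boot=1, seed=0)


def compare_responders(
    fits: Sequence[TumorGrowthResults], cutoff: float = 365.0
) -> pd.DataFrame:
    """Compare fitted parameters between responding and resistant series.

    A fit is "responding" when its posterior-median t_Vmin is at or above the
    cutoff (one year by default) and "resistant" otherwise.  Each parameter's
    posterior medians are compared between groups with a Wilcoxon rank-sum
    test; with an empty group the tests are skipped (p = NaN).
    """
    from .concordance import wilcoxon_rank_sum

    med_tv = np.array([f.t_vmin_median for f in fits])
    responding = med_tv >= cutoff
    rows = []
    names = TumorGrowthResults.PARAM_NAMES
    for j, name in enumerate(names):
        med = np.array([float(np.median(f.params[:, j])) for f in fits])
        a, b = med[responding], med[~responding]
        if len(a) == 0 or len(b) == 0:
            stat, p = math.nan, math.nan
        else:
            stat, p = wilcoxon_rank_sum(a, b)
        rows.append({
            "param": name,
            "median_responding": float(np.median(a)) if len(a) else math.nan,
            "median_resistant": float(np.median(b)) if len(b) else math.nan,
            "n_responding": int(responding.sum()),
            "n_resistant": int((~responding).sum()),
            "statistic": stat,
            "p_value": p,
        })
    return pd.DataFrame(rows).set_index("param")
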