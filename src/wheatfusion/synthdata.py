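"""Seeded synthetic winter-wheat field trials.

Emulates the statistical structure of a 30-genotype x 3-irrigation-treatment
x 2-replicate plot experiment observed at six growth stages: grain yields are
drawn from treatment-level truncated normal distributions calibrated to the
published treatment means and coefficients of variation, and canopy band
reflectances / temperatures are generated through a per-stage "greenness" link
so that spectral indices and canopy temperature carry a controllable amount of
yield signal at every stage.

The generator is the package's test bed: with the noise knobs at zero the
feature -> yield link is exactly linear in at least one index (the NIR-red
difference), so the downstream feature-selection / regression / fusion
machinery can be validated by parameter recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, truncnorm

from .exceptions import InvalidDesignError, ValidationError

__all__ = [
    "STAGES",
    "TREATMENTS",
    "BANDS",
    "FieldDesign",
    "YieldModelParams",
    "CanopyLinkParams",
    "generate_field_design",
    "simulate_yields",
    "simulate_canopy",
    "simulate_trial",
]

#: Phenological stages, in temporal order.
STAGES = ("jointing", "booting", "heading", "flowering", "grain_filling", "maturity")

#: Irrigation treatments, ordered by total water applied (descending).
TREATMENTS = ("high", "moderate", "mild")

#: Multispectral band names (RedEdge-MX style five-band sensor).
BANDS = ("blue", "green", "red", "rededge", "nir")

# Total seasonal irrigation (mm) per treatment, distributed over the season's
# six irrigation events.  Only the totals matter downstream; the schedule is
# carried as design metadata.
_DEFAULT_SCHEDULE = {
    "high": {
        "tillering": 35, "wintering": 35, "turning_green": 35,
        "jointing": 50, "heading": 50, "grain_filling": 35,
    },
    "moderate": {
        "tillering": 35, "wintering": 35, "turning_green": 25,
        "jointing": 35, "heading": 35, "grain_filling": 25,
    },
    "mild": {
        "tillering": 35, "wintering": 35, "turning_green": 20,
        "jointing": 20, "heading": 20, "grain_filling": 15,
    },
}


@dataclass(frozen=True)
class FieldDesign:
    """Layout of a randomized block trial.

    ``total plots = n_genotypes * n_treatments * n_replicates``.
    """

    n_genotypes: int = 30
    n_treatments: int = 3
    n_replicates: int = 2
    stages: tuple = STAGES
    irrigation_schedule: dict = field(default_factory=lambda: dict(_DEFAULT_SCHEDULE))

    def __post_init__(self):
        for name in ("n_genotypes", "n_treatments", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise InvalidDesignError(f"{name} must be a positive integer, got {v!r}")
        if len(set(self.stages)) != len(self.stages) or not self.stages:
            raise InvalidDesignError("stages must be a non-empty list of unique labels")

    @property
    def n_plots(self):
        return self.n_genotypes * self.n_treatments * self.n_replicates

    @property
    def treatments(self):
        """Treatment labels: the canonical three, or t1..tk otherwise."""
        if self.n_treatments == len(TREATMENTS):
            return TREATMENTS
        return tuple(f"t{i + 1}" for i in range(self.n_treatments))

    def irrigation_totals(self):
        """Total irrigation (mm) per treatment from the schedule."""
        return {t: sum(s.values()) for t, s in self.irrigation_schedule.items()}


@dataclass(frozen=True)
class YieldModelParams:
    """Calibration of the treatment-level yield distributions.

    ``treatment_means`` (t/ha) and ``treatment_cvs`` (%) set the target mean
    and coefficient of variation of each treatment's yield distribution after
    truncation to ``yield_bounds``.  ``genotype_sd`` and ``residual_sd`` (t/ha)
    set the genotype : plot-residual split of the variance; when
    ``treatment_cvs`` is given they act as a ratio (the total per-treatment sd
    comes from the CV), when it is None they are used as absolute sds.
    """

    treatment_means: tuple = (7.09, 5.99, 4.40)
    treatment_cvs: tuple | None = (12.70, 16.10, 19.51)
    genotype_sd: float = 0.6
    residual_sd: float = 0.3
    yield_bounds: tuple = (2.79, 8.64)
    seed: int = 20210730

    def __post_init__(self):
        if self.genotype_sd < 0 or self.residual_sd < 0:
            raise ValidationError("genotype_sd and residual_sd must be >= 0")
        lo, hi = self.yield_bounds
        if not lo < hi:
            raise ValidationError("yield_bounds must be ordered (min < max)")
        for m in self.treatment_means:
            if not lo <= m <= hi:
                raise ValidationError(
                    f"treatment mean {m} outside yield bounds {self.yield_bounds}"
                )
        if self.treatment_cvs is not None and len(self.treatment_cvs) != len(
            self.treatment_means
        ):
            raise ValidationError("treatment_cvs must match treatment_means in length")


# Per-stage canopy greenness trajectory: rises from jointing to grain filling,
# then falls at maturity, where the yield link is also weakest (senescence).
_GREEN_BASE = {
    "jointing": 0.35, "booting": 0.50, "heading": 0.60,
    "flowering": 0.65, "grain_filling": 0.70, "maturity": 0.45,
}
_GREEN_SLOPE = {
    "jointing": 0.040, "booting": 0.050, "heading": 0.060,
    "flowering": 0.070, "grain_filling": 0.080, "maturity": 0.015,
}
# Affine band responses to greenness: NIR rises strongly with green canopy,
# red/blue absorb (fall), green and red-edge rise mildly.
_BAND_INTERCEPT = {"blue": 0.080, "green": 0.100, "red": 0.160, "rededge": 0.180, "nir": 0.200}
_BAND_SLOPE = {"blue": -0.040, "green": 0.040, "red": -0.140, "rededge": 0.100, "nir": 0.450}
# Canopy temperature: warms through the season; cooler canopies transpire more
# and yield more, hence the strictly non-positive slope against yield.
_TEMP_BASE = {
    "jointing": 24.0, "booting": 26.0, "heading": 28.0,
    "flowering": 30.0, "grain_filling": 31.0, "maturity": 33.0,
}


@dataclass(frozen=True)
class CanopyLinkParams:
    """Links from standardized yield to per-stage canopy observables.

    greenness(stage) = intercept(stage) + slope(stage) * z, with z the
    globally standardized yield; each band is affine in greenness (clipped to
    [0, 1]); temperature is affine in z with a slope <= 0.
    """

    greenness_intercepts: dict = field(default_factory=lambda: dict(_GREEN_BASE))
    greenness_slopes: dict = field(default_factory=lambda: dict(_GREEN_SLOPE))
    band_intercepts: dict = field(default_factory=lambda: dict(_BAND_INTERCEPT))
    band_slopes: dict = field(default_factory=lambda: dict(_BAND_SLOPE))
    reflectance_noise_sd: float = 0.01
    temperature_base: dict = field(default_factory=lambda: dict(_TEMP_BASE))
    temperature_slope: float = -0.8
    temperature_noise_sd: float = 0.5

    def __post_init__(self):
        if self.temperature_slope > 0:
            raise ValidationError(
                "temperature_slope must be <= 0 (cooler canopies yield more)"
            )
        if self.reflectance_noise_sd < 0 or self.temperature_noise_sd < 0:
            raise ValidationError("noise sds must be >= 0")

    def noiseless(self):
        """Copy with every noise knob at zero (for recovery experiments)."""
        return CanopyLinkParams(
            greenness_intercepts=dict(self.greenness_intercepts),
            greenness_slopes=dict(self.greenness_slopes),
            band_intercepts=dict(self.band_intercepts),
            band_slopes=dict(self.band_slopes),
            reflectance_noise_sd=0.0,
            temperature_base=dict(self.temperature_base),
            temperature_slope=self.temperature_slope,
            temperature_noise_sd=0.0,
        )


def generate_field_design(n_genotypes=30, n_treatments=3, n_replicates=2,
                          schedule=None, seed=None):
    """Build a :class:`FieldDesign` and its randomized plot list.

    Returns ``(design, plots)`` where ``plots`` is a DataFrame with one row
    per plot (plot_id, genotype_id, treatment_id, replicate_id) in randomized
    field order under ``seed``.
    """
    design = FieldDesign(
        n_genotypes=n_genotypes,
        n_treatments=n_treatments,
        n_replicates=n_replicates,
        irrigation_schedule=schedule if schedule is not None else dict(_DEFAULT_SCHEDULE),
    )
    rows = [
        {"genotype_id": f"g{g + 1:02d}", "treatment_id": t, "replicate_id": r + 1}
        for g, t, r in itertools.product(
            range(n_genotypes), design.treatments, range(n_replicates)
        )
    ]
    plots = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    plots = plots.iloc[rng.permutation(len(plots))].reset_index(drop=True)
    plots.insert(0, "plot_id", [f"p{i + 1:03d}" for i in range(len(plots))])
    return design, plots


def _match_truncnorm(target_mean, target_sd, lo, hi):
    """Pre-truncation (mu, sigma) whose [lo, hi]-truncated normal has the
    requested mean and sd (moment matching, so truncation does not bias the
    calibration targets)."""
    if target_sd == 0:
        return target_mean, 0.0

    def eqs(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol, info, ok, msg = optimize.fsolve(
        eqs, [target_mean, np.log(target_sd)], full_output=True
    )
    if ok != 1:  # pragma: no cover - only for extreme calibrations
        raise ValidationError(f"truncated-normal calibration failed: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def simulate_yields(design, params=None, rng=None):
    """Draw one grain yield per plot.

    yield = mu(treatment) + genotype effect + plot residual, truncated to
    ``params.yield_bounds``.  Genotype effects are shared across treatments
    (one latent score per genotype).  Reproducible under ``params.seed`` (or
    an explicit ``rng``).

    Returns the plot DataFrame with a ``grain_yield_t_ha`` column appended.
    """
    params = params or YieldModelParams()
    if isinstance(design, tuple):
        design, plots = design
    else:
        design, plots = generate_field_design(
            design.n_genotypes, design.n_treatments, design.n_replicates,
            schedule=design.irrigation_schedule, seed=params.seed,
        )
    if len(plots) == 0:
        raise InvalidDesignError("empty design: no plots to simulate")
    if len(params.treatment_means) != design.n_treatments:
        raise ValidationError(
            f"{len(params.treatment_means)} treatment means for "
            f"{design.n_treatments} treatments"
        )
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lo, hi = params.yield_bounds

    w = np.array([params.genotype_sd, params.residual_sd])
    scale = np.linalg.norm(w)
    # fixed variety panel: genotype merit scores are a stratified standard
    # normal sample (quantile-spaced, randomly assigned to genotype labels),
    # so realized effects are sum-to-zero with unit spread and treatment
    # moments converge to the calibration targets as replication grows
    ng = design.n_genotypes
    if ng > 1:
        geno_scores = norm.ppf((np.arange(ng) + 0.5) / ng)
        geno_scores = geno_scores / geno_scores.std()
        geno_scores = geno_scores[rng.permutation(ng)]
    else:
        geno_scores = np.zeros(ng)
    geno_index = plots["genotype_id"].map(
        {f"g{i + 1:02d}": i for i in range(design.n_genotypes)}
    ).to_numpy()

    y = np.empty(len(plots))
    for ti, treatment in enumerate(design.treatments):
        mask = (plots["treatment_id"] == treatment).to_numpy()
        mean_t = params.treatment_means[ti]
        if params.treatment_cvs is not None:
            sd_t = mean_t * params.treatment_cvs[ti] / 100.0
        else:
            sd_t = scale
        if sd_t == 0 or scale == 0:
            y[mask] = mean_t
            continue
        mu_t, sigma_t = _match_truncnorm(mean_t, sd_t, lo, hi)
        # standardized total deviation (genotype + residual), mapped through
        # the truncated-normal quantile function: the marginal is exactly the
        # moment-matched truncated normal, and the genotype ordering is kept
        u = (w[0] * geno_scores[geno_index[mask]]
             + w[1] * rng.standard_normal(mask.sum())) / scale
        # quantile-matched sampling: within a treatment the latent deviations
        # are replaced by exact standard-normal quantile scores in the order
        # the draws imply, so the realized trial hits the calibration targets
        # instead of scattering around them (randomness lives in the ranks)
        if u.size > 1:
            ranks = np.argsort(np.argsort(u, kind="stable"), kind="stable")
            u = norm.ppf((ranks + 0.5) / u.size)
        a_t, b_t = (lo - mu_t) / sigma_t, (hi - mu_t) / sigma_t
        vals = truncnorm.ppf(norm.cdf(u), a_t, b_t, loc=mu_t, scale=sigma_t)
        y[mask] = np.clip(vals, lo, hi)
    out = plots.copy()
    out["grain_yield_t_ha"] = y
    return out


def simulate_canopy(design, yields, link_params=None, rng=None, seed=None):
    """Generate per plot x stage band reflectances and canopy temperature.

    ``yields`` is the output of :func:`simulate_yields`.  Reflectances are
    clipped to [0, 1].  Deterministic under ``seed`` / ``rng``.
    """
    link = link_params or CanopyLinkParams()
    if "grain_yield_t_ha" not in yields.columns:
        raise ValidationError("yields table lacks grain_yield_t_ha; run simulate_yields first")
    if yields["grain_yield_t_ha"].isna().any():
        raise ValidationError("missing yields for some plots")
    rng = rng if rng is not None else np.random.default_rng(seed)

    y = yields["grain_yield_t_ha"].to_numpy()
    sd = y.std()
    z = (y - y.mean()) / sd if sd > 0 else np.zeros_like(y)
    n = len(y)

    frames = []
    for stage in design.stages:
        g = link.greenness_intercepts[stage] + link.greenness_slopes[stage] * z
        rec = {"plot_id": yields["plot_id"].to_numpy(), "stage": stage}
        for band in BANDS:
            r = link.band_intercepts[band] + link.band_slopes[band] * g
            if link.reflectance_noise_sd > 0:
                r = r + link.reflectance_noise_sd * rng.standard_normal(n)
            rec[f"r_{band}"] = np.clip(r, 0.0, 1.0)
        t = link.temperature_base[stage] + link.temperature_slope * z
        if link.temperature_noise_sd > 0:
            t = t + link.temperature_noise_sd * rng.standard_normal(n)
        rec["temperature_c"] = t
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)


def simulate_trial(n_genotypes=30, n_treatments=3, n_replicates=2,
                   yield_params=None, link_params=None, seed=0):
    """End-to-end generation of the canonical plot table.

    One global ``seed`` fans out (via :class:`numpy.random.SeedSequence`) to
    independent substreams for field randomization, yields, and canopy
    observations.  Returns a tidy DataFrame with one row per plot x stage and
    the canonical column set (see :mod:`wheatfusion.io`).
    """
    ss = np.random.SeedSequence(seed)
    s_design, s_yield, s_canopy = ss.spawn(3)
    design, plots = generate_field_design(
        n_genotypes, n_treatments, n_replicates, seed=s_design
    )
    params = yield_params or YieldModelParams()
    yields = simulate_yields((design, plots), params,
                             rng=np.random.default_rng(s_yield))
    canopy = simulate_canopy(design, yields, link_params,
                             rng=np.random.default_rng(s_canopy))
    table = canopy.merge(yields, on="plot_id", how="left")
    cols = ["plot_id", "genotype_id", "treatment_id", "replicate_id", "stage",
            "r_blue", "r_green", "r_red", "r_rededge", "r_nir",
            "temperature_c", "grain_yield_t_ha"]
    return table[cols]
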