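"""Synthetic survey generator.

Produces plot- and household-level tables whose seven cover measurements
reproduce the experiment's dependence structure (Spearman matrix) and
marginal summaries (medians, upper-tail share), with covariates that
drive measurement error in the published directions.

Marginals
---------
The benchmark (line transect, ``lt``) is ``100 * Beta(a, b)`` with shape
parameters frozen in :mod:`rescover.config` so that the median is 60 %
and 4 % of plots exceed 90 % cover.  Every other method's margin is a
strictly monotone power transform of the same Beta quantile,

    Q_m(u) = 100 * Q_beta(u) ** gamma_m,   gamma_m = ln(med_m/100) / ln(0.6),

which hits the published median offsets exactly (m1 thirty points below
the benchmark, m2 two and a half above m1, m5 five below, m6 identical)
while keeping the support (0, 100) and avoiding ties.

Measurement error
-----------------
Covariates never shift a method's margin; they act through two
margin-preserving channels.

*Attenuation*: each survey method's latent normal score is blended with
fresh noise, ``z' = sqrt(1-lam_i) z + sqrt(lam_i) eps``, where the noise
load ``lam_i`` is a logistic function of log field size (+), distance
(+, interviewee methods) and slope severity (−).

*Misreporting*: for the interviewee methods (m1, m3) the respondent
additionally reports the wrong side of the 30 % adoption threshold with
probability ``pi_i`` (log-linear in the same covariates): the latent
percentile is reflected across the threshold's quantile by a
measure-preserving swap.  Threshold misclassification therefore rises
with field size and distance and falls with slope, the sign pattern the
linear probability models in :mod:`rescover.compare` detect.
"""

from __future__ import annotations



import numpy as np
import pandas as pd
from scipy import stats

from . import config as cfg
from .config import GeneratorConfig
from .copula import nearest_positive_definite


# ---------------------------------------------------------------------------
# marginals
# ---------------------------------------------------------------------------

def method_gamma(method: str) -> float:
    """Power-transform exponent linking a method's margin to the benchmark's."""
    med = cfg.METHOD_MEDIANS[method]
    return float(np.log(med / 100.0) / np.log(cfg.LT_MEDIAN / 100.0))


def marginal_ppf(method: str):
    """Quantile function (percent scale) of a method's marginal distribution."""
    g = method_gamma(method)

    def ppf(u: np.ndarray) -> np.ndarray:
        x = stats.beta.ppf(u, cfg.LT_BETA_A, cfg.LT_BETA_B)
        return 100.0 * np.power(x, g)

    return ppf


def visual_aid_category(percent: np.ndarray) -> np.ndarray:
    """Six-level visual-aid category (1..6) for a continuous cover percent."""
    return np.searchsorted(np.asarray(cfg.VISUAL_AID_CUTS), np.asarray(percent)) + 1


def visual_aid_percent(category: np.ndarray) -> np.ndarray:
    """Cover percent reported for each visual-aid category."""
    vals = np.asarray(cfg.VISUAL_AID_VALUES)
    return vals[np.asarray(category, dtype=int) - 1]


# ---------------------------------------------------------------------------
# joint draws
# ---------------------------------------------------------------------------

def method_correlation_matrix() -> np.ndarray:
    """Gaussian-copula correlation matrix implied by the Spearman targets.

    Entries are mapped pairwise through ``2 sin(pi rho_s / 6)`` and the
    matrix is repaired to the nearest positive-definite correlation
    matrix (the pairwise map does not guarantee joint feasibility).
    """
    spear = cfg.spearman_matrix_targets()
    pear = 2.0 * np.sin(np.pi * spear / 6.0)
    np.fill_diagonal(pear, 1.0)
    return nearest_positive_definite(pear)


def draw_joint_uniforms(n: int, rng: np.random.Generator,
                        corr: np.ndarray | None = None) -> np.ndarray:
    """Draw n rows of copula uniforms for all seven methods (METHODS order)."""
    r = method_correlation_matrix() if corr is None else corr
    chol = np.linalg.cholesky(r)
    z = rng.standard_normal((n, r.shape[0])) @ chol.T
    return stats.norm.cdf(z)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _draw_households(n: int, n_ea: int, rng: np.random.Generator) -> pd.DataFrame:
    ea = 1 + (np.arange(n) % n_ea)
    age = np.clip(rng.normal(cfg.MEAN_HEAD_AGE, 12.0, n), 18, 90).round(0)
    edu = np.clip(rng.poisson(cfg.MEAN_HEAD_EDUCATION, n), 0, 16)
    farm = np.clip(rng.lognormal(np.log(cfg.MEAN_FARM_SIZE_HA) - 0.5 * 0.6**2, 0.6, n), 0.05, None)
    herd = np.clip(rng.lognormal(np.log(cfg.MEAN_HERD_TLU) - 0.5 * 0.7**2, 0.7, n), 0.0, None)
    return pd.DataFrame({
        "household_id": np.arange(1, n + 1),
        "ea_id": ea,
        "head_sex": np.where(rng.random(n) < cfg.SHARE_MALE_HEAD, "male", "female"),
        "head_age": age,
        "head_education": edu,
        "training": rng.random(n) < cfg.SHARE_TRAINED,
        "farm_size": farm.round(3),
        "herd_tlu": herd.round(3),
        "phones": rng.poisson(cfg.MEAN_PHONES, n),
    })


def _draw_plot_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    # log-normal field size / distance centred on the published means
    fs_sigma, d_sigma = 0.5, 0.55
    field_size = rng.lognormal(np.log(cfg.MEAN_FIELD_SIZE_M2) - 0.5 * fs_sigma**2, fs_sigma, n)
    distance = rng.lognormal(np.log(cfg.MEAN_DISTANCE_M) - 0.5 * d_sigma**2, d_sigma, n)
    return pd.DataFrame({
        "field_size": field_size.round(1),
        "distance": distance.round(1),
        "slope": rng.choice(cfg.SLOPE_LEVELS, size=n, p=cfg.SLOPE_SHARES),
        "soil": rng.choice(cfg.SOIL_TYPES, size=n, p=cfg.SOIL_SHARES),
        "residue_type": rng.choice(cfg.RESIDUE_TYPES, size=n, p=cfg.RESIDUE_SHARES),
        "rocks_gt20": rng.random(n) < 0.20,
    })


_SLOPE_SEVERITY = {"flat": 0.0, "slight": 1.0, "steep": 2.0}
_MEAN_SEVERITY = 0.65   # under the default flat/slight/steep shares


def _noise_load(conf: GeneratorConfig, plots: pd.DataFrame, method: str) -> np.ndarray:
    """Per-plot noise load lam in (0, 1) for a survey method's latent score.

    Log-odds of the load increase with standardised log field size and
    (for interviewee methods) distance, and decrease with slope
    severity.  m6 additionally loads on vertisol soils; m5 is left
    unmodulated (its error process is physical, not perceptual, and is
    emulated by the imagery modules).
    """
    n = len(plots)
    eta = np.full(n, conf.noise_base)
    if method in ("m1", "m2", "m3", "m4"):
        zfs = _standardize(np.log(plots["field_size"].to_numpy()))
        sev = plots["slope"].map(_SLOPE_SEVERITY).to_numpy()
        eta = eta + conf.noise_field_size * zfs - conf.noise_slope * (sev - _MEAN_SEVERITY)
        if method in ("m1", "m3"):
            zd = _standardize(np.log(plots["distance"].to_numpy()))
            eta = eta + conf.noise_distance * zd
    elif method == "m6":
        eta = eta + conf.noise_vertisol_m6 * (plots["soil"].to_numpy() == "vertisol")
    else:
        eta = np.full(n, -4.0)  # m5: negligible covariate modulation
    return 1.0 / (1.0 + np.exp(-eta))


def _misreport_prob(conf: GeneratorConfig, plots: pd.DataFrame) -> np.ndarray:
    """Probability that an interviewee reports the wrong adoption side.

    Log-linear in standardised log field size (+), log distance (+) and
    slope severity (−), clipped to [0, 0.9].
    """
    zfs = _standardize(np.log(plots["field_size"].to_numpy()))
    zd = _standardize(np.log(plots["distance"].to_numpy()))
    sev = plots["slope"].map(_SLOPE_SEVERITY).to_numpy()
    g = (conf.misreport_field_size * zfs + conf.misreport_distance * zd
         - conf.misreport_slope * (sev - _MEAN_SEVERITY))
    return np.clip(conf.misreport_base * np.exp(g), 0.0, 0.9)


def _threshold_quantile(method: str, threshold: float = 30.0) -> float:
    """Copula-uniform quantile at which a method's latent percent crosses
    the adoption threshold (for m3/m4 the relevant latent cut is the
    visual-aid boundary below the threshold category)."""
    g = method_gamma("m1" if method == "m3" else method)
    cut = threshold
    if method in cfg.DISCRETE_METHODS:
        # adoption flips where the reported category value crosses the
        # threshold: the latent cut is the visual-aid boundary between
        # the last sub-threshold and first supra-threshold categories
        vals = np.asarray(cfg.VISUAL_AID_VALUES)
        k = int(np.searchsorted(vals, threshold))
        cut = cfg.VISUAL_AID_CUTS[k - 1]
    x = (cut / 100.0) ** (1.0 / g)
    return float(stats.beta.cdf(x, cfg.LT_BETA_A, cfg.LT_BETA_B))


def _swap_across(u: np.ndarray, swap: np.ndarray, q: float) -> np.ndarray:
    """Measure-preserving reflection of uniforms across the quantile q."""
    out = u.copy()
    low = u < q
    out[swap & low] = q + (u[swap & low] / q) * (1.0 - q)
    out[swap & ~low] = (u[swap & ~low] - q) / (1.0 - q) * q
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate_survey(conf: GeneratorConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic survey: (plots, households) tables.

    Returns
    -------
    plots : DataFrame
        One row per plot with the seven measurements (``m3``/``m4`` both
        as category 1..6 and mapped percent), covariates and ids.  ``m5``
        and ``m6`` are missing (NaN) outside their subsamples.
    households : DataFrame
        One row per household with head and wealth covariates.
    """
    conf = conf or GeneratorConfig()
    conf.validate()
    rng = np.random.default_rng(conf.seed)

    households = _draw_households(conf.n_households, conf.n_ea, rng)

    # household-to-plot assignment: fill households with max_plots each
    # until the plot total is reached, remainder get one fewer
    n_two = conf.n_plots - conf.n_households
    hh_ids = np.concatenate([
        np.repeat(households["household_id"].to_numpy()[:n_two], conf.max_plots_per_household),
        households["household_id"].to_numpy()[n_two:],
    ])[: conf.n_plots]
    n = conf.n_plots

    plots = _draw_plot_covariates(n, rng)
    plots.insert(0, "ea_id", households.set_index("household_id").loc[hh_ids, "ea_id"].to_numpy())
    plots.insert(0, "household_id", hh_ids)
    plots.insert(0, "plot_id", np.arange(1, n + 1))

    # latent scores: benchmark plus correlated method scores, then
    # per-plot attenuation for the error-prone methods
    corr = method_correlation_matrix()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(cfg.METHODS))) @ chol.T
    for j, m in enumerate(cfg.METHODS):
        if m == "lt":
            continue
        lam = _noise_load(conf, plots, m)
        z[:, j] = np.sqrt(1.0 - lam) * z[:, j] + np.sqrt(lam) * rng.standard_normal(n)
    u = stats.norm.cdf(z)

    # interviewee misreport channel: swap across the adoption threshold
    pi = _misreport_prob(conf, plots)
    for m in ("m1", "m3"):
        j = cfg.METHODS.index(m)
        u[:, j] = _swap_across(u[:, j], rng.random(n) < pi, _threshold_quantile(m))

    for j, m in enumerate(cfg.METHODS):
        vals = marginal_ppf(m)(u[:, j])
        if m in cfg.DISCRETE_METHODS:
            cat = visual_aid_category(vals)
            plots[m + "_cat"] = cat
            plots[m] = visual_aid_percent(cat)
        else:
            plots[m] = vals.round(4)

    # missingness completely at random, exact subset sizes
    for m, keep in (("m5", conf.n_m5), ("m6", conf.n_m6)):
        drop = rng.choice(n, size=n - keep, replace=False)
        plots.loc[plots.index[drop], m] = np.nan

    order = ["plot_id", "household_id", "ea_id",
             "lt", "m1", "m2", "m3_cat", "m3", "m4_cat", "m4", "m5", "m6",
             "field_size", "distance", "slope", "soil", "residue_type", "rocks_gt20"]
    return plots[order], households


def apply_decay(lt_values: np.ndarray, decay_mean: float = 0.25,
                decay_sd: float = 0.10, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Simulate a repeated line-transect visit with proportional residue decay.

    Each plot's cover is multiplied by ``1 - d`` with ``d`` drawn from a
    Beta distribution with mean ``decay_mean`` and standard deviation
    ``decay_sd`` (``decay_sd=0`` gives the deterministic reduction), so
    the second visit never exceeds the first and the mean proportional
    reduction equals ``decay_mean`` — the repeat-visit consistency check
    of the field protocol (25 % average reduction over two months).
    """
    if not 0.0 <= decay_mean < 1.0:
        raise ValueError("decay_mean must lie in [0, 1)")
    x = np.asarray(lt_values, dtype=float)
    if decay_mean == 0.0 or decay_sd == 0.0:
        return x * (1.0 - decay_mean)
    var = decay_sd**2
    maxvar = decay_mean * (1.0 - decay_mean)
    if var >= maxvar:
        raise ValueError("decay_sd too large for a Beta-distributed reduction")
    k = maxvar / var - 1.0
    a, b = decay_mean * k, (1.0 - decay_mean) * k
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = rng.beta(a, b, size=x.shape)
    return x * (1.0 - d)
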