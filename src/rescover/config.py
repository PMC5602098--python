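"""Study-design constants and generator configuration.

The synthetic survey emulates a methodological experiment in which seven
measurements of crop residue cover were taken on the same plots:

======  =====================================================  ====
method  protocol                                                 N
======  =====================================================  ====
lt      line transect (30 m rope, 4 corner transects) — benchmark  314
m1      interviewee percentage estimate, away from field          314
m2      enumerator percentage estimate, visiting the field        314
m3      interviewee visual aid (six reference photos)             314
m4      enumerator visual aid (six reference photos)              314
m5      drone RGB photo, excess-green segmentation                182
m6      Landsat NDTI, scaled 0-100                                251
======  =====================================================  ====

All defaults below encode the published summary statistics of that
experiment (sample sizes, rank-correlation matrix, marginal medians and
tail shares, covariate means).  They are the generator's study
conditions, not tuning knobs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

#: Methods in canonical order.  ``lt`` is the benchmark.
METHODS = ("lt", "m1", "m2", "m3", "m4", "m5", "m6")

#: Methods whose survey instrument yields one of six ordered categories.
DISCRETE_METHODS = ("m3", "m4")

#: Spearman rank-correlation targets between measurement methods
#: (lower triangle of the published 7x7 matrix; the m5--m6 entry was
#: not statistically distinguishable from zero).
SPEARMAN_TARGETS: dict[tuple[str, str], float] = {
    ("lt", "m1"): 0.60,
    ("lt", "m2"): 0.73,
    ("lt", "m3"): 0.59,
    ("lt", "m4"): 0.76,
    ("lt", "m5"): -0.25,
    ("lt", "m6"): 0.57,
    ("m1", "m2"): 0.68,
    ("m1", "m3"): 0.76,
    ("m1", "m4"): 0.62,
    ("m1", "m5"): -0.32,
    ("m1", "m6"): 0.42,
    ("m2", "m3"): 0.55,
    ("m2", "m4"): 0.75,
    ("m2", "m5"): -0.16,
    ("m2", "m6"): 0.39,
    ("m3", "m4"): 0.60,
    ("m3", "m5"): -0.26,
    ("m3", "m6"): 0.42,
    ("m4", "m5"): -0.28,
    ("m4", "m6"): 0.47,
    ("m5", "m6"): 0.09,
}

# --- LT marginal -----------------------------------------------------------
# Cover in percent is 100 * Beta(a, b).  The two shape parameters are the
# (unique) solution of the two published constraints
#     median = 60 %   and   P(cover > 90 %) = 4 %
# solved once with a numerical root finder and frozen here.
LT_BETA_A = 3.133872
LT_BETA_B = 2.193869
LT_MEDIAN = 60.0

#: Median cover by method, in percent.  The survey methods sit below the
#: benchmark (m1 by 30 points, m2 only 2.5 above m1, m5 five points
#: below LT); m6's marginal matches the benchmark's.
METHOD_MEDIANS: dict[str, float] = {
    "lt": 60.0,
    "m1": 30.0,
    "m2": 32.5,
    "m3": 30.0,   # convention: interviewee visual aid shares m1's centre
    "m4": 60.0,   # convention: enumerator visual aid tracks the benchmark
    "m5": 55.0,
    "m6": 60.0,
}

# --- six-level visual-aid scheme ------------------------------------------
#: Upper cut points (percent) between the six reference photos.
VISUAL_AID_CUTS = (10.0, 25.0, 40.0, 60.0, 80.0)
#: Cover value (percent) reported for each of the six categories.
VISUAL_AID_VALUES = (5.0, 17.5, 32.5, 50.0, 70.0, 90.0)

# --- covariate population values ------------------------------------------
SOIL_TYPES = ("cambisol", "leptosol", "luvisol", "vertisol")
SOIL_SHARES = (0.146, 0.255, 0.207, 0.392)
RESIDUE_TYPES = ("barley", "maize", "teff", "wheat")
RESIDUE_SHARES = (0.220, 0.280, 0.191, 0.309)
SLOPE_LEVELS = ("flat", "slight", "steep")
SLOPE_SHARES = (0.50, 0.35, 0.15)   # not published; realistic convention
MEAN_FIELD_SIZE_M2 = 2139.0
MEAN_DISTANCE_M = 433.0
MEAN_HEAD_AGE = 46.2
MEAN_HEAD_EDUCATION = 3.3
MEAN_FARM_SIZE_HA = 1.2
MEAN_HERD_TLU = 2.8
SHARE_MALE_HEAD = 0.494
SHARE_TRAINED = 0.50
MEAN_PHONES = 1.0   # not published; realistic convention


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic survey generator.

    The defaults reproduce the experiment's design: 197 households in 5
    enumeration areas contributing 314 plots, with the drone measure
    (m5) present on 182 plots and the satellite measure (m6) on 251.

    ``noise_*`` parameters steer how strongly plot covariates attenuate
    the survey methods' agreement with the benchmark (the measurement
    error process); see the methods note for the mechanism.
    """

    n_households: int = 197
    n_ea: int = 5
    max_plots_per_household: int = 2
    n_plots: int = 314
    n_m5: int = 182
    n_m6: int = 251
    decay_mean: float = 0.25
    decay_sd: float = 0.10
    # attenuation channel: log-odds of the noise load on survey methods
    noise_base: float = -2.2
    noise_field_size: float = 0.8
    noise_distance: float = 0.8
    noise_slope: float = 0.8
    noise_vertisol_m6: float = 0.5
    # misreport channel: interviewee methods swap sides of the adoption
    # threshold with this covariate-modulated probability
    misreport_base: float = 0.25
    misreport_field_size: float = 0.9
    misreport_distance: float = 0.9
    misreport_slope: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots > self.n_households * self.max_plots_per_household:
            raise ValueError(
                f"n_plots={self.n_plots} exceeds n_households x max_plots_per_household "
                f"= {self.n_households * self.max_plots_per_household}"
            )
        if not 0.0 <= self.decay_mean < 1.0:
            raise ValueError("decay_mean must lie in [0, 1)")
        for n in (self.n_m5, self.n_m6):
            if not 0 <= n <= self.n_plots:
                raise ValueError("m5/m6 subset sizes must lie in [0, n_plots]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**json.loads(Path(path).read_text()))


def spearman_matrix_targets() -> "np.ndarray":
    """The 7x7 target Spearman matrix in METHODS order."""
    k = len(METHODS)
    out = np.eye(k)
    for (a, b), rho in SPEARMAN_TARGETS.items():
        i, j = METHODS.index(a), METHODS.index(b)
        out[i, j] = out[j, i] = rho
    return out
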