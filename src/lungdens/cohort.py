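"""Subject-level cohort simulator for BO-vs-control densitometry studies.

Generates tables of clinical covariates, pulmonary function tests (PFTs)
and lung density indices (LDIs) for a control group and a bronchiolitis
obliterans (BO) group. Each variable is drawn from a group-specific
normal marginal (defaults calibrated to the study population this package
targets: 30 controls / 51 BO children) through a Gaussian copula that
imposes configurable rank correlations between LDIs and PFTs, followed by
truncation to each variable's valid range.

Columns and units
-----------------
``subject_id``; ``group`` in {control, BO}; ``age_years``; ``sex`` in
{male, female}; PFTs ``fvc_pct, fev1_pct, fev1_fvc_pct, fef2575_pct,
tlc_pct, rv_pct, dlco_pct, va_l, sraw_pct``; LDIs ``ins_volume_ml,
exp_volume_ml, ins_mld_hu, exp_mld_hu, mldd_hu, ei_volume_pct,
ei_mld_pct, e950_pct, e900_pct, e850_pct, e650_pct, e600_pct``.

Because every variable is sampled from its own marginal, per-subject
arithmetic identities between LDIs (e.g. mldd_hu = exp_mld_hu -
ins_mld_hu) hold only in distribution, not row by row; simulated tables
are calibrated for group-level statistics, not for re-deriving one index
from another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PFT_VARIABLES",
    "LDI_VARIABLES",
    "CohortSimParams",
    "NonPositiveSemidefiniteError",
    "generate_cohort_table",
    "validate_cohort",
]

PFT_VARIABLES = (
    "fvc_pct",
    "fev1_pct",
    "fev1_fvc_pct",
    "fef2575_pct",
    "tlc_pct",
    "rv_pct",
    "dlco_pct",
    "va_l",
    "sraw_pct",
)

LDI_VARIABLES = (
    "ins_volume_ml",
    "exp_volume_ml",
    "ins_mld_hu",
    "exp_mld_hu",
    "mldd_hu",
    "ei_volume_pct",
    "ei_mld_pct",
    "e950_pct",
    "e900_pct",
    "e850_pct",
    "e650_pct",
    "e600_pct",
)

ALL_VARIABLES = PFT_VARIABLES + LDI_VARIABLES

# Group marginals (mean, SD) for the default study population.
CONTROL_MARGINALS: Dict[str, Tuple[float, float]] = {
    "fvc_pct": (95.3, 12.2),
    "fev1_pct": (88.4, 12.3),
    "fev1_fvc_pct": (86.2, 6.0),
    "fef2575_pct": (86.1, 19.3),
    "tlc_pct": (95.0, 10.8),
    "rv_pct": (91.0, 32.6),
    "dlco_pct": (77.6, 15.4),
    "va_l": (3.6, 1.1),
    "sraw_pct": (134.5, 48.9),
    "ins_volume_ml": (2868.4, 1367.1),
    "exp_volume_ml": (1558.2, 761.4),
    "ins_mld_hu": (-788.0, 74.5),
    "exp_mld_hu": (-659.0, 61.6),
    "mldd_hu": (129.0, 54.3),
    "ei_volume_pct": (57.6, 15.0),
    "ei_mld_pct": (83.9, 6.2),
    "e950_pct": (0.0, 0.0),
    "e900_pct": (0.4, 1.0),
    "e850_pct": (3.9, 9.7),
    "e650_pct": (20.7, 10.2),
    "e600_pct": (26.2, 13.8),
}

BO_MARGINALS: Dict[str, Tuple[float, float]] = {
    "fvc_pct": (73.7, 23.3),
    "fev1_pct": (53.2, 21.8),
    "fev1_fvc_pct": (66.7, 18.8),
    "fef2575_pct": (36.6, 32.1),
    "tlc_pct": (99.5, 24.4),
    "rv_pct": (172.8, 84.0),
    "dlco_pct": (67.0, 21.2),
    "va_l": (2.5, 1.0),
    "sraw_pct": (277.4, 253.0),
    "ins_volume_ml": (2393.3, 1308.7),
    "exp_volume_ml": (1674.9, 823.4),
    "ins_mld_hu": (-794.6, 71.0),
    "exp_mld_hu": (-731.4, 69.6),
    "mldd_hu": (63.8, 47.2),
    "ei_volume_pct": (73.3, 18.3),
    "ei_mld_pct": (92.2, 5.9),
    "e950_pct": (0.8, 1.7),
    "e900_pct": (7.7, 11.3),
    "e850_pct": (22.6, 21.6),
    "e650_pct": (10.9, 7.5),
    "e600_pct": (13.8, 9.2),
}

# (median, iqr_low, iqr_high) of age per group; draws are normal with
# scale = IQR / 1.349, truncated to plausible pediatric ages [3, 18].
AGE_DISTRIBUTIONS = {"control": (12.5, 9.0, 15.0), "BO": (9.0, 6.0, 15.0)}
AGE_RANGE_YEARS = (3.0, 18.0)

MALE_FRACTION = {"control": 18 / 30, "BO": 32 / 51}

SPIROMETRY_VARS = ("fvc_pct", "fev1_pct", "fev1_fvc_pct", "fef2575_pct")
PLETHYSMOGRAPHY_VARS = ("tlc_pct", "rv_pct", "sraw_pct", "dlco_pct", "va_l")

# Subject-level probability that a whole PFT modality is missing
# (children too young or too obstructed to complete the manoeuvre).
DEFAULT_MISSINGNESS = {
    "spirometry": {"control": 6 / 30, "BO": 13 / 51},
    "plethysmography": {"control": 6 / 30, "BO": 19 / 51},
}

# Valid ranges for truncation (clip, not resample). Percent-of-predicted
# PFTs may legitimately exceed 100; only ratio/fraction variables are
# bounded above.
VARIABLE_BOUNDS: Dict[str, Tuple[float, float]] = {
    **{v: (0.0, math.inf) for v in PFT_VARIABLES},
    "ins_volume_ml": (0.0, math.inf),
    "exp_volume_ml": (0.0, math.inf),
    "ins_mld_hu": (-1000.0, 100.0),
    "exp_mld_hu": (-1000.0, 100.0),
    "mldd_hu": (-math.inf, math.inf),
    "ei_volume_pct": (0.0, 100.0),
    "ei_mld_pct": (0.0, 100.0),
    **{v: (0.0, 100.0) for v in ("e950_pct", "e900_pct", "e850_pct", "e650_pct", "e600_pct")},
}

# Default rank correlations (Spearman) between LDIs and PFTs, reflecting
# the obstructive physiology the simulator emulates: airflow limitation
# (FEV1) tracks the E/I indices, airway resistance (sRaw) tracks the
# expiratory low-attenuation fractions, hyperinflation (RV) tracks the
# high-attenuation fractions. Kept as disjoint "stars" so the implied
# copula matrix stays positive semi-definite.
DEFAULT_RANK_CORRELATIONS: Dict[Tuple[str, str], float] = {
    ("mldd_hu", "fev1_pct"): 0.5,
    ("ei_mld_pct", "fev1_pct"): -0.5,
    ("ei_volume_pct", "fev1_pct"): -0.45,
    ("e900_pct", "sraw_pct"): 0.6,
    ("e850_pct", "sraw_pct"): 0.5,
    ("e950_pct", "sraw_pct"): 0.4,
    ("exp_mld_hu", "rv_pct"): -0.5,
    ("e600_pct", "rv_pct"): -0.5,
    ("e650_pct", "rv_pct"): -0.5,
}


class NonPositiveSemidefiniteError(ValueError):
    """Raised when the requested correlation structure is not a valid copula."""


def _rank_to_pearson(rho: float) -> float:
    """Copula (Pearson) parameter giving Spearman rank correlation ``rho``."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def _nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Nearest PSD correlation matrix by eigenvalue clipping + renormalisation."""
    w, v = np.linalg.eigh((matrix + matrix.T) / 2.0)
    fixed = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class CohortSimParams:
    """Configuration of the cohort simulator.

    ``rank_correlations`` maps unordered variable pairs to target Spearman
    correlations; the implied Gaussian-copula matrix (identity plus the
    converted pairs) must be symmetric positive semi-definite.
    """

    n_control: int = 30
    n_bo: int = 51
    control_marginals: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(CONTROL_MARGINALS)
    )
    bo_marginals: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(BO_MARGINALS)
    )
    rank_correlations: Mapping[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_CORRELATIONS)
    )
    missingness: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MISSINGNESS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_bo < 1:
            raise ValueError("group sizes must be positive")
        for margins in (self.control_marginals, self.bo_marginals):
            for var in ALL_VARIABLES:
                if var not in margins:
                    raise ValueError(f"missing marginal for variable {var!r}")
                if margins[var][1] < 0:
                    raise ValueError(f"negative SD for variable {var!r}")
        for modality, rates in self.missingness.items():
            for g, r in rates.items():
                if not (0.0 <= r <= 1.0):
                    raise ValueError(f"missingness rate {modality}/{g} outside [0, 1]")
        self.copula_matrix()  # validates PSD

    def copula_matrix(self) -> np.ndarray:
        """Pearson correlation matrix of the Gaussian copula (validated PSD)."""
        idx = {v: i for i, v in enumerate(ALL_VARIABLES)}
        r = np.eye(len(ALL_VARIABLES))
        for (a, b), rho in self.rank_correlations.items():
            if a not in idx or b not in idx:
                raise ValueError(f"unknown variable in correlation pair ({a!r}, {b!r})")
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"rank correlation for ({a}, {b}) outside [-1, 1]")
            r[idx[a], idx[b]] = r[idx[b], idx[a]] = _rank_to_pearson(rho)
        w = np.linalg.eigvalsh(r)
        if w.min() < -1e-10:
            hint = _nearest_psd(r)
            raise NonPositiveSemidefiniteError(
                "requested correlation structure is not positive semi-definite "
                f"(min eigenvalue {w.min():.3e}); nearest valid matrix has entries "
                f"{np.round(hint[np.triu_indices_from(hint, 1)], 3).tolist()} "
                "on the upper triangle — reduce the requested correlations"
            )
        return r


def _truncnorm_loc_for_median(target: float, scale: float, lo: float, hi: float) -> float:
    """Location parameter putting the truncated-normal median at ``target``.

    Truncation to an asymmetric window skews the median away from the
    location; solving for the location keeps the simulated group medians on
    their targets in distribution.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    def median_err(loc: float) -> float:
        pa, pb = norm.cdf((lo - loc) / scale), norm.cdf((hi - loc) / scale)
        return loc + scale * norm.ppf((pa + pb) / 2.0) - target

    return float(brentq(median_err, lo, hi))


def _copula_factor(r: np.ndarray) -> np.ndarray:
    """Square root of a PSD correlation matrix (eigen-based; tolerates singular)."""
    w, v = np.linalg.eigh(r)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _draw_group(
    rng: np.random.Generator,
    n: int,
    group: str,
    marginals: Mapping[str, Tuple[float, float]],
    factor: np.ndarray,
    missingness: Mapping[str, Mapping[str, float]],
    id_prefix: str,
    id_start: int,
) -> pd.DataFrame:
    z = rng.standard_normal((n, len(ALL_VARIABLES))) @ factor.T
    data: Dict[str, np.ndarray] = {}
    for j, var in enumerate(ALL_VARIABLES):
        mean, sd = marginals[var]
        lo, hi = VARIABLE_BOUNDS[var]
        data[var] = np.clip(mean + sd * z[:, j], lo, hi)

    median, q1, q3 = AGE_DISTRIBUTIONS[group]
    scale = (q3 - q1) / 1.349
    loc = _truncnorm_loc_for_median(median, scale, *AGE_RANGE_YEARS)
    a, b = [(x - loc) / scale for x in AGE_RANGE_YEARS]
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    sex = np.where(rng.random(n) < MALE_FRACTION[group], "male", "female")

    df = pd.DataFrame(
        {
            "subject_id": [f"{id_prefix}{id_start + i:03d}" for i in range(n)],
            "group": group,
            "age_years": np.round(age, 1),
            "sex": sex,
            **data,
        }
    )
    for modality, variables in [
        ("spirometry", SPIROMETRY_VARS),
        ("plethysmography", PLETHYSMOGRAPHY_VARS),
    ]:
        rate = missingness.get(modality, {}).get(group, 0.0)
        drop = rng.random(n) < rate
        df.loc[drop, list(variables)] = np.nan
    return df


def generate_cohort_table(params: Optional[CohortSimParams] = None) -> pd.DataFrame:
    """Simulate a BO/control cohort table.

    Draws are reproducible under ``params.seed``; the demographics,
    copula, and missingness mechanisms use named substreams of that seed.
    """
    params = params or CohortSimParams()
    from .phantom import _substream

    factor = _copula_factor(params.copula_matrix())
    rng = _substream(params.seed, "cohort")
    frames = [
        _draw_group(
            rng, params.n_control, "control", params.control_marginals, factor,
            params.missingness, "CTRL", 1,
        ),
        _draw_group(
            rng, params.n_bo, "BO", params.bo_marginals, factor,
            params.missingness, "BO", 1,
        ),
    ]
    return pd.concat(frames, ignore_index=True)


def validate_cohort(table: pd.DataFrame) -> None:
    """Check the structural invariants of a cohort table."""
    required = {"subject_id", "group", "age_years", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing required columns: {sorted(missing)}")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    bad_groups = set(table["group"]) - {"control", "BO"}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if (table["age_years"] < 0).any():
        raise ValueError("ages must be non-negative")
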