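"""Synthetic women's-record generator with a district random intercept.

Emulates the hierarchical structure the downstream analysis assumes: women
nested in districts, categorical covariates drawn from configurable margins
(defaults resemble the source survey's published univariate distribution),
and a binary modern-vs-traditional outcome generated from a random-intercept
logistic model

    logit P(modern) = beta0 + sum_k beta_k x_k + u_j,   u_j ~ N(0, sigma_u^2).

Betas may reference both individual categories (``"marital:married"``) and
community-level categories (``"community_facility_access:high"``); community
dummies are derived from the generated covariates by the same district
aggregation used in the analysis, so community effects enter the generator
exactly as the model later sees them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import coding
from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "GeographyConfig",
    "default_margins",
    "default_betas",
    "generate_population",
    "apply_sample_filter",
    "logit",
]


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


#: per-variable category probabilities; defaults follow the published
#: univariate margins of the 2016 survey (media is drawn at the composite
#: level so its margins hold exactly; raw items are drawn consistently with
#: the composite).  Secondary/higher split of the published combined 35.7%
#: is a package choice (30.0/5.7), as is the poorest/poorer and
#: richer/richest halving of the collapsed wealth margins.
def default_margins() -> dict[str, dict[str, float]]:
    return {
        "age_group": {"15-19": 0.074, "20-29": 0.420, "30-39": 0.326, "40+": 0.180},
        "marital": {
            "single": 0.107,
            "married": 0.370,
            "living_together": 0.352,
            "previously_married": 0.171,
        },
        "head_sex": {"male": 0.664, "female": 0.336},
        "parity": {"1": 0.220, "2": 0.164, "3": 0.154, "4+": 0.462},
        "ever_terminated": {"no": 0.774, "yes": 0.226},
        "education_raw": {"none": 0.084, "primary": 0.559, "secondary": 0.300, "higher": 0.057},
        "media_exposure": {"low": 0.269, "medium": 0.354, "high": 0.377},
        "wanted_last": {"then": 0.539, "later": 0.334, "no_more": 0.127},
        "wealth_raw": {
            "poorest": 0.153,
            "poorer": 0.153,
            "middle": 0.186,
            "richer": 0.254,
            "richest": 0.254,
        },
        "religion": {"anglican": 0.323, "catholic": 0.386, "muslim": 0.135, "other": 0.156},
        "employed": {"no": 0.192, "yes": 0.808},
        "residence": {"urban": 0.300, "rural": 0.700},
        "visited_facility_12m": {"no": 0.45, "yes": 0.55},
        "fp_media_source": {"0": 0.57, "1": 0.43},
    }


#: default log-odds effects: signs follow the study's reported directions
#: (marriage, education, wealth up; female household head, pregnancy
#: termination, Islam/other religion, community facility access down) at
#: magnitudes modest but detectable at the default design size.
def default_betas() -> dict[str, float]:
    return {
        "age_group:20-29": -0.25,
        "age_group:30-39": -0.27,
        "age_group:40+": -0.22,
        "marital:married": 0.45,
        "marital:living_together": 0.35,
        "marital:previously_married": -0.05,
        "head_sex:female": -0.35,
        "parity:2": 0.03,
        "parity:3": -0.05,
        "parity:4+": 0.04,
        "ever_terminated:yes": -0.20,
        "education:primary": 0.28,
        "education:secondary+": 0.30,
        "media_exposure:medium": -0.10,
        "media_exposure:high": 0.00,
        "wanted_last:later": 0.05,
        "wanted_last:no_more": -0.13,
        "wealth:middle": 0.18,
        "wealth:rich": 0.20,
        "religion:catholic": -0.10,
        "religion:muslim": -0.28,
        "religion:other": -0.20,
        "employed:yes": 0.12,
        "residence_majority:rural": 0.10,
        "community_age:old": 0.05,
        "community_ses:high": 0.20,
        "community_media_fp:high": 0.10,
        "community_education:high": 0.15,
        "community_facility_access:high": -0.15,
    }


_MODERN_METHODS = {
    "injectables": 0.35,
    "pill": 0.20,
    "implants": 0.15,
    "male condom": 0.12,
    "iud": 0.05,
    "female sterilization": 0.05,
    "emergency contraception": 0.03,
    "female condom": 0.02,
    "other modern": 0.02,
    "male sterilization": 0.01,
}
_TRADITIONAL_METHODS = {
    "withdrawal": 0.45,
    "rhythm": 0.35,
    "lactational amenorrhea": 0.15,
    "other traditional": 0.05,
}


@dataclass
class GeographyConfig:
    """Toy planar geography: a road grid, facilities, lakes, districts."""

    grid_nx: int = 8
    grid_ny: int = 8
    cell_km: float = 20.0
    n_facilities: int = 12
    n_lakes: int = 2
    lake_radius_km: float = 12.0
    unlocated_fraction: float = 0.0
    snap_jitter_km: float = 2.0


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic population.

    Defaults emulate the source survey scale: 112 districts (the number of
    modelled communities), 165 interviewed women per district (~18.5k
    total), an any-method use rate and a currently-pregnant rate chosen so
    the analytic sample after screening lands near 9.2k, a marginal modern
    share of 53.2% among users, and a district random-intercept variance of
    0.10 on the logit scale.
    """

    n_districts: int = 112
    #: per-district sample size: an int, or an inclusive (low, high) range
    #: drawn uniformly per district
    women_per_district: int | tuple[int, int] = 165
    #: intercept log-odds; ``None`` calibrates it so the marginal modern
    #: share matches ``target_modern_share`` after centring the realized
    #: covariate effects (first-moment correction)
    beta0: float | None = None
    target_modern_share: float = 0.532
    betas: dict[str, float] = field(default_factory=default_betas)
    sigma_u2: float = 0.10
    covariate_margins: dict[str, dict[str, float]] = field(default_factory=default_margins)
    p_use_any: float = 10300.0 / 18506.0
    p_pregnant: float = 1065.0 / 10300.0
    seed: int = 0
    geography: GeographyConfig = field(default_factory=GeographyConfig)

    def __post_init__(self) -> None:
        if self.n_districts < 2:
            raise ConfigurationError("n_districts must be >= 2")
        wpd = self.women_per_district
        if isinstance(wpd, (tuple, list)):
            if len(wpd) != 2 or wpd[0] < 1 or wpd[1] < wpd[0]:
                raise ConfigurationError(
                    "women_per_district range must be (low, high) with 1 <= low <= high"
                )
        elif wpd < 1:
            raise ConfigurationError("women_per_district must be >= 1")
        if self.sigma_u2 < 0:
            raise ConfigurationError("sigma_u2 must be >= 0")
        for var, margin in self.covariate_margins.items():
            total = sum(margin.values())
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"margins for {var!r} sum to {total!r}, not 1"
                )
            if any(p < 0 for p in margin.values()):
                raise ConfigurationError(f"negative probability in margins for {var!r}")

    def child_seed(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        stage_key = zlib.crc32(stage.encode("utf-8"))
        ss = np.random.SeedSequence(self.seed, spawn_key=(stage_key,))
        return np.random.default_rng(ss)


def _draw_categorical(rng, margin: dict[str, float], n: int) -> np.ndarray:
    cats = list(margin)
    p = np.array([margin[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=n, p=p)


def _media_items_from_composite(rng, composite: np.ndarray) -> np.ndarray:
    """Draw the three raw media items consistent with the composite class.

    low -> no item accessed; medium -> exactly one; high -> two (70%) or
    three (30%) items.  Accessed items take frequency code 1 or 2 with
    equal probability.
    """
    n = len(composite)
    n_access = np.zeros(n, dtype=int)
    n_access[composite == "medium"] = 1
    hi = composite == "high"
    n_access[hi] = rng.choice([2, 3], size=int(hi.sum()), p=[0.7, 0.3])
    # rank a uniform draw per row; the n_access lowest-ranked items are accessed
    ranks = np.argsort(np.argsort(rng.random((n, 3)), axis=1), axis=1)
    accessed = ranks < n_access[:, None]
    codes = rng.integers(1, 3, size=(n, 3))
    return np.where(accessed, codes, 0)


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate one synthetic women's-record table.

    Returns a DataFrame with one row per interviewed woman (users and
    non-users alike; screening is a separate, downstream step).  The
    modern/traditional outcome and the method code exist only for women
    using some method.  Deterministic for a fixed ``config.seed``.
    """
    rng = config.child_seed("population")
    wpd = config.women_per_district
    if isinstance(wpd, (tuple, list)):
        sizes = rng.integers(wpd[0], wpd[1] + 1, size=config.n_districts)
    else:
        sizes = np.full(config.n_districts, wpd)
    n_total = int(sizes.sum())
    district_id = np.repeat(np.arange(config.n_districts), sizes)

    df = pd.DataFrame({"woman_id": np.arange(n_total), "district_id": district_id})
    margins = config.covariate_margins
    for var in [
        "age_group",
        "marital",
        "head_sex",
        "parity",
        "ever_terminated",
        "education_raw",
        "wanted_last",
        "wealth_raw",
        "religion",
        "employed",
        "residence",
        "visited_facility_12m",
    ]:
        df[var] = _draw_categorical(rng, margins[var], n_total)
    composite = _draw_categorical(rng, margins["media_exposure"], n_total)
    items = _media_items_from_composite(rng, composite)
    df["media_newspaper"], df["media_radio"], df["media_tv"] = items.T
    df["fp_media_source"] = _draw_categorical(
        rng, {int(k): v for k, v in margins["fp_media_source"].items()}, n_total
    ).astype(int)

    df["used_any_method"] = np.where(
        rng.random(n_total) < config.p_use_any, "yes", "no"
    )
    df["pregnant_now"] = np.where(rng.random(n_total) < config.p_pregnant, "yes", "no")

    # individual-level part of the linear predictor
    eta = np.zeros(n_total)
    coded = df.copy()
    coded["education"] = coded["education_raw"].map(
        {"none": "none", "primary": "primary", "secondary": "secondary+", "higher": "secondary+"}
    )
    coded["wealth"] = coded["wealth_raw"].map(
        {"poorest": "poor", "poorer": "poor", "middle": "middle", "richer": "rich", "richest": "rich"}
    )
    coded["media_exposure"] = composite
    # community-level dummies derived exactly as the analysis derives them
    coded["outcome_modern"] = np.nan  # aggregation ignores the outcome
    summary = coding.aggregate_community(coded)
    coded = coding.attach_community(coded, summary)
    for key, beta in config.betas.items():
        var, _, cat = key.partition(":")
        if var not in coded.columns:
            raise ConfigurationError(f"beta refers to unknown variable {var!r}")
        eta = eta + beta * (coded[var].astype(str) == cat).to_numpy(float)

    if config.beta0 is None:
        beta0 = logit(config.target_modern_share) - float(np.mean(eta))
    else:
        beta0 = config.beta0
    u = rng.normal(0.0, np.sqrt(config.sigma_u2), size=config.n_districts)
    eta = eta + beta0 + u[district_id]
    p_modern = 1.0 / (1.0 + np.exp(-eta))
    modern = rng.random(n_total) < p_modern

    used = df["used_any_method"] == "yes"
    outcome = pd.Series(np.nan, index=df.index)
    outcome[used] = modern[used].astype(float)
    df["outcome"] = outcome

    method = pd.Series(pd.NA, index=df.index, dtype="object")
    mod_codes = list(_MODERN_METHODS)
    mod_p = np.array(list(_MODERN_METHODS.values()))
    trad_codes = list(_TRADITIONAL_METHODS)
    trad_p = np.array(list(_TRADITIONAL_METHODS.values()))
    is_mod = used & (outcome == 1.0)
    is_trad = used & (outcome == 0.0)
    method[is_mod] = rng.choice(mod_codes, size=int(is_mod.sum()), p=mod_p / mod_p.sum())
    method[is_trad] = rng.choice(trad_codes, size=int(is_trad.sum()), p=trad_p / trad_p.sum())
    df["method_code"] = method
    return df


# re-exported here because screening is part of the data-preparation story
apply_sample_filter = coding.apply_sample_filter


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down configuration for quick runs and examples."""
    base = SimulationConfig(n_districts=20, women_per_district=60)
    return replace(base, **overrides)
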