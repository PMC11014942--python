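"""Two-endmember apportionment of nitrate between atmospheric deposition
and microbial nitrification, using oxygen isotopes.

Nitrate produced by nitrification inherits one oxygen atom from dissolved
O2 and two from ambient water, so its delta18O is low (near 0 permil) and it
carries no mass-independent anomaly (Delta17O = 0 permil). Nitrate formed
photochemically in the atmosphere via ozone chemistry is strongly enriched
(delta18O near 92 permil over coastal East Antarctica) and carries a large
positive Delta17O (~32 permil). A linear mass balance between those two
endmembers therefore apportions an observed nitrate pool:

    f_atm = (obs - em_bio) / (em_atm - em_bio),    f_bio = 1 - f_atm

with either delta18O or Delta17O as the tracer. Measurement and endmember
uncertainties are propagated by Monte-Carlo resampling from independent
Gaussians.

All delta/Delta values are permil (delta18O, delta17O vs VSMOW; delta15N vs
AIR); fractions are dimensionless in [0, 1].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateEndmemberError,
    InvalidMeasurementError,
    InvalidUncertaintyError,
    NoDataError,
)

__all__ = [
    "Tracer",
    "SampleType",
    "IsotopeMeasurement",
    "Endmember",
    "MixingResult",
    "ATMOSPHERIC",
    "BIOLOGICAL",
    "DEFAULT_LAMBDA_MDF",
    "SIGMA_D15N",
    "SIGMA_D18O",
    "SIGMA_D17O_ANOMALY",
    "delta17O_anomaly",
    "biological_endmember_d18O",
    "two_endmember_fraction",
    "aggregate_observations",
    "monte_carlo_fraction",
    "apportion_dataset",
]

# Pooled-standard-deviation measurement precisions of the bacterial
# denitrifier method (1 sigma, permil): used as defaults wherever a
# measurement does not state its own uncertainty.
SIGMA_D15N = 0.6
SIGMA_D18O = 0.3
SIGMA_D17O_ANOMALY = 0.8

#: Slope of the mass-dependent fractionation line in the linear anomaly
#: definition Delta17O = delta17O - lambda * delta18O. 0.52 is the
#: community-standard value; measured Delta17O values bypass the formula.
DEFAULT_LAMBDA_MDF = 0.52


class Tracer(str, enum.Enum):
    """Which oxygen-isotope quantity the mixing model is run on."""

    d18O = "d18O"
    D17O = "D17O"


class SampleType(str, enum.Enum):
    sediment = "sediment"
    soil = "soil"
    lake_water = "lake_water"
    snow_atmosphere = "snow_atmosphere"


def _require_finite(name: str, value: float) -> float:
    if value is None or not math.isfinite(value):
        raise InvalidMeasurementError(f"{name} must be finite, got {value!r}")
    return float(value)


def _require_sigma(name: str, value: float) -> float:
    v = _require_finite(name, value)
    if v < 0:
        raise InvalidUncertaintyError(f"{name} must be >= 0, got {v}")
    return v


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One sample's nitrate (or water) isotope record.

    ``D17O`` is the mass-independent anomaly; when both ``d17O`` and
    ``D17O`` are supplied the measured anomaly takes precedence over the
    value computed from ``d17O``. Uncertainties default to the denitrifier
    method's pooled precisions.
    """

    sample_id: str
    sample_type: SampleType
    d18O: float
    d17O: float | None = None
    D17O: float | None = None
    d15N: float | None = None
    sigma_d18O: float = SIGMA_D18O
    sigma_D17O: float = SIGMA_D17O_ANOMALY
    sigma_d15N: float = SIGMA_D15N

    def __post_init__(self) -> None:
        _require_finite("d18O", self.d18O)
        for name in ("d17O", "D17O", "d15N"):
            v = getattr(self, name)
            if v is not None:
                _require_finite(name, v)
        for name in ("sigma_d18O", "sigma_D17O", "sigma_d15N"):
            _require_sigma(name, getattr(self, name))
        if not isinstance(self.sample_type, SampleType):
            object.__setattr__(self, "sample_type", SampleType(self.sample_type))

    def anomaly(self, lambda_mdf: float = DEFAULT_LAMBDA_MDF) -> float:
        """Return Delta17O, preferring the measured anomaly when present."""
        if self.D17O is not None:
            return self.D17O
        if self.d17O is None:
            raise InvalidMeasurementError(
                f"sample {self.sample_id!r}: Delta17O requested but neither "
                "d17O nor D17O is available"
            )
        return delta17O_anomaly(self.d17O, self.d18O, lambda_mdf)

    def tracer_value(self, tracer: Tracer) -> float:
        return self.d18O if tracer is Tracer.d18O else self.anomaly()

    def tracer_sigma(self, tracer: Tracer) -> float:
        return self.sigma_d18O if tracer is Tracer.d18O else self.sigma_D17O

    def has_tracer(self, tracer: Tracer) -> bool:
        if tracer is Tracer.d18O:
            return True
        return self.D17O is not None or self.d17O is not None


@dataclass(frozen=True)
class Endmember:
    """A named nitrate source pool with characteristic isotope values."""

    name: str
    d18O: float
    sigma_d18O: float = 0.0
    D17O: float = 0.0
    sigma_D17O: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("d18O", self.d18O)
        _require_finite("D17O", self.D17O)
        _require_sigma("sigma_d18O", self.sigma_d18O)
        _require_sigma("sigma_D17O", self.sigma_D17O)

    def tracer_value(self, tracer: Tracer) -> float:
        return self.d18O if tracer is Tracer.d18O else self.D17O

    def tracer_sigma(self, tracer: Tracer) -> float:
        return self.sigma_d18O if tracer is Tracer.d18O else self.sigma_D17O


#: Annual-mean atmospheric nitrate over coastal East Antarctica:
#: delta18O ~ 92 permil, Delta17O ~ 32 permil.
ATMOSPHERIC = Endmember("atmospheric", d18O=92.0, D17O=32.0)

#: Nitrification-produced nitrate: delta18O ~ 0.6 permil (the published
#: constant for this system; see also :func:`biological_endmember_d18O`),
#: Delta17O = 0 permil since O2 and water both carry no anomaly.
BIOLOGICAL = Endmember("biological", d18O=0.6, D17O=0.0)


def delta17O_anomaly(
    d17O: float, d18O: float, lambda_mdf: float = DEFAULT_LAMBDA_MDF
) -> float:
    """Mass-independent anomaly ``Delta17O = d17O - lambda * d18O`` (permil).

    Mass-dependent processes move delta17O and delta18O along a line of
    slope ``lambda_mdf``; the anomaly measures the deviation from that
    line and is conserved through mass-dependent chemistry, which makes it
    the cleaner of the two tracers for atmospheric nitrate.
    """
    d17O = _require_finite("d17O", d17O)
    d18O = _require_finite("d18O", d18O)
    if not (0.0 < lambda_mdf < 1.0) or not math.isfinite(lambda_mdf):
        raise ConfigurationError(
            f"lambda_mdf must lie in (0, 1), got {lambda_mdf!r}"
        )
    return d17O - lambda_mdf * d18O


def biological_endmember_d18O(
    d18O_water: float = -12.7,
    d18O_O2: float = 23.9,
    w_water: float = 2.0 / 3.0,
) -> float:
    """delta18O of nitrification-produced nitrate from its oxygen sources.

    During nitrification two of the three nitrate oxygen atoms derive from
    ambient water and one from dissolved O2, so the product delta18O is the
    weighted mean ``w_water * d18O_water + (1 - w_water) * d18O_O2``.
    Defaults are the study system's values: lake water at -12.7 permil and
    atmospheric O2 at 23.9 permil, giving -0.5 permil. Note the shipped
    :data:`BIOLOGICAL` endmember constant is the published 0.6 permil, which
    this arithmetic does not exactly reproduce; both values are exposed
    rather than silently reconciled.
    """
    if not (0.0 <= w_water <= 1.0):
        raise ConfigurationError(f"w_water must lie in [0, 1], got {w_water!r}")
    d18O_water = _require_finite("d18O_water", d18O_water)
    d18O_O2 = _require_finite("d18O_O2", d18O_O2)
    return w_water * d18O_water + (1.0 - w_water) * d18O_O2


@dataclass(frozen=True)
class MixingResult:
    """Apportioned source fractions for one observation (or group mean).

    ``f_atm + f_bio == 1`` always. ``ci_low``/``ci_high`` bracket ``f_atm``
    (95% Monte-Carlo percentile interval) when uncertainty propagation was
    run; ``clipped`` flags a point estimate that fell outside [0, 1] before
    clipping, and ``out_of_hull`` records an observation outside the
    endmember interval when clipping was not requested.
    """

    f_atm: float
    f_bio: float
    tracer: Tracer
    point_obs: float
    ci_low: float | None = None
    ci_high: float | None = None
    median: float | None = None
    n_draws: int = 0
    seed: int | None = None
    clipped: bool = False
    out_of_hull: bool = False
    group: str | None = None

    def __post_init__(self) -> None:
        if abs(self.f_atm + self.f_bio - 1.0) > 1e-12:
            raise ValueError("f_atm + f_bio must equal 1")


def two_endmember_fraction(
    obs: float,
    em_bio: float,
    em_atm: float,
    clip: bool = True,
    tracer: Tracer = Tracer.d18O,
) -> MixingResult:
    """Linear mass balance between two endmembers.

    ``f_atm = (obs - em_bio) / (em_atm - em_bio)``. With ``clip`` (the
    default) a fraction outside [0, 1] — possible whenever noise pushes an
    observation past an endmember — is clipped and flagged; without it the
    value is returned as-is with ``out_of_hull`` set.
    """
    obs = _require_finite("obs", obs)
    em_bio = _require_finite("em_bio", em_bio)
    em_atm = _require_finite("em_atm", em_atm)
    if em_atm == em_bio:
        raise DegenerateEndmemberError(
            f"endmembers coincide at {em_atm} permil; mixing is undefined"
        )
    f_atm = (obs - em_bio) / (em_atm - em_bio)
    outside = not (0.0 <= f_atm <= 1.0)
    clipped = False
    if outside and clip:
        f_atm = min(1.0, max(0.0, f_atm))
        clipped = True
    return MixingResult(
        f_atm=f_atm,
        f_bio=1.0 - f_atm,
        tracer=tracer,
        point_obs=obs,
        clipped=clipped,
        out_of_hull=outside and not clip,
    )


def aggregate_observations(
    measurements: Sequence[IsotopeMeasurement],
    tracer: Tracer = Tracer.d18O,
    mode: str = "mean_first",
) -> float | list[float]:
    """Collapse a group of measurements for mixing.

    ``mean_first`` returns the arithmetic mean of the tracer values (mix
    once on the group mean — the conventional procedure); ``per_sample``
    returns the individual values so the caller can mix each sample and
    average the fractions instead.
    """
    usable = [m for m in measurements if m.has_tracer(tracer)]
    if not usable:
        raise NoDataError(f"no measurement carries tracer {tracer.value}")
    values = [m.tracer_value(tracer) for m in usable]
    if mode == "mean_first":
        return float(np.mean(values))
    if mode == "per_sample":
        return values
    raise ConfigurationError(f"unknown aggregation mode {mode!r}")


def monte_carlo_fraction(
    obs: float,
    sigma_obs: float,
    em_bio: Endmember,
    em_atm: Endmember,
    tracer: Tracer = Tracer.d18O,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> MixingResult:
    """Propagate Gaussian uncertainty through the mass balance.

    The observation and both endmembers are drawn from independent normals
    (no covariance information is available for this system); each draw's
    ``f_atm`` is clipped to [0, 1]. The point estimate is the closed form on
    the means; the interval is the [2.5, 97.5] percentile range of the
    draws. Identical seed and inputs give identical output.
    """
    if seed is None:
        raise ConfigurationError("monte_carlo_fraction requires an explicit seed")
    if n_draws < 1:
        raise ConfigurationError(f"n_draws must be >= 1, got {n_draws}")
    sigma_obs = _require_sigma("sigma_obs", sigma_obs)
    mu_bio = em_bio.tracer_value(tracer)
    mu_atm = em_atm.tracer_value(tracer)
    point = two_endmember_fraction(obs, mu_bio, mu_atm, clip=True, tracer=tracer)

    rng = np.random.default_rng(seed)
    obs_d = rng.normal(obs, sigma_obs, n_draws)
    bio_d = rng.normal(mu_bio, em_bio.tracer_sigma(tracer), n_draws)
    atm_d = rng.normal(mu_atm, em_atm.tracer_sigma(tracer), n_draws)
    denom = atm_d - bio_d
    # a draw where the endmembers cross is meaningless; fall back to the
    # mean separation rather than dividing by ~0
    bad = np.abs(denom) < 1e-9
    denom[bad] = mu_atm - mu_bio
    f = np.clip((obs_d - bio_d) / denom, 0.0, 1.0)
    lo, med, hi = np.percentile(f, [2.5, 50.0, 97.5])
    return replace(
        point,
        ci_low=float(lo),
        ci_high=float(hi),
        median=float(med),
        n_draws=int(n_draws),
        seed=int(seed),
    )


@dataclass(frozen=True)
class ApportionConfig:
    """Knobs for :func:`apportion_dataset`."""

    aggregation: str = "mean_first"
    n_draws: int = 10_000
    seed: int | None = None
    clip: bool = True
    lambda_mdf: float = DEFAULT_LAMBDA_MDF
    monte_carlo: bool = True


def _group_result(
    group: str,
    members: list[IsotopeMeasurement],
    tracer: Tracer,
    em_bio: Endmember,
    em_atm: Endmember,
    cfg: ApportionConfig,
    seed: int | None,
) -> MixingResult:
    mu_bio = em_bio.tracer_value(tracer)
    mu_atm = em_atm.tracer_value(tracer)
    usable = [m for m in members if m.has_tracer(tracer)]
    if cfg.aggregation == "per_sample":
        per = [
            two_endmember_fraction(
                m.tracer_value(tracer), mu_bio, mu_atm, clip=cfg.clip, tracer=tracer
            )
            for m in usable
        ]
        f_atm = float(np.mean([r.f_atm for r in per]))
        base = MixingResult(
            f_atm=f_atm,
            f_bio=1.0 - f_atm,
            tracer=tracer,
            point_obs=float(np.mean([r.point_obs for r in per])),
            clipped=any(r.clipped for r in per),
            out_of_hull=any(r.out_of_hull for r in per),
        )
        obs = base.point_obs
    else:
        obs = aggregate_observations(usable, tracer, "mean_first")
        base = two_endmember_fraction(obs, mu_bio, mu_atm, clip=cfg.clip, tracer=tracer)
    if cfg.monte_carlo:
        if cfg.seed is None:
            raise ConfigurationError("Monte-Carlo apportionment requires a seed")
        # standard error of the group mean drives the observation noise
        sig = float(np.mean([m.tracer_sigma(tracer) for m in usable]))
        sigma_obs = sig / math.sqrt(len(usable))
        mc = monte_carlo_fraction(
            obs, sigma_obs, em_bio, em_atm, tracer, cfg.n_draws, seed
        )
        base = replace(
            base,
            ci_low=mc.ci_low,
            ci_high=mc.ci_high,
            median=mc.median,
            n_draws=mc.n_draws,
            seed=seed,
        )
    return replace(base, group=group)


def apportion_dataset(
    measurements: Iterable[IsotopeMeasurement],
    em_bio: Endmember = BIOLOGICAL,
    em_atm: Endmember = ATMOSPHERIC,
    config: ApportionConfig | None = None,
) -> pd.DataFrame:
    """Apportion every sample-type group on every available tracer.

    Returns one row per (sample_type, tracer): delta18O always, Delta17O
    whenever at least one group member carries it. When both tracers exist
    for a group both rows are emitted side by side; the two balances are
    never averaged together. An empty input yields an empty table.
    """
    cfg = config or ApportionConfig()
    measurements = list(measurements)
    rows: list[MixingResult] = []
    groups: dict[str, list[IsotopeMeasurement]] = {}
    for m in measurements:
        groups.setdefault(m.sample_type.value, []).append(m)
    # deterministic per-(group, tracer) child seeds
    seq = (
        np.random.SeedSequence(cfg.seed) if cfg.seed is not None else None
    )
    for gi, (group, members) in enumerate(sorted(groups.items())):
        for ti, tracer in enumerate((Tracer.d18O, Tracer.D17O)):
            if not any(m.has_tracer(tracer) for m in members):
                continue
            child_seed = (
                int(seq.spawn(1)[0].generate_state(1)[0] % (2**31))
                if seq is not None
                else None
            )
            rows.append(
                _group_result(group, members, tracer, em_bio, em_atm, cfg, child_seed)
            )
    columns = [
        "group",
        "tracer",
        "point_obs",
        "f_atm",
        "f_bio",
        "ci_low",
        "ci_high",
        "median",
        "n_draws",
        "seed",
        "clipped",
        "out_of_hull",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "tracer": r.tracer.value,
                "point_obs": r.point_obs,
                "f_atm": r.f_atm,
                "f_bio": r.f_bio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "median": r.median,
                "n_draws": r.n_draws,
                "seed": r.seed,
                "clipped": r.clipped,
                "out_of_hull": r.out_of_hull,
            }
            for r in rows
        ],
        columns=columns,
    )
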