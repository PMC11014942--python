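"""Synthetic datasets with known ground truth for every pipeline stage.

Emulates the three input families the pipeline consumes — nitrate isotope
tables, marker-gene annotation tables, and SIP density-fraction profiles —
with the study conditions baked in as defaults: Gaussian measurement noise
at the denitrifier-method precisions (0.3 permil delta18O, 0.8 permil
Delta17O, 0.6 permil delta15N), qPCR-like abundances spanning 1e2-1e4
copies per ng DNA, an anammox-absent preset, and a configurable true
buoyant-density shift for labeled DNA.

Randomness: every generator call derives its own child stream from the
single spec seed via ``numpy`` SeedSequence spawn keys fixed per generator
(isotopes=0, annotation=1, sip=2), so each module can be exercised in
isolation yet reproduces jointly. Ground truth is written to a sidecar
dict/JSON only, never into the measurement tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .inventory import NCYCLE_PANEL, AnnotationTable, GeneProcessMap
from .isotopes import (
    ATMOSPHERIC,
    BIOLOGICAL,
    Endmember,
    IsotopeMeasurement,
    SampleType,
)
from .sip import SIPProfile

__all__ = [
    "SigmaSet",
    "SIPSimSpec",
    "SimSpec",
    "gen_isotope_dataset",
    "gen_annotation_table",
    "gen_sip_profiles",
]

_STREAM = {"isotopes": 0, "annotation": 1, "sip": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM[stream],))
    )


@dataclass(frozen=True)
class SigmaSet:
    """Measurement 1-sigma noise, permil (instrument precisions)."""

    d18O: float = 0.3
    D17O: float = 0.8
    d15N: float = 0.6
    d18O_water: float = 1.5

    def __post_init__(self) -> None:
        for name in ("d18O", "D17O", "d15N", "d18O_water"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"sigma {name} must be >= 0")


@dataclass(frozen=True)
class SIPSimSpec:
    """Conditions of a simulated SIP gradient experiment.

    The 12C profile is Gaussian-shaped over the density grid; the 13C
    profile is the same shape translated by ``true_shift``. Each fraction's
    abundance receives independent multiplicative lognormal noise of
    coefficient-of-variation ~``noise_cv``. Grid defaults (1.69-1.77 g/mL,
    14 fractions) are conventional CsCl-gradient values; peak width 0.012
    g/mL matches typical community DNA bands; 3 replicate microcosms.
    """

    true_shift: float = 0.015
    n_fractions: int = 14
    density_min: float = 1.69
    density_max: float = 1.77
    peak_density: float = 1.725
    peak_width: float = 0.012
    noise_cv: float = 0.2
    replicates: int = 3
    total_abundance: float = 1e6
    target_gene: str = "amoA"
    temperature_C: float = 10.0

    def __post_init__(self) -> None:
        if self.n_fractions < 3:
            raise ConfigurationError("n_fractions must be >= 3")
        if self.density_min >= self.density_max:
            raise ConfigurationError("density range must be increasing")
        if self.noise_cv < 0 or self.peak_width <= 0 or self.replicates < 1:
            raise ConfigurationError("invalid SIP noise/width/replicate spec")


@dataclass(frozen=True)
class SimSpec:
    """Full simulation specification; the seed is mandatory.

    ``true_f_atm`` maps sample-type name -> true atmospheric fraction of
    its nitrate pool; defaults reflect nitrification-dominated sediments
    and soils (~95% biological). ``process_presence`` maps process ->
    present?; the default mimics the study system: every nitrogen-cycle
    process present except anammox.
    """

    seed: int
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"sediment": 6, "soil": 6}
    )
    true_f_atm: Mapping[str, float] = field(
        default_factory=lambda: {"sediment": 0.05, "soil": 0.04}
    )
    em_atm: Endmember = ATMOSPHERIC
    em_bio: Endmember = BIOLOGICAL
    sigmas: SigmaSet = field(default_factory=SigmaSet)
    process_presence: Mapping[str, bool] = field(
        default_factory=lambda: {
            "n2_fixation": True,
            "nitrification": True,
            "denitrification": True,
            "dnra": True,
            "anr": True,
            "anammox": False,
        }
    )
    abundance_range: tuple[float, float] = (1e2, 1e4)
    sip: SIPSimSpec = field(default_factory=SIPSimSpec)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("SimSpec requires an explicit seed")
        for k, f in self.true_f_atm.items():
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"true_f_atm[{k!r}] must lie in [0, 1]")
        lo, hi = self.abundance_range
        if not (0 < lo <= hi):
            raise ConfigurationError("abundance_range must satisfy 0 < lo <= hi")


def gen_isotope_dataset(
    spec: SimSpec,
) -> tuple[list[IsotopeMeasurement], dict]:
    """Simulate nitrate isotope measurements for each sample-type group.

    Per sample the true composition is the two-endmember mix
    ``f_atm * em_atm + (1 - f_atm) * em_bio`` on both tracers, plus
    independent Gaussian noise at the spec sigmas. delta15N is drawn
    around a fixed 5 permil baseline (it carries no source information in
    this model). Returns the measurement list and a ground-truth sidecar
    dict; truth never appears in the measurements themselves.
    """
    rng = _rng(spec.seed, "isotopes")
    out: list[IsotopeMeasurement] = []
    truth: dict = {"seed": spec.seed, "groups": {}}
    for stype in sorted(spec.n_samples):
        n = spec.n_samples[stype]
        f_atm = spec.true_f_atm.get(stype, 0.0)
        true_d18O = f_atm * spec.em_atm.d18O + (1 - f_atm) * spec.em_bio.d18O
        true_D17O = f_atm * spec.em_atm.D17O + (1 - f_atm) * spec.em_bio.D17O
        truth["groups"][stype] = {
            "true_f_atm": f_atm,
            "true_f_bio": 1 - f_atm,
            "true_d18O": true_d18O,
            "true_D17O": true_D17O,
            "n": n,
        }
        for i in range(n):
            out.append(
                IsotopeMeasurement(
                    sample_id=f"{stype}_{i + 1:02d}",
                    sample_type=SampleType(stype),
                    d18O=true_d18O + rng.normal(0.0, spec.sigmas.d18O),
                    D17O=true_D17O + rng.normal(0.0, spec.sigmas.D17O),
                    d15N=5.0 + rng.normal(0.0, spec.sigmas.d15N),
                    sigma_d18O=spec.sigmas.d18O,
                    sigma_D17O=spec.sigmas.D17O,
                    sigma_d15N=spec.sigmas.d15N,
                )
            )
    return out, truth


def gen_annotation_table(
    spec: SimSpec,
    gmap: GeneProcessMap = NCYCLE_PANEL,
    n_samples: int = 6,
) -> tuple[AnnotationTable, dict]:
    """Simulate a qPCR-style gene x sample abundance table.

    Genes of present processes receive log-uniform abundances over the
    spec range (default 1e2-1e4 copies per ng DNA); genes whose every
    process is absent are exactly 0. The default presence map leaves
    anammox (hzo, hzs) undetected, mirroring its absence from the study
    system. Returns the table and the presence ground truth.
    """
    rng = _rng(spec.seed, "annotation")
    genes = sorted(gmap.genes)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    lo, hi = spec.abundance_range
    data = pd.DataFrame(0.0, index=samples, columns=genes)
    for gene in genes:
        procs = gmap.lookup(gene)
        present = any(spec.process_presence.get(p, True) for p in procs)
        if present:
            data[gene] = 10 ** rng.uniform(np.log10(lo), np.log10(hi), n_samples)
    truth = {
        "seed": spec.seed,
        "process_presence": dict(spec.process_presence),
        "absent_processes": sorted(
            p for p, v in spec.process_presence.items() if not v
        ),
    }
    return AnnotationTable(data, value_kind="copies_per_ng"), truth


def gen_sip_profiles(
    spec: SimSpec,
) -> tuple[list[SIPProfile], list[SIPProfile], dict]:
    """Simulate paired 13C/12C SIP profiles across replicate microcosms.

    12C replicates are Gaussian bands over the density grid; 13C
    replicates are the identical band translated rigidly to heavier
    density by ``true_shift`` (band and fraction densities move together,
    so at zero noise delta-WMD equals the true shift exactly). Fraction
    abundances get independent multiplicative lognormal noise
    (CV ~ ``noise_cv``). Returns (13C list, 12C list, truth sidecar).
    """
    s = spec.sip
    rng = _rng(spec.seed, "sip")
    grid = np.linspace(s.density_min, s.density_max, s.n_fractions)
    sigma_log = np.sqrt(np.log1p(s.noise_cv**2))

    def band(center: float) -> np.ndarray:
        shape = np.exp(-0.5 * ((grid - center) / s.peak_width) ** 2)
        return s.total_abundance * shape / shape.sum()

    def noisy(signal: np.ndarray) -> np.ndarray:
        if sigma_log == 0:
            return signal
        return signal * rng.lognormal(-0.5 * sigma_log**2, sigma_log, signal.size)

    p13: list[SIPProfile] = []
    p12: list[SIPProfile] = []
    base = band(s.peak_density)
    for rep in range(1, s.replicates + 1):
        p13.append(
            SIPProfile(
                treatment="13C",
                temperature_C=s.temperature_C,
                densities=tuple(grid + s.true_shift),
                abundances=tuple(noisy(base)),
                target_gene=s.target_gene,
                replicate=rep,
            )
        )
        p12.append(
            SIPProfile(
                treatment="12C",
                temperature_C=s.temperature_C,
                densities=tuple(grid),
                abundances=tuple(noisy(base)),
                target_gene=s.target_gene,
                replicate=rep,
            )
        )
    truth = {
        "seed": spec.seed,
        "true_shift": s.true_shift,
        "peak_density_12C": s.peak_density,
        "n_fractions": s.n_fractions,
        "replicates": s.replicates,
    }
    return p13, p12, truth
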