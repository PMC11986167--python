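"""Synthetic grape spectra and ripening-trait generator.

The generator emulates the statistical structure the downstream analysis
assumes: three maturity groups (less / semi / fully mature, 35 clusters
each) whose anthocyanin (An), total soluble solids (TSS) and titratable
acidity (TA) follow group-specific truncated normal distributions, and a
VIS/NIR reflectance spectrum per sample on the 302-1148 nm, 2 nm grid.

Spectra are a smooth continuum (low reflectance in the blue rising to a
NIR plateau) minus Gaussian absorption features whose depths are linear in
a driving trait:

* anthocyanin absorbs near 520 nm (stronger An -> deeper dip),
* a chlorophyll-like red feature near 675 nm tracks acidity (unripe,
  high-TA fruit is greener),
* a water/sugar feature sits near 970 nm driven by TSS,

plus additive i.i.d. Gaussian band noise.  Reflectance is clipped to
[0, 1].  Trait-trait correlations are induced by the group structure only
(no explicit within-group copula): pooled data still shows the expected
sign pattern (An-TSS positive, TA negative against the rest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectraSet, TraitTable

TRAITS = ("An", "TSS", "TA")


@dataclass(frozen=True)
class TraitSpec:
    """min/max/mean/sd describing one trait within one maturity group."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"need min <= mean <= max, got {self.min}/{self.mean}/{self.max}"
            )


@dataclass(frozen=True)
class GroupSpec:
    """One maturity group: label, size, and its three trait distributions."""

    name: str
    n: int
    An: TraitSpec
    TSS: TraitSpec
    TA: TraitSpec

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("group size must be >= 1")

    def trait(self, name: str) -> TraitSpec:
        return getattr(self, name)


@dataclass(frozen=True)
class GaussianFeature:
    """One absorption feature: depth = coefficient * driving trait value."""

    center: float       # nm
    width: float        # Gaussian sigma, nm
    trait: str          # driving trait column
    coefficient: float  # reflectance units per trait unit
    sign: float = 1.0   # +1 absorbs (lowers reflectance)


@dataclass(frozen=True)
class SpectralModelSpec:
    """Forward model for rendering reflectance from traits."""

    grid_start: float = 302.0
    grid_stop: float = 1148.0
    grid_step: float = 2.0
    baseline_low: float = 0.10       # blue-end reflectance
    baseline_high: float = 0.55      # NIR plateau
    baseline_center: float = 700.0   # logistic midpoint, nm
    baseline_scale: float = 80.0     # logistic width, nm
    features: tuple[GaussianFeature, ...] = ()
    noise_sd: float = 0.005

    def __post_init__(self):
        if self.grid_step <= 0:
            raise ValueError("grid step must be positive")
        if self.grid_stop <= self.grid_start:
            raise ValueError("grid stop must exceed grid start")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        for f in self.features:
            if not (self.grid_start <= f.center <= self.grid_stop):
                raise ValueError(
                    f"feature center {f.center} nm outside grid "
                    f"[{self.grid_start}, {self.grid_stop}]"
                )

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + self.grid_step / 2,
                         self.grid_step)

    def baseline(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths, float) - self.baseline_center) / self.baseline_scale
        return self.baseline_low + (self.baseline_high - self.baseline_low) / (
            1.0 + np.exp(-z)
        )


@dataclass
class SyntheticDataset:
    spectra: SpectraSet
    traits: TraitTable
    truth: SpectralModelSpec

    def __post_init__(self):
        if self.spectra.sample_ids != self.traits.sample_ids:
            raise ValueError("spectra and traits must share sample ids and order")


# -- default study conditions ------------------------------------------------
# Group-wise descriptive statistics of the three maturity stages
# (An in mg/L, TSS and TA in %); sizes 35/35/35.

#: reference group means of the maturation index (TSS/TA).  Not derivable
#: from the per-trait specs: the mean of a ratio is not the ratio of means.
REFERENCE_TSS_TA_MEANS = {"LM": 16.28, "SM": 22.72, "FM": 32.61}

def default_groups() -> list[GroupSpec]:
    return [
        GroupSpec("LM", 35,
                  An=TraitSpec(126.13, 88.36, 13.75, 348.25),
                  TSS=TraitSpec(11.51, 0.98, 8.75, 13.20),
                  TA=TraitSpec(0.73, 0.12, 0.51, 1.12)),
        GroupSpec("SM", 35,
                  An=TraitSpec(231.41, 130.42, 136.75, 483.50),
                  TSS=TraitSpec(14.45, 0.24, 14.25, 14.95),
                  TA=TraitSpec(0.65, 0.09, 0.51, 0.77)),
        GroupSpec("FM", 35,
                  An=TraitSpec(755.66, 203.95, 145.50, 1038.75),
                  TSS=TraitSpec(17.21, 1.47, 15.00, 20.25),
                  TA=TraitSpec(0.53, 0.05, 0.42, 0.64)),
    ]


def default_spectral_model(noise_sd: float = 0.005) -> SpectralModelSpec:
    # Coefficients sized so the deepest dips stay clear of the [0, 1] clip:
    # max An ~1039 mg/L * 1.2e-4 = 0.125 against a ~0.14 baseline at 520 nm.
    return SpectralModelSpec(
        features=(
            GaussianFeature(520.0, 40.0, "An", 1.2e-4),
            GaussianFeature(675.0, 25.0, "TA", 0.20),
            GaussianFeature(970.0, 50.0, "TSS", 0.012),
        ),
        noise_sd=noise_sd,
    )


# -- sampling ----------------------------------------------------------------

def _truncnorm_loc(spec: TraitSpec) -> float:
    """Location parameter whose truncated-normal mean equals spec.mean.

    Truncation shifts the mean away from the location parameter, so using
    the target mean as the location would bias every sample mean.  The
    truncated mean is strictly increasing in the location, so a bracketed
    root-find recovers the exact location.
    """
    from scipy.optimize import brentq

    def truncated_mean(mu: float) -> float:
        a = (spec.min - mu) / spec.sd
        b = (spec.max - mu) / spec.sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=spec.sd)

    lo = spec.min - 10 * spec.sd
    hi = spec.max + 10 * spec.sd
    try:
        return brentq(lambda mu: truncated_mean(mu) - spec.mean, lo, hi,
                      xtol=1e-10)
    except ValueError:
        # target mean at (or numerically beyond) a truncation bound: no
        # finite location reaches it exactly; use the nominal location
        return spec.mean


def _draw_truncnorm(spec: TraitSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.sd == 0:
        return np.full(n, spec.mean)
    loc = _truncnorm_loc(spec)
    a = (spec.min - loc) / spec.sd
    b = (spec.max - loc) / spec.sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=spec.sd,
                               size=n, random_state=rng)


def sample_traits(groups: list[GroupSpec], seed: int) -> TraitTable:
    """Draw per-group truncated-normal traits and derive TSS/TA.

    Group sizes are honored exactly.  A non-positive TA draw (possible only
    if a group's configured TA range dips to 0) is re-sampled so the ratio
    stays finite.
    """
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], []
    counter = 0
    for g in groups:
        draws = {t: _draw_truncnorm(g.trait(t), g.n, rng) for t in TRAITS}
        ta = draws["TA"]
        while np.any(ta <= 0):
            bad = ta <= 0
            ta[bad] = _draw_truncnorm(g.TA, int(bad.sum()), rng)
        for i in range(g.n):
            counter += 1
            ids.append(f"s{counter:03d}")
            labels.append(g.name)
            rows.append({t: draws[t][i] for t in TRAITS})
    df = pd.DataFrame(rows)
    df["TSS_TA"] = df["TSS"] / df["TA"]
    return TraitTable(sample_ids=ids, data=df, groups=labels)


def render_spectra(traits: TraitTable, spec: SpectralModelSpec,
                   seed: int = 0) -> SpectraSet:
    """Render one reflectance spectrum per trait row under the forward model."""
    for f in spec.features:
        if f.trait not in traits.data.columns:
            raise ValueError(f"feature at {f.center} nm drives unknown trait "
                             f"{f.trait!r}")
    wl = spec.wavelengths
    n = len(traits)
    refl = np.tile(spec.baseline(wl), (n, 1))
    for f in spec.features:
        shape = np.exp(-0.5 * ((wl - f.center) / f.width) ** 2)
        depth = f.sign * f.coefficient * traits[f.trait]
        refl -= depth[:, None] * shape[None, :]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        refl += rng.normal(0.0, spec.noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.0)
    groups = traits.groups if traits.groups is not None else ["NA"] * n
    return SpectraSet(wl, refl, list(traits.sample_ids), list(groups))


def make_dataset(groups: list[GroupSpec] | None = None,
                 spec: SpectralModelSpec | None = None,
                 seed: int = 0) -> SyntheticDataset:
    """Compose trait sampling and spectrum rendering under one seed."""
    groups = groups if groups is not None else default_groups()
    spec = spec if spec is not None else default_spectral_model()
    traits = sample_traits(groups, seed=seed)
    # derive an independent stream for the band noise from the same seed
    spectra = render_spectra(traits, spec, seed=seed + 1_000_003)
    return SyntheticDataset(spectra=spectra, traits=traits, truth=spec)


# -- config I/O --------------------------------------------------------------

def groups_to_dict(groups: list[GroupSpec]) -> list[dict]:
    return [asdict(g) for g in groups]


def groups_from_dict(payload: list[dict]) -> list[GroupSpec]:
    out = []
    for g in payload:
        out.append(GroupSpec(
            name=g["name"], n=int(g["n"]),
            An=TraitSpec(**g["An"]), TSS=TraitSpec(**g["TSS"]),
            TA=TraitSpec(**g["TA"]),
        ))
    return out


def spectral_model_to_dict(spec: SpectralModelSpec) -> dict:
    d = asdict(spec)
    d["features"] = [asdict(f) for f in spec.features]
    return d


def spectral_model_from_dict(d: dict) -> SpectralModelSpec:
    d = dict(d)
    feats = tuple(GaussianFeature(**f) for f in d.pop("features", ()))
    return SpectralModelSpec(features=feats, **d)


def write_truth_json(spec: SpectralModelSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spectral_model_to_dict(spec), indent=2))
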