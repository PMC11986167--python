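"""Exhaustive two- and three-band index optimization via R² correlograms.

For a chosen index form (two-band ratio RSI2, two-band normalized
difference NDI2, or three-band normalized difference NDI3) and a target
trait, every wavelength combination on a strided subset of the grid is
turned into an index, the trait is regressed on it by ordinary least
squares, and the coefficient of determination R² is recorded.  The result
is a 2-D matrix (band pairs) or a top-k list (band triplets) — the
"correlogram map" used to pick optimal wavelengths for new indices.

Symmetry conventions follow the index algebra exactly: RSI2 is searched
over ordered pairs (R_a/R_b and R_b/R_a give different regression R²
because the ratio is nonlinear), NDI2 over unordered pairs (the sign flip
under a band swap leaves R² unchanged), and NDI3 over (a; {b, c}) with
b <= c (the form is symmetric in its 2nd and 3rd bands; b == c allowed).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .indices import (
    IndexDefinition,
    IndexForm,
    ndi2_name,
    ndi3_name,
    rsi_name,
)
from .spectra import SpectraSet, TraitTable

_SEARCH_FORMS = (IndexForm.RSI2, IndexForm.NDI2, IndexForm.NDI3)

#: default cap on the number of 3-band combinations per trait
DEFAULT_TRIPLET_BUDGET = 40_000_000


class BudgetExceededError(ValueError):
    pass


@dataclass
class SimpleFit:
    """OLS of a trait on an index: y = intercept + slope * x."""

    r2: float
    slope: float
    intercept: float
    pvalue: float
    n: int
    degenerate: bool = False


def fit_simple_regression(x: np.ndarray, y: np.ndarray) -> SimpleFit:
    """Simple linear regression with pairwise deletion of missing values.

    Zero variance in either variable yields R² = 0 with the ``degenerate``
    flag set rather than an error, so exhaustive searches can skip
    constant indices gracefully.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired finite observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SimpleFit(0.0, 0.0, float(np.mean(y)), 1.0, x.size, degenerate=True)
    res = stats.linregress(x, y)
    return SimpleFit(float(res.rvalue**2), float(res.slope),
                     float(res.intercept), float(res.pvalue), x.size)


# ---------------------------------------------------------------------------
# vectorized column-wise R² (pairwise deletion, degenerate -> NaN)

def _columnwise_r2(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    valid = np.isfinite(X)
    Xv = np.where(valid, X, 0.0)
    n = valid.sum(axis=0).astype(float)
    sy = valid * y[:, None]
    sum_x = Xv.sum(axis=0)
    sum_y = sy.sum(axis=0)
    sum_xy = (Xv * y[:, None]).sum(axis=0)
    sum_x2 = (Xv * Xv).sum(axis=0)
    sum_y2 = (sy * y[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sum_xy - sum_x * sum_y / n
        varx = sum_x2 - sum_x**2 / n
        vary = sum_y2 - sum_y**2 / n
        r2 = cov**2 / (varx * vary)
    scale_x = np.maximum(sum_x2, 1.0)
    scale_y = np.maximum(sum_y2, 1.0)
    bad = (n < 3) | (varx <= 1e-12 * scale_x) | (vary <= 1e-12 * scale_y)
    r2 = np.where(bad, np.nan, np.clip(r2, 0.0, 1.0))
    return r2


@dataclass
class Correlogram:
    """R² of one trait against every band combination of one index form."""

    trait: str
    form: IndexForm
    wavelengths: np.ndarray                    # strided axis, nm
    stride: float                              # nm
    matrix: np.ndarray | None = None           # 2-band forms: (m, m) R²
    triplets: list[tuple[tuple[float, float, float], float]] = field(
        default_factory=list)                  # NDI3: top-k [(a,b,c), R²]

    def top(self, k: int) -> list[tuple[tuple[float, ...], float]]:
        """Best-k combinations, ranked by R² descending (NaN skipped)."""
        if self.form is IndexForm.NDI3:
            return sorted(self.triplets, key=lambda t: (-t[1], t[0]))[:k]
        m = self.matrix
        wl = self.wavelengths
        if self.form is IndexForm.NDI2:
            iu = np.triu_indices(len(wl), k=1)
            combos = [((wl[i], wl[j]), m[i, j]) for i, j in zip(*iu)]
        else:  # RSI2: ordered pairs, a != b
            combos = [((wl[i], wl[j]), m[i, j])
                      for i in range(len(wl)) for j in range(len(wl)) if i != j]
        combos = [(c, float(v)) for c, v in combos if np.isfinite(v)]
        combos.sort(key=lambda t: (-t[1], t[0]))
        return combos[:k]

    def to_csv(self, path: str | Path) -> None:
        if self.matrix is None:
            df = pd.DataFrame(
                [{"band_a": a, "band_b": b, "band_c": c, "r2": v}
                 for (a, b, c), v in self.triplets]
            )
        else:
            df = pd.DataFrame(self.matrix,
                              index=self.wavelengths.astype(int),
                              columns=self.wavelengths.astype(int))
        df.to_csv(path, float_format="%.8g")

    def plot(self, ax=None):
        """Heat-map of the 2-band R² matrix (matplotlib)."""
        if self.matrix is None:
            raise ValueError("only 2-band correlograms have a matrix to plot")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.pcolormesh(self.wavelengths, self.wavelengths, self.matrix,
                           vmin=0, vmax=1, shading="nearest")
        ax.set_xlabel("wavelength b (nm)")
        ax.set_ylabel("wavelength a (nm)")
        ax.set_title(f"{self.form.value} vs {self.trait}: R²")
        plt.colorbar(im, ax=ax)
        return ax


def _strided_bands(sset: SpectraSet, stride: float) -> tuple[np.ndarray, np.ndarray]:
    wl = sset.wavelengths
    step = float(np.min(np.diff(wl)))
    if stride <= 0 or abs(stride / step - round(stride / step)) > 1e-9:
        raise ValueError(f"stride {stride} nm must be a positive multiple of "
                         f"the grid step {step} nm")
    every = int(round(stride / step))
    idx = np.arange(0, wl.size, every)
    return wl[idx], sset.reflectance[:, idx]


def correlogram_2d(sset: SpectraSet, traits: TraitTable, trait: str,
                   form: IndexForm | str, stride: float = 2.0) -> Correlogram:
    """Full R² matrix over all strided band pairs for a two-band form."""
    form = IndexForm(form)
    if form not in (IndexForm.RSI2, IndexForm.NDI2):
        raise ValueError("correlogram_2d supports RSI2 and NDI2 only")
    wl, R = _strided_bands(sset, stride)
    y = traits[trait]
    m = wl.size
    out = np.full((m, m), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(m):
            a = R[:, i][:, None]
            if form is IndexForm.RSI2:
                X = np.where(R == 0, np.nan, a / R)
            else:
                den = a + R
                X = np.where(den == 0, np.nan, (a - R) / den)
            out[i, :] = _columnwise_r2(X, y)
    # a == b is degenerate for both forms (constant 1 or constant 0)
    np.fill_diagonal(out, np.nan)
    if form is IndexForm.NDI2:  # enforce exact symmetry against fp jitter
        iu = np.triu_indices(m, k=1)
        out[(iu[1], iu[0])] = out[iu]
    return Correlogram(trait=trait, form=form, wavelengths=wl,
                       stride=float(stride), matrix=out)


def correlogram_3d(sset: SpectraSet, traits: TraitTable, trait: str,
                   stride: float = 4.0, top_k: int = 20,
                   budget: int = DEFAULT_TRIPLET_BUDGET) -> Correlogram:
    """Top-k NDI3 triplets (a; {b, c}, b <= c) over the strided grid."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    wl, R = _strided_bands(sset, stride)
    y = traits[trait]
    m = wl.size
    n_triplets = m * (m * (m + 1) // 2)
    if n_triplets > budget:
        raise BudgetExceededError(
            f"{n_triplets} triplets at stride {stride} nm exceeds the budget "
            f"of {budget}; increase the stride or the budget"
        )
    bi, ci = np.triu_indices(m)           # b <= c
    S = R[:, bi] + R[:, ci]               # n x P pair sums
    heap: list[tuple[float, tuple[float, float, float]]] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for ia in range(m):
            a = R[:, ia][:, None]
            den = a + S
            X = np.where(den == 0, np.nan, (a - S) / den)
            r2 = _columnwise_r2(X, y)
            order = np.argsort(np.nan_to_num(r2, nan=-np.inf))[::-1]
            for ip in order[: top_k]:
                v = r2[ip]
                if not np.isfinite(v):
                    continue
                trip = (float(wl[ia]), float(wl[bi[ip]]), float(wl[ci[ip]]))
                if len(heap) < top_k:
                    heapq.heappush(heap, (float(v), trip))
                elif v > heap[0][0]:
                    heapq.heapreplace(heap, (float(v), trip))
    ranked = sorted(((trip, v) for v, trip in heap), key=lambda t: (-t[1], t[0]))
    return Correlogram(trait=trait, form=IndexForm.NDI3, wavelengths=wl,
                       stride=float(stride), triplets=ranked)


# ---------------------------------------------------------------------------
# selection of the best combinations across forms

@dataclass
class RankedIndex:
    definition: IndexDefinition
    r2: float
    slope: float
    intercept: float
    pvalue: float


@dataclass
class SelectionResult:
    trait: str
    ranked: list[RankedIndex]

    @property
    def definitions(self) -> list[IndexDefinition]:
        return [r.definition for r in self.ranked]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "trait": self.trait,
            "ranked": [{
                **r.definition.to_dict(),
                "r2": r.r2, "slope": r.slope,
                "intercept": r.intercept, "pvalue": r.pvalue,
            } for r in self.ranked],
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _definition_for(form: IndexForm, wl: tuple[float, ...]) -> IndexDefinition:
    if form is IndexForm.RSI2:
        return IndexDefinition(rsi_name(*wl), form, wl)
    if form is IndexForm.NDI2:
        return IndexDefinition(ndi2_name(*wl), form, wl)
    return IndexDefinition(ndi3_name(*wl), form, wl)


def select_top_indices(correlograms: list[Correlogram], k: int,
                       sset: SpectraSet, traits: TraitTable) -> SelectionResult:
    """Globally rank combinations across forms and refit their regressions.

    Ties in R² are broken toward fewer bands, then lexicographically
    smaller wavelengths.  Requesting more combinations than exist returns
    everything available.
    """
    if not correlograms:
        raise ValueError("need at least one correlogram")
    trait = correlograms[0].trait
    if any(c.trait != trait for c in correlograms):
        raise ValueError("all correlograms must target the same trait")
    if k == 0:
        return SelectionResult(trait=trait, ranked=[])
    candidates: list[tuple[float, int, tuple[float, ...], IndexForm]] = []
    for c in correlograms:
        for wl, v in c.top(max(k, 1) * 4):
            candidates.append((float(v), len(wl), tuple(wl), c.form))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    seen: set[tuple] = set()
    y = traits[trait]
    ranked: list[RankedIndex] = []
    from .indices import evaluate_index

    for v, _, wl, form in candidates:
        key = (form.value, wl)
        if key in seen:
            continue
        seen.add(key)
        d = _definition_for(form, wl)
        fit = fit_simple_regression(evaluate_index(sset, d), y)
        ranked.append(RankedIndex(d, fit.r2, fit.slope, fit.intercept, fit.pvalue))
        if len(ranked) >= k:
            break
    return SelectionResult(trait=trait, ranked=ranked)


# ---------------------------------------------------------------------------
# model-style front end

class BandSearch:
    """Band-combination search posed as a model over a dataset.

    ``BandSearch(spectra, traits, trait="An").fit()`` runs the requested
    searches and returns a :class:`BandSearchResults` holding the
    correlograms, ready for ranking and export.
    """

    def __init__(self, spectra: SpectraSet, traits: TraitTable, trait: str,
                 forms: tuple[IndexForm | str, ...] = (IndexForm.RSI2, IndexForm.NDI2),
                 stride: float = 4.0, top_k: int = 20,
                 budget: int = DEFAULT_TRIPLET_BUDGET):
        self.spectra = spectra
        self.traits = traits
        self.trait = trait
        self.forms = tuple(IndexForm(f) for f in forms)
        self.stride = float(stride)
        self.top_k = int(top_k)
        self.budget = int(budget)

    def fit(self) -> "BandSearchResults":
        correlograms = []
        for form in self.forms:
            if form is IndexForm.NDI3:
                correlograms.append(correlogram_3d(
                    self.spectra, self.traits, self.trait,
                    stride=self.stride, top_k=self.top_k, budget=self.budget))
            else:
                correlograms.append(correlogram_2d(
                    self.spectra, self.traits, self.trait, form,
                    stride=self.stride))
        return BandSearchResults(self, correlograms)


class BandSearchResults:
    def __init__(self, model: BandSearch, correlograms: list[Correlogram]):
        self.model = model
        self.correlograms = correlograms

    def select_top(self, k: int | None = None) -> SelectionResult:
        k = k if k is not None else self.model.top_k
        return select_top_indices(self.correlograms, k,
                                  self.model.spectra, self.model.traits)

    def summary(self, k: int = 10) -> pd.DataFrame:
        sel = self.select_top(k)
        return pd.DataFrame([{
            "index": r.definition.name,
            "form": r.definition.form.value,
            "wavelengths": ",".join(f"{w:g}" for w in r.definition.wavelengths),
            "r2": r.r2,
            "slope": r.slope,
            "intercept": r.intercept,
            "pvalue": r.pvalue,
        } for r in sel.ranked])
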