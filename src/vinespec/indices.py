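"""Spectral reflectance indices (SRIs) for fruit-ripeness monitoring.

An SRI is a scalar combination of reflectance values at a few fixed
wavelengths that proxies a biochemical trait (anthocyanin, soluble solids,
acidity).  Three generic forms are supported besides the four classic
published indices:

``RSI2``
    ratio spectral index, ``R_a / R_b`` (order matters);
``NDI2``
    two-band normalized difference, ``(R_a - R_b) / (R_a + R_b)``;
``NDI3``
    three-band normalized difference,
    ``(R_a - R_b - R_c) / (R_a + R_b + R_c)`` (symmetric in b and c).

The published forms are the normalized difference vegetation index (NDVI,
780/670 nm), the anthocyanin index (NAI, 760/720 nm), the greenness index
(GI, R554/R677) and the pigment-sensitive ripening monitoring index
(PRMI, (R750 - R678)/R550).

:func:`default_registry` returns the 30-index working set used throughout
the package: the 4 published indices, 12 two-band ratio indices and 14
three-band normalized-difference indices tuned to the pigment (540-690 nm)
and NIR water (950-1148 nm) regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import SpectraSet


class IndexForm(str, Enum):
    PUBLISHED_NDVI = "PUBLISHED_NDVI"
    PUBLISHED_NAI = "PUBLISHED_NAI"
    PUBLISHED_GI = "PUBLISHED_GI"
    PUBLISHED_PRMI = "PUBLISHED_PRMI"
    RSI2 = "RSI2"
    NDI2 = "NDI2"
    NDI3 = "NDI3"


_ARITY = {
    IndexForm.PUBLISHED_NDVI: 2,
    IndexForm.PUBLISHED_NAI: 2,
    IndexForm.PUBLISHED_GI: 2,
    IndexForm.PUBLISHED_PRMI: 3,
    IndexForm.RSI2: 2,
    IndexForm.NDI2: 2,
    IndexForm.NDI3: 3,
}


@dataclass(frozen=True)
class IndexDefinition:
    """A named spectral index: its functional form plus its wavelengths."""

    name: str
    form: IndexForm
    wavelengths: tuple[float, ...]

    def __post_init__(self) -> None:
        form = IndexForm(self.form)
        object.__setattr__(self, "form", form)
        wl = tuple(float(w) for w in self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        if len(wl) != _ARITY[form]:
            raise ValueError(
                f"{self.name}: form {form.value} needs {_ARITY[form]} "
                f"wavelengths, got {len(wl)}"
            )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "form": self.form.value,
            "wavelengths": list(self.wavelengths),
        }


def evaluate_index(sset: SpectraSet, idx: IndexDefinition) -> np.ndarray:
    """Evaluate one index per sample.

    Bands are resolved on the grid via :meth:`SpectraSet.band_at` (nearest
    band, tie toward the lower wavelength).  Samples whose denominator is
    exactly zero get NaN — undefined values propagate as missing, never as
    a silent 0.
    """
    bands = [sset.band_at(w)[1] for w in idx.wavelengths]
    form = idx.form
    if form in (IndexForm.PUBLISHED_NDVI, IndexForm.PUBLISHED_NAI, IndexForm.NDI2):
        a, b = bands
        num, den = a - b, a + b
    elif form in (IndexForm.PUBLISHED_GI, IndexForm.RSI2):
        a, b = bands
        num, den = a, b
    elif form is IndexForm.PUBLISHED_PRMI:
        a, b, c = bands
        num, den = a - b, c
    elif form is IndexForm.NDI3:
        a, b, c = bands
        num, den = a - b - c, a + b + c
    else:  # pragma: no cover
        raise ValueError(f"unknown form {form}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, np.nan, num / np.where(den == 0, 1.0, den))
    return out


class IndexRegistry:
    """An ordered, unique-by-name collection of index definitions."""

    def __init__(self, definitions: list[IndexDefinition],
                 aliases: dict[str, str] | None = None):
        names = [d.name for d in definitions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate index names: {sorted(dupes)}")
        self._defs = list(definitions)
        self._by_name = {d.name: d for d in definitions}
        #: alternative spellings occasionally used in report tables,
        #: mapped onto the canonical definitions
        self.aliases = dict(aliases or {})

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self._defs]

    def get(self, name: str) -> IndexDefinition:
        canonical = self.aliases.get(name, name)
        try:
            return self._by_name[canonical]
        except KeyError:
            raise KeyError(f"unknown index {name!r}") from None

    def subset(self, names: list[str]) -> "IndexRegistry":
        return IndexRegistry([self.get(n) for n in names])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"indices": [d.to_dict() for d in self._defs], "aliases": self.aliases},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "IndexRegistry":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        defs = [
            IndexDefinition(d["name"], IndexForm(d["form"]), tuple(d["wavelengths"]))
            for d in obj["indices"]
        ]
        return cls(defs, aliases=obj.get("aliases"))


def evaluate_registry(sset: SpectraSet, registry: IndexRegistry) -> pd.DataFrame:
    """samples x indices feature matrix, columns in registry order."""
    data = {d.name: evaluate_index(sset, d) for d in registry}
    return pd.DataFrame(data, index=pd.Index(sset.sample_ids, name="sample_id"))


# ---------------------------------------------------------------------------
# the default 30-index working set

_RSI2_PAIRS = [
    (670, 594), (684, 1140), (598, 644), (592, 650), (610, 628), (638, 614),
    (664, 434), (668, 448), (638, 490), (540, 950), (626, 1018), (632, 964),
]

_NDI3_TRIPLES = [
    (822, 750, 552), (824, 750, 554), (822, 750, 550),
    (1126, 696, 696), (1126, 694, 696), (1126, 696, 694),
    (1126, 698, 696), (1126, 696, 698),
    (1144, 684, 562), (1144, 682, 566), (1144, 682, 564),
    (1148, 690, 690), (1148, 688, 690), (1148, 688, 688),
]

#: report-table spellings that differ from the canonical definitions
DEFAULT_ALIASES = {
    "RSI_668,442": "RSI_668,448",
    "RSI_680,1140": "RSI_684,1140",
    "R_822,750,552": "NDI_822,750,552",
    "R_1144,684,562": "NDI_1144,684,562",
}


def rsi_name(a: float, b: float) -> str:
    return f"RSI_{a:g},{b:g}"


def ndi2_name(a: float, b: float) -> str:
    return f"NDI_{a:g},{b:g}"


def ndi3_name(a: float, b: float, c: float) -> str:
    return f"NDI_{a:g},{b:g},{c:g}"


def default_registry() -> IndexRegistry:
    """The canonical 30-index registry: 4 published + 12 RSI + 14 NDI."""
    defs = [
        IndexDefinition("NDVI", IndexForm.PUBLISHED_NDVI, (780, 670)),
        IndexDefinition("NAI", IndexForm.PUBLISHED_NAI, (760, 720)),
        IndexDefinition("GI", IndexForm.PUBLISHED_GI, (554, 677)),
        IndexDefinition("PRMI", IndexForm.PUBLISHED_PRMI, (750, 678, 550)),
    ]
    defs += [
        IndexDefinition(rsi_name(a, b), IndexForm.RSI2, (a, b))
        for a, b in _RSI2_PAIRS
    ]
    defs += [
        IndexDefinition(ndi3_name(a, b, c), IndexForm.NDI3, (a, b, c))
        for a, b, c in _NDI3_TRIPLES
    ]
    return IndexRegistry(defs, aliases=dict(DEFAULT_ALIASES))
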