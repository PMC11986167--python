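"""Reflectance spectra and trait-table containers, calibration, and CSV I/O.

A :class:`SpectraSet` holds a samples x bands reflectance matrix on a fixed
wavelength grid (nm).  The canonical grid for the supported field instrument
is 302-1148 nm at a 2 nm bandwidth (424 bands), but any strictly increasing
grid is accepted.  A :class:`TraitTable` holds the per-sample ripening
indicators: anthocyanin concentration (An, mg/L), total soluble solids
(TSS, %), titratable acidity (TA, %) and the maturation index TSS/TA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TRAIT_NAMES = ("An", "TSS", "TA", "TSS_TA")

#: canonical instrument grid: 302-1148 nm inclusive, 2 nm bandwidth
DEFAULT_GRID = np.arange(302, 1149, 2)


@dataclass
class SpectraSet:
    """Calibrated reflectance spectra for a set of samples.

    Parameters
    ----------
    wavelengths : array of nm values, strictly increasing
    reflectance : (n_samples, n_bands) matrix, finite, nominally in [0, 1]
    sample_ids : unique sample identifiers
    groups : per-sample maturity label (e.g. ``LM``/``SM``/``FM``)
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = [str(g) for g in self.groups]
        n, b = self.reflectance.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} spectra but {len(self.sample_ids)} sample ids"
            )
        if len(self.groups) != n:
            raise ValueError("groups must align with sample ids")
        if b != self.wavelengths.size:
            raise ValueError(
                f"{b} reflectance columns but {self.wavelengths.size} wavelengths"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def band_at(self, nm: float) -> tuple[float, np.ndarray]:
        """Per-sample reflectance at the grid band nearest ``nm``.

        Exact grid matches are returned as-is; otherwise the nearest grid
        wavelength is used, with ties broken toward the lower wavelength.
        Returns ``(resolved_wavelength, values)`` so callers always know
        which band actually answered the query.
        """
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= nm <= hi):
            raise ValueError(
                f"wavelength {nm} nm outside grid range [{lo:g}, {hi:g}] nm"
            )
        dist = np.abs(self.wavelengths - nm)
        # argmin returns the first (lowest-wavelength) minimiser: tie-low rule
        j = int(np.argmin(dist))
        return float(self.wavelengths[j]), self.reflectance[:, j]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"w{int(w) if float(w).is_integer() else w}" for w in self.wavelengths]
        df = pd.DataFrame(self.reflectance, columns=cols)
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class TraitTable:
    """Per-sample ripening indicators with the derived TSS/TA ratio."""

    sample_ids: list[str]
    data: pd.DataFrame = field(repr=False)
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        missing = [c for c in ("An", "TSS", "TA") if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns {missing}")
        if len(self.data) != len(self.sample_ids):
            raise ValueError("trait rows must align with sample ids")
        if np.any(self.data["TA"].to_numpy() <= 0):
            raise ValueError("TA must be strictly positive")
        if "TSS_TA" not in self.data.columns:
            self.data = self.data.assign(
                TSS_TA=self.data["TSS"] / self.data["TA"]
            )
        if self.groups is not None:
            self.groups = [str(g) for g in self.groups]
            if len(self.groups) != len(self.sample_ids):
                raise ValueError("groups must align with sample ids")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __getitem__(self, trait: str) -> np.ndarray:
        return self.data[trait].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = self.data[list(TRAIT_NAMES)].copy()
        if self.groups is not None:
            df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitTable":
        groups = df["group"].tolist() if "group" in df.columns else None
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            data=df[[c for c in TRAIT_NAMES if c in df.columns]].reset_index(drop=True),
            groups=groups,
        )


def average_scans(scans: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic per-band mean of repeated scans of one sample.

    Field protocol averages several scans taken at different positions on a
    cluster; this is that reduction.
    """
    if len(scans) == 0:
        raise ValueError("need at least one scan")
    arrs = [np.asarray(s, dtype=float) for s in scans]
    lengths = {a.shape for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"ragged scan lengths: {sorted(lengths)}")
    return np.mean(arrs, axis=0)


def calibrate_reflectance(
    raw: np.ndarray,
    white_reference: np.ndarray,
    wavelengths: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> SpectraSet:
    """Convert raw counts to reflectance against a white-reference scan.

    Reflectance is the per-band ratio raw / white_reference, clipped to
    [0, 1] (a near-100% Spectralon reference can yield ratios slightly
    above 1).  The white reference must be strictly positive everywhere.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    white = np.asarray(white_reference, dtype=float)
    if wavelengths is None:
        wavelengths = DEFAULT_GRID[: raw.shape[1]]
    wavelengths = np.asarray(wavelengths, dtype=float)
    if white.shape != (raw.shape[1],):
        raise ValueError("white reference must have one value per band")
    bad = np.where(white <= 0)[0]
    if bad.size:
        raise ValueError(
            "non-positive white reference at wavelength(s) "
            + ", ".join(f"{wavelengths[j]:g} nm" for j in bad[:5])
        )
    refl = np.clip(raw / white[None, :], 0.0, 1.0)
    n = raw.shape[0]
    ids = list(sample_ids) if sample_ids is not None else [f"s{i+1}" for i in range(n)]
    grp = list(groups) if groups is not None else ["NA"] * n
    return SpectraSet(wavelengths, refl, ids, grp)


# ---------------------------------------------------------------------------
# wide-CSV dialect: sample_id,group,w302,w304,...,w1148

def write_spectra_csv(sset: SpectraSet, path: str | Path) -> None:
    sset.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read the wide spectra CSV; wavelength columns are re-sorted ascending."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    if "group" not in df.columns:
        raise ValueError(f"{path}: missing 'group' column")
    wcols = [c for c in df.columns if c.startswith("w")]
    try:
        nm = {c: float(c[1:]) for c in wcols}
    except ValueError as exc:
        raise ValueError(f"{path}: malformed wavelength column: {exc}") from exc
    if not wcols:
        raise ValueError(f"{path}: no wavelength columns (w<nm>) found")
    if len(set(nm.values())) != len(wcols):
        raise ValueError(f"{path}: duplicate wavelength columns")
    wcols.sort(key=lambda c: nm[c])
    mat = df[wcols].to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        i, j = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"{path}: non-numeric/missing reflectance at row {i} column {wcols[j]}"
        )
    return SpectraSet(
        wavelengths=np.array([nm[c] for c in wcols]),
        reflectance=mat,
        sample_ids=df["sample_id"].astype(str).tolist(),
        groups=df["group"].astype(str).tolist(),
    )


def write_traits_csv(traits: TraitTable, path: str | Path) -> None:
    traits.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_traits_csv(path: str | Path) -> TraitTable:
    return TraitTable.from_frame(pd.read_csv(path))
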