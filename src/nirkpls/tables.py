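"""Tabular containers for spectra and reference chemistry.

A :class:`SpectraTable` is the ``X`` of calibration: one reflectance
spectrum per row over a common wavelength axis.  A reference table (plain
:class:`pandas.DataFrame`, one column per analyte) is the ``Y``.  Both
round-trip through CSV with the sample identifier in the first column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Analyte names with the units used throughout: sugar (percent),
#: vitamin C (mg/kg) and organic acid (g/kg).  Units are carried verbatim
#: and never converted.
ANALYTE_UNITS = {"SU": "%", "VC": "mg/kg", "OA": "g/kg"}


@dataclass
class SpectraTable:
    """n samples x p wavelengths of reflectance spectra.

    Parameters
    ----------
    X : ndarray, shape (n, p)
        Reflectance values (unitless, typically in (0, 1)).
    wavelengths : ndarray, shape (p,)
        Strictly increasing wavelength axis in nm.
    ids : list of str, length n
        Sample (or pixel) identifiers aligned with the rows of ``X``.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ids = list(self.ids)
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but {self.wavelengths.size} "
                "wavelengths were given"
            )
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids must align with the rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("spectra contain non-finite values")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def select(self, indices) -> "SpectraTable":
        """Row subset keeping the wavelength axis."""
        idx = np.asarray(indices, dtype=int)
        return SpectraTable(self.X[idx], self.wavelengths, [self.ids[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        if df.columns[0] != "id":
            raise ValueError("first column of a spectra CSV must be 'id'")
        wavelengths = np.array([float(c) for c in df.columns[1:]])
        return cls(df.iloc[:, 1:].to_numpy(float), wavelengths, df["id"].astype(str).tolist())


def read_reference_csv(path) -> pd.DataFrame:
    """Read a reference-chemistry table (first column id, then analytes)."""
    df = pd.read_csv(path)
    if df.columns[0] != "id":
        raise ValueError("first column of a reference CSV must be 'id'")
    return df.set_index("id")


def write_reference_csv(reference: pd.DataFrame, path) -> None:
    reference.rename_axis("id").to_csv(path)
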