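"""Spectroscopy helpers: CD mean-residue ellipticity and paramagnetic
titration normalization.

Circular dichroism signals recorded in millidegrees are put on the
per-residue molar scale

    MRE = CD_mdeg / (c * 10 * L * N_r)     [deg cm^2 dmol^-1 res^-1]

with ``c`` the peptide concentration in mol/L, ``L`` the path length in cm
and ``N_r`` the residue count.

Paramagnetic (Gd-DTPA) titrations report per-residue NMR peak volumes as a
function of added Gd3+.  Adding titrant dilutes the sample, so each point is
multiplied by its cumulative dilution factor (V0 + sum(V_added)) / V0 before
being normalized to the (corrected) Gd-free reference point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CDSpectrum", "PRETitration", "mre_convert", "pre_normalize",
           "read_cd_csv", "read_titration_csv"]


class SpectroError(ValueError):
    pass


@dataclass(frozen=True)
class CDSpectrum:
    """A CD spectrum in millidegrees with the sample parameters needed for
    the mean-residue-ellipticity conversion."""

    wavelength_nm: np.ndarray
    signal_mdeg: np.ndarray
    concentration_molar: float
    path_length_cm: float
    n_residues: int

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        sig = np.asarray(self.signal_mdeg, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "signal_mdeg", sig)
        if wl.shape != sig.shape:
            raise SpectroError("wavelength and signal lengths differ")
        if self.concentration_molar <= 0 or self.path_length_cm <= 0 or self.n_residues <= 0:
            raise SpectroError("concentration, path length and residue count must be > 0")


def mre_convert(spectrum: CDSpectrum) -> np.ndarray:
    """Mean residue ellipticity, deg cm^2 dmol^-1 per residue."""
    denom = spectrum.concentration_molar * 10.0 * spectrum.path_length_cm * spectrum.n_residues
    if denom == 0:
        raise SpectroError("zero denominator in MRE conversion")
    return spectrum.signal_mdeg / denom


@dataclass(frozen=True)
class PRETitration:
    """Peak volumes of one residue across a paramagnetic titration.

    The first point must be the Gd-free reference.  ``added_volumes`` are
    the cumulative-step titrant additions (same units as
    ``initial_volume``); the first entry is 0.
    """

    residue: str
    peak_volumes: np.ndarray
    added_volumes: np.ndarray
    initial_volume: float

    def __post_init__(self) -> None:
        pv = np.asarray(self.peak_volumes, dtype=float)
        av = np.asarray(self.added_volumes, dtype=float)
        object.__setattr__(self, "peak_volumes", pv)
        object.__setattr__(self, "added_volumes", av)
        if pv.shape != av.shape:
            raise SpectroError("peak and added-volume lengths differ")
        if pv.size == 0 or av[0] != 0:
            raise SpectroError("first point must be the Gd-free reference (0 added)")
        if self.initial_volume <= 0:
            raise SpectroError("initial volume must be > 0")
        if np.any(pv <= 0):
            raise SpectroError("peak volumes must be > 0")
        if np.any(np.diff(av) < 0):
            raise SpectroError("added volumes must be cumulative (non-decreasing)")


def pre_normalize(titration: PRETitration) -> np.ndarray:
    """Dilution-corrected intensities normalized to the Gd-free reference."""
    dilution = (titration.initial_volume + titration.added_volumes) / titration.initial_volume
    corrected = titration.peak_volumes * dilution
    return corrected / corrected[0]


# --------------------------------------------------------------------------
# CSV readers (columns documented in the README)
# --------------------------------------------------------------------------

def read_cd_csv(
    path, concentration_molar: float, path_length_cm: float, n_residues: int
) -> CDSpectrum:
    """Read a CD spectrum CSV with columns ``wavelength_nm, signal_mdeg``."""
    df = pd.read_csv(path, comment="#")
    if not {"wavelength_nm", "signal_mdeg"} <= set(df.columns):
        raise SpectroError("CD CSV needs columns: wavelength_nm, signal_mdeg")
    return CDSpectrum(
        df["wavelength_nm"].to_numpy(),
        df["signal_mdeg"].to_numpy(),
        concentration_molar,
        path_length_cm,
        n_residues,
    )


def read_titration_csv(path, initial_volume: float) -> list[PRETitration]:
    """Read a titration CSV with columns ``residue, added_volume,
    peak_volume`` (one row per residue per titration point)."""
    df = pd.read_csv(path, comment="#")
    needed = {"residue", "added_volume", "peak_volume"}
    if not needed <= set(df.columns):
        raise SpectroError(f"titration CSV needs columns: {sorted(needed)}")
    out = []
    for residue, grp in df.groupby("residue", sort=False):
        grp = grp.sort_values("added_volume")
        out.append(
            PRETitration(
                str(residue),
                grp["peak_volume"].to_numpy(),
                grp["added_volume"].to_numpy(),
                initial_volume,
            )
        )
    return out
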