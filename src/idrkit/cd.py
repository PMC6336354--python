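"""Circular-dichroism unit conversion.

Converts raw instrument readings in millidegrees to molar ellipticity
[theta] = m_deg * M / (10 * L * C) in deg cm^2 dmol^-1, where M is the
molecular weight (g/mol), L the cuvette path length (cm) and C the mass
concentration (g/L).  An optional per-residue mean ellipticity divides by
the number of residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EllipticityInput:
    mdeg: float                 # raw signal, millidegrees
    molecular_weight: float     # g/mol
    path_length_cm: float
    concentration_g_per_l: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0 or self.path_length_cm <= 0 or self.concentration_g_per_l <= 0:
            raise ValueError("molecular weight, path length and concentration must be positive")


def molar_ellipticity(inp: EllipticityInput) -> float:
    """[theta] = m_deg * M / (10 * L * C), deg cm^2 dmol^-1."""
    return inp.mdeg * inp.molecular_weight / (10.0 * inp.path_length_cm * inp.concentration_g_per_l)


def convert_spectrum(
    spectrum: pd.DataFrame,
    molecular_weight: float,
    path_length_cm: float,
    concentration_g_per_l: float,
    blank: pd.DataFrame | None = None,
    n_residues: int | None = None,
) -> pd.DataFrame:
    """Convert a (wavelength_nm, mdeg) spectrum to molar ellipticity.

    A blank buffer spectrum, if given, is subtracted pointwise (wavelengths
    must match).  With ``n_residues`` set, the mean per-residue ellipticity
    is reported instead of the molar one.
    """
    wl = np.asarray(spectrum["wavelength_nm"], dtype=float)
    mdeg = np.asarray(spectrum["mdeg"], dtype=float)
    if blank is not None:
        bwl = np.asarray(blank["wavelength_nm"], dtype=float)
        if bwl.shape != wl.shape or not np.allclose(bwl, wl):
            raise ValueError("blank wavelengths do not match sample wavelengths")
        mdeg = mdeg - np.asarray(blank["mdeg"], dtype=float)
    scale = molecular_weight / (10.0 * path_length_cm * concentration_g_per_l)
    theta = mdeg * scale
    col = "molar_ellipticity"
    if n_residues is not None:
        theta = theta / n_residues
        col = "mean_residue_ellipticity"
    return pd.DataFrame({"wavelength_nm": wl, col: theta})
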