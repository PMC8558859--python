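"""Matplotlib views of density maps, PMFs and spectra."""

from __future__ import annotations

import numpy as np

from .constants import HC_EV_NM


def plot_density(dmap, ax=None, cmap="coolwarm"):
    """Heat map of an axis-collapsed ligand density."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        dmap.density.T,
        origin="lower",
        extent=(dmap.x_edges[0], dmap.x_edges[-1], dmap.y_edges[0], dmap.y_edges[-1]),
        cmap=cmap,
        aspect="equal",
    )
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.figure.colorbar(im, ax=ax, label="ligand density (per frame)")
    return ax


def plot_pmf(profile, ax=None, label=None):
    """Free-energy profile with optional bootstrap band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.bin_centers, profile.free_energy, label=label)
    if profile.uncertainty is not None:
        ax.fill_between(
            profile.bin_centers,
            profile.free_energy - profile.uncertainty,
            profile.free_energy + profile.uncertainty,
            alpha=0.3,
        )
    ax.set_xlabel(r"$\xi$ (nm)")
    ax.set_ylabel("PMF (kJ/mol)")
    if label:
        ax.legend()
    return ax


def plot_spectrum(spectrum, ax=None, wavelength: bool = False, label=None):
    """Absorption spectrum in energy (eV) or wavelength (nm) domain."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if wavelength:
        x = HC_EV_NM / spectrum.grid_ev
        order = np.argsort(x)
        ax.plot(x[order], spectrum.intensity[order], label=label)
        ax.set_xlabel("wavelength (nm)")
    else:
        ax.plot(spectrum.grid_ev, spectrum.intensity, label=label)
        ax.set_xlabel("energy (eV)")
    ax.set_ylabel("intensity (arb. u.)")
    if label:
        ax.legend()
    return ax
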