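"""Reference data for the AD tau protofilament / bTVBT4 ligand system.

Small published quantities used as pipeline inputs and bookkeeping
anchors: the binding-site residue triads of the Alzheimer's-disease tau
fold, per-residue ligand-residue interaction energies from atomistic MD,
vertical excitation energies of the ligand's two bi-thiophene conformers,
and band-maximum reference wavelengths.  All energies kJ/mol or eV;
wavelengths nm.
"""

from __future__ import annotations

import pandas as pd

from .trajectory import SiteDefinition

__all__ = [
    "SITE_A",
    "SITE_B",
    "tau_site_interaction_energies",
    "site_energy_inputs",
    "ligand_excitations",
    "REFERENCE_WAVELENGTHS",
    "MAJOR_MODE_POPULATIONS",
    "FIBRIL_GEOMETRY",
]

#: Binding site A of the AD tau fold: hydrophobic pocket at
#: Ile360/Thr361/His362, frame anchored His362 -> Ile360.
SITE_A = SiteDefinition(
    "A", triad=(360, 361, 362), his_anchor=(362, "CA"), ile_anchor=(360, "CA")
)

#: Binding site B: Arg349/Val350/Gln351.
SITE_B = SiteDefinition(
    "B", triad=(349, 350, 351), his_anchor=(351, "CA"), ile_anchor=(349, "CA")
)

_ENERGY_ROWS = [
    # site, residue id, residue, LJ mean, LJ sd, Coulomb mean, Coulomb sd
    ("A", 360, "ILE", -50.5, 7.0, 4.8, 1.0),
    ("A", 361, "THR", -4.8, 2.0, -1.8, 2.0),
    ("A", 362, "HIS", -36.7, 8.0, -24.9, 14.0),
    ("B", 349, "ARG", -73.2, 13.0, 5.6, 12.0),
    ("B", 350, "VAL", -13.0, 4.0, -7.8, 4.0),
    ("B", 351, "GLN", -32.0, 11.0, 1.8, 9.0),
]


def tau_site_interaction_energies() -> pd.DataFrame:
    """Per-residue ligand-residue LJ/Coulomb interaction energies (kJ/mol).

    MD averages for the two tau binding sites; site totals are the sums
    of the per-residue means (A: LJ -91.9, Coulomb -21.9;
    B: LJ -118.2, Coulomb -0.5).
    """
    return pd.DataFrame(
        _ENERGY_ROWS,
        columns=[
            "site",
            "residue",
            "res_name",
            "lj_mean",
            "lj_sd",
            "coulomb_mean",
            "coulomb_sd",
        ],
    )


def site_energy_inputs(site: str) -> tuple[dict, dict]:
    """(means, sds) maps residue -> (lj, coulomb) for one site, ready for
    :func:`sitekit.synthetic.generate_energy_records`."""
    df = tau_site_interaction_energies()
    df = df[df["site"] == site]
    if df.empty:
        raise KeyError(f"unknown site {site!r}")
    means = {int(r.residue): (r.lj_mean, r.coulomb_mean) for r in df.itertuples()}
    sds = {int(r.residue): (r.lj_sd, r.coulomb_sd) for r in df.itertuples()}
    return means, sds


def ligand_excitations() -> pd.DataFrame:
    """Vertical S1 <- S0 excitation energies of the free ligand.

    TDDFT values for the trans and cis bi-thiophene conformers at two
    settings of long-range exact exchange (100 % and 65 %), with
    transition wavelengths and oscillator strengths.
    """
    rows = [
        ("trans", 100, 2.619, 473.5, 1.45),
        ("trans", 65, 2.541, 487.9, 1.45),
        ("cis", 100, 2.621, 473.0, 1.43),
        ("cis", 65, 2.547, 486.8, 1.44),
    ]
    return pd.DataFrame(
        rows, columns=["conformer", "exchange_pct", "energy_ev", "wavelength_nm", "f"]
    )


#: Band-maximum reference wavelengths (nm) for the solvated and
#: protein-bound ligand: simulated cis/trans/combined maxima in water,
#: the experimental water value, the simulated protein-site maximum and
#: its blue shift relative to the measured excitation spectrum.
REFERENCE_WAVELENGTHS = {
    "water_cis": 485.0,
    "water_trans": 480.0,
    "water_combined": 483.0,
    "water_experiment": 470.0,
    "protein_theory": 502.0,
    "protein_blue_shift_nm": 33.0,
}

#: Equilibrium major-mode populations at site A from the PMF study,
#: ranked UR > UL > DR > DL.
MAJOR_MODE_POPULATIONS = {"UR": 0.47, "UL": 0.30, "DR": 0.19, "DL": 0.04}

#: Relaxed periodic fibril geometry: layers per periodic cell, per-layer
#: twist (degrees) and rise (nm) at 300 K, under 2-fold screw symmetry.
FIBRIL_GEOMETRY = {
    "n_layers": 185,
    "screw_order": 2,
    "twist_deg": 0.97,
    "rise_nm": 0.48,
    "temperature_K": 300.0,
}
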