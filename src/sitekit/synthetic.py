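"""Synthetic inputs with planted ground truth for the whole pipeline.

Every downstream stage (density maps, mode classification, WHAM, spectra)
is exercised on data generated here, with the statistical structure the
analysis assumes:

* a toy C-shaped protofilament layer with labelled binding-site triads,
* ligand trajectories with planted binding-site occupancy, major-mode
  (ethyl up/down x left/right) and minor-mode (torsional) labels,
* umbrella-sampling window series drawn from the exact biased Boltzmann
  density of a known analytic 1-D potential, and
* per-snapshot excitation energies and per-residue LJ/Coulomb interaction
  records drawn about stated means.

Because the generating parameters are known, recovery by the analysis
modules is a sharp statistical test (binomial confidence intervals for
mode weights, standard-error bounds for means, analytic profiles for
WHAM).  A single integer seed feeds a splittable ``SeedSequence`` so each
generator draws from an independent, reproducible stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, KB_KJ_PER_MOL_K
from .fibril import FibrilModel, Layer
from .trajectory import (
    LIGAND_ATOM_LABELS,
    MAJOR_MODES,
    LigandTrajectory,
    SiteDefinition,
    site_frame,
)

__all__ = [
    "SyntheticConfig",
    "AnalyticPotential",
    "generate_toy_layer",
    "generate_ligand_trajectory",
    "generate_umbrella_windows",
    "generate_snapshot_energies",
    "generate_energy_records",
    "write_umbrella_windows",
    "read_umbrella_windows",
]

#: Charge split between the bi-thiophene and benzothiazole moieties of the
#: cationic ligand (ground state); defines the charge-center pseudo-atom.
_CHARGE_SPLIT = (0.44, 0.56)

# pseudo-bond lengths (nm) and angles (deg) of the six-point toy ligand
_BONDS = (0.40, 0.40, 0.25, 0.35)
_ANGLES = (120.0, 120.0, 120.0)


def _normalized(w, name: str, tol: float = 1e-12):
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError(f"{name} must be non-negative")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 (got {w.sum()!r})")
    return w


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-trajectory generator.

    Defaults mirror the simulation setup being emulated: 60 ligands
    sampled both in the bulk and in the cavity, frames 20 ps apart,
    300 K, and planted major-mode weights of 47/30/19/4 % (assigned to
    the modes in the fixed order UL/UR/DL/DR).  ``bulk_fraction`` is the
    per-configuration probability of a ligand being free in the box
    rather than bound at site A.
    """

    seed: int = 0
    n_frames: int = 2000
    n_ligands: int = 60
    mode_weights: tuple = (0.47, 0.30, 0.19, 0.04)
    minor_mode_weights: tuple = ((0.25, 0.25, 0.25, 0.25),) * 4
    site_center: np.ndarray | None = None
    site_spread: float = 0.10
    bulk_fraction: float = 0.5
    temperature: float = DEFAULT_TEMPERATURE_K
    box: np.ndarray | None = None
    frame_interval_ps: float = 20.0

    def __post_init__(self) -> None:
        self.mode_weights = tuple(_normalized(self.mode_weights, "mode_weights"))
        if len(self.mode_weights) != 4:
            raise ValueError("mode_weights must have four entries (UL/UR/DL/DR)")
        if len(self.minor_mode_weights) != 4:
            raise ValueError("minor_mode_weights needs one vector per major mode")
        self.minor_mode_weights = tuple(
            tuple(_normalized(w, "minor_mode_weights")) for w in self.minor_mode_weights
        )
        if self.site_spread <= 0:
            raise ValueError("site_spread must be positive")
        if not 0.0 <= self.bulk_fraction <= 1.0:
            raise ValueError("bulk_fraction must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class AnalyticPotential:
    """A 1-D potential with a known closed form, used as a WHAM oracle.

    Stands in for the free-energy landscape along the ligand pulling
    coordinate.  ``kind`` is one of ``harmonic | double-well | tabulated |
    multi-well | custom``; ``fn`` evaluates U(x) in kJ/mol for x in nm
    over ``domain``.
    """

    kind: str
    fn: callable
    domain: tuple[float, float]
    params: dict = field(default_factory=dict)

    def __call__(self, x):
        return self.fn(np.asarray(x, dtype=float))

    @classmethod
    def harmonic(cls, k: float = 100.0, x0: float = 0.0, domain=(-1.0, 1.0)):
        """U(x) = k/2 (x - x0)^2."""
        return cls(
            "harmonic",
            lambda x: 0.5 * k * (x - x0) ** 2,
            domain,
            {"k": k, "x0": x0},
        )

    @classmethod
    def double_well(
        cls,
        barrier: float = 6.0,
        half_separation: float = 0.5,
        center: float = 0.0,
        tilt: float = 0.0,
        domain=(-1.2, 1.2),
    ):
        """Quartic double well with minima at center +/- half_separation.

        ``barrier`` (kJ/mol) is the height at the central maximum;
        ``tilt`` adds a linear term making the wells inequivalent.
        """
        w = half_separation
        if w <= 0:
            raise ValueError("half_separation must be positive")

        def u(x):
            y = x - center
            return barrier * (y**2 - w**2) ** 2 / w**4 + tilt * y

        return cls(
            "double-well",
            u,
            domain,
            {"barrier": barrier, "half_separation": w, "center": center, "tilt": tilt},
        )

    @classmethod
    def multi_well(cls, depths, centers, widths, domain):
        """Sum of Gaussian wells: U(x) = -sum_i d_i exp(-(x-c_i)^2/2w_i^2).

        With a single well of depth D and a domain extending several
        widths past the well, the PMF binding energy (bulk plateau minus
        minimum) equals D by construction.
        """
        depths = np.asarray(depths, dtype=float)
        centers = np.asarray(centers, dtype=float)
        widths = np.asarray(widths, dtype=float)
        if (widths <= 0).any():
            raise ValueError("well widths must be positive")

        def u(x):
            x = np.asarray(x, dtype=float)
            terms = depths * np.exp(
                -((x[..., None] - centers) ** 2) / (2.0 * widths**2)
            )
            return -terms.sum(axis=-1)

        return cls(
            "multi-well",
            u,
            domain,
            {"depths": depths, "centers": centers, "widths": widths},
        )

    @classmethod
    def tabulated(cls, x, u, domain=None):
        from scipy.interpolate import CubicSpline

        x = np.asarray(x, dtype=float)
        u = np.asarray(u, dtype=float)
        spline = CubicSpline(x, u)
        if domain is None:
            domain = (float(x[0]), float(x[-1]))
        return cls("tabulated", spline, domain, {"x": x, "u": u})

    @classmethod
    def from_callable(cls, fn, domain, kind: str = "custom"):
        return cls(kind, fn, domain, {})


# ---------------------------------------------------------------------------
# toy protofilament layer
# ---------------------------------------------------------------------------


def generate_toy_layer(
    n_residues: int = 73,
    c_shape_radius: float = 4.0,
    seed: int = 0,
    start_res_id: int = 306,
) -> Layer:
    """A planar C-shaped arc of pseudo-residues with labelled site triads.

    Emulates the cross-section of one tau protofilament layer: an open
    270-degree arc of ``n_residues`` residues (four pseudo-atoms each: N,
    CA, CB, C) in the z = 0 plane.  Residue ids start at ``start_res_id``
    (306, the first ordered core residue of the tau fold); if the id
    ranges 360-362 and 349-351 fall inside the arc they are labelled as
    the site-A (Ile/Thr/His) and site-B (Arg/Val/Gln) triads, otherwise
    triads are placed at fixed fractions of the arc.  Site definitions
    are attached to ``layer.sites``.
    """
    if n_residues < 3:
        raise ValueError("a C-shaped layer needs at least 3 residues")
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(np.linspace(135.0, -135.0, n_residues))
    dtheta = theta[1] - theta[0]
    r = c_shape_radius

    ids = start_res_id + np.arange(n_residues)
    # choose the two site triads
    if ids[0] <= 360 and ids[-1] >= 362:
        a_triad = (360, 361, 362)
    else:
        m = n_residues // 2
        a_triad = tuple(int(i) for i in ids[m - 1 : m + 2])
    if ids[0] <= 349 and ids[-1] >= 351 and 349 >= ids[0] + 3:
        b_triad = (349, 350, 351)
    else:
        q = max(1, n_residues // 4)
        b_triad = tuple(int(i) for i in ids[q - 1 : q + 2])

    res_names = np.array(["GLY"] * n_residues, dtype=object)
    for triad, names in ((a_triad, ("ILE", "THR", "HIS")), (b_triad, ("ARG", "VAL", "GLN"))):
        for rid, name in zip(triad, names):
            res_names[rid - start_res_id] = name

    atom_names, res_names_out, res_ids_out, coords = [], [], [], []
    for i in range(n_residues):
        ca = np.array([r * np.cos(theta[i]), r * np.sin(theta[i]), 0.0])
        tangent = np.array([-np.sin(theta[i]), np.cos(theta[i]), 0.0]) * np.sign(dtheta)
        inward = -np.array([np.cos(theta[i]), np.sin(theta[i]), 0.0])
        jitter = rng.normal(0.0, 0.01, size=(4, 3))
        positions = {
            "N": ca - 0.12 * tangent + jitter[0],
            "CA": ca,
            "CB": ca + 0.15 * inward + jitter[1],
            "C": ca + 0.12 * tangent + jitter[2],
        }
        for name, pos in positions.items():
            atom_names.append(name)
            res_names_out.append(res_names[i])
            res_ids_out.append(int(ids[i]))
            coords.append(pos)

    layer = Layer(
        atom_names=np.array(atom_names, dtype=object),
        res_names=np.array(res_names_out, dtype=object),
        res_ids=np.array(res_ids_out, dtype=int),
        coords=np.array(coords),
    )
    layer.sites = {
        "A": SiteDefinition(
            "A",
            triad=a_triad,
            his_anchor=(a_triad[2], "CA"),
            ile_anchor=(a_triad[0], "CA"),
        ),
        "B": SiteDefinition(
            "B",
            triad=b_triad,
            his_anchor=(b_triad[2], "CA"),
            ile_anchor=(b_triad[0], "CA"),
        ),
    }
    return layer


# ---------------------------------------------------------------------------
# planted ligand trajectories
# ---------------------------------------------------------------------------


def _place_chain(d1_deg: np.ndarray, d2_deg: np.ndarray) -> np.ndarray:
    """Build the 5-atom ligand chain (BTC, VIN, BZT, THI, ETH) for each row.

    Vectorised internal-coordinate construction: fixed pseudo-bond
    lengths and 120-degree angles; ``d1`` is the BTC-VIN-BZT-THI torsion
    (bi-thiophene inter-ring stand-in) and ``d2`` the VIN-BZT-THI-ETH
    torsion (thiazole-ethyl stand-in).
    """
    n = len(d1_deg)
    pts = np.zeros((n, 5, 3))
    b1, b2, b3, b4 = _BONDS
    a = np.deg2rad(_ANGLES[0])
    pts[:, 1] = [b1, 0.0, 0.0]
    pts[:, 2] = pts[:, 1] + [b2 * -np.cos(a), b2 * np.sin(a), 0.0]
    pts[:, 3] = _place_atoms(pts[:, 0], pts[:, 1], pts[:, 2], b3, _ANGLES[1], d1_deg)
    pts[:, 4] = _place_atoms(pts[:, 1], pts[:, 2], pts[:, 3], b4, _ANGLES[2], d2_deg)
    return pts


def _place_atoms(p0, p1, p2, bond, angle_deg, dihedral_deg) -> np.ndarray:
    """Vectorised NeRF placement over leading axes."""
    t_ang = np.deg2rad(angle_deg)
    t_dih = np.deg2rad(np.asarray(dihedral_deg, dtype=float))
    d = np.stack(
        [
            np.broadcast_to(-bond * np.cos(t_ang), t_dih.shape),
            bond * np.sin(t_ang) * np.cos(t_dih),
            bond * np.sin(t_ang) * np.sin(t_dih),
        ],
        axis=-1,
    )
    bc = p2 - p1
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(p1 - p0, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.stack([bc, np.cross(n, bc), n], axis=-1)
    return p2 + np.einsum("...ij,...j->...i", m, d)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batch of rotation matrices mapping unit vectors a onto b."""
    a = a / np.linalg.norm(a, axis=-1, keepdims=True)
    b = b / np.linalg.norm(b, axis=-1, keepdims=True)
    v = np.cross(a, b)
    c = (a * b).sum(-1)
    s2 = (v * v).sum(-1)
    n = a.shape[0]
    vx = np.zeros((n, 3, 3))
    vx[:, 0, 1] = -v[:, 2]
    vx[:, 0, 2] = v[:, 1]
    vx[:, 1, 0] = v[:, 2]
    vx[:, 1, 2] = -v[:, 0]
    vx[:, 2, 0] = -v[:, 1]
    vx[:, 2, 1] = v[:, 0]
    factor = np.where(s2 > 1e-24, (1.0 - c) / np.where(s2 > 1e-24, s2, 1.0), 0.0)
    out = (
        np.eye(3)
        + vx
        + np.einsum("nij,njk->nik", vx, vx) * factor[:, None, None]
    )
    # degenerate rows: parallel (identity already) or antipodal (180 turn)
    anti = (s2 <= 1e-24) & (c < 0)
    for i in np.flatnonzero(anti):
        p = np.cross(a[i], [1.0, 0.0, 0.0])
        if np.linalg.norm(p) < 1e-8:
            p = np.cross(a[i], [0.0, 1.0, 0.0])
        p = p / np.linalg.norm(p)
        out[i] = 2.0 * np.outer(p, p) - np.eye(3)
    return out


def _charge_center(chain: np.ndarray) -> np.ndarray:
    """Charge-center pseudo-atom from the chain: weighted mean of the
    bi-thiophene and benzothiazole centroids by their moiety charges."""
    return _CHARGE_SPLIT[0] * chain[..., 0, :] + _CHARGE_SPLIT[1] * chain[..., 2, :]


def generate_ligand_trajectory(
    config: SyntheticConfig, fibril: FibrilModel
) -> LigandTrajectory:
    """Planted-occupancy ligand trajectory around a labelled fibril.

    Each (frame, ligand) configuration is independently either free in
    the simulation box (probability ``bulk_fraction``) or bound at site A
    with a major mode drawn from ``mode_weights`` and a minor mode from
    the per-major ``minor_mode_weights``.  Bound ligands have their ethyl
    vector oriented in the planted quadrant of the site frame and their
    two minor-mode torsions set near 0 or 180 degrees; the charge center
    is scattered isotropically about the site centroid with standard
    deviation ``site_spread``.  Ground-truth labels are attached as
    ``trajectory.truth``.
    """
    if "A" not in fibril.template.sites:
        raise ValueError("fibril template has no labelled site-A triad")
    site = fibril.template.sites["A"]
    center, xhat, yhat, zhat = site_frame(fibril, site)
    if config.site_center is not None:
        center = np.asarray(config.site_center, dtype=float)

    if config.box is None:
        lo = fibril.all_coords().min(axis=0) - 2.0
        hi = fibril.all_coords().max(axis=0) + 2.0
    else:
        box = np.asarray(config.box, dtype=float).reshape(2, 3)
        lo, hi = box[0], box[1]

    n = config.n_frames * config.n_ligands
    ss = np.random.SeedSequence(config.seed)
    rng_state, rng_mode, rng_geom, rng_bulk = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    is_bulk = rng_state.random(n) < config.bulk_fraction
    major_idx = rng_mode.choice(4, size=n, p=np.asarray(config.mode_weights))
    minor_idx = np.empty(n, dtype=int)
    for m in range(4):
        sel = major_idx == m
        minor_idx[sel] = rng_mode.choice(
            4, size=int(sel.sum()), p=np.asarray(config.minor_mode_weights[m])
        )

    # torsions near 0/180 per minor-mode bit, noise well inside the bin
    noise = rng_geom.normal(0.0, 20.0, size=(n, 2))
    d2 = 180.0 * (minor_idx // 2) + noise[:, 0]  # thiazole-ethyl (first bit)
    d1 = 180.0 * (minor_idx % 2) + noise[:, 1]  # inter-ring (second bit)
    chain = _place_chain(d1, d2)

    # orient the ethyl vector into the planted quadrant of the site frame
    tz = np.abs(rng_geom.normal(0.6, 0.2, size=n)).clip(0.05, None)
    ty = np.abs(rng_geom.normal(0.6, 0.2, size=n)).clip(0.05, None)
    tx = rng_geom.normal(0.0, 0.5, size=n)
    up = np.isin(major_idx, [0, 1])  # UL, UR
    right = np.isin(major_idx, [1, 3])  # UR, DR
    tz = np.where(up, tz, -tz)
    ty = np.where(right, ty, -ty)
    target = (
        tx[:, None] * xhat + ty[:, None] * yhat + tz[:, None] * zhat
    )
    e = chain[:, 4] - chain[:, 3]
    rot = _rotation_between(e, target)
    chain = np.einsum("nij,naj->nai", rot, chain)

    # translate so the charge center sits at the (jittered) site centroid
    chg = _charge_center(chain)
    offset = center + rng_geom.normal(0.0, config.site_spread, size=(n, 3)) - chg
    chain = chain + offset[:, None, :]

    # bulk configurations: random orientation, uniform in box, outside sites
    n_bulk = int(is_bulk.sum())
    if n_bulk:
        db = rng_bulk.uniform(-180.0, 180.0, size=(n_bulk, 2))
        bulk_chain = _place_chain(db[:, 0], db[:, 1])
        # random rotation from normalised Gaussian frames
        rand = rng_bulk.normal(size=(n_bulk, 3))
        rot_b = _rotation_between(
            np.broadcast_to([0.0, 0.0, 1.0], (n_bulk, 3)).copy(), rand
        )
        spin = rng_bulk.uniform(0.0, 2 * np.pi, size=n_bulk)
        cs, sn = np.cos(spin), np.sin(spin)
        spin_m = np.zeros((n_bulk, 3, 3))
        spin_m[:, 0, 0] = cs
        spin_m[:, 0, 1] = -sn
        spin_m[:, 1, 0] = sn
        spin_m[:, 1, 1] = cs
        spin_m[:, 2, 2] = 1.0
        rot_b = np.einsum("nij,njk->nik", rot_b, spin_m)
        bulk_chain = np.einsum("nij,naj->nai", rot_b, bulk_chain)
        pos = np.empty((n_bulk, 3))
        exclusion = []
        for s in fibril.template.sites.values():
            exclusion.append(
                (fibril.template.triad_centroid(s.triad), s.cutoff + 0.1)
            )
        todo = np.arange(n_bulk)
        while len(todo):
            cand = rng_bulk.uniform(lo, hi, size=(len(todo), 3))
            bad = np.zeros(len(todo), dtype=bool)
            for c, r in exclusion:
                bad |= np.linalg.norm(cand - c, axis=1) <= r
            pos[todo[~bad]] = cand[~bad]
            todo = todo[bad]
        bulk_chain = bulk_chain + (pos - _charge_center(bulk_chain))[:, None, :]
        chain[is_bulk] = bulk_chain

    coords6 = np.concatenate([chain, _charge_center(chain)[:, None, :]], axis=1)
    coords = coords6.reshape(config.n_frames, config.n_ligands, 6, 3)

    idx = np.indices((config.n_frames, config.n_ligands))
    truth = pd.DataFrame(
        {
            "frame": idx[0].ravel(),
            "ligand": idx[1].ravel(),
            "bound": ~is_bulk,
            "major": np.where(
                is_bulk, "unbound", np.take(np.array(MAJOR_MODES, dtype=object), major_idx)
            ),
            "minor": np.where(is_bulk, -1, minor_idx),
        }
    )
    return LigandTrajectory(
        coords,
        LIGAND_ATOM_LABELS,
        frame_interval_ps=config.frame_interval_ps,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# umbrella-sampling windows
# ---------------------------------------------------------------------------


def generate_umbrella_windows(
    potential: AnalyticPotential,
    centers,
    k_umb: float,
    n_samples: int,
    temperature: float = DEFAULT_TEMPERATURE_K,
    seed: int = 0,
    step: float = 0.05,
    burn_in: int = 1000,
    thinning: int = 10,
) -> list:
    """Draw biased window samples from a known analytic potential.

    For each window center c the reaction coordinate is sampled from the
    biased Boltzmann density proportional to
    ``exp(-[U(x) + k_umb/2 (x-c)^2] / kT)`` with a Metropolis chain
    (Gaussian proposals of width ``step``, ``burn_in`` discarded steps,
    one sample kept every ``thinning`` steps).  Proposals outside the
    potential's domain are rejected, i.e. the density is truncated to the
    domain.  Returns :class:`~sitekit.pmf.UmbrellaWindow` objects.
    """
    from .pmf import UmbrellaWindow

    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("at least one window center is required")
    if np.any(np.diff(centers) < 0):
        raise ValueError("window centers must be sorted ascending")
    if k_umb <= 0:
        raise ValueError("k_umb must be positive")
    kT = KB_KJ_PER_MOL_K * temperature
    lo, hi = potential.domain
    total = burn_in + n_samples * thinning
    # one independent stream per window; chains advance in lockstep so the
    # (cheap, vectorised) potential is evaluated once per step for all
    children = np.random.SeedSequence(seed).spawn(len(centers))
    prop = np.empty((len(centers), total))
    logu = np.empty((len(centers), total))
    for j, child in enumerate(children):
        rng = np.random.default_rng(child)
        prop[j] = rng.normal(0.0, step, size=total)
        logu[j] = np.log(rng.random(total))
    x = np.clip(centers, lo, hi).astype(float)
    u = potential(x) + 0.5 * k_umb * (x - centers) ** 2
    samples = np.empty((len(centers), n_samples))
    kept = 0
    for i in range(total):
        xn = x + prop[:, i]
        inside = (xn >= lo) & (xn <= hi)
        xe = np.where(inside, xn, x)  # evaluate only in-domain points
        un = potential(xe) + 0.5 * k_umb * (xe - centers) ** 2
        accept = inside & (logu[:, i] < -(un - u) / kT)
        x = np.where(accept, xn, x)
        u = np.where(accept, un, u)
        if i >= burn_in and (i - burn_in) % thinning == thinning - 1:
            samples[:, kept] = x
            kept += 1
    return [
        UmbrellaWindow(
            center=float(c), k_umb=k_umb, samples=samples[j], temperature=temperature
        )
        for j, c in enumerate(centers)
    ]


def write_umbrella_windows(windows, directory) -> None:
    """Write windows as one two-column series per window plus metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, w in enumerate(windows):
        name = f"window_{i:03d}.tsv"
        np.savetxt(directory / name, w.samples, fmt="%.8f")
        meta.append(
            {
                "file": name,
                "center": w.center,
                "k_umb": w.k_umb,
                "temperature": w.temperature,
            }
        )
    (directory / "windows.json").write_text(json.dumps(meta, indent=1))


def read_umbrella_windows(directory) -> list:
    from .pmf import UmbrellaWindow

    directory = Path(directory)
    meta = json.loads((directory / "windows.json").read_text())
    return [
        UmbrellaWindow(
            center=m["center"],
            k_umb=m["k_umb"],
            samples=np.loadtxt(directory / m["file"]),
            temperature=m["temperature"],
        )
        for m in meta
    ]


# ---------------------------------------------------------------------------
# snapshot energies and interaction-energy records
# ---------------------------------------------------------------------------


def generate_snapshot_energies(
    mean: float, sigma: float, n: int, seed: int = 0
) -> np.ndarray:
    """I.i.d. normal vertical excitation energies (eV) for n snapshots.

    Emulates decorrelated configurations (>= 20 ps apart) whose
    excitation energies scatter about a condensed-phase mean.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return mean + sigma * rng.standard_normal(n)


def generate_energy_records(
    per_residue_means: dict,
    per_residue_sds: dict,
    n_frames: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frame LJ/Coulomb interaction records about stated means.

    ``per_residue_means`` and ``per_residue_sds`` map residue id to an
    ``(lj, coulomb)`` pair in kJ/mol.  Each frame draws independent
    normal values per residue and channel; aggregation downstream
    recovers the means within standard-error bounds.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    for res, (lj_m, cou_m) in per_residue_means.items():
        lj_s, cou_s = per_residue_sds[res]
        if lj_s < 0 or cou_s < 0:
            raise ValueError("standard deviations must be non-negative")
        lj = rng.normal(lj_m, lj_s, size=n_frames)
        cou = rng.normal(cou_m, cou_s, size=n_frames)
        rows.append(
            pd.DataFrame(
                {"frame": np.arange(n_frames), "residue": res, "lj": lj, "coulomb": cou}
            )
        )
    return pd.concat(rows, ignore_index=True)
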