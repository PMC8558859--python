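"""Ligand-trajectory analysis: density maps, binding-mode classification,
mode populations, backbone planarity and interaction-energy aggregation.

The ligand studied here is a cationic bi-thiophene-vinylene-benzothiazole
(bTV-type) oligothiophene.  It is represented by six labelled reference
points (see :data:`LIGAND_ATOM_LABELS`): the bi-thiophene centroid, the
vinylene midpoint, the benzothiazole centroid, the thiazole-ring centroid,
the terminal ethyl carbon, and the molecular charge center.  These are the
minimum set needed to

* locate the ligand relative to a binding site (charge center),
* orient its ethyl group in the local site frame (major modes
  up/down x left/right), and
* resolve the torsional minor modes (thiazole-ethyl and bi-thiophene
  inter-ring rotations).

Binding site A on the Alzheimer's tau protofilament is the hydrophobic
pocket formed by Ile360/Thr361/His362; site B involves
Arg349/Val350/Gln351.  The local frame for the major-mode classification
is anchored on the His and Ile residues of the site triad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fibril import FibrilModel, axis_frame
from .geometry import dihedral, perpendicular_unit

__all__ = [
    "LIGAND_ATOM_LABELS",
    "DEFAULT_MINOR_DIHEDRALS",
    "TOY_BACKBONE_DIHEDRALS",
    "MAJOR_MODES",
    "SiteDefinition",
    "LigandTrajectory",
    "DensityMap",
    "density_map",
    "site_frame",
    "classify_major_mode",
    "classify_minor_mode",
    "classify_trajectory",
    "ModePopulations",
    "mode_populations",
    "planarity",
    "EnergyAggregate",
    "aggregate_energies",
]

#: Labels of the six ligand reference points, in chain order
#: (bi-thiophene, vinylene, benzothiazole, thiazole ring, ethyl terminal
#: carbon) plus the off-chain charge center.
LIGAND_ATOM_LABELS: tuple[str, ...] = ("BTC", "VIN", "BZT", "THI", "ETH", "CHG")

#: Dihedral quadruples (by atom label) defining the two minor-mode
#: torsions: rotation about the thiazole-ethyl bond and about the
#: bi-thiophene inter-ring bond.
DEFAULT_MINOR_DIHEDRALS: tuple[tuple[str, str, str, str], ...] = (
    ("VIN", "BZT", "THI", "ETH"),
    ("BTC", "VIN", "BZT", "THI"),
)

#: The two chain torsions resolvable on the six-point toy ligand; used as
#: its (reduced) conjugated-backbone dihedral set for planarity scoring.
TOY_BACKBONE_DIHEDRALS = DEFAULT_MINOR_DIHEDRALS

#: Major binding modes: up/down x left/right orientation of the ethyl
#: group in the site frame.
MAJOR_MODES: tuple[str, ...] = ("UL", "UR", "DL", "DR")

_TIE_EPS = 1e-6


@dataclass(frozen=True)
class SiteDefinition:
    """A fibril binding site: residue triad, frame anchors and cutoff.

    ``his_anchor`` / ``ile_anchor`` are ``(residue_id, atom_name)`` pairs
    naming the two atoms whose in-plane separation defines the local x
    direction of the mode-classification frame (His -> Ile for site A).
    ``cutoff`` (nm) is the maximum charge-center distance from the triad
    C-alpha centroid for a ligand to count as bound.
    """

    name: str
    triad: tuple[int, int, int]
    his_anchor: tuple[int, str]
    ile_anchor: tuple[int, str]
    cutoff: float = 0.7

    def __post_init__(self) -> None:
        if len(set(self.triad)) != 3:
            raise ValueError("site triad residues must be distinct")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class LigandTrajectory:
    """Per-frame coordinates of labelled ligand reference atoms.

    ``coords`` has shape (n_frames, n_ligands, n_atoms, 3) in nm.
    ``truth`` optionally carries generator ground-truth labels
    (columns: frame, ligand, bound, major, minor) for recovery tests.
    """

    coords: np.ndarray
    atom_labels: tuple[str, ...] = LIGAND_ATOM_LABELS
    frame_interval_ps: float = 20.0
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[3] != 3:
            raise ValueError("coords must have shape (frames, ligands, atoms, 3)")
        if self.coords.shape[2] != len(self.atom_labels):
            raise ValueError("atom axis does not match atom_labels")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, label: str) -> int:
        try:
            return self.atom_labels.index(label)
        except ValueError:
            raise KeyError(f"no ligand atom labelled {label!r}") from None

    def atom(self, label: str) -> np.ndarray:
        """Coordinates of one labelled atom, shape (frames, ligands, 3)."""
        return self.coords[:, :, self.atom_index(label), :]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (frame, ligand, atom, x, y, z)."""
        f, l, a, _ = self.coords.shape
        idx = np.indices((f, l, a))
        return pd.DataFrame(
            {
                "frame": idx[0].ravel(),
                "ligand": idx[1].ravel(),
                "atom": np.take(np.array(self.atom_labels, dtype=object), idx[2].ravel()),
                "x": self.coords[..., 0].ravel(),
                "y": self.coords[..., 1].ravel(),
                "z": self.coords[..., 2].ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        atom_labels: tuple[str, ...] = LIGAND_ATOM_LABELS,
        frame_interval_ps: float = 20.0,
    ) -> "LigandTrajectory":
        f = int(df["frame"].max()) + 1
        l = int(df["ligand"].max()) + 1
        a = len(atom_labels)
        coords = np.full((f, l, a, 3), np.nan)
        ai = {lab: i for i, lab in enumerate(atom_labels)}
        coords[
            df["frame"].to_numpy(int),
            df["ligand"].to_numpy(int),
            np.array([ai[x] for x in df["atom"]], dtype=int),
        ] = df[["x", "y", "z"]].to_numpy(float)
        if np.isnan(coords).any():
            raise ValueError("trajectory table is missing atom records")
        return cls(coords, atom_labels, frame_interval_ps)

    @classmethod
    def read_csv(cls, path, **kwargs) -> "LigandTrajectory":
        return cls.from_frame(pd.read_csv(path), **kwargs)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------


@dataclass
class DensityMap:
    """Axis-collapsed ligand density over the fibril cross-section.

    The grid counts ligand reference points projected onto the plane
    perpendicular to the fibril axis, summed along the axis over all
    layers (optionally after untwisting each point by its layer's screw
    rotation so that symmetry-equivalent sites superpose) and over all
    frames.  ``counts / frame_count`` is the time-averaged density.
    """

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float
    frame_count: int
    ligand_count: int
    n_outside: int = 0
    untwisted: bool = True

    @property
    def density(self) -> np.ndarray:
        return self.counts / float(self.frame_count)

    def argmax_center(self) -> tuple[float, float]:
        """In-plane (x, y) center of the most occupied bin."""
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (
            0.5 * (self.x_edges[i] + self.x_edges[i + 1]),
            0.5 * (self.y_edges[j] + self.y_edges[j + 1]),
        )

    def total(self) -> int:
        return int(self.counts.sum()) + self.n_outside


def site_frame(
    fibril: FibrilModel, site: SiteDefinition
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Local orthonormal frame of a binding site.

    Returns ``(center, xhat, yhat, zhat)``: the triad C-alpha centroid,
    the unit in-plane His->Ile direction, ``yhat = zhat x xhat``, and the
    fibril axis direction.  The frame is equivariant under rigid motions
    of the model, so mode labels are rotation-invariant.
    """
    tmpl = fibril.template
    center = tmpl.triad_centroid(site.triad)
    _, frame = axis_frame(fibril)
    zhat = frame[:, 2]
    his = tmpl.atom_coord(*site.his_anchor)
    ile = tmpl.atom_coord(*site.ile_anchor)
    xhat = perpendicular_unit(ile - his, zhat)
    yhat = np.cross(zhat, xhat)
    return center, xhat, yhat, zhat


def density_map(
    traj: LigandTrajectory,
    fibril: FibrilModel,
    bin_size: float = 0.05,
    untwist: bool = True,
    reference_atom: str = "CHG",
    extent: tuple[float, float, float, float] | None = None,
) -> DensityMap:
    """Bin ligand positions onto the fibril cross-section plane.

    Each ligand reference point is assigned to its nearest layer
    ``k = round(axial position / rise)``; with ``untwist`` the point is
    rotated about the axis by ``-k`` times the per-layer screw rotation,
    superposing all symmetry-equivalent binding sites, then projected
    onto the cross-section plane and binned.

    ``extent = (xmin, xmax, ymin, ymax)`` fixes the map domain (nm,
    in-plane axis coordinates); points outside are counted in
    ``n_outside``.  By default the domain is fitted to the data and
    padded to whole bins.
    """
    if traj.n_frames == 0 or traj.n_ligands == 0:
        raise ValueError("trajectory is empty")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    origin, frame = axis_frame(fibril)
    xhat, yhat, zhat = frame[:, 0], frame[:, 1], frame[:, 2]
    pts = traj.atom(reference_atom).reshape(-1, 3) - origin
    axial = pts @ zhat
    perp = pts - np.outer(axial, zhat)
    if untwist:
        k = np.rint(axial / fibril.rise)
        ang = np.deg2rad(-k * fibril.rotation_per_layer)
        cross = np.cross(np.broadcast_to(zhat, perp.shape), perp)
        perp = perp * np.cos(ang)[:, None] + cross * np.sin(ang)[:, None]
    px = perp @ xhat
    py = perp @ yhat
    if extent is None:
        lo_x = np.floor(px.min() / bin_size) * bin_size
        hi_x = np.ceil(px.max() / bin_size) * bin_size
        lo_y = np.floor(py.min() / bin_size) * bin_size
        hi_y = np.ceil(py.max() / bin_size) * bin_size
        hi_x = max(hi_x, lo_x + bin_size)
        hi_y = max(hi_y, lo_y + bin_size)
    else:
        lo_x, hi_x, lo_y, hi_y = extent
    x_edges = np.arange(lo_x, hi_x + 0.5 * bin_size, bin_size)
    y_edges = np.arange(lo_y, hi_y + 0.5 * bin_size, bin_size)
    counts, _, _ = np.histogram2d(px, py, bins=[x_edges, y_edges])
    inside = (
        (px >= x_edges[0]) & (px <= x_edges[-1]) & (py >= y_edges[0]) & (py <= y_edges[-1])
    )
    return DensityMap(
        counts=counts,
        x_edges=x_edges,
        y_edges=y_edges,
        bin_size=bin_size,
        frame_count=traj.n_frames,
        ligand_count=traj.n_ligands,
        n_outside=int((~inside).sum()),
        untwisted=untwist,
    )


# ---------------------------------------------------------------------------
# binding-mode classification
# ---------------------------------------------------------------------------


def _as_atom_dict(ligand) -> dict:
    if isinstance(ligand, dict):
        return ligand
    raise TypeError("ligand atoms must be a mapping label -> coordinate")


def classify_major_mode(
    ligand: dict,
    site: SiteDefinition,
    fibril: FibrilModel,
    frame: tuple | None = None,
) -> str:
    """Major binding mode (UL/UR/DL/DR) of one ligand configuration.

    The ethyl vector ``e`` runs from the thiazole-ring centroid to the
    terminal ethyl carbon.  In the site frame (z = fibril axis, x = His->
    Ile in-plane direction, y = z x x): up (U) if ``e . z > 0`` else down
    (D); right (R) if ``e . y > 0`` else left (L).  Exact ties (within
    1e-6) resolve to U and R deterministically.  Returns ``"unbound"``
    when the charge center lies beyond the site cutoff.
    """
    atoms = _as_atom_dict(ligand)
    for lab in ("THI", "ETH", "CHG"):
        if lab not in atoms:
            raise ValueError(f"ligand is missing labelled atom {lab!r}")
    center, xhat, yhat, zhat = frame if frame is not None else site_frame(fibril, site)
    chg = np.asarray(atoms["CHG"], dtype=float)
    if np.linalg.norm(chg - center) > site.cutoff:
        return "unbound"
    e = np.asarray(atoms["ETH"], dtype=float) - np.asarray(atoms["THI"], dtype=float)
    ez, ey = e @ zhat, e @ yhat
    ud = "U" if ez > -_TIE_EPS else "D"
    lr = "R" if ey > -_TIE_EPS else "L"
    return ud + lr


def classify_minor_mode(
    ligand: dict,
    dihedrals: tuple[tuple[str, str, str, str], ...] = DEFAULT_MINOR_DIHEDRALS,
) -> int:
    """Minor (torsional) mode index in 0..3.

    Each of the two torsions (thiazole-ethyl, bi-thiophene inter-ring) is
    binned by the sign of its cosine — near-planar-cis (|theta| < 90°,
    bit 0) vs near-planar-trans (bit 1) — and the index is
    ``2 * bit(first) + bit(second)``.
    """
    atoms = _as_atom_dict(ligand)
    if len(dihedrals) != 2:
        raise ValueError("exactly two minor-mode dihedrals are required")
    bits = []
    for quad in dihedrals:
        pts = [np.asarray(atoms[a], dtype=float) for a in quad]
        theta = dihedral(*pts)
        bits.append(0 if np.cos(np.deg2rad(theta)) > 0 else 1)
    return 2 * bits[0] + bits[1]


def classify_trajectory(
    traj: LigandTrajectory,
    fibril: FibrilModel,
    site: SiteDefinition,
    minor: bool = True,
) -> pd.DataFrame:
    """Classify every (frame, ligand) into major and minor binding modes.

    Returns a table with columns ``frame, ligand, major, minor`` where
    ``major`` is one of UL/UR/DL/DR/unbound and ``minor`` is -1 for
    unbound configurations.  Vectorised over the whole trajectory.
    """
    center, xhat, yhat, zhat = site_frame(fibril, site)
    chg = traj.atom("CHG")
    bound = np.linalg.norm(chg - center, axis=-1) <= site.cutoff
    e = traj.atom("ETH") - traj.atom("THI")
    ez, ey = e @ zhat, e @ yhat
    ud = np.where(ez > -_TIE_EPS, "U", "D")
    lr = np.where(ey > -_TIE_EPS, "R", "L")
    major = np.where(bound, np.char.add(ud, lr), "unbound")
    f, l = traj.n_frames, traj.n_ligands
    idx = np.indices((f, l))
    out = pd.DataFrame(
        {
            "frame": idx[0].ravel(),
            "ligand": idx[1].ravel(),
            "major": major.ravel(),
        }
    )
    if minor:
        minors = np.full((f, l), -1, dtype=int)
        quads = [
            [traj.atom_index(a) for a in quad] for quad in DEFAULT_MINOR_DIHEDRALS
        ]
        bits = []
        for quad in quads:
            p = [traj.coords[:, :, i, :] for i in quad]
            theta = _dihedral_array(*p)
            bits.append((np.cos(theta) <= 0).astype(int))
        minors_all = 2 * bits[0] + bits[1]
        minors = np.where(bound, minors_all, -1)
        out["minor"] = minors.ravel()
    return out


def _dihedral_array(p0, p1, p2, p3) -> np.ndarray:
    """Vectorised signed dihedral (radians) over leading axes."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = (n1 * n2).sum(-1)
    y = (m1 * n2).sum(-1)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------
# mode populations and residence times
# ---------------------------------------------------------------------------


@dataclass
class ModePopulations:
    """Results container for binding-mode population estimation.

    ``fractions`` are per-mode occupancies over bound frames (summing to
    one), ``ci95`` their 95 % binomial (normal-approximation) intervals,
    and ``residence_ps`` mean contiguous residence times.  ``empty`` is
    true when the trajectory contained no bound configurations.
    """

    fractions: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    residence_ps: dict = field(default_factory=dict)
    n_bound: int = 0
    n_total: int = 0
    frame_interval_ps: float = 20.0

    @property
    def empty(self) -> bool:
        return self.n_bound == 0

    def summary(self) -> str:
        lines = [
            "Binding-mode populations",
            "=" * 58,
            f"bound configurations: {self.n_bound} / {self.n_total}",
            f"{'mode':>6} {'fraction':>10} {'95% CI':>19} {'residence (ps)':>16}",
        ]
        for mode, frac in sorted(self.fractions.items(), key=lambda kv: -kv[1]):
            lo, hi = self.ci95[mode]
            res = self.residence_ps.get(mode, float("nan"))
            lines.append(
                f"{mode:>6} {frac:>10.4f} [{lo:>7.4f}, {hi:>7.4f}] {res:>16.1f}"
            )
        return "\n".join(lines)


def mode_populations(
    labels: pd.DataFrame | "list[str]",
    frame_interval_ps: float = 20.0,
    by: str = "major",
) -> ModePopulations:
    """Per-mode occupancy fractions and mean residence times.

    ``labels`` is either the table produced by :func:`classify_trajectory`
    or a plain sequence of labels for a single ligand.  Fractions are
    computed over bound configurations only; the residence time of a mode
    is the mean length of its contiguous runs (per ligand, along frames)
    times the frame interval.
    """
    if not isinstance(labels, pd.DataFrame):
        labels = pd.DataFrame(
            {"frame": np.arange(len(labels)), "ligand": 0, "major": list(labels)}
        )
    col = labels[by].astype(str)
    bound_mask = col != "unbound"
    n_bound = int(bound_mask.sum())
    result = ModePopulations(
        n_bound=n_bound,
        n_total=len(labels),
        frame_interval_ps=frame_interval_ps,
    )
    if n_bound == 0:
        return result
    counts = col[bound_mask].value_counts()
    for mode, c in counts.items():
        p = c / n_bound
        se = np.sqrt(max(p * (1 - p) / n_bound, 0.0))
        result.counts[mode] = int(c)
        result.fractions[mode] = float(p)
        result.ci95[mode] = (float(p - 1.96 * se), float(p + 1.96 * se))
    # residence: contiguous runs per ligand along sorted frames
    runs: dict[str, list[int]] = {m: [] for m in result.fractions}
    for _, sub in labels.sort_values("frame").groupby("ligand"):
        seq = sub[by].astype(str).to_numpy()
        start = 0
        for i in range(1, len(seq) + 1):
            if i == len(seq) or seq[i] != seq[start]:
                if seq[start] in runs:
                    runs[seq[start]].append(i - start)
                start = i
    for mode, lengths in runs.items():
        result.residence_ps[mode] = float(np.mean(lengths) * frame_interval_ps)
    return result


# ---------------------------------------------------------------------------
# planarity
# ---------------------------------------------------------------------------


def planarity(ligand, dihedral_set) -> float:
    """Planarity score of a conjugated backbone: sum of |cos theta_i|.

    ``dihedral_set`` lists 4-tuples, each either atom labels resolved in
    the ``ligand`` mapping or explicit coordinates.  A fully planar
    backbone (all torsions 0° or 180°) scores ``len(dihedral_set)``;
    fully twisted (all 90°) scores 0.  With the molecule's four
    pi-conjugated backbone torsions this score sits near 3.4-3.5 for the
    tau-bound and solvated ligand.
    """
    total = 0.0
    for quad in dihedral_set:
        pts = []
        for a in quad:
            if isinstance(a, str):
                pts.append(np.asarray(_as_atom_dict(ligand)[a], dtype=float))
            else:
                pts.append(np.asarray(a, dtype=float))
        theta = dihedral(*pts)
        total += abs(np.cos(np.deg2rad(theta)))
    return float(total)


# ---------------------------------------------------------------------------
# interaction-energy aggregation
# ---------------------------------------------------------------------------


@dataclass
class EnergyAggregate:
    """Per-residue and site-total ligand-residue interaction energies.

    ``per_residue`` is indexed by residue id with columns
    ``lj_mean, lj_sd, coulomb_mean, coulomb_sd`` (kJ/mol); totals are the
    sums of per-residue means, with standard deviations of the per-frame
    site totals.  Standard deviations are population (ddof=0) values,
    matching the large-sample averaging convention of MD analyses.
    """

    per_residue: pd.DataFrame
    lj_total: float
    lj_total_sd: float
    coulomb_total: float
    coulomb_total_sd: float
    n_frames: int

    def summary(self) -> str:
        lines = [
            "Ligand-residue interaction energies (kJ/mol)",
            "=" * 58,
            self.per_residue.round(2).to_string(),
            "-" * 58,
            f"LJ total      {self.lj_total:9.1f} +/- {self.lj_total_sd:.1f}",
            f"Coulomb total {self.coulomb_total:9.1f} +/- {self.coulomb_total_sd:.1f}",
        ]
        return "\n".join(lines)


def aggregate_energies(records: pd.DataFrame, site: SiteDefinition) -> EnergyAggregate:
    """Aggregate per-frame LJ/Coulomb records over a site's residue triad.

    ``records`` must have columns ``frame, residue, lj, coulomb`` with one
    row per (frame, residue).  Site totals are exactly the sums of the
    per-residue mean energies.  Residues of the site absent from the
    records raise ``KeyError``.
    """
    required = {"frame", "residue", "lj", "coulomb"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    missing = [r for r in site.triad if r not in set(records["residue"])]
    if missing:
        raise KeyError(f"records are missing site residues {missing}")
    sub = records[records["residue"].isin(site.triad)]
    per = (
        sub.groupby("residue")
        .agg(
            lj_mean=("lj", "mean"),
            lj_sd=("lj", lambda s: s.std(ddof=0)),
            coulomb_mean=("coulomb", "mean"),
            coulomb_sd=("coulomb", lambda s: s.std(ddof=0)),
        )
        .loc[list(site.triad)]
    )
    frame_totals = sub.groupby("frame")[["lj", "coulomb"]].sum()
    return EnergyAggregate(
        per_residue=per,
        lj_total=float(per["lj_mean"].sum()),
        lj_total_sd=float(frame_totals["lj"].std(ddof=0)),
        coulomb_total=float(per["coulomb_mean"].sum()),
        coulomb_total_sd=float(frame_totals["coulomb"].std(ddof=0)),
        n_frames=int(sub["frame"].nunique()),
    )
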