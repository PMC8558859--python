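"""Potentials of mean force from umbrella sampling, and Boltzmann mode
populations.

Umbrella sampling drives a ligand along a 1-D reaction coordinate
(here: the pulling distance from a fibril binding site toward the bulk)
with harmonic restraints ``w_i(x) = k/2 (x - c_i)^2`` at staggered window
centers.  The weighted-histogram analysis method (WHAM) recombines the
biased window histograms into the unbiased probability density ``p(x)``
by self-consistent iteration of the window free-energy shifts

    f_i = -kT ln sum_b p(x_b) exp(-w_i(x_b)/kT)
    p(x_b) = sum_i n_ib / sum_i N_i exp[(f_i - w_i(x_b))/kT]

after which the PMF is ``F(x) = -kT ln p(x)`` up to an additive constant.
The binding free energy is the plateau (bulk) value of the PMF minus its
global minimum; per-mode binding energies convert to equilibrium mode
populations through the Boltzmann distribution.

The estimator follows the model/results idiom: :class:`Wham` is built
from the window data and ``fit()`` returns a :class:`PMFProfile` results
object carrying the profile, window shifts, convergence diagnostics,
optional block-bootstrap uncertainties, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE_K, KB_KJ_PER_MOL_K

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "Wham",
    "WhamCoverageError",
    "WhamConvergenceError",
    "binding_energy",
    "boltzmann_populations",
    "detect_intermediate_minima",
]


class WhamCoverageError(ValueError):
    """Raised when the window histograms leave gaps in the coordinate range."""


class WhamConvergenceError(RuntimeError):
    """Raised when WHAM self-consistency fails to reach tolerance."""

    def __init__(self, n_iter: int, last_delta: float, tol: float):
        self.n_iter = n_iter
        self.last_delta = last_delta
        self.tol = tol
        super().__init__(
            f"WHAM did not converge in {n_iter} iterations "
            f"(last shift change {last_delta:.3e} kJ/mol, tol {tol:.3e})"
        )


@dataclass
class UmbrellaWindow:
    """One umbrella-sampling window: restraint and sampled coordinate series."""

    center: float
    k_umb: float
    samples: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.k_umb <= 0:
            raise ValueError("k_umb must be positive")
        if self.samples.size == 0:
            raise ValueError("window has no samples")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def bias(self, x) -> np.ndarray:
        return 0.5 * self.k_umb * (np.asarray(x, dtype=float) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free energy versus reaction coordinate, with fit diagnostics.

    ``free_energy`` is in kJ/mol on ``bin_centers`` (nm), shifted per
    ``reference``: ``"bulk-zero"`` (mean over the outer plateau set to 0)
    or ``"min-zero"`` (global minimum set to 0).  When produced by
    :meth:`Wham.fit`, ``window_shifts`` holds the converged per-window
    free energies and ``uncertainty`` optional bootstrap standard errors.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    reference: str = "min-zero"
    temperature: float = DEFAULT_TEMPERATURE_K
    bin_width: float | None = None
    window_shifts: np.ndarray | None = None
    n_iter: int | None = None
    converged: bool | None = None
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.bin_centers.shape != self.free_energy.shape:
            raise ValueError("bin_centers and free_energy must align")

    @classmethod
    def from_arrays(cls, bin_centers, free_energy, **kwargs) -> "PMFProfile":
        return cls(bin_centers, free_energy, **kwargs)

    def minimum(self) -> tuple[float, float]:
        i = int(np.argmin(self.free_energy))
        return float(self.bin_centers[i]), float(self.free_energy[i])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"xi_nm": self.bin_centers, "pmf_kJ_per_mol": self.free_energy}
        )
        if self.uncertainty is not None:
            df["se_kJ_per_mol"] = self.uncertainty
        return df

    def summary(self) -> str:
        xmin, fmin = self.minimum()
        lines = [
            "Potential of mean force (WHAM)",
            "=" * 58,
            f"bins: {len(self.bin_centers)}"
            + (f" x {self.bin_width} nm" if self.bin_width else ""),
            f"range: [{self.bin_centers[0]:.3f}, {self.bin_centers[-1]:.3f}] nm",
            f"reference: {self.reference}; temperature: {self.temperature:.1f} K",
            f"global minimum: {fmin:.2f} kJ/mol at {xmin:.3f} nm",
        ]
        if self.converged is not None:
            lines.append(
                f"converged: {self.converged} after {self.n_iter} iterations"
            )
        if self.window_shifts is not None:
            lines.append(f"windows: {len(self.window_shifts)}")
        return "\n".join(lines)


def _solve(log_n_b, log_N_k, u_kb_over_kT, tol_red, max_iter):
    """Self-consistent WHAM iteration in log space.

    Returns (log p_b up to a constant, reduced shifts f_k/kT, iterations,
    last reduced change).
    """
    K = len(log_N_k)
    f = np.zeros(K)
    last = np.inf
    for it in range(1, max_iter + 1):
        denom = logsumexp(
            log_N_k[:, None] + f[:, None] - u_kb_over_kT, axis=0
        )
        log_p = log_n_b - denom
        f_new = -logsumexp(log_p[None, :] - u_kb_over_kT, axis=1)
        f_new = f_new - f_new[0]
        last = float(np.max(np.abs(f_new - f)))
        f = f_new
        if last < tol_red:
            return log_p, f, it, last
    return log_p, f, max_iter, last


class Wham:
    """Weighted-histogram PMF estimator over a set of umbrella windows.

    Parameters
    ----------
    windows : list of UmbrellaWindow
        All windows must share one temperature.
    bin_width : float
        Histogram resolution along the reaction coordinate (nm).

    The histogram support must be contiguous (every interior bin covered
    by at least one sample); disjoint, non-overlapping windows raise
    :class:`WhamCoverageError` at construction.
    """

    def __init__(self, windows, bin_width: float = 0.02):
        if len(windows) == 0:
            raise ValueError("at least one window is required")
        temps = {w.temperature for w in windows}
        if len(temps) != 1:
            raise ValueError("all windows must share one temperature")
        self.windows = list(windows)
        self.temperature = temps.pop()
        self.kT = KB_KJ_PER_MOL_K * self.temperature
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = bin_width
        self._build_histograms()

    def _build_histograms(self) -> None:
        all_samples = np.concatenate([w.samples for w in self.windows])
        lo = np.floor(all_samples.min() / self.bin_width) * self.bin_width
        hi = np.ceil(all_samples.max() / self.bin_width) * self.bin_width
        edges = np.arange(lo, hi + 0.5 * self.bin_width, self.bin_width)
        if len(edges) < 3:
            edges = np.array([lo, lo + self.bin_width, lo + 2 * self.bin_width])
        self.edges = edges
        self.bin_centers = 0.5 * (edges[:-1] + edges[1:])
        self.counts = np.stack(
            [np.histogram(w.samples, bins=edges)[0] for w in self.windows]
        ).astype(float)
        total = self.counts.sum(axis=0)
        # main support: the contiguous nonempty run holding the most
        # populated bin; stray extreme-tail samples outside it are dropped
        peak = int(np.argmax(total))
        lo_i = peak
        while lo_i > 0 and total[lo_i - 1] > 0:
            lo_i -= 1
        hi_i = peak
        while hi_i < len(total) - 1 and total[hi_i + 1] > 0:
            hi_i += 1
        in_run = np.zeros(len(total), dtype=bool)
        in_run[lo_i : hi_i + 1] = True
        kept = self.counts[:, in_run].sum(axis=1)
        if np.any(kept < 0.5 * self.counts.sum(axis=1)):
            raise WhamCoverageError(
                "window histograms do not overlap: some windows sample "
                "entirely outside the contiguous support"
            )
        sl = slice(lo_i, hi_i + 1)
        self.bin_centers = self.bin_centers[sl]
        self.counts = self.counts[:, sl]
        self.N_k = self.counts.sum(axis=1)
        self.u_kb = np.stack([w.bias(self.bin_centers) for w in self.windows])

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 100_000,
        reference: str = "bulk-zero",
        bulk_last: float = 0.5,
        n_boot: int = 0,
        boot_seed: int = 0,
    ) -> PMFProfile:
        """Solve the WHAM equations and return the PMF results object.

        ``tol`` is the convergence tolerance (kJ/mol) on the window
        free-energy shifts.  ``reference`` selects the additive-constant
        convention; for ``"bulk-zero"`` the mean over the last
        ``bulk_last`` nm of the coordinate is set to zero (matching PMFs
        with flat solvated tails).  ``n_boot > 0`` adds per-bin standard
        errors from a block bootstrap over window samples.
        """
        log_p, f_red, n_iter, last = self._fit_raw(tol, max_iter)
        if last >= tol / self.kT:
            raise WhamConvergenceError(n_iter, last * self.kT, tol)
        pmf = -self.kT * log_p
        pmf = self._reference_shift(pmf, reference, bulk_last)
        uncertainty = None
        if n_boot > 0:
            uncertainty = self._bootstrap(
                n_boot, boot_seed, tol, max_iter, reference, bulk_last
            )
        return PMFProfile(
            bin_centers=self.bin_centers.copy(),
            free_energy=pmf,
            reference=reference,
            temperature=self.temperature,
            bin_width=self.bin_width,
            window_shifts=f_red * self.kT,
            n_iter=n_iter,
            converged=True,
            uncertainty=uncertainty,
        )

    def _fit_raw(self, tol, max_iter):
        with np.errstate(divide="ignore"):
            log_n_b = np.log(self.counts.sum(axis=0))
            log_N_k = np.log(self.N_k)
        return _solve(log_n_b, log_N_k, self.u_kb / self.kT, tol / self.kT, max_iter)

    def _reference_shift(self, pmf, reference, bulk_last):
        if reference == "min-zero":
            return pmf - np.nanmin(pmf)
        if reference == "bulk-zero":
            cut = self.bin_centers[-1] - bulk_last
            mask = self.bin_centers >= cut
            return pmf - np.nanmean(pmf[mask])
        raise ValueError(f"unknown reference convention {reference!r}")

    def _bootstrap(self, n_boot, seed, tol, max_iter, reference, bulk_last):
        rng = np.random.default_rng(seed)
        profiles = []
        for _ in range(n_boot):
            resampled = []
            for w in self.windows:
                n = len(w.samples)
                block = max(1, n // 20)
                n_blocks = int(np.ceil(n / block))
                starts = rng.integers(0, max(n - block + 1, 1), size=n_blocks)
                idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
                resampled.append(
                    UmbrellaWindow(w.center, w.k_umb, w.samples[idx], w.temperature)
                )
            try:
                boot = Wham(resampled, self.bin_width)
                prof = boot.fit(tol=tol, max_iter=max_iter, reference=reference,
                                bulk_last=bulk_last)
            except (WhamCoverageError, WhamConvergenceError):
                continue
            profiles.append(
                np.interp(
                    self.bin_centers,
                    prof.bin_centers,
                    prof.free_energy,
                    left=np.nan,
                    right=np.nan,
                )
            )
        if not profiles:
            return None
        return np.nanstd(np.stack(profiles), axis=0)


def binding_energy(pmf: PMFProfile, bulk_region: tuple[float, float]) -> float:
    """Binding free energy: bulk-plateau PMF minus the global minimum.

    ``bulk_region = (lo, hi)`` in nm must lie within the sampled domain.
    The result is non-negative by construction (the minimum is global);
    larger values mean stronger binding.
    """
    lo, hi = bulk_region
    if hi <= lo:
        raise ValueError("bulk_region must be a non-empty interval (lo, hi)")
    mask = (pmf.bin_centers >= lo) & (pmf.bin_centers <= hi)
    if not mask.any():
        raise ValueError("bulk_region contains no PMF bins")
    return float(np.mean(pmf.free_energy[mask]) - np.min(pmf.free_energy))


def boltzmann_populations(
    energies: dict, temperature: float = DEFAULT_TEMPERATURE_K
) -> dict:
    """Equilibrium mode populations from (positive) binding energies.

    ``p_i = exp(E_i/kT) / sum_j exp(E_j/kT)``: stronger binding (larger
    binding energy, deeper well) gives the larger population.  Invariant
    under adding a constant to all energies; fractions sum to one.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    keys = list(energies)
    e = np.array([energies[k] for k in keys], dtype=float)
    if not np.isfinite(e).all():
        raise ValueError("binding energies must be finite")
    z = e / (KB_KJ_PER_MOL_K * temperature)
    p = np.exp(z - logsumexp(z))
    return {k: float(v) for k, v in zip(keys, p)}


def detect_intermediate_minima(pmf: PMFProfile, prominence: float) -> np.ndarray:
    """Positions (nm) of secondary local PMF minima above a prominence.

    Shallow intermediate wells along the exit path (e.g. transient
    contacts with a secondary binding site) appear as local minima; the
    global minimum and the domain edges are excluded.  Returns an empty
    array when nothing qualifies.
    """
    f = pmf.free_energy
    idx, _ = find_peaks(-f, prominence=prominence)
    idx = idx[idx != int(np.argmin(f))]
    return pmf.bin_centers[idx]
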