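"""Decomposition of spectra into known species contributions.

Given a library of species basis spectra (flavin redox/protonation forms,
tryptophan radicals, decomposition products, optional smooth nuisance
terms), every measured spectrum - a column of a TA matrix or one member of
a stationary illumination sequence - is expressed as a linear combination
of the basis.  The resulting mole-fraction trajectories are themselves a
diagnostic: if the basis is right and nothing is missing, the species sum
stays constant at 1.  Conservation is therefore *monitored and reported*,
never silently enforced by renormalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import interp1d
from scipy.optimize import nnls

from .dataio import TAMatrix
from .target import SpeciesSpectrum

__all__ = [
    "BasisSet",
    "MoleFractionProfile",
    "BasisDecomposition",
    "decompose",
    "shift_spectrum",
    "pocket_ph",
]


@dataclass
class BasisSet:
    """An ordered collection of species spectra on one wavelength grid."""

    species: list
    nuisance: list = field(default_factory=list)  # scatter/offset columns

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise ValueError("need at least one species spectrum")
        wl = self.species[0].wavelengths
        for s in self.species + self.nuisance:
            if s.wavelengths.shape != wl.shape or not np.allclose(s.wavelengths, wl):
                raise ValueError(f"spectrum {s.name!r} is not on the common grid")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.species[0].wavelengths

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def matrix(self) -> np.ndarray:
        """(n_wavelengths, n_species + n_nuisance) design matrix."""
        cols = [s.amplitude for s in self.species] + [s.amplitude for s in self.nuisance]
        return np.column_stack(cols)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix()))

    @classmethod
    def from_csv(cls, path: str) -> "BasisSet":
        """Read a multi-column delimited file: first column wavelength,
        remaining columns one named species each (header row)."""
        import pandas as pd

        df = pd.read_csv(path)
        wl = df.iloc[:, 0].to_numpy(float)
        species = [
            SpeciesSpectrum(str(c), wl, df[c].to_numpy(float))
            for c in df.columns[1:]
        ]
        return cls(species)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        df = pd.DataFrame({"wavelength_nm": self.wavelengths})
        for s in self.species + self.nuisance:
            df[s.name] = s.amplitude
        df.to_csv(path, index=False)


@dataclass
class MoleFractionProfile:
    """Per-time (or per-pulse) species fractions with fit diagnostics.

    ``sum_deviation`` is |sum_i x_i - 1| per point: the conservation
    diagnostic the decomposition is judged by.
    """

    times: np.ndarray
    names: list[str]
    fractions: np.ndarray       # (n_times, n_species)
    residual_norm: np.ndarray   # per time point
    sum_deviation: np.ndarray   # per time point
    nuisance_coeffs: Optional[np.ndarray] = None
    normalization: float = 1.0
    condition_number: float = 1.0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.fractions[:, self.names.index(name)]

    def frame(self):
        import pandas as pd

        df = pd.DataFrame(self.fractions, columns=self.names)
        df.insert(0, "time", self.times)
        df["residual_norm"] = self.residual_norm
        df["sum_deviation"] = self.sum_deviation
        return df

    def summary(self) -> str:
        lines = [
            "Basis decomposition",
            f"  species: {', '.join(self.names)}",
            f"  points: {self.times.size}",
            f"  basis condition number: {self.condition_number:.3g}",
            f"  max |sum - 1|: {float(np.max(self.sum_deviation)):.3e}",
            f"  max residual norm: {float(np.max(self.residual_norm)):.3e}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - plotting
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, n in enumerate(self.names):
            ax.plot(self.times, self.fractions[:, i], "o-", label=n, ms=3)
        ax.set_xlabel("time / pulse index")
        ax.set_ylabel("mole fraction")
        ax.legend()
        return ax


class BasisDecomposition:
    """Model object: decompose a matrix/sequence over a species basis.

    Parameters
    ----------
    data : TAMatrix or 2-D array (n_wavelengths, n_times) with ``wavelengths``.
    basis : BasisSet (resampled onto the data grid if necessary).
    mode : ``"unconstrained"`` (plain least squares, the default - physical
        reasonability is a *check*) or ``"nonnegative"`` (NNLS).
    normalize : ``"first"`` scales all coefficients by the species total of
        the first point (the fitted dark-state amount); ``"none"`` reports
        raw coefficients; a float divides by that amount.
    """

    def __init__(
        self,
        data: Union[TAMatrix, np.ndarray],
        basis: BasisSet,
        mode: str = "unconstrained",
        normalize: Union[str, float] = "first",
        wavelengths: Optional[np.ndarray] = None,
        times: Optional[np.ndarray] = None,
        cond_warn: float = 1e6,
    ) -> None:
        if mode not in ("unconstrained", "nonnegative"):
            raise ValueError(f"unknown mode {mode!r}")
        if isinstance(data, TAMatrix):
            self.values = data.values
            self.wavelengths = data.wavelengths
            self.times = data.times
            self.mask = data.effective_mask()
        else:
            self.values = np.asarray(data, dtype=float)
            if wavelengths is None:
                raise ValueError("wavelengths required for array input")
            self.wavelengths = np.asarray(wavelengths, dtype=float)
            self.times = (
                np.arange(self.values.shape[1], dtype=float)
                if times is None
                else np.asarray(times, dtype=float)
            )
            self.mask = np.zeros_like(self.values, dtype=bool)
        self.basis = _resample_basis(basis, self.wavelengths)
        self.mode = mode
        self.normalize = normalize
        cond = self.basis.condition_number()
        if not np.isfinite(cond) or cond > 1e10:
            raise ValueError(f"ill-conditioned basis (cond = {cond:.3g})")
        if cond > cond_warn:
            warnings.warn(f"basis condition number {cond:.3g} > {cond_warn:g}")
        self.condition_number = cond

    def fit(self) -> MoleFractionProfile:
        S = self.basis.matrix()
        n_sp = len(self.basis.species)
        coeffs = np.empty((self.times.size, S.shape[1]))
        resid = np.empty(self.times.size)
        for j in range(self.times.size):
            ok = ~self.mask[:, j]
            y = self.values[ok, j]
            Sj = S[ok]
            if self.mode == "nonnegative":
                c, rn = nnls(Sj, y)
            else:
                c, rss, *_ = np.linalg.lstsq(Sj, y, rcond=None)
                rn = float(np.sqrt(rss[0])) if rss.size else float(
                    np.linalg.norm(y - Sj @ c)
                )
            coeffs[j] = c
            resid[j] = rn
        species_coeffs = coeffs[:, :n_sp]
        nuisance = coeffs[:, n_sp:] if S.shape[1] > n_sp else None
        if self.normalize == "none":
            norm = 1.0
        elif self.normalize == "first":
            norm = float(species_coeffs[0].sum())
            if norm <= 0:
                raise ValueError("cannot normalize: first-point total <= 0")
        else:
            norm = float(self.normalize)
        fractions = species_coeffs / norm
        total = fractions.sum(axis=1)
        return MoleFractionProfile(
            times=self.times,
            names=self.basis.names,
            fractions=fractions,
            residual_norm=resid,
            sum_deviation=np.abs(total - 1.0),
            nuisance_coeffs=nuisance,
            normalization=norm,
            condition_number=self.condition_number,
        )


def decompose(
    data: Union[TAMatrix, np.ndarray],
    basis: BasisSet,
    mode: str = "unconstrained",
    **kwargs,
) -> MoleFractionProfile:
    """Functional wrapper around :class:`BasisDecomposition`."""
    return BasisDecomposition(data, basis, mode=mode, **kwargs).fit()


def _resample_basis(basis: BasisSet, wavelengths: np.ndarray) -> BasisSet:
    if basis.wavelengths.shape == wavelengths.shape and np.allclose(
        basis.wavelengths, wavelengths
    ):
        return basis
    lo = max(basis.wavelengths[0], wavelengths[0])
    hi = min(basis.wavelengths[-1], wavelengths[-1])
    if lo >= hi:
        raise ValueError("no wavelength overlap between data and basis")

    def rs(s: SpeciesSpectrum) -> SpeciesSpectrum:
        f = interp1d(s.wavelengths, s.amplitude, bounds_error=False, fill_value=0.0)
        return SpeciesSpectrum(s.name, wavelengths, f(wavelengths), s.provenance)

    return BasisSet([rs(s) for s in basis.species], [rs(s) for s in basis.nuisance])


def shift_spectrum(s: SpeciesSpectrum, delta_nm: float) -> SpeciesSpectrum:
    """Shift a spectrum by ``delta_nm`` (positive = redshift).

    The amplitude is resampled at ``lambda - delta_nm``; points falling
    outside the original grid are set to zero.
    """
    span = s.wavelengths[-1] - s.wavelengths[0]
    if abs(delta_nm) >= span:
        raise ValueError("shift exceeds the grid span")
    if delta_nm == 0.0:
        return SpeciesSpectrum(s.name, s.wavelengths.copy(), s.amplitude.copy(), s.provenance)
    f = interp1d(s.wavelengths, s.amplitude, kind="cubic", bounds_error=False, fill_value=0.0)
    shifted = f(s.wavelengths - delta_nm)
    return SpeciesSpectrum(
        s.name,
        s.wavelengths.copy(),
        shifted,
        (s.provenance + f" shifted {delta_nm:+g} nm").strip(),
    )


def pocket_ph(ratio_base_to_acid: float, pKa: float = 8.0) -> float:
    """Henderson-Hasselbalch estimate of the local (binding-pocket) pH.

    ``pH = pKa + log10([base]/[acid])`` with base = FAD anion radical and
    acid = neutral FADH radical; their concentration ratio follows from the
    decomposed absorption amplitudes.
    """
    if not ratio_base_to_acid > 0:
        raise ValueError("concentration ratio must be positive")
    return float(pKa + np.log10(ratio_base_to_acid))
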