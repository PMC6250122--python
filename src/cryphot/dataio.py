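"""Containers and preprocessing for spectro-temporal difference-absorption data.

The central object is :class:`TAMatrix`, a wavelength x time matrix of
pump-induced absorbance changes (in OD) with explicit axes, a polarization
tag and an optional exclusion mask.  This module also converts streak-camera
image triplets into transient absorption and applies the standard
preprocessing steps of broadband pump-probe spectroscopy: subtraction of the
averaged pre-time-zero scatter, correction of the probe-continuum chirp, and
construction of the quasi-logarithmic delay axis that weights every decade of
dynamics equally in a global fit.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TAMatrix",
    "StreakTriplet",
    "ChirpModel",
    "ta_from_streak",
    "subtract_pre_t0",
    "chirp_correct",
    "build_time_axis",
    "read_matrix",
    "write_matrix",
]

POLARIZATIONS = ("magic", "parallel", "perpendicular", "unpolarized")


def _check_axis(name: str, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError(f"{name} axis must be 1-D with at least 2 points")
    d = np.diff(axis)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{name} axis must be strictly monotonic")
    return axis


@dataclass
class TAMatrix:
    """A difference-absorption matrix dA(lambda, t).

    Parameters
    ----------
    wavelengths : array, nm, strictly ascending.
    times : array, strictly monotonic, in ``time_unit``.
    values : 2-D array, OD; rows are wavelengths, columns time points.
    polarization : one of ``magic | parallel | perpendicular | unpolarized``.
    mask : optional boolean array, same shape as ``values``; True marks
        cells excluded from every fit (scatter/emission regions, cells the
        streak conversion could not evaluate).
    time_unit : declared unit of ``times`` (internally everything important
        is done in seconds via :attr:`times_s`).
    meta : free-form provenance dictionary.
    """

    wavelengths: np.ndarray
    times: np.ndarray
    values: np.ndarray
    polarization: str = "magic"
    mask: Optional[np.ndarray] = None
    time_unit: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .units import TIME_UNITS

        self.wavelengths = _check_axis("wavelength", self.wavelengths)
        if np.any(np.diff(self.wavelengths) < 0):
            raise ValueError("wavelength axis must be ascending (nm)")
        self.times = _check_axis("time", self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.wavelengths.size, self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.wavelengths.size}, {self.times.size})"
            )
        if self.polarization not in POLARIZATIONS:
            raise ValueError(f"unknown polarization {self.polarization!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must equal values shape")
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"unknown time unit {self.time_unit!r}")

    # -- convenience -----------------------------------------------------
    @property
    def times_s(self) -> np.ndarray:
        """Time axis converted to seconds."""
        from .units import TIME_UNITS

        return self.times * TIME_UNITS[self.time_unit]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def n_times(self) -> int:
        return self.times.size

    def effective_mask(self) -> np.ndarray:
        """Boolean exclusion mask (all-False when no mask is set)."""
        if self.mask is None:
            return np.zeros_like(self.values, dtype=bool)
        return self.mask

    def copy(self) -> "TAMatrix":
        return replace(
            self,
            wavelengths=self.wavelengths.copy(),
            times=self.times.copy(),
            values=self.values.copy(),
            mask=None if self.mask is None else self.mask.copy(),
            meta=dict(self.meta),
        )


@dataclass
class StreakTriplet:
    """The three streak-camera images of one flash-photolysis sequence.

    ``d_fl``: flash lamp + laser; ``d_0``: no incoming light (dark);
    ``d_f``: flash lamp only.  All share one (wavelength, time) grid.
    """

    wavelengths: np.ndarray
    times: np.ndarray
    d_fl: np.ndarray
    d_0: np.ndarray
    d_f: np.ndarray
    time_unit: str = "s"
    n_sequences: int = 1

    def __post_init__(self) -> None:
        self.wavelengths = _check_axis("wavelength", self.wavelengths)
        self.times = _check_axis("time", self.times)
        shape = (self.wavelengths.size, self.times.size)
        for name in ("d_fl", "d_0", "d_f"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative intensities")
            setattr(self, name, arr)


@dataclass
class ChirpModel:
    """Low-order polynomial model of the probe-continuum group delay t0(lambda).

    ``coefficients[i]`` multiplies ``(lambda - reference_nm)**i``; units are
    ``time_unit`` per nm**i.  The white-light chirp of a CaF2 continuum is
    smooth and of order ~1 ps across the visible, so quadratic models are
    usually sufficient.
    """

    coefficients: np.ndarray
    reference_nm: float = 500.0
    time_unit: str = "s"
    max_spread: Optional[float] = None  # sanity window in time_unit

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, float))

    def t0(self, wavelengths: np.ndarray) -> np.ndarray:
        """Evaluate t0(lambda) on a wavelength grid (in ``time_unit``)."""
        x = np.asarray(wavelengths, float) - self.reference_nm
        out = np.polynomial.polynomial.polyval(x, self.coefficients)
        if self.max_spread is not None:
            spread = np.ptp(out)
            if spread > self.max_spread:
                raise ValueError(
                    f"chirp spread {spread:g} exceeds allowed window "
                    f"{self.max_spread:g} {self.time_unit}"
                )
        return out


# ---------------------------------------------------------------------------
# streak-camera image arithmetic
# ---------------------------------------------------------------------------

def ta_from_streak(triplet: StreakTriplet) -> TAMatrix:
    """Convert a streak-camera image triplet to transient absorption.

    dA = -log10[(D_FL - D_0) / (D_F - D_0)] element-wise (decadic OD).
    Cells where either difference is <= 0 cannot be evaluated and are
    masked rather than fabricated.
    """
    num = triplet.d_fl - triplet.d_0
    den = triplet.d_f - triplet.d_0
    bad = (num <= 0) | (den <= 0)
    values = np.zeros_like(num)
    ok = ~bad
    values[ok] = -np.log10(num[ok] / den[ok])
    if bad.all():
        warnings.warn("streak conversion produced a fully masked matrix")
    return TAMatrix(
        wavelengths=triplet.wavelengths,
        times=triplet.times,
        values=values,
        polarization="unpolarized",
        mask=bad if bad.any() else None,
        time_unit=triplet.time_unit,
        meta={"source": "streak", "n_sequences": triplet.n_sequences},
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def subtract_pre_t0(m: TAMatrix, t_max_pre: float) -> TAMatrix:
    """Subtract the averaged pre-time-zero signal per wavelength.

    Pump scatter reaching the detector is time-independent, so its spectrum
    is estimated as the mean of all columns with ``t < t_max_pre`` and
    removed from the whole matrix.  Requires at least 3 pre-t0 time points.
    """
    pre = m.times < t_max_pre
    if pre.sum() < 3:
        raise ValueError(
            f"need >= 3 time points before {t_max_pre!r}, found {int(pre.sum())}"
        )
    mask = m.effective_mask()
    vals = np.where(mask, np.nan, m.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        offset = np.nanmean(vals[:, pre], axis=1)
    offset = np.where(np.isfinite(offset), offset, 0.0)
    out = m.copy()
    out.values = m.values - offset[:, None]
    out.meta["pre_t0_subtracted"] = float(t_max_pre)
    return out


def chirp_correct(m: TAMatrix, c: ChirpModel) -> TAMatrix:
    """Shift every wavelength row by -t0(lambda) onto the common time axis.

    Rows are re-interpolated with a shape-preserving piecewise cubic
    (monotone Hermite), which avoids the ringing of global splines near the
    coherent artefact.  Points shifted outside the measured axis are masked.
    """
    from .units import TIME_UNITS

    if c.time_unit != m.time_unit:
        scale = TIME_UNITS[c.time_unit] / TIME_UNITS[m.time_unit]
    else:
        scale = 1.0
    t0 = c.t0(m.wavelengths) * scale
    out = m.copy()
    # exact test: sub-ps delays are far below any absolute "close to zero"
    if np.all(t0 == 0.0):
        return out
    newmask = m.effective_mask().copy()
    for i in range(m.n_wavelengths):
        if t0[i] == 0.0:
            continue
        # the sample at shifted time t corresponds to raw time t + t0
        t_src = m.times + t0[i]
        inside = (t_src >= m.times[0]) & (t_src <= m.times[-1])
        interp = PchipInterpolator(m.times, m.values[i], extrapolate=False)
        row = interp(t_src)
        row[~inside] = 0.0
        out.values[i] = row
        newmask[i, ~inside] = True
    if newmask.any():
        out.mask = newmask
    out.meta["chirp_corrected"] = True
    return out


def build_time_axis(
    t_min: float, t_switch: float, t_max: float, n_points: int
) -> np.ndarray:
    """Quasi-logarithmic delay axis: linear up to ``t_switch``, then
    logarithmic with equal point counts per decade.

    Allocating the same number of points to the linear segment as to each
    log decade gives every timescale equal weight in an unweighted global
    fit.
    """
    if not (t_min < t_switch < t_max):
        raise ValueError("require t_min < t_switch < t_max")
    if t_switch <= 0:
        raise ValueError("t_switch must be positive for the log segment")
    if n_points < 10:
        if n_points < 3:
            raise ValueError("n_points must be >= 3")
    n_decades = np.log10(t_max / t_switch)
    n_blocks = 1.0 + n_decades
    n_lin = max(2, int(round(n_points / n_blocks)))
    n_log = n_points - n_lin
    lin = np.linspace(t_min, t_switch, n_lin)
    log = np.geomspace(t_switch, t_max, n_log + 1)[1:]
    axis = np.concatenate([lin, log])
    axis = np.unique(axis)
    if np.any(np.diff(axis) <= 0):
        raise ValueError("constructed axis is not strictly increasing")
    return axis


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_matrix(m: TAMatrix, path: str) -> None:
    """Write a matrix as delimited text (.csv/.tsv/.txt) or HDF5 (.h5/.hdf5).

    Text layout: first row is the time axis, first column the wavelength
    axis; the top-left cell holds the time unit.  Masked cells are written
    as ``nan`` in text (the mask is stored explicitly in HDF5).
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("wavelengths", data=m.wavelengths)
            f.create_dataset("times", data=m.times)
            f.create_dataset("values", data=m.values)
            f.create_dataset("mask", data=m.effective_mask())
            f.attrs["time_unit"] = m.time_unit
            f.attrs["polarization"] = m.polarization
            g = f.create_group("meta")
            for k, v in m.meta.items():
                try:
                    g.attrs[k] = v
                except TypeError:
                    g.attrs[k] = repr(v)
    else:
        delim = "\t" if path.endswith(".tsv") else ","
        vals = np.where(m.effective_mask(), np.nan, m.values)
        buf = io.StringIO()
        header = m.time_unit + delim + delim.join(f"{t:.10g}" for t in m.times)
        buf.write(f"# polarization={m.polarization}\n")
        buf.write(header + "\n")
        for wl, row in zip(m.wavelengths, vals):
            buf.write(
                f"{wl:.10g}" + delim + delim.join(f"{v:.10g}" for v in row) + "\n"
            )
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def read_matrix(path: str) -> TAMatrix:
    """Read a matrix written by :func:`write_matrix` (text or HDF5)."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            mask = np.asarray(f["mask"], dtype=bool)
            return TAMatrix(
                wavelengths=np.asarray(f["wavelengths"]),
                times=np.asarray(f["times"]),
                values=np.asarray(f["values"]),
                polarization=str(f.attrs.get("polarization", "unpolarized")),
                mask=mask if mask.any() else None,
                time_unit=str(f.attrs.get("time_unit", "s")),
                meta={k: v for k, v in f["meta"].attrs.items()} if "meta" in f else {},
            )
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    polarization = "unpolarized"
    if lines and lines[0].startswith("#"):
        hdr = lines.pop(0)
        if "polarization=" in hdr:
            polarization = hdr.split("polarization=")[1].strip()
    delim = "\t" if "\t" in lines[0] else ","
    head = lines[0].split(delim)
    time_unit = head[0].strip() or "s"
    times = np.array([float(x) for x in head[1:]])
    wl, rows = [], []
    for ln in lines[1:]:
        parts = ln.split(delim)
        wl.append(float(parts[0]))
        rows.append([float(x) for x in parts[1:]])
    values = np.array(rows)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return TAMatrix(
        wavelengths=np.array(wl),
        times=times,
        values=values,
        polarization=polarization,
        mask=mask if mask.any() else None,
        time_unit=time_unit,
    )
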