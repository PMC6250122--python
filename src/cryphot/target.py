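"""Target analysis: from decay-associated to species-associated spectra.

A global fit yields model-free DADS and rate constants.  Imposing an
explicit compartmental scheme (which species feeds which, with what
branching) converts the exponential amplitudes into concentration profiles
of physical species and the DADS into species-associated spectra (SAS).
Because the transformation between the exponential basis and the
compartment concentrations is linear and invertible, the reconstruction
F.B is preserved and chi^2 is *identical* to the global fit's - model
appropriateness is judged on the shapes of the SAS, not on fit quality.

This module also implements the spectral arithmetic used to dissect the
flavin-tryptophan radical-pair spectra: addition of the ground-state
spectrum to the DADS sum (fixing the amount of photo-excited ground
state), least-squares stripping of the flavin difference spectrum from a
DADS, and conversion of the stripping coefficient into the radical-pair
recombination fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .globalfit import DADSResult, IRF, KineticBasis, conv_exp
from .units import format_time

__all__ = [
    "KineticModel",
    "SASResult",
    "SpeciesSpectrum",
    "concentrations",
    "sas_from_dads",
    "add_ground_state",
    "strip_flavin",
    "estimate_rpr",
]


@dataclass
class SpeciesSpectrum:
    """A named species spectrum on a wavelength grid (extinction-scaled OD)."""

    name: str
    wavelengths: np.ndarray
    amplitude: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.wavelengths.shape != self.amplitude.shape:
            raise ValueError("wavelengths and amplitude must have equal shape")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError(f"non-finite values in spectrum {self.name!r}")


class KineticModel:
    """First-order compartment scheme.

    Parameters
    ----------
    compartments : names of the transient species (the ground state is
        implicit: any rate not routed to another compartment drains there).
    transitions : iterable of ``(source, destination, rate)``; destination
        ``None`` routes to the ground state.  Rates in 1/s.
    p0 : initial population vector (the photo-excited fraction at t=0);
        for a closed single-photon scheme it sums to 1.
    """

    def __init__(
        self,
        compartments: Sequence[str],
        transitions: Sequence[tuple],
        p0: Sequence[float],
    ) -> None:
        self.compartments = list(compartments)
        n = len(self.compartments)
        idx = {c: i for i, c in enumerate(self.compartments)}
        K = np.zeros((n, n))
        for src, dst, rate in transitions:
            if rate < 0:
                raise ValueError(f"negative rate for {src}->{dst}")
            i = idx[src]
            K[i, i] -= rate
            if dst is not None:
                K[idx[dst], i] += rate
        self.K = K
        self.transitions = list(transitions)
        self.p0 = np.asarray(p0, dtype=float)
        if self.p0.size != n:
            raise ValueError("p0 length must equal number of compartments")
        if np.any(self.p0 < 0):
            raise ValueError("p0 entries must be nonnegative")

    @classmethod
    def identity(cls, rates: Sequence[float]) -> "KineticModel":
        """Trivial model: one independent compartment per exponential.

        Each compartment carries its own unit source, so SAS == DADS.
        """
        names = [f"component_{i + 1}" for i in range(len(rates))]
        transitions = [(n, None, k) for n, k in zip(names, rates)]
        return cls(names, transitions, np.ones(len(names)))

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigen-decomposition K = V diag(lam) V^-1 plus modal weights."""
        lam, V = np.linalg.eig(self.K)
        if np.max(np.abs(lam.imag)) > 1e-9 * (1.0 + np.max(np.abs(lam.real))):
            raise ValueError("oscillatory eigenvalues: scheme is not a cascade")
        lam = lam.real
        V = V.real
        c = np.linalg.solve(V, self.p0)
        return lam, V, c

    @property
    def eigenrates(self) -> np.ndarray:
        """Decay rates (-eigenvalues of K), one per compartment."""
        lam, _, _ = self.eigensystem()
        return -lam

    def branching_fractions(self) -> dict[str, dict]:
        """Per-source split of the outgoing flux, derived from K."""
        out: dict[str, dict] = {}
        for src in self.compartments:
            rates = {
                (dst if dst is not None else "ground"): r
                for s, dst, r in self.transitions
                if s == src
            }
            total = sum(rates.values())
            if total > 0:
                out[src] = {d: r / total for d, r in rates.items()}
        return out


def concentrations(
    model: KineticModel,
    basis: Optional[KineticBasis],
    irf: Optional[IRF],
    t: np.ndarray,
    rate_rtol: float = 1e-6,
) -> np.ndarray:
    """Concentration matrix C(t) of the scheme, shape (n_times, n_compartments).

    Solves dC/dt = K C with the photo-excitation source p0 convolved with
    the Gaussian IRF (C == 0 before time zero).  When a fitted
    ``KineticBasis`` is supplied, the scheme's eigenrates must match the
    fitted rates within ``rate_rtol`` - that is the consistency condition
    for mapping DADS onto this scheme.
    """
    lam, V, c = model.eigensystem()
    eigenrates = -lam
    if basis is not None:
        a = np.sort(eigenrates)
        b = np.sort(basis.rates)
        # eigenvalue round-off is absolute at the scale of the largest rate
        tol = rate_rtol * (np.max(np.abs(b)) + 1e-300)
        if a.size != b.size or np.any(np.abs(a - b) > tol + rate_rtol * np.abs(b)):
            raise ValueError(
                f"model eigenrates {a} do not match fitted rates {b}"
            )
    t = np.asarray(t, dtype=float)
    G = np.column_stack([conv_exp(t, k, irf) for k in eigenrates])
    C = G @ (V * c[None, :]).T
    return C


def sas_from_dads(
    r: DADSResult, model: KineticModel, rate_rtol: float = 1e-6
) -> "SASResult":
    """Transform DADS into SAS under a compartmental scheme.

    Writing the concentrations as C(t) = F(t) A with F the fitted
    exponential basis and A the (invertible) modal amplitude map, the data
    reconstruction F B = C SAS holds with SAS = A^-1 B.  chi^2 is copied
    unchanged - asserted, not assumed.
    """
    lam, V, c = model.eigensystem()
    eigenrates = -lam
    rates = r.basis.rates
    if model.n_compartments != r.basis.n_components:
        raise ValueError(
            f"{model.n_compartments} compartments cannot be identified from "
            f"{r.basis.n_components} exponentials"
        )
    # match each fitted rate with one eigenrate (absolute tolerance at the
    # scale of the largest rate: eigenvalue round-off is not relative)
    tol = rate_rtol * (np.max(np.abs(rates)) + 1e-300)
    order = []
    remaining = list(range(eigenrates.size))
    for k in rates:
        j = min(remaining, key=lambda i: abs(eigenrates[i] - k))
        if abs(eigenrates[j] - k) > tol + rate_rtol * abs(k):
            raise ValueError(
                f"model eigenrates {np.sort(eigenrates)} do not match "
                f"fitted rates {np.sort(rates)}"
            )
        order.append(j)
        remaining.remove(j)
    # A[j, c] = V[c, i_j] * (V^-1 p0)_{i_j}: coefficient of exp component j
    # in compartment c
    A = (V * c[None, :]).T[order, :]
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"amplitude map is singular (cond={cond:.2e}): the scheme is "
            "unidentifiable from these rates"
        )
    sas = np.linalg.solve(A, r.dads)
    return SASResult(
        model=model,
        sas=sas,
        amplitude_map=A,
        chi2=r.chi2,
        dads_result=r,
    )


@dataclass
class SASResult:
    """Species-associated spectra and the map that produced them."""

    model: KineticModel
    sas: np.ndarray             # (n_compartments, n_wavelengths)
    amplitude_map: np.ndarray   # (n_components, n_compartments)
    chi2: float
    dads_result: DADSResult
    ground_state_fraction: Optional[float] = None
    meta: dict = field(default_factory=dict)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.dads_result.wavelengths

    def concentrations(self, t: Optional[np.ndarray] = None) -> np.ndarray:
        if t is None:
            t = self.dads_result.data.times_s
        return concentrations(
            self.model, self.dads_result.basis, self.dads_result.irf, t
        )

    def summary(self) -> str:
        lines = [
            "Target analysis",
            f"  compartments: {', '.join(self.model.compartments)}",
            f"  chi^2 (unchanged from global fit) = {self.chi2:.6e}",
        ]
        for src, splits in self.model.branching_fractions().items():
            parts = ", ".join(f"{d}: {f:.3f}" for d, f in splits.items())
            lines.append(f"  branching from {src}: {parts}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spectral arithmetic
# ---------------------------------------------------------------------------

def add_ground_state(
    sum_dads: np.ndarray,
    ground: SpeciesSpectrum,
    fraction: Optional[float] = None,
    band: tuple[float, float] = (430.0, 490.0),
) -> tuple[np.ndarray, float]:
    """Add the ground-state spectrum to the DADS sum.

    The DADS sum equals (initially excited species - ground state) scaled by
    the photo-excited amount.  Adding the right amount of ground-state
    spectrum removes the bleach, and that amount *is* the excited fraction,
    from which quantum yields are referenced.  If ``fraction`` is None the
    smallest amount that leaves no negative lobe inside the ground-state
    absorption ``band`` is chosen.

    Returns ``(spectrum, fraction_used)``.
    """
    sum_dads = np.asarray(sum_dads, dtype=float)
    if sum_dads.shape != ground.amplitude.shape:
        raise ValueError("sum_dads and ground spectrum must share one grid")
    if fraction is None:
        wl = ground.wavelengths
        in_band = (wl >= band[0]) & (wl <= band[1])
        g = ground.amplitude[in_band]
        s = sum_dads[in_band]
        sig = g > 0.05 * np.max(np.abs(g)) if np.any(g > 0) else np.zeros_like(g, bool)
        if not np.any(sig):
            raise ValueError("ground spectrum has no absorption in the band")
        fraction = float(np.max(-s[sig] / g[sig]))
        fraction = max(fraction, 0.0)
    return sum_dads + fraction * ground.amplitude, float(fraction)


def strip_flavin(
    spectrum: np.ndarray,
    flavin_diff: np.ndarray,
    wavelengths: np.ndarray,
    window: tuple[float, float] = (430.0, 500.0),
) -> tuple[np.ndarray, float]:
    """Subtract the flavin difference spectrum until its features vanish.

    alpha minimizes ||spectrum - alpha*flavin_diff||^2 over the
    flavin-dominated ``window`` (least-squares projection - the
    reproducible form of "subtract such that all flavin features
    disappear").  Returns ``(spectrum - alpha*flavin_diff, alpha)``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    flavin_diff = np.asarray(flavin_diff, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    in_win = (wavelengths >= window[0]) & (wavelengths <= window[1])
    if not np.any(in_win):
        raise ValueError("empty stripping window")
    f = flavin_diff[in_win]
    s = spectrum[in_win]
    denom = float(f @ f)
    if denom < 1e-12 * max(float(spectrum @ spectrum), 1e-300):
        raise ValueError("flavin difference spectrum is ~0 inside the window")
    alpha = float(s @ f) / denom
    stripped = spectrum - alpha * flavin_diff
    return stripped, alpha


def residual_flavin_correlation(
    stripped: np.ndarray,
    flavin_diff: np.ndarray,
    wavelengths: np.ndarray,
    window: tuple[float, float] = (430.0, 500.0),
) -> float:
    """Pearson correlation of the stripped residual with the flavin
    difference spectrum inside the window (diagnostic; ~0 after a clean
    strip)."""
    in_win = (wavelengths >= window[0]) & (wavelengths <= window[1])
    a = stripped[in_win]
    b = flavin_diff[in_win]
    scale = max(float(np.max(np.abs(stripped))), float(np.max(np.abs(flavin_diff))))
    if np.std(a) == 0 or np.std(b) == 0 or np.max(np.abs(a)) < 1e-9 * scale:
        # residual below numerical noise: no evidence of leftover flavin
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def estimate_rpr(alpha: float) -> float:
    """Radical-pair recombination fraction from the stripping coefficient.

    If only a fraction ``alpha`` of the (excitation-scaled) flavin
    difference spectrum survives in the persistent DADS, the complement
    ``1 - alpha`` of the initially formed radical pairs recombined to the
    ground state.  ``alpha`` slightly outside [0, 1] is tolerated (noise)
    and the result clipped to [0, 1].
    """
    if not (0.0 <= alpha <= 1.2):
        raise ValueError(f"stripping coefficient {alpha:.3f} outside [0, 1.2]")
    return float(np.clip(1.0 - alpha, 0.0, 1.0))
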