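"""SVD-based rank analysis of spectro-temporal matrices.

The number of exponential components a matrix supports is decided before
any nonlinear fitting: a component is counted as significant when its
singular value stands above the noise floor *and* both its left (spectral)
and right (temporal) singular vectors are smooth, as measured by their
first-lag autocorrelation.  Noise vectors decorrelate lag-to-lag; genuine
kinetic/spectral structure does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import TAMatrix

__all__ = ["RankReport", "svd_rank"]


@dataclass
class RankReport:
    singular_values: np.ndarray  # descending
    left_autocorr: np.ndarray    # first-lag autocorrelation of each u_i
    right_autocorr: np.ndarray   # first-lag autocorrelation of each v_i
    recommended_rank: int
    noise_floor: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = ["  i    sigma_i      ac(u_i)   ac(v_i)   significant"]
        for i, (s, au, av) in enumerate(
            zip(self.singular_values, self.left_autocorr, self.right_autocorr)
        ):
            sig = "yes" if i < self.recommended_rank else ""
            lines.append(f"{i + 1:>3}  {s:.4e}  {au:>8.3f}  {av:>8.3f}   {sig}")
        lines.append(
            f"noise floor {self.noise_floor:.3e}; "
            f"recommended rank {self.recommended_rank}"
        )
        return "\n".join(lines)


def _first_lag_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return 0.0
    return float(x[:-1] @ x[1:]) / denom


def svd_rank(
    m: TAMatrix,
    autocorr_threshold: float = 0.8,
    sv_ratio_floor: float = 3.0,
) -> RankReport:
    """Estimate the number of resolvable kinetic components.

    Parameters
    ----------
    autocorr_threshold : minimum first-lag autocorrelation of *both*
        singular vectors of a component for it to count as signal.
    sv_ratio_floor : the noise floor is ``sv_ratio_floor`` times the median
        of the trailing half of the singular-value spectrum.

    The recommended rank is the number of *leading* components that clear
    both criteria (the count stops at the first failure: parsimony protects
    the subsequent nonlinear fit).
    """
    vals = np.where(m.effective_mask(), np.nan, m.values)
    # rows/columns that are entirely masked carry no information
    row_ok = ~np.all(np.isnan(vals), axis=1)
    col_ok = ~np.all(np.isnan(vals), axis=0)
    sub = vals[np.ix_(row_ok, col_ok)]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError("unmasked submatrix must have >= 2 rows and columns")
    if np.isnan(sub).any():
        # impute isolated masked cells with the row mean; rank analysis is a
        # diagnostic, the fits themselves never consume imputed values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rowmean = np.nanmean(sub, axis=1)
        rowmean = np.where(np.isfinite(rowmean), rowmean, 0.0)
        idx = np.where(np.isnan(sub))
        sub = sub.copy()
        sub[idx] = rowmean[idx[0]]

    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    if s[0] == 0.0:
        warnings.warn("degenerate (all-zero) matrix: rank 0")
        return RankReport(s, np.zeros_like(s), np.zeros_like(s), 0, 0.0)

    tail = s[s.size // 2:]
    noise_floor = sv_ratio_floor * float(np.median(tail))
    left_ac = np.array([_first_lag_autocorr(u[:, i]) for i in range(s.size)])
    right_ac = np.array([_first_lag_autocorr(vt[i]) for i in range(s.size)])

    rank = 0
    for i in range(s.size):
        if (
            s[i] > noise_floor
            and left_ac[i] >= autocorr_threshold
            and right_ac[i] >= autocorr_threshold
        ):
            rank += 1
        else:
            break
    rank = min(rank, min(sub.shape))
    if rank == 0:
        warnings.warn("no significant component found (rank 0)")
    return RankReport(s, left_ac, right_ac, rank, noise_floor)
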