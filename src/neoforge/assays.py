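"""Functional-assay quantification: ΔMFI, 4PL EC50, LDH lysis, VAF.

Four small estimators used downstream of antigen discovery:

* ΔMFI — peptide-induced HLA stabilization, the difference in mean
  fluorescence intensity with and without peptide.
* EC50 — functional avidity from a four-parameter logistic (4PL) fit of a
  dose-response titration, the concentration of half-maximal response.
* LDH release — percent specific lysis from plate absorbances, corrected
  for effector-spontaneous and target-minimal release and normalized to
  the detergent-lysed maximum.
* VAF — variant allele frequency, variant-supporting reads over depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class DoseResponse:
    concentrations: tuple  # nM, strictly positive
    responses: tuple

    def __post_init__(self):
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if len(set(self.concentrations)) < 4:
            raise ValueError("4PL fitting needs >= 4 distinct concentrations")
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses differ in length")


@dataclass(frozen=True)
class LdhPlate:
    experimental: float
    effector_spontaneous: float
    target_minimal: float
    target_maximal: float
    et_ratio: float = float("nan")

    def __post_init__(self):
        if not self.target_maximal > self.target_minimal:
            raise ValueError("maximal release must exceed minimal release")


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    hill: float
    ec50: float
    residual_sse: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / x) ** self.hill)


def delta_mfi(mfi_with_peptide: float, mfi_without: float) -> float:
    """Stabilization signal; may be negative and is reported as-is."""
    if mfi_with_peptide < 0 or mfi_without < 0:
        raise ValueError("MFI values are nonnegative")
    return mfi_with_peptide - mfi_without


def four_pl(x, top, bottom, hill, ec50):
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):  # extreme ratios saturate to the asymptote
        return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def fit_4pl(data: DoseResponse, seed: int = 0, n_starts: int = 8) -> FourPLFit:
    """Least-squares 4PL fit on log10 dose with jittered multi-start.

    r(x) = bottom + (top - bottom) / (1 + (ec50/x)^hill); EC50 is returned
    in the input concentration units.  Initial values come from the data
    quantiles; ``n_starts`` jittered restarts (seeded) guard against local
    minima.  Warns when the responses do not span both asymptote regions.
    """
    x = np.asarray(data.concentrations, dtype=float)
    r = np.asarray(data.responses, dtype=float)
    lo, hi = r.min(), r.max()
    span = hi - lo if hi > lo else 1.0
    order = np.argsort(x)
    if abs(r[order[0]] - lo) > 0.25 * span and abs(r[order[0]] - hi) > 0.25 * span:
        warnings.warn("responses may not span the lower asymptote; EC50 poorly constrained")

    logx = np.log10(x)

    def residuals(theta):
        top, bottom, hill, log_ec50 = theta
        return four_pl(x, top, bottom, hill, 10.0 ** log_ec50) - r

    # initial EC50 guess: dose nearest the half-maximal response
    half = (lo + hi) / 2.0
    guess_log_ec50 = logx[np.argmin(np.abs(r - half))]
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        jitter = rng.normal(0, [0.05 * span, 0.05 * span, 0.3, 0.3]) if k else np.zeros(4)
        theta0 = np.array([hi, lo, 1.0, guess_log_ec50]) + jitter
        try:
            sol = least_squares(residuals, theta0, method="lm", max_nfev=5000)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if sol.success and (best is None or sse < best[0]):
            best = (sse, sol.x)
    if best is None:
        raise RuntimeError("4PL fit failed to converge from any start")
    sse, (top, bottom, hill, log_ec50) = best
    # canonical orientation: report hill > 0 curves with top >= bottom
    ec50 = 10.0 ** log_ec50
    if hill < 0:
        top, bottom, hill = bottom, top, -hill
    return FourPLFit(float(top), float(bottom), float(hill), float(ec50), sse)


def ldh_release_pct(plate: LdhPlate, clip: bool = True):
    """Percent specific lysis from LDH absorbances.

    100 * (experimental - effector_spontaneous - target_minimal)
        / (target_maximal - target_minimal),
    clipped to [0, 100] with a flag when clipping fired.
    """
    denom = plate.target_maximal - plate.target_minimal
    pct = 100.0 * (plate.experimental - plate.effector_spontaneous - plate.target_minimal) / denom
    clipped = False
    if clip and not 0.0 <= pct <= 100.0:
        excess = max(0.0 - pct, pct - 100.0)
        pct = float(np.clip(pct, 0.0, 100.0))
        clipped = excess > 1e-9  # float round-off at the limits is not clipping
    return pct, clipped


def vaf(alt_reads: int, depth: int) -> float:
    """Variant allele frequency: alt_reads / depth."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= alt_reads <= depth:
        raise ValueError("require 0 <= alt_reads <= depth")
    return alt_reads / depth
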