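"""GC-MS fatty-acid quantification and 13C isotopologue analysis.

Covers four operations on fatty-acid methyl-ester (FAME) panels:

* relative quantification — total ion counts normalized to the
  heptadecanoate internal standard and to protein (or tissue / volume), and
  the desaturation indices scd_index = palmitoleate/palmitate and
  fads2_index = sapienate/palmitate (product-to-substrate activity proxies
  for SCD and FADS2);
* absolute quantification against a 9-point standard-curve fit;
* correction of raw isotopologue spectra for natural 13C abundance by
  non-negative least squares against the binomial convolution matrix;
* fractional contribution of the tracer, FC = sum(i * x_i) / (n * sum(x_i)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import comb

__all__ = [
    "FattyAcidPanel",
    "IsotopologueVector",
    "StandardCurve",
    "NATURAL_13C",
    "correction_matrix",
    "natural_abundance_correction",
    "fractional_contribution",
    "desaturation_indices",
    "fit_standard_curve",
    "absolute_quantification",
]

NATURAL_13C = 0.0107  # natural abundance of carbon-13

INTERNAL_STANDARD = "heptadecanoate"


@dataclass
class FattyAcidPanel:
    """Per-sample total ion counts per fatty-acid species.

    ``ion_counts`` is sample x species (including the internal-standard
    channel); ``normalizer`` is the per-sample protein mass (mg), tissue
    mass (mg) or volume (uL).
    """

    ion_counts: pd.DataFrame
    normalizer: pd.Series
    internal_standard: str = INTERNAL_STANDARD

    def __post_init__(self) -> None:
        if (self.ion_counts.to_numpy() < 0).any():
            raise ValueError("ion counts must be non-negative")
        norm = self.normalizer.reindex(self.ion_counts.index)
        if norm.isna().any() or (norm <= 0).any():
            raise ValueError("normalizer must be positive for every sample")
        self.normalizer = norm


@dataclass
class IsotopologueVector:
    """Raw isotopologue intensities M+0 ... M+n for one species."""

    species: str
    n_carbons: int
    intensities: np.ndarray
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be at least 1")
        if self.intensities.size != self.n_carbons + 1:
            raise ValueError(
                f"expected {self.n_carbons + 1} intensities, got "
                f"{self.intensities.size}")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass
class StandardCurve:
    """Dilution series (amount in ug vs detector response) with an OLS fit."""

    amounts: np.ndarray
    responses: np.ndarray
    slope: float = field(init=False)
    intercept: float = field(init=False)
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.amounts = np.asarray(self.amounts, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.unique(self.amounts).size < 2:
            raise ValueError("standard curve needs at least 2 distinct amounts")
        fit = scipy.stats.linregress(self.amounts, self.responses)
        self.slope = float(fit.slope)
        self.intercept = float(fit.intercept)
        self.r2 = float(fit.rvalue**2)


def fit_standard_curve(amounts, responses) -> StandardCurve:
    return StandardCurve(amounts, responses)


def correction_matrix(n_carbons: int, p13c: float = NATURAL_13C) -> np.ndarray:
    """Binomial natural-abundance convolution matrix.

    ``M[i, j]`` is the probability that a molecule with j tracer-labeled
    carbons is observed as the M+i isotopologue, given that each of its
    n - j unlabeled carbons is 13C with probability ``p13c``:

        M[i, j] = C(n-j, i-j) * p^(i-j) * (1-p)^(n-i)   for i >= j.

    Columns sum to 1 for any 0 <= p < 1.
    """
    if not 0 <= p13c < 1:
        raise ValueError("p13c must be in [0, 1)")
    n = n_carbons
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    # entries below the diagonal (i < j) are meaningless and overwritten
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        M = comb(n - j, i - j) * p13c ** (i - j) * (1 - p13c) ** (n - i)
    M[i < j] = 0.0
    return M


def natural_abundance_correction(
    raw: IsotopologueVector,
    p13c: float = NATURAL_13C,
    residual_tol: float = 1e-6,
) -> np.ndarray:
    """Correct a raw spectrum for natural 13C abundance.

    Solves ``raw ~ M x`` by non-negative least squares and renormalizes the
    solution to sum to 1 (NNLS rather than direct inversion: measurement
    noise can otherwise yield negative fractions).  Stores the result on
    ``raw.corrected`` and returns it.  Warns when the relative residual of
    the fit exceeds ``residual_tol``.
    """
    y = raw.intensities
    total = y.sum()
    if total <= 0:
        raise ValueError("cannot correct an all-zero spectrum")
    M = correction_matrix(raw.n_carbons, p13c)
    x, rnorm = scipy.optimize.nnls(M, y / total)
    if rnorm > residual_tol:
        warnings.warn(
            f"natural-abundance correction residual {rnorm:.3g} exceeds "
            f"{residual_tol:.1g}", stacklevel=2)
    if x.sum() == 0:
        raise ValueError("correction produced an all-zero solution")
    x = x / x.sum()
    raw.corrected = x
    return x


def fractional_contribution(corrected: np.ndarray | IsotopologueVector) -> float:
    """Tracer fractional contribution of a corrected isotopologue vector."""
    if isinstance(corrected, IsotopologueVector):
        if corrected.corrected is None:
            raise ValueError("spectrum has not been corrected yet")
        x = corrected.corrected
    else:
        x = np.asarray(corrected, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("zero total signal; fractional contribution undefined")
    n = x.size - 1
    i = np.arange(n + 1)
    return float((i * x).sum() / (n * total))


def desaturation_indices(panel: FattyAcidPanel) -> pd.DataFrame:
    """Per-sample SCD/FADS2 desaturation indices and normalized abundances.

    The indices are ratios of raw ion counts (palmitoleate/palmitate and
    sapienate/palmitate) — internal-standard and protein normalization
    cancels in the ratio.  Normalized abundances
    (counts / internal standard / normalizer) are returned alongside with
    ``norm_`` column prefixes.
    """
    counts = panel.ion_counts
    for channel in ("palmitate", "palmitoleate", "sapienate", panel.internal_standard):
        if channel not in counts.columns:
            raise KeyError(f"panel is missing the {channel!r} channel")
    palmitate = counts["palmitate"]
    if (palmitate == 0).any():
        bad = palmitate.index[palmitate == 0][0]
        raise ValueError(f"palmitate counts are zero in sample {bad!r}; "
                         "desaturation indices undefined")
    istd = counts[panel.internal_standard]
    if (istd <= 0).any():
        raise ValueError("internal-standard counts must be positive")

    out = pd.DataFrame(index=counts.index)
    out["scd_index"] = counts["palmitoleate"] / palmitate
    out["fads2_index"] = counts["sapienate"] / palmitate
    species = [c for c in counts.columns if c != panel.internal_standard]
    norm = counts[species].div(istd, axis=0).div(panel.normalizer, axis=0)
    for sp in species:
        out[f"norm_{sp}"] = norm[sp]
    return out


def absolute_quantification(
    curve: StandardCurve,
    response: float,
    molecular_weight: float,
    extracted_volume_ul: float = 20.0,
) -> float:
    """Concentration (uM) from a detector response via the standard curve.

    amount_ug = (response - intercept) / slope; a negative inferred amount is
    clamped to zero with a warning.  Concentration is
    amount_ug / MW(g/mol) / volume(uL) * 1e6.
    """
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    if molecular_weight <= 0 or extracted_volume_ul <= 0:
        raise ValueError("molecular weight and volume must be positive")
    amount_ug = (response - curve.intercept) / curve.slope
    if amount_ug < 0:
        warnings.warn("response below the curve intercept; amount clamped to 0",
                      stacklevel=2)
        amount_ug = 0.0
    return amount_ug / molecular_weight / extracted_volume_ul * 1e6
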