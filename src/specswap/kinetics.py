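"""Ping-pong bi-bi kinetics: rate law, fitting, and specificity classification.

Aminotransferases follow a ping-pong bi-bi mechanism (the first product,
oxaloacetate or the aromatic keto acid, leaves before the second substrate
binds), whose initial-rate law without substrate inhibition is

    v = [E] * kcat * [AA] * [cosub] / (Km_AA*[cosub] + Km_cosub*[AA] + [AA]*[cosub])

When the amino-acid substrate cannot be brought near saturation (Km above
the highest attainable concentration), the law collapses to its first-order
limit v = [E] * (kcat/Km_AA) * [AA], and only the specificity constant
kcat/Km is identifiable.

The substrate preference of an enzyme is the ratio of specificity constants
(kcat/Km) for the dicarboxylic (aspartate) versus aromatic (phenylalanine)
reaction: ratio > 1 means AATase, < 1 TATase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigurationError, FitError, InputError
from .io_formats import KineticDataset

#: Highest amino-acid concentration (mM) routinely attainable in the assay;
#: a fitted Km above this is reported as "no saturation" (NS).
DEFAULT_NS_BOUND_MM = 40.0


@dataclass(frozen=True)
class RateLawParams:
    """Full ping-pong parameters: kcat (s^-1), Km's (mM)."""

    kcat: float
    Km_AA: float
    Km_cosub: float

    def __post_init__(self) -> None:
        for name, v in (("kcat", self.kcat), ("Km_AA", self.Km_AA), ("Km_cosub", self.Km_cosub)):
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be positive and finite, got {v}")


def pingpong_rate(
    params: RateLawParams,
    conc_AA: float | np.ndarray,
    conc_cosub: float | np.ndarray,
    conc_E: float | np.ndarray,
) -> float | np.ndarray:
    """Initial rate under the ping-pong bi-bi law (no substrate inhibition)."""
    A = np.asarray(conc_AA, dtype=float)
    B = np.asarray(conc_cosub, dtype=float)
    if np.any(A < 0) or np.any(B < 0):
        raise InputError("negative substrate concentration")
    denom = params.Km_AA * B + params.Km_cosub * A + A * B
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom > 0, conc_E * params.kcat * A * B / np.where(denom > 0, denom, 1.0), 0.0)
    return float(v) if v.ndim == 0 else v


def reduced_rate(
    kcat_over_Km: float,
    conc_AA: float | np.ndarray,
    conc_E: float | np.ndarray,
) -> float | np.ndarray:
    """First-order limit: v = [E] * (kcat/Km) * [AA]."""
    A = np.asarray(conc_AA, dtype=float)
    v = conc_E * kcat_over_Km * A
    return float(v) if v.ndim == 0 else v


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticFitResult:
    enzyme: str
    substrate: str
    model_used: str  # "full" | "reduced"
    saturated: bool
    params: RateLawParams | None  # None for reduced fits
    std_errors: dict[str, float]
    specificity_constant: float  # kcat/Km_AA, M^-1 s^-1
    specificity_constant_se: float
    residual_rms: float
    n_points: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.specificity_constant) and self.specificity_constant > 0):
            raise FitError(
                f"non-positive specificity constant {self.specificity_constant} "
                f"for {self.enzyme}/{self.substrate}"
            )


def _hanes_initial_guess(A: np.ndarray, B: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Starting point from a Hanes linearization A/v = Km/Vmax + A/Vmax at the
    highest co-substrate level, with a crude co-substrate Km guess."""
    mask = B >= np.median(B)
    a, v = A[mask], y[mask]
    ok = v > 0
    a, v = a[ok], v[ok]
    if len(a) >= 2 and np.ptp(a) > 0:
        slope, intercept = np.polyfit(a, a / v, 1)
        if slope > 0 and intercept > 0:
            vmax = 1.0 / slope
            km_a = intercept * vmax
            return max(vmax, 1e-9), max(km_a, 1e-9), max(float(np.median(B)) / 2, 1e-9)
    vmax = float(np.max(y)) * 1.5
    return max(vmax, 1e-9), max(float(np.median(A)), 1e-9), max(float(np.median(B)) / 2, 1e-9)


def _fit_reduced(A: np.ndarray, E: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS through the origin on (conc_AA, rate/conc_E).

    Returns (slope = kcat/Km in mM^-1 s^-1, se, residual rms).
    """
    x = A
    yy = y / E
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise InputError("all amino-acid concentrations are zero")
    slope = float(np.sum(x * yy)) / sxx
    resid = yy - slope * x
    dof = max(len(x) - 1, 1)
    sigma2 = float(np.sum(resid**2)) / dof
    se = math.sqrt(sigma2 / sxx)
    rms = math.sqrt(float(np.mean(resid**2)))
    return slope, se, rms


def fit_pingpong(
    data: KineticDataset,
    enzyme: str,
    substrate: str,
    model: str = "auto",
    ns_bound_mM: float = DEFAULT_NS_BOUND_MM,
    weighting: str = "none",
) -> KineticFitResult:
    """Fit rate measurements for one enzyme/substrate pair.

    ``model``: "full" (three-parameter ping-pong), "reduced" (first-order
    slope only), or "auto" — fit the full model and fall back to the reduced
    one when the amino-acid substrate shows no saturation (fitted Km_AA above
    ``ns_bound_mM`` or the maximum tested concentration, or an unbounded
    standard error), mirroring how "NS" rows are reported.

    ``weighting``: "none" (unweighted least squares) or "relative"
    (1/rate^2, i.e. constant coefficient of variation).

    The specificity constant kcat/Km is reported in M^-1 s^-1 (concentrations
    are mM, hence the factor 1000).
    """
    if model not in ("auto", "full", "reduced"):
        raise ConfigurationError(f"unknown model {model!r}")
    if weighting not in ("none", "relative"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    rows = data.for_assay(enzyme, substrate)
    A = rows["conc_aa_mM"].to_numpy(float)
    B = rows["conc_cosub_mM"].to_numpy(float)
    E = rows["conc_e"].to_numpy(float)
    y = rows["rate"].to_numpy(float)
    n_distinct_A = len(np.unique(A[A > 0]))

    def reduced_result(saturated: bool) -> KineticFitResult:
        if n_distinct_A < 3:
            raise InputError(
                f"reduced fit needs >= 3 distinct [AA] values, have {n_distinct_A}"
            )
        slope, se, rms = _fit_reduced(A, E, y)
        if slope <= 0:
            raise FitError(f"non-positive fitted slope for {enzyme}/{substrate}")
        return KineticFitResult(
            enzyme=enzyme,
            substrate=substrate,
            model_used="reduced",
            saturated=saturated,
            params=None,
            std_errors={"kcat_over_Km": se * 1000.0},
            specificity_constant=slope * 1000.0,  # mM^-1 -> M^-1
            specificity_constant_se=se * 1000.0,
            residual_rms=rms,
            n_points=len(rows),
        )

    if model == "reduced":
        return reduced_result(saturated=False)

    if len(rows) < 5 or n_distinct_A < 3:
        if model == "full":
            raise InputError(
                f"full fit needs >= 5 points with >= 3 distinct [AA]; "
                f"have {len(rows)} points, {n_distinct_A} distinct [AA]"
            )
        return reduced_result(saturated=False)

    kcat0, km_a0, km_b0 = _hanes_initial_guess(A, B, y / E)

    # fit on the turnover scale (rate/[E], s^-1) so absolute-tolerance
    # convergence tests are meaningful regardless of enzyme concentration
    yy = y / E

    def law(x, kcat, km_a, km_b):
        a, b = x
        return kcat * a * b / (km_a * b + km_b * a + a * b)

    sigma = np.abs(yy) if weighting == "relative" else None
    try:
        popt, pcov = curve_fit(
            law,
            (A, B),
            yy,
            p0=(kcat0, km_a0, km_b0),
            sigma=sigma,
            bounds=(1e-12, np.inf),
            maxfev=500 * 10,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
    except (RuntimeError, ValueError) as exc:
        if model == "auto":
            return reduced_result(saturated=False)
        raise FitError(f"full ping-pong fit failed for {enzyme}/{substrate}: {exc}") from exc
    kcat, km_a, km_b = (float(p) for p in popt)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    km_a_se = float(perr[1])

    max_tested = float(np.max(A))
    ns_threshold = min(ns_bound_mM, max_tested) if model == "auto" else ns_bound_mM
    unsaturated = (
        km_a > ns_threshold or not np.isfinite(km_a_se) or km_a_se > km_a
    )
    if model == "auto" and unsaturated:
        return reduced_result(saturated=False)

    params = RateLawParams(kcat=kcat, Km_AA=km_a, Km_cosub=km_b)
    resid = yy - law((A, B), *popt)
    spec = kcat / km_a * 1000.0  # mM^-1 s^-1 -> M^-1 s^-1
    # delta-method SE for the ratio, ignoring kcat-Km covariance sign issues
    with np.errstate(invalid="ignore"):
        rel = math.sqrt(
            (perr[0] / kcat) ** 2
            + (km_a_se / km_a) ** 2
            - 2 * float(pcov[0, 1]) / (kcat * km_a)
        ) if np.isfinite(pcov[0, 1]) else float("nan")
    spec_se = spec * rel if np.isfinite(rel) else float("nan")
    return KineticFitResult(
        enzyme=enzyme,
        substrate=substrate,
        model_used="full",
        saturated=not unsaturated,
        params=params,
        std_errors={"kcat": float(perr[0]), "Km_AA": km_a_se, "Km_cosub": float(perr[2])},
        specificity_constant=spec,
        specificity_constant_se=spec_se,
        residual_rms=math.sqrt(float(np.mean(resid**2))),
        n_points=len(rows),
    )


# ---------------------------------------------------------------------------
# Specificity ratio and classification
# ---------------------------------------------------------------------------

def round_sigfig(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures using round-half-even."""
    if value == 0 or not np.isfinite(value):
        return value
    from decimal import ROUND_HALF_EVEN, Decimal

    d = Decimal(repr(float(value)))
    exponent = d.adjusted()  # floor(log10(|value|))
    quant = Decimal(1).scaleb(exponent - sig + 1)
    return float(d.quantize(quant, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class SpecificityCall:
    ratio: float
    rounded_ratio: float
    label: str  # "AATase" | "TATase" | "ambiguous"


def classify_ratio(ratio: float) -> SpecificityCall:
    """Label by the >1 / <1 rule on the 2-significant-figure ratio."""
    if not (np.isfinite(ratio) and ratio > 0):
        raise InputError(f"specificity ratio must be positive and finite, got {ratio}")
    rounded = round_sigfig(ratio, 2)
    if rounded > 1:
        label = "AATase"
    elif rounded < 1:
        label = "TATase"
    else:
        label = "ambiguous"
    return SpecificityCall(ratio=ratio, rounded_ratio=rounded, label=label)


def specificity_ratio(
    fit_asp: KineticFitResult, fit_aromatic: KineticFitResult
) -> SpecificityCall:
    """Ratio of specificity constants, aspartate over aromatic reaction."""
    num = fit_asp.specificity_constant
    den = fit_aromatic.specificity_constant
    if not (np.isfinite(num) and np.isfinite(den)) or num <= 0 or den <= 0:
        raise InputError("both specificity constants must be present and positive")
    return classify_ratio(num / den)


def specificity_ratio_from_constants(asp: float, aromatic: float) -> SpecificityCall:
    """Ratio straight from two published kcat/Km constants (M^-1 s^-1)."""
    if not (np.isfinite(asp) and np.isfinite(aromatic)) or asp <= 0 or aromatic <= 0:
        raise InputError("specificity constants must be positive and finite")
    return classify_ratio(asp / aromatic)
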