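"""SORS differential processing.

The zero measurement is dominated by the container (surface layer), the
offset measurement is enriched in the fluid (subsurface layer).  Scaled
subtraction of one channel from the other isolates a single layer:

* forward SORS:  fluid     = offset - SF_f * zero
* reverse SORS:  container = zero   - SF_r * offset

The scaling factor SF is chosen so that the unwanted layer's contribution
cancels.  Two deterministic forward estimators are provided:

1. window regression — inside a configured container-dominant wavenumber
   window, SF_f is the non-negative least-squares coefficient of the zero
   spectrum against the offset spectrum;
2. negativity-penalty grid search — both layers are non-negative, so the
   subtraction residual stays non-negative until the unwanted layer is
   over-subtracted; SF is the largest grid value whose negativity penalty
   sum(max(0, -residual)^2) stays at the noise floor.

Both estimators can only err on the over-subtraction side (the window one
because fluid leaking into the window raises the regression ratio, the
penalty one because fluid background masks emerging negativity), so when a
window is configured the smaller of the two is used.  The reverse factor
(nulling the fluid from the zero channel) is not identifiable from
non-negativity alone when the container fluorescence never vanishes; it is
instead chosen so that the sharp spectral detail of the container branch is
orthogonal to the detail of the forward-isolated fluid spectrum, falling
back to the role-exchanged penalty search in degenerate cases.

The isolated fluid spectrum is then baseline-corrected (iteratively clipped
polynomial fit, order 5) and SNV-normalized for multivariate analysis; the
container branch is left un-normalized so curve-resolution scores keep
physical magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    AlignmentError,
    DegenerateInputError,
    SORSMeasurement,
    Spectrum,
    WavenumberAxis,
    resample,
    truncate,
)

__all__ = [
    "PreprocessConfig",
    "split_container_basis",
    "deflate_against_references",
    "default_container_basis",
    "ProcessedPair",
    "estimate_scaling_factor",
    "sors_subtract",
    "reverse_sors",
    "baseline_correct",
    "snv",
    "process_measurement",
    "robust_noise_sd",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the differential-processing chain."""

    # container-dominant window: the high-wavenumber edge of the analysis
    # region, beyond the fluid Raman bands
    sf_window: tuple[float, float] | None = (1720.0, 1800.0)
    sf_grid: tuple[float, float, float] = (0.0, 5.0, 0.01)  # (min, max, step)
    sf_penalty_tol: float = 1e-9  # relative negativity-penalty floor
    baseline_order: int = 5
    baseline_iterations: int = 20
    snv_epsilon: float = 1e-12
    truncate_lo: float = 750.0
    truncate_hi: float = 1800.0

    def __post_init__(self):
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.sf_grid[0] < 0 or self.sf_grid[2] <= 0:
            raise ValueError("sf_grid must have min >= 0 and step > 0")
        if self.snv_epsilon <= 0:
            raise ValueError("snv_epsilon must be > 0")


@dataclass
class ProcessedPair:
    """Outcome of processing one SORS measurement."""

    fluid_spectrum: Spectrum
    container_spectrum: Spectrum
    sf_forward: float
    sf_reverse: float

    def __post_init__(self):
        if self.sf_forward < 0 or self.sf_reverse < 0:
            raise ValueError("scaling factors must be >= 0")


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise sd from the median absolute second difference.

    Second differences annihilate locally-linear signal, so smooth spectra
    contribute little; for white Gaussian noise the second difference has
    sd sqrt(6)*sigma and median(|N(0,s)|) = 0.6745 s.
    """
    d2 = np.diff(np.asarray(y, dtype=float), n=2)
    if d2.size == 0:
        return 0.0
    return float(np.median(np.abs(d2)) / (0.6744897501960817 * np.sqrt(6.0)))


def _check_common_axis(a: Spectrum, b: Spectrum) -> None:
    if a.axis != b.axis:
        raise AlignmentError("spectra are not on a common axis; resample first")


def _penalty_scaling_factor(num: np.ndarray, den: np.ndarray,
                            grid: tuple[float, float, float],
                            ptol: float,
                            transform=None) -> float:
    """Largest SF whose negativity penalty stays at the noise floor.

    penalty(SF) = sum(min(t(num - SF*den), 0)^2) where t is an optional
    linear high-pass.  The feasibility threshold combines an estimated
    white-noise floor with the negativity the two inputs carry on their own
    (high-pass side lobes, envelope wiggles), so only negativity *created by
    the subtraction* counts against an SF value.
    """
    lo, hi, step = grid
    t = transform if transform is not None else (lambda v: v)
    t_num, t_den = t(num), t(den)
    scale = float(np.sum(t_num * t_num))
    if scale == 0.0:
        return 0.0
    sd_num = robust_noise_sd(num)
    sd_den = robust_noise_sd(den)
    n = num.size
    p_num0 = float(np.sum(np.square(np.minimum(t_num, 0.0))))
    dep_num = float(-min(t_num.min(), 0.0))

    # The residual's intrinsic negativity (high-pass side lobes of the
    # remaining fluid bands) can only shrink as SF grows — its coefficient
    # is b_o - SF*b_z — so the allowance is anchored to the numerator's own
    # negativity and does not scale with SF; only the white-noise term does.
    def feasible(sf: float) -> bool:
        r = t(num - sf * den)
        penalty = float(np.sum(np.square(np.minimum(r, 0.0))))
        sigma_sf = np.sqrt(sd_num**2 + sf**2 * sd_den**2)
        noise_floor = n * sigma_sf**2
        if penalty > ptol * scale + noise_floor + 2.0 * p_num0:
            return False
        # concentrated dips: the deepest point may not move the total energy
        # but still flags over-subtraction once it clears the depth the
        # numerator carries on its own plus a generous noise extreme
        depth_allow = 5.0 * sigma_sf + dep_num + ptol * scale
        return float(r.min()) >= -depth_allow

    best = lo if feasible(lo) else None
    current_step = step
    current_lo = lo
    # coarse grid, then two decades of refinement around the last feasible SF
    for _ in range(3):
        sf_values = np.arange(current_lo, hi + 0.5 * current_step, current_step)
        last = None
        for sf in sf_values:
            if feasible(float(sf)):
                last = float(sf)
            elif last is not None:
                break
        if last is None:
            break
        best = last
        current_lo = last
        hi = last + current_step
        current_step /= 10.0
    return best if best is not None else 0.0


_HP_SIZE = 31  # smoothing kernel (points); wider than any Raman band


def _highpass(y: np.ndarray) -> np.ndarray:
    """Sharp spectral detail: y minus a locally-quadratic smooth.

    A Savitzky-Golay smooth of polynomial order 2 follows fluorescence
    envelopes (locally quadratic, including steep flanks) exactly while
    passing Raman-bandwidth features; being linear, it preserves the mixing
    ratios between channels that the SF estimators rely on.
    """
    return y - savgol_filter(y, _HP_SIZE, 2, mode="nearest")


def _window_sf(num: np.ndarray, den: np.ndarray, x: np.ndarray,
               window: tuple[float, float]) -> float | None:
    """Non-negative least-squares coefficient of den against num in window;
    None when the window carries no den signal."""
    wlo, whi = window
    mask = (x >= wlo) & (x <= whi)
    if not np.any(mask):
        raise ValueError(f"sf_window [{wlo}, {whi}] does not overlap the axis")
    d, m = den[mask], num[mask]
    dd = float(d @ d)
    if dd == 0.0:
        return None
    return max(0.0, float(d @ m) / dd)


def estimate_scaling_factor(
    zero: Spectrum,
    offset: Spectrum,
    config: PreprocessConfig = PreprocessConfig(),
    direction: Literal["forward", "reverse"] = "forward",
) -> float:
    """Estimate the subtraction scaling factor.

    forward: SF for offset - SF*zero, chosen to cancel the container from
    the fluid branch.  Three candidate estimates are formed — window
    regression (exact when the window is container-pure, biased high by any
    fluid leakage), raw negativity search (exact at low noise, biased high
    when a fluorescence floor masks negativity), and high-passed negativity
    search (robust to smooth floors, blind to featureless glass) — and the
    smallest is returned, since each candidate can only err on the
    over-subtraction side in its blind regime.

    reverse: SF for zero - SF*offset, chosen so the high-passed container
    branch is orthogonal to the high-passed forward-isolated fluid spectrum
    (non-negativity alone cannot identify this factor when the container
    fluorescence never vanishes).
    """
    _check_common_axis(zero, offset)
    z, o = zero.intensity, offset.intensity
    if direction == "forward":
        if not np.any(z != 0):
            raise DegenerateInputError("zero spectrum is identically zero")
        candidates = [
            _penalty_scaling_factor(o, z, config.sf_grid, config.sf_penalty_tol),
            _penalty_scaling_factor(o, z, config.sf_grid, config.sf_penalty_tol,
                                    transform=_highpass),
        ]
        if config.sf_window is not None:
            wsf = _window_sf(o, z, zero.wavenumbers, config.sf_window)
            if wsf is not None:
                candidates.append(wsf)
        return min(candidates)
    if direction != "reverse":
        raise ValueError(f"unknown direction {direction!r}")
    if not np.any(o != 0):
        raise DegenerateInputError("offset spectrum is identically zero")
    sf_f = estimate_scaling_factor(zero, offset, config, "forward")
    g_d = _highpass(o - sf_f * z)
    z_d = _highpass(z)
    o_d = _highpass(o)
    # restrict the orthogonality criterion to strong fluid-detail pixels so
    # residual broadband structure cannot bias the ratio
    g_abs = np.abs(g_d)
    mask = g_abs >= 0.2 * g_abs.max() if g_abs.max() > 0 else g_abs > -1
    zw, ow, gw = z_d[mask], o_d[mask], g_d[mask]
    denom = float(ow @ gw)
    norm = float(np.linalg.norm(ow) * np.linalg.norm(gw))
    if norm == 0.0 or denom <= 1e-6 * norm:
        # degenerate fluid detail: fall back to role-exchanged penalty search
        return _penalty_scaling_factor(z, o, config.sf_grid, config.sf_penalty_tol)
    return max(0.0, float(zw @ gw) / denom)


def sors_subtract(zero: Spectrum, offset: Spectrum, sf: float) -> Spectrum:
    """offset - sf*zero: the fluid (subsurface) branch."""
    _check_common_axis(zero, offset)
    if sf < 0:
        raise ValueError("sf must be >= 0")
    y = offset.intensity - sf * zero.intensity
    meta = dict(offset.meta)
    meta.update(channel="processed", layer="fluid", sf=sf)
    return Spectrum(offset.axis, y, meta)


def reverse_sors(zero: Spectrum, offset: Spectrum, sf: float) -> Spectrum:
    """zero - sf*offset: the container (surface) branch."""
    _check_common_axis(zero, offset)
    if sf < 0:
        raise ValueError("sf must be >= 0")
    y = zero.intensity - sf * offset.intensity
    meta = dict(zero.meta)
    meta.update(channel="processed", layer="container", sf=sf)
    return Spectrum(zero.axis, y, meta)


def baseline_correct(spectrum: Spectrum, order: int = 5,
                     iterations: int = 20,
                     extra_basis: np.ndarray | None = None) -> Spectrum:
    """Iteratively clipped polynomial baseline removal.

    A polynomial of the given order is fit to the spectrum; points above the
    fit are replaced by the fit value (suppressing peaks) and the fit is
    repeated.  The final polynomial is subtracted.

    ``extra_basis`` optionally extends the baseline model with additional
    smooth shapes (e.g. known container fluorescence envelopes that a
    polynomial cannot express); they participate in the same clipped fit.
    """
    n = len(spectrum.axis)
    if n <= order + 1:
        raise ValueError(
            f"baseline order {order} needs more than {order + 1} points, got {n}"
        )
    x = spectrum.wavenumbers
    # scale to [-1, 1] for numerical conditioning
    x01 = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    y = spectrum.intensity.astype(float).copy()
    cols = [x01**k for k in range(order + 1)]
    if extra_basis is not None:
        for row in np.atleast_2d(extra_basis):
            scale = np.abs(row).max()
            if scale > 0:
                cols.append(row / scale)
    A = np.column_stack(cols)
    fit = np.zeros_like(y)
    for _ in range(max(1, iterations)):
        coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
        fit = A @ coeffs
        y = np.minimum(y, fit)
    return spectrum.with_intensity(
        spectrum.intensity - fit, channel="processed", baseline_order=order
    )


def snv(spectrum: Spectrum, epsilon: float = 1e-12) -> Spectrum:
    """Standard normal variate: per-spectrum centering and unit scaling."""
    if len(spectrum.axis) < 2:
        raise ValueError("SNV needs at least 2 points")
    y = spectrum.intensity
    sd = float(np.std(y))
    if sd < epsilon:  # constant spectrum: no scale information
        out = np.zeros_like(y)
    else:
        out = (y - float(np.mean(y))) / sd
    return spectrum.with_intensity(out, channel="processed", normalized="snv")


def split_container_basis(
    basis: np.ndarray,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Split container references into sharp (polymer) and smooth (glass)
    subsets.  Sharp profiles are identifiable in the high-pass domain and
    are used for deflation; featureless envelopes extend the baseline model
    instead, where being smooth makes them harmless."""
    sharp, smooth = [], []
    for b in np.atleast_2d(basis):
        b_hp = _highpass(b)
        (sharp if float(b_hp @ b_hp) > 0.01 * float(b @ b) else smooth).append(b)
    return (
        np.vstack(sharp) if sharp else None,
        np.vstack(smooth) if smooth else None,
    )


def deflate_against_references(spectrum: Spectrum,
                               sharp_basis: np.ndarray) -> Spectrum:
    """Remove container residue by least-squares projection of the
    spectrum's high-pass detail onto sharp reference container profiles."""
    B = np.atleast_2d(sharp_basis)
    B_hp = np.vstack([_highpass(b) for b in B])
    f_hp = _highpass(spectrum.intensity)
    coeffs, *_ = np.linalg.lstsq(B_hp.T, f_hp, rcond=None)
    return spectrum.with_intensity(
        spectrum.intensity - coeffs @ B,
        deflation_coeffs=coeffs.tolist(),
    )


def default_container_basis(axis: WavenumberAxis) -> np.ndarray | None:
    """Reference container profiles rendered on ``axis`` (deflation basis)."""
    from . import simulate  # deferred: simulate depends only on core

    rows = [
        simulate.render_container(cdef, axis).intensity
        for cdef in simulate.CONTAINER_LIBRARY.values()
    ]
    return np.vstack(rows) if rows else None


def process_measurement(
    measurement: SORSMeasurement,
    config: PreprocessConfig = PreprocessConfig(),
    target_axis: WavenumberAxis | None = None,
    container_basis: np.ndarray | None = None,
) -> ProcessedPair:
    """Full differential chain for one zero/offset pair.

    resample (optional) -> truncate -> estimate SF both directions ->
    scaled subtraction; the fluid branch is additionally baseline-corrected
    and SNV-normalized, the container branch is left un-normalized.

    The fluid spectrum's meta records ``contrast_ratio`` — the RMS of the
    raw subtraction relative to the offset RMS — which downstream code uses
    to flag measurements with no usable zero/offset contrast.
    """
    tag = f"{measurement.sample_id}/{measurement.replicate_id}"
    try:
        zero, offset = measurement.zero, measurement.offset
        if target_axis is not None:
            zero = resample(zero, target_axis)
            offset = resample(offset, target_axis)
        zero_t = truncate(zero, config.truncate_lo, config.truncate_hi)
        offset_t = truncate(offset, config.truncate_lo, config.truncate_hi)
        sf_f = estimate_scaling_factor(zero_t, offset_t, config, "forward")
        sf_r = estimate_scaling_factor(zero_t, offset_t, config, "reverse")
        # subtraction and baseline run on the full measured axis so the
        # polynomial fit is constrained beyond the analysis window; the
        # poorly-determined fit edges are then truncated away
        fluid_raw = sors_subtract(zero, offset, sf_f)
        container = reverse_sors(zero, offset, sf_r)
        # container deflation: any sharp container residue left by an
        # imperfect SF is removed by least-squares projection of the fluid
        # branch onto the reference container profiles (high-pass domain,
        # so broad fluorescence — handled later by the baseline — is
        # ignored).  The references are fluid- and noise-free, so the fit
        # is unbiased; featureless glass profiles carry no sharp detail and
        # are suppressed by the conditioning cutoff.
        basis = container_basis
        if basis is None:
            basis = default_container_basis(fluid_raw.axis)
        smooth_refs = None
        if basis is not None and len(basis):
            sharp, smooth_refs = split_container_basis(basis)
            if sharp is not None:
                fluid_raw = deflate_against_references(fluid_raw, sharp)
        fluid_t = truncate(fluid_raw, config.truncate_lo, config.truncate_hi)
        offset_rms = float(np.sqrt(np.mean(offset_t.intensity**2)))
        fluid_rms = float(np.sqrt(np.mean(fluid_t.intensity**2)))
        contrast = fluid_rms / offset_rms if offset_rms > 0 else 0.0
        fluid = baseline_correct(
            fluid_raw, config.baseline_order, config.baseline_iterations,
            extra_basis=smooth_refs,
        )
        fluid = truncate(fluid, config.truncate_lo, config.truncate_hi)
        fluid = snv(fluid, config.snv_epsilon)
        fluid.meta["contrast_ratio"] = contrast
        return ProcessedPair(
            fluid_spectrum=fluid,
            container_spectrum=truncate(
                container, config.truncate_lo, config.truncate_hi
            ),
            sf_forward=sf_f,
            sf_reverse=sf_r,
        )
    except (ValueError, KeyError) as exc:
        raise type(exc)(f"{tag}: {exc}") from exc
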