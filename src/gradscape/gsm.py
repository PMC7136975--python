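"""Gradient surface metrics (surface metrology on habitat rasters).

Nine landscape-level surface-metrology statistics computed on a continuous
suitability raster, usually an ellipse clip:

========  =====================================================
Sa        average surface roughness, mean |height|
S10       ten-point height (5 highest peaks + 5 deepest pits)
Ssk       skewness of the height distribution
Sdr       surface-area ratio, % excess over the flat plane
Std       dominant texture direction (degrees, [0, 180))
Stdi      texture direction index, mean/max of the angular spectrum
Srwi      radial wavelength index, mean/max of the radial spectrum
Sfd       fractal dimension from the radial power-spectrum slope
Sbi       surface bearing index, Sq / height at 5% bearing area
========  =====================================================

Heights are measured from the mean of valid cells.  Spatial-domain metrics
(Sa, S10, Ssk, Sdr, Sbi) use valid cells only; the Fourier metrics need a
full grid, so masked cells are mean-filled (adding no spectral power) and
a Hann taper suppresses clip-boundary leakage — both choices are recorded
in the output metadata.  ``Sfd`` uses the convention ``Sfd = 4 + s/2``
with ``s`` the log-log slope of radially averaged power, which maps a
fractional-Brownian surface of roughness exponent H to ``Sfd = 3 - H``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .raster import Raster

__all__ = [
    "GSM_NAMES",
    "amplitude_metrics",
    "sdr",
    "fourier_texture_metrics",
    "sbi",
    "gsm_vector",
]

GSM_NAMES = ["Sa", "S10", "Ssk", "Sdr", "Std", "Stdi", "Srwi", "Sfd", "Sbi"]


class MetricUndefinedError(ValueError):
    """A metric's preconditions are not met (e.g. zero-variance surface)."""


def _heights(surface: Raster) -> np.ndarray:
    z = surface.valid_values().astype(float)
    return z - z.mean()


def amplitude_metrics(surface: Raster) -> dict[str, float]:
    """Sa, S10 and Ssk from mean-referenced heights.

    Local extrema for S10 are cells strictly above (below) all their valid
    8-neighbors; with fewer than 5 on a side, the available ones are used
    but the divisor stays 5.
    """
    z = _heights(surface)
    if z.size < 9:
        raise MetricUndefinedError("need at least 9 valid cells")
    if np.ptp(surface.valid_values()) == 0.0:
        raise MetricUndefinedError("zero-variance surface: Ssk undefined")
    sa = float(np.abs(z).mean())
    sq = float(np.sqrt((z ** 2).mean()))
    ssk = float((z ** 3).mean() / sq ** 3)

    zgrid = np.where(surface.mask, np.nan, surface.values.astype(float))
    zgrid = zgrid - np.nanmean(zgrid)
    peaks, pits = _local_extrema(zgrid)
    top = np.sort(peaks)[::-1][:5]
    bot = np.sort(pits)[:5]
    s10 = float((top.sum() + np.abs(bot).sum()) / 5.0)
    return {"Sa": sa, "S10": s10, "Ssk": ssk}


def _local_extrema(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Heights of strict 8-neighbor local maxima and minima (NaN-aware)."""
    n, m = z.shape
    is_max = ~np.isnan(z)
    is_min = is_max.copy()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = np.full_like(z, np.nan)
            r0, r1 = max(dr, 0), n + min(dr, 0)
            c0, c1 = max(dc, 0), m + min(dc, 0)
            nb[r0:r1, c0:c1] = z[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            with np.errstate(invalid="ignore"):
                is_max &= np.isnan(nb) | (z > nb)
                is_min &= np.isnan(nb) | (z < nb)
    return z[is_max & ~np.isnan(z)], z[is_min & ~np.isnan(z)]


def sdr(surface: Raster) -> float:
    """Surface-area ratio: percent excess of the 3-D surface over its plan area.

    Each 2x2 block of valid cell centers is split into two 3-D triangles
    (x, y in meters, z in native units); blocks with any invalid cell are
    skipped.
    """
    z = np.where(surface.mask, np.nan, surface.values.astype(float))
    cs = surface.cell_size
    z00 = z[:-1, :-1]
    z01 = z[:-1, 1:]
    z10 = z[1:, :-1]
    z11 = z[1:, 1:]
    ok = ~(np.isnan(z00) | np.isnan(z01) | np.isnan(z10) | np.isnan(z11))
    if not ok.any():
        raise MetricUndefinedError("no complete 2x2 block of valid cells")

    def tri_area(dza, dzb):
        # triangle with legs (cs, 0, dza) and (0, cs, dzb): cross product norm / 2
        return 0.5 * np.sqrt((cs * dzb) ** 2 + (cs * dza) ** 2 + cs ** 4)

    a1 = tri_area(z01 - z00, z10 - z00)
    a2 = tri_area(z10 - z11, z01 - z11)
    surf = (a1 + a2)[ok].sum()
    plan = ok.sum() * cs * cs
    return float(100.0 * (surf - plan) / plan)


def fourier_texture_metrics(surface: Raster, taper: bool = True,
                            n_angle_bins: int = 180) -> dict[str, float]:
    """Std, Stdi, Srwi, Sfd from the 2-D amplitude spectrum.

    The surface is mean-filled over masked cells, mean-centered, optionally
    Hann-tapered, and Fourier transformed.  The angular spectrum F(theta)
    sums amplitude into 1-degree bins of wavevector angle (0 = variation
    along the x/east axis); the radial spectrum G(r) sums amplitude into
    unit annuli of wavevector radius (index units).  Sfd comes from an OLS
    fit of log radially-averaged power against log r over r in
    [2, Nyquist/2].
    """
    if min(surface.shape) < 16:
        raise MetricUndefinedError("need at least a 16x16 grid for Fourier metrics")
    vals = surface.values.astype(float)
    valid = ~surface.mask
    if not valid.any() or np.ptp(vals[valid]) == 0.0:
        raise MetricUndefinedError("degenerate surface: texture undefined")
    mean = vals[valid].mean()
    z = np.where(surface.mask, mean, vals) - mean
    n, m = z.shape
    if taper:
        z = z * np.outer(np.hanning(n), np.hanning(m))
    F = np.fft.fft2(z)
    A = np.abs(F)
    fy = np.fft.fftfreq(n)[:, None] * n   # row wavenumber (north-south), index units
    fx = np.fft.fftfreq(m)[None, :] * m   # column wavenumber (east-west)
    A[0, 0] = 0.0  # exclude DC

    # angular spectrum over [0, 180): angle of the wavevector from east;
    # mean amplitude per 1-degree bin, so bin population (which varies on a
    # square grid) does not masquerade as anisotropy
    theta = np.degrees(np.arctan2(np.broadcast_to(fy, A.shape),
                                  np.broadcast_to(fx, A.shape))) % 180.0
    bins = np.minimum((theta * n_angle_bins / 180.0).astype(int), n_angle_bins - 1)
    nz = np.ones(A.shape, dtype=bool)
    nz[0, 0] = False
    cnt = np.bincount(bins[nz].ravel(), minlength=n_angle_bins)
    Fth = np.bincount(bins[nz].ravel(), weights=A[nz].ravel(),
                      minlength=n_angle_bins)
    occupied = cnt > 0
    Fth = np.where(occupied, Fth / np.maximum(cnt, 1), 0.0)
    std = float(np.argmax(Fth) * (180.0 / n_angle_bins))  # first max on ties
    stdi = float(Fth[occupied].mean() / Fth.max())

    # radial spectrum: mean amplitude per unit-width annulus
    r = np.hypot(np.broadcast_to(fy, A.shape), np.broadcast_to(fx, A.shape))
    rbin = np.round(r).astype(int)
    nyq = min(n, m) // 2
    sel = (rbin >= 1) & (rbin <= nyq)
    rcnt = np.bincount(rbin[sel], minlength=nyq + 1)[1:]
    G = np.bincount(rbin[sel], weights=A[sel], minlength=nyq + 1)[1:]
    G = G / np.maximum(rcnt, 1)
    srwi = float(G.mean() / G.max())

    # fractal dimension from radially averaged power
    P = A ** 2
    counts = np.bincount(rbin[sel], minlength=nyq + 1)[1:]
    Pr = np.bincount(rbin[sel], weights=P[sel], minlength=nyq + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        Pr = Pr / counts
    radii = np.arange(1, nyq + 1)
    fit_sel = (radii >= 2) & (radii <= nyq / 2) & (Pr > 0)
    if fit_sel.sum() < 3:
        raise MetricUndefinedError("too few radial bins for the Sfd fit")
    slope = np.polyfit(np.log(radii[fit_sel]), np.log(Pr[fit_sel]), 1)[0]
    sfd = float(4.0 + slope / 2.0)
    return {"Std": std, "Stdi": stdi, "Srwi": srwi, "Sfd": sfd}


def sbi(surface: Raster) -> float:
    """Surface bearing index: Sq over the height at 5% bearing area.

    The bearing-area (Abbott) curve is the survival function of heights;
    its 5% point is the mean-referenced height exceeded by the top 5% of
    cells (linear interpolation).  For a Gaussian surface Sbi tends to
    1/1.6449.
    """
    z = _heights(surface)
    if z.size < 100:
        raise MetricUndefinedError("need at least 100 valid cells for Sbi")
    if np.ptp(surface.valid_values()) == 0.0:
        raise MetricUndefinedError("zero-variance surface")
    sq = float(np.sqrt((z ** 2).mean()))
    z05 = float(np.quantile(z, 0.95))
    if z05 <= 0.0:
        raise MetricUndefinedError("bearing height at 5% is non-positive")
    return sq / z05


def gsm_vector(surface: Raster, taper: bool = True) -> dict[str, float]:
    """All nine metrics; undefined components propagate as NaN with a warning."""
    out: dict[str, float] = {}

    def _try(fn, names):
        try:
            res = fn()
            if isinstance(res, dict):
                out.update(res)
            else:
                out[names[0]] = res
        except MetricUndefinedError as exc:
            warnings.warn(f"{'/'.join(names)} undefined: {exc}")
            for nm in names:
                out[nm] = np.nan

    _try(lambda: amplitude_metrics(surface), ["Sa", "S10", "Ssk"])
    _try(lambda: sdr(surface), ["Sdr"])
    _try(lambda: fourier_texture_metrics(surface, taper=taper),
         ["Std", "Stdi", "Srwi", "Sfd"])
    _try(lambda: sbi(surface), ["Sbi"])
    # a constant surface still has well-defined Sa = 0 and S10 = 0 even
    # though Ssk (odd moment over zero variance) does not exist
    if np.isnan(out.get("Sa", np.nan)):
        z = surface.valid_values().astype(float)
        if z.size >= 9 and np.ptp(z) == 0.0:
            out["Sa"] = 0.0
            out["S10"] = 0.0
    return {k: out[k] for k in GSM_NAMES}
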