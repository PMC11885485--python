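"""Phase retrieval from propagation-based phase-contrast images.

All filters are written in FFT pixel-frequency units.  With f in
cycles/pixel and F the Fresnel number of the (effective) pixel, the phase
of the contrast transfer function is

    chi(f) = pi * (fx^2 + fy^2) / F      (== pi*lambda*z_eff*|f_phys|^2),

and for a weak homogeneous object (B = (beta/delta)*(-phi)) the measured
contrast obeys

    FT[I - 1] = 2*(sin(chi) + (beta/delta)*cos(chi)) * FT[phi].

Four schemes are provided:

``ctf_single``
    Tikhonov-regularized inversion of the relation above at one distance,
    with a two-band regularizer switching from alpha_low to alpha_high at
    the first CTF maximum (chi = pi/2).
``ctf_multi_cg``
    Multi-distance least squares across several Fresnel numbers (distances
    chosen so the CTF zeros do not coincide), refined by conjugate-gradient
    iterations on the linearized quadratic objective.
``paganin`` / ``paganin_generalized``
    Single-material low-pass filters returning a projected thickness map;
    the generalized variant replaces k^2 by the discrete Laplacian symbol,
    which suppresses high frequencies less and matches the sampling of the
    detector grid.
``bac``
    Bronnikov-aided correction for the direct-contrast regime: a weakly
    regularized Bronnikov phase estimate whose Laplacian is divided out of
    the edge-enhanced intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import get_preset

_VALID_METHODS = ("ctf_single", "ctf_multi_cg", "paganin", "gpm", "bac", "none")


@dataclass
class RetrievalParams:
    method: str = "ctf_single"
    beta_over_delta: float = 1.0 / 27.0
    alpha_low: float = 1e-3
    alpha_high: float = 1e-1
    fresnel_numbers: tuple[float, ...] = ()
    cg_iterations: int = 10
    bac_alpha: float = 0.01
    bac_gamma: float = 0.5
    pixel_m: float | None = None
    wavelength_m: float | None = None
    z_eff_m: float | None = None
    delta: float | None = None
    beta: float | None = None
    pad: int = 2

    def __post_init__(self):
        if self.method not in _VALID_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if min(self.alpha_low, self.alpha_high, self.bac_alpha) < 0:
            raise ValueError("regularizers must be non-negative")
        if self.bac_gamma < 0:
            raise ValueError("bac_gamma must be non-negative")

    @property
    def fresnel_number(self) -> float:
        if not self.fresnel_numbers:
            if None in (self.pixel_m, self.wavelength_m, self.z_eff_m):
                raise ValueError("no Fresnel number available in params")
            return self.pixel_m**2 / (self.z_eff_m * self.wavelength_m)
        return self.fresnel_numbers[0]

    @property
    def mu(self) -> float:
        """Linear attenuation coefficient 4*pi*beta/lambda (1/m)."""
        if self.beta is None or self.wavelength_m is None:
            raise ValueError("mu requires beta and wavelength")
        if self.beta == 0:
            raise ValueError("beta = 0: attenuation coefficient undefined")
        return 4 * np.pi * self.beta / self.wavelength_m


def chi_grid(shape: tuple[int, int], fresnel_number: float) -> np.ndarray:
    """chi(f) = pi*(fx^2+fy^2)/F on the FFT frequency grid of `shape`."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    return np.pi * (fy**2 + fx**2) / fresnel_number


def _pad(img: np.ndarray, pad: int):
    if pad <= 1:
        return img, (0, 0)
    h, w = img.shape
    py, px = (pad - 1) * h // 2, (pad - 1) * w // 2
    return np.pad(img, ((py, py), (px, px)), mode="reflect"), (py, px)


def _crop(img: np.ndarray, margins, shape):
    py, px = margins
    if py == 0 and px == 0:
        return img
    return img[py:py + shape[0], px:px + shape[1]]


def _band_alpha(chi: np.ndarray, fresnel_number: float,
                alpha_low: float, alpha_high: float) -> np.ndarray:
    """Two-band Tikhonov weight switching at the first CTF maximum.

    The transition is a smooth logistic in radial frequency centred at
    chi = pi/2 (f^2 = F/2), with width 10% of the transition radius.
    """
    f2 = chi * fresnel_number / np.pi
    f1sq = fresnel_number / 2.0
    if f1sq >= 0.5:          # first maximum beyond Nyquist: low band everywhere
        return np.full_like(chi, alpha_low)
    f = np.sqrt(f2)
    f1 = np.sqrt(f1sq)
    s = 1.0 / (1.0 + np.exp(-(f - f1) / (0.1 * f1)))
    return alpha_low + (alpha_high - alpha_low) * s


def ctf_factor(chi: np.ndarray, beta_over_delta: float) -> np.ndarray:
    """D(f) = sin(chi) + (beta/delta)*cos(chi)."""
    return np.sin(chi) + beta_over_delta * np.cos(chi)


def ctf_single(normalized_intensity: np.ndarray, params: RetrievalParams) -> np.ndarray:
    """Single-distance CTF phase retrieval of a flat-corrected image."""
    F = params.fresnel_number
    img, margins = _pad(np.asarray(normalized_intensity, dtype=float) - 1.0,
                        params.pad)
    chi = chi_grid(img.shape, F)
    d = ctf_factor(chi, params.beta_over_delta)
    alpha = _band_alpha(chi, F, params.alpha_low, params.alpha_high)
    denom = 2.0 * d**2 + alpha
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "singular CTF filter: zero regularizer at a CTF zero")
    phi_hat = np.fft.fft2(img) * d / denom
    phi = np.fft.ifft2(phi_hat).real
    return _crop(phi, margins, normalized_intensity.shape)


def _ctf_apply(phi: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Linearized forward model: phi -> simulated contrast I-1 (periodic)."""
    return np.fft.ifft2(2.0 * d * np.fft.fft2(phi)).real


def ctf_multi_cg(normalized_intensities, params: RetrievalParams,
                 return_objectives: bool = False):
    """Multi-distance CTF retrieval with conjugate-gradient refinement.

    `normalized_intensities` is a stack (n_distances, H, W) matching
    ``params.fresnel_numbers``.  The direct multi-distance least-squares
    estimate initializes CG on

        J(phi) = sum_j ||C_j(phi) - (I_j - 1)||^2 + alpha_low*||phi||^2,

    which is quadratic and SPD, so J is non-increasing per iteration (an
    increase triggers rollback and stop).  With one distance the result is
    exactly ``ctf_single``.
    """
    stack = np.asarray(normalized_intensities, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    fns = np.asarray(params.fresnel_numbers, dtype=float)
    if fns.size == 0:
        fns = np.asarray([params.fresnel_number])
    if len(fns) != len(stack):
        raise ValueError("one Fresnel number per distance required")
    if len(fns) == 1:
        phi = ctf_single(stack[0], replace(params, fresnel_numbers=(fns[0],)))
        return (phi, []) if return_objectives else phi
    if np.unique(np.round(fns, 12)).size < fns.size:
        warnings.warn("identical distances: degenerate multi-distance system",
                      RuntimeWarning, stacklevel=2)

    shape = stack.shape[1:]
    imgs, margins = [], (0, 0)
    for im in stack:
        p, margins = _pad(im - 1.0, params.pad)
        imgs.append(p)
    imgs = np.asarray(imgs)
    wshape = imgs.shape[1:]
    chis = [chi_grid(wshape, F) for F in fns]
    ds = [ctf_factor(c, params.beta_over_delta) for c in chis]

    # direct least-squares initialization with the two-band regularizer
    alpha = _band_alpha(chis[0], fns[0], params.alpha_low, params.alpha_high)
    num = sum(d * np.fft.fft2(im) for d, im in zip(ds, imgs))
    den = 2.0 * sum(d**2 for d in ds) + alpha
    phi = np.fft.ifft2(num / den).real

    # CG on the normal equations A phi = b with scalar Tikhonov weight
    a_reg = params.alpha_low

    def apply_a(x):
        out = a_reg * x
        for d in ds:
            out = out + np.fft.ifft2(4.0 * d**2 * np.fft.fft2(x)).real
        return out

    b = np.zeros(wshape)
    for d, im in zip(ds, imgs):
        b += np.fft.ifft2(2.0 * d * np.fft.fft2(im)).real

    def objective(x):
        j = a_reg * np.sum(x**2)
        for d, im in zip(ds, imgs):
            j += np.sum((_ctf_apply(x, d) - im) ** 2)
        return j

    objs = [objective(phi)]
    r = b - apply_a(phi)
    p = r.copy()
    rs = np.sum(r * r)
    for _ in range(params.cg_iterations):
        if rs == 0:
            break
        ap = apply_a(p)
        alpha_cg = rs / np.sum(p * ap)
        cand = phi + alpha_cg * p
        j = objective(cand)
        if j > objs[-1] * (1 + 1e-12):
            break                      # rollback: keep previous phi
        phi = cand
        objs.append(j)
        r = r - alpha_cg * ap
        rs_new = np.sum(r * r)
        p = r + (rs_new / rs) * p
        rs = rs_new

    phi = _crop(phi, margins, shape)
    return (phi, objs) if return_objectives else phi


def min_ctf_power(fresnel_numbers, n: int = 512) -> float:
    """min over radial f of sum_j sin^2(chi_j), up to Nyquist.

    Evaluated from the first CTF maximum (chi = pi/2 of the largest Fresnel
    number) upward: below it no distance has crossed a zero yet and the
    weak sine transfer there is common to any defocus series (the
    absorption coupling covers it), so only the band containing zeros is
    diagnostic.  A value well above zero means the distances leave no
    common CTF zero below the Nyquist frequency.
    """
    f1 = np.sqrt(max(fresnel_numbers) / 2.0)
    f = np.linspace(min(f1, 0.5), 0.5, n)
    total = np.zeros_like(f)
    for F in fresnel_numbers:
        total += np.sin(np.pi * f**2 / F) ** 2
    return float(total.min())


def paganin(normalized_intensity: np.ndarray, params: RetrievalParams,
            generalized: bool = False) -> np.ndarray:
    """Single-material (Paganin) thickness retrieval.

    Returns the projected thickness map in metres.  In pixel-frequency
    units the filter denominator is 1 + (delta/beta)*chi(f); the
    generalized variant replaces chi by its discrete-Laplacian counterpart
    (exact for the sampled grid, converging to chi as the pixel size goes
    to zero at fixed physical frequency).
    """
    if params.beta_over_delta <= 0:
        raise ValueError("single-material retrieval requires beta/delta > 0")
    F = params.fresnel_number
    img, margins = _pad(np.asarray(normalized_intensity, dtype=float), params.pad)
    dob = 1.0 / params.beta_over_delta
    if generalized:
        fy = np.fft.fftfreq(img.shape[0])[:, None]
        fx = np.fft.fftfreq(img.shape[1])[None, :]
        lap = (2.0 - np.cos(2 * np.pi * fy) - np.cos(2 * np.pi * fx)) / (2 * np.pi * F)
        denom = 1.0 + dob * lap
    else:
        denom = 1.0 + dob * chi_grid(img.shape, F)
    filtered = np.fft.ifft2(np.fft.fft2(img) / denom).real
    filtered = np.clip(filtered, 1e-12, None)
    t = -np.log(filtered) / params.mu
    return _crop(t, margins, normalized_intensity.shape)


def paganin_generalized(normalized_intensity: np.ndarray,
                        params: RetrievalParams) -> np.ndarray:
    """Generalized Paganin method (discrete-Laplacian filter symbol)."""
    return paganin(normalized_intensity, params, generalized=True)


def _laplacian_5pt(img: np.ndarray) -> np.ndarray:
    out = -4.0 * img
    out += np.roll(img, 1, axis=0) + np.roll(img, -1, axis=0)
    out += np.roll(img, 1, axis=1) + np.roll(img, -1, axis=1)
    return out


def bac(normalized_intensity: np.ndarray, params: RetrievalParams,
        eps: float = 1e-3, return_report: bool = False):
    """Bronnikov-aided correction for direct-contrast (F ~ 1) images.

    Step 1 estimates a modified-Bronnikov phase
    ``phi = IFT[FT[I-1] / (fx^2+fy^2 + bac_alpha)]``; step 2 divides the
    intensity by ``1 - bac_gamma * laplacian(phi)`` (5-point stencil).
    Non-positive denominators are clipped at `eps` and counted.
    """
    intensity = np.asarray(normalized_intensity, dtype=float)
    img, margins = _pad(intensity - 1.0, params.pad)
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    k2 = fy**2 + fx**2
    phi = np.fft.ifft2(np.fft.fft2(img) / (k2 + params.bac_alpha)).real
    lap = _laplacian_5pt(phi)
    lap = _crop(lap, margins, intensity.shape)
    denom = 1.0 - params.bac_gamma * lap
    n_clipped = int((denom <= eps).sum())
    denom = np.clip(denom, eps, None)
    out = intensity / denom
    if return_report:
        return out, {"n_clipped": n_clipped}
    return out


def tune_bac_gamma(normalized_intensity: np.ndarray, params: RetrievalParams,
                   gammas=None) -> float:
    """Pick bac_gamma minimizing the total variation of the corrected image.

    Edge overshoot dominates the TV of a direct-contrast image of a
    piecewise-smooth object, so the TV minimum is a serviceable deterministic
    surrogate for overshoot suppression.
    """
    if gammas is None:
        gammas = np.linspace(0.0, 2.0, 41)
    best, best_tv = params.bac_gamma, np.inf
    for g in gammas:
        out = bac(normalized_intensity, replace(params, bac_gamma=float(g)))
        tv = np.abs(np.diff(out, axis=0)).sum() + np.abs(np.diff(out, axis=1)).sum()
        if tv < best_tv:
            best, best_tv = float(g), tv
    return best


# method each instrument preset used
_PRESET_METHODS = {
    "SR-CB3": "ctf_multi_cg",
    "SR-CB1": "ctf_single",
    "SR-PB": "ctf_single",
    "SR-CB2": "ctf_single",
    "SR-PB2": "gpm",
    "muCT1-overview": "bac",
    "muCT1-temporal-bone": "bac",
    "muCT2-overview": "none",
    "muCT2-ROI": "none",
    "muCT2-nanofocus": "none",
}

_PRESET_BETA_OVER_DELTA = {
    "SR-CB3": 1.0 / 27.0,
    "SR-CB1": 1.0 / 15.0,
    "SR-PB": 1.0 / 15.0,
    "SR-CB2": 1.0 / 45.0,
}


def select_method(preset_name: str, beta_over_delta: float | None = None) -> RetrievalParams:
    """Retrieval parameters matching a named instrument preset."""
    preset = get_preset(preset_name)   # raises with the preset list
    try:
        method = _PRESET_METHODS[preset_name]
    except KeyError:
        raise KeyError(
            f"no retrieval method recorded for preset {preset_name!r}; "
            f"known: {sorted(_PRESET_METHODS)}") from None
    if beta_over_delta is None:
        beta_over_delta = _PRESET_BETA_OVER_DELTA.get(preset_name, 1.0 / 27.0)
    fns: tuple[float, ...] = ()
    if preset.fresnel is not None:
        if method == "ctf_multi_cg" and preset.n_distances > 1:
            # nominal defocus series: moving the sample in a cone beam
            # changes M and z_eff, spreading the per-plane Fresnel numbers
            # so the CTF zeros of the planes do not coincide
            spread = np.geomspace(1.0, 2.6, preset.n_distances)
            fns = tuple(float(preset.fresnel * s) for s in spread)
        else:
            fns = (preset.fresnel,)
    elif preset.z01_mm is not None:
        fns = (preset.geometry().fresnel_number,)
    return RetrievalParams(method=method, beta_over_delta=beta_over_delta,
                           fresnel_numbers=fns)
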