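"""FT-IR spectrum handling: I/O, averaging, region segmentation, band fitting.

Mid-infrared absorbance spectra of blood plasma (KBr-disc transmission,
350-4000 cm^-1 at 4 cm^-1 resolution) show five characteristic regions: a
broad low-wavenumber peak (R1, 350-1000), a quiet fingerprint stretch (R2,
1000-1500), the amide I/II envelope (R3, 1500-1800), a weak broad feature (R4,
1850-2500) and the major O-H/N-H/C-H stretching massif (R5, 2700-3800).
Overlapping absorptions inside a region are resolved by deconvolution: a
bounded nonlinear least-squares fit of a sum of Gaussian bands

    A(nu) = sum_b  A_b exp(-(nu - c_b)^2 / (2 sigma_b^2)).

The Gaussian profile keeps synthetic benchmarks exact; a pseudo-Voigt profile
(Gaussian/Lorentzian mix) is available for experimental line shapes.

File formats: two-column CSV (wavenumber, absorbance) and the JCAMP-DX
``XYDATA (X++(Y..Y))`` / ``XYPOINTS`` dialects, parsed by a small reader in
this module.
"""

from __future__ import annotations

import csv as _csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Spectrum",
    "SpectralRegion",
    "Band",
    "BandFit",
    "default_axis",
    "default_regions",
    "read_spectrum",
    "write_spectrum_csv",
    "average_spectra",
    "resample_to_axis",
    "segment_regions",
    "gaussian_bands",
    "deconvolve_region",
]


def default_axis() -> np.ndarray:
    """The acquisition axis: 350 cm^-1 upward in 4 cm^-1 steps, 913 points."""
    return 350.0 + 4.0 * np.arange(913)


@dataclass
class Spectrum:
    wavenumber: np.ndarray
    absorbance: np.ndarray
    subject_id: str = ""
    plasma_kind: Literal["native", "deproteinized"] = "native"

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumber.shape != self.absorbance.shape or self.wavenumber.ndim != 1:
            raise ValueError("wavenumber and absorbance must be equal-length vectors")
        if len(self.wavenumber) > 1 and np.any(np.diff(self.wavenumber) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if np.any(~np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    def __len__(self) -> int:
        return len(self.wavenumber)


@dataclass(frozen=True)
class SpectralRegion:
    label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        # lo == hi is tolerated (selects nothing); lo > hi is a mistake
        if self.lo > self.hi:
            raise ValueError(f"region {self.label}: lo must be <= hi")


def default_regions() -> list[SpectralRegion]:
    """The five canonical plasma regions (note the 1800-1850 gap and >3800 tail)."""
    return [
        SpectralRegion("R1", 350.0, 1000.0),
        SpectralRegion("R2", 1000.0, 1500.0),
        SpectralRegion("R3", 1500.0, 1800.0),
        SpectralRegion("R4", 1850.0, 2500.0),
        SpectralRegion("R5", 2700.0, 3800.0),
    ]


@dataclass
class Band:
    """One Gaussian component: apex ``center`` (cm^-1), width ``sigma`` (cm^-1,
    standard deviation), apex ``amplitude`` (absorbance).  ``assignment`` is a
    free-text biochemical annotation and is never interpreted."""

    center: float
    sigma: float
    amplitude: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass
class BandFit:
    window: tuple[float, float]
    bands: list[Band]
    residual_rms: float
    r_squared: float
    converged: bool = True
    message: str = ""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_csv(text: str) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for row in _csv.reader(io.StringIO(text)):
        if not row or row[0].strip().startswith("#"):
            continue
        try:
            x, y = float(row[0]), float(row[1])
        except (ValueError, IndexError):
            if not xs:  # tolerate a single header line
                continue
            raise ValueError(f"unparseable CSV row: {row!r}")
        xs.append(x)
        ys.append(y)
    if not xs:
        raise ValueError("no data rows found")
    return np.array(xs), np.array(ys)


def _parse_jcamp(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: XYDATA=(X++(Y..Y)) and XYPOINTS=(XY..XY)."""
    labels: dict[str, str] = {}
    data_mode = None
    rows: list[str] = []
    for line in text.splitlines():
        line = line.split("$$")[0].rstrip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = re.sub(r"[\s_-]", "", key).upper()
            val = val.strip()
            if key == "XYDATA":
                data_mode = "xydata"
            elif key == "XYPOINTS":
                data_mode = "xypoints"
            elif key == "END":
                break
            else:
                labels[key] = val
                data_mode = None
        elif data_mode and line.strip():
            rows.append(line.strip())
    if data_mode is None and not rows:
        raise ValueError("no XYDATA/XYPOINTS block found")
    xfac = float(labels.get("XFACTOR", 1.0))
    yfac = float(labels.get("YFACTOR", 1.0))
    xs, ys = [], []
    if data_mode == "xypoints":
        for row in rows:
            for pair in re.split(r"[;]", row):
                nums = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", pair)
                if len(nums) >= 2:
                    xs.append(float(nums[0]) * xfac)
                    ys.append(float(nums[1]) * yfac)
    else:  # (X++(Y..Y)): first number per line is X, the rest are Y at DELTAX steps
        if "DELTAX" in labels:
            deltax = float(labels["DELTAX"])
        else:
            first = float(labels["FIRSTX"])
            last = float(labels["LASTX"])
            npt = int(float(labels["NPOINTS"]))
            deltax = (last - first) / (npt - 1)
        for row in rows:
            nums = [float(t) for t in re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", row)]
            if not nums:
                continue
            x0 = nums[0] * xfac
            for j, y in enumerate(nums[1:]):
                xs.append(x0 + j * deltax * xfac)
                ys.append(y * yfac)
    if not xs:
        raise ValueError("JCAMP-DX block contained no points")
    return np.array(xs), np.array(ys)


def read_spectrum(
    path: str | Path,
    dialect: Literal["csv", "jcamp", "auto"] = "auto",
    subject_id: str = "",
    plasma_kind: Literal["native", "deproteinized"] = "native",
) -> Spectrum:
    """Read one spectrum; a descending stored axis is reversed to ascending."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    if dialect == "auto":
        dialect = "jcamp" if text.lstrip().startswith("##") else "csv"
    x, y = _parse_jcamp(text) if dialect == "jcamp" else _parse_csv(text)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{path}: wavenumber axis not strictly monotonic")
    return Spectrum(x, y, subject_id=subject_id or path.stem, plasma_kind=plasma_kind)


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["wavenumber_cm1", "absorbance"])
        for x, y in zip(spec.wavenumber, spec.absorbance):
            w.writerow([f"{x:.6g}", f"{y:.10g}"])


# ---------------------------------------------------------------------------
# averaging / segmentation
# ---------------------------------------------------------------------------

def resample_to_axis(spec: Spectrum, axis: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``axis`` (no extrapolation beyond the ends)."""
    axis = np.asarray(axis, dtype=float)
    if axis[0] < spec.wavenumber[0] or axis[-1] > spec.wavenumber[-1]:
        raise ValueError("target axis extends beyond the measured range")
    y = np.interp(axis, spec.wavenumber, spec.absorbance)
    return replace(spec, wavenumber=axis, absorbance=y)


def average_spectra(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of spectra sharing an axis (the healthy-reference step)."""
    if not spectra:
        raise ValueError("cannot average an empty list")
    kinds = {s.plasma_kind for s in spectra}
    if len(kinds) > 1:
        raise ValueError(f"mixed plasma kinds {sorted(kinds)}: average them separately")
    axis = spectra[0].wavenumber
    for s in spectra[1:]:
        if len(s) != len(axis) or not np.allclose(s.wavenumber, axis):
            raise ValueError(
                f"spectrum {s.subject_id!r} is on a different axis; "
                "resample_to_axis first"
            )
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return Spectrum(axis.copy(), mean, subject_id="average", plasma_kind=spectra[0].plasma_kind)


def segment_regions(
    spec: Spectrum, regions: Sequence[SpectralRegion] | None = None
) -> list[tuple[SpectralRegion, Spectrum]]:
    """Half-open [lo, hi) slices; points falling in no region are dropped."""
    if regions is None:
        regions = default_regions()
    srt = sorted(regions, key=lambda r: r.lo)
    for a, b in zip(srt[:-1], srt[1:]):
        if b.lo < a.hi:
            raise ValueError(f"regions {a.label} and {b.label} overlap")
    out = []
    for r in regions:
        m = (spec.wavenumber >= r.lo) & (spec.wavenumber < r.hi)
        out.append(
            (r, replace(spec, wavenumber=spec.wavenumber[m], absorbance=spec.absorbance[m]))
        )
    return out


# ---------------------------------------------------------------------------
# band deconvolution
# ---------------------------------------------------------------------------

def gaussian_bands(
    axis: np.ndarray, bands: Sequence[Band], eta: float = 0.0
) -> np.ndarray:
    """Evaluate a sum of bands on ``axis``.

    ``eta`` is the Lorentzian fraction of a pseudo-Voigt profile; 0 (default)
    is pure Gaussian.
    """
    axis = np.asarray(axis, dtype=float)
    y = np.zeros_like(axis)
    for b in bands:
        z = (axis - b.center) / b.sigma
        g = np.exp(-0.5 * z * z)
        if eta > 0:
            lor = 1.0 / (1.0 + z * z)
            y += b.amplitude * ((1 - eta) * g + eta * lor)
        else:
            y += b.amplitude * g
    return y


def _band_candidates(x: np.ndarray, y: np.ndarray) -> list[float]:
    """Candidate band centers, strongest first.

    A Gaussian band leaves a sharp negative second-derivative lobe at its
    center even when it only shows as a shoulder of a larger neighbour, so
    candidates are the local minima of the Savitzky-Golay-smoothed second
    derivative (window 13 points, cubic), merged within 2 grid steps.
    """
    from scipy.signal import savgol_coeffs, savgol_filter

    if len(y) < 13:
        order = np.argsort(y)[::-1]
        return [float(x[i]) for i in order[: max(1, len(y) // 3)]]
    dx = float(np.median(np.diff(x)))
    win = 13
    d2 = savgol_filter(y, win, 3, deriv=2, delta=dx)
    # noise floor: sd of what the smoother removed, propagated through the
    # second-derivative filter; candidates below 4 sigma are noise wiggles
    noise_sd = float(np.std(y - savgol_filter(y, win, 3)))
    d2_noise_sd = noise_sd * float(
        np.linalg.norm(savgol_coeffs(win, 3, deriv=2, delta=dx))
    )
    strength: dict[int, float] = {}
    for i in range(1, len(d2) - 1):
        if d2[i] < 0 and d2[i] <= d2[i - 1] and d2[i] < d2[i + 1]:
            if -d2[i] > 4.0 * d2_noise_sd:
                strength[i] = -d2[i]
    idx = sorted(strength, key=lambda i: -strength[i])
    kept: list[int] = []
    for i in idx:
        if all(abs(i - j) > 5 for j in kept):
            kept.append(i)
    return [float(x[i]) for i in kept]


def deconvolve_region(
    spec: Spectrum,
    window: tuple[float, float],
    n_bands: int,
    init: Sequence[Band] | Literal["auto"] = "auto",
    eta: float = 0.0,
    baseline: bool = False,
    max_restarts: int = 3,
) -> BandFit:
    """Fit ``n_bands`` Gaussian (or pseudo-Voigt) bands inside ``window``.

    Bounds: amplitude >= 0, center inside the window, sigma in
    [2 cm^-1, window width].  With ``init="auto"`` the fit is grown greedily:
    starting centers come from the second-derivative candidate list
    (:func:`_band_candidates`), and while fewer than ``n_bands`` bands are
    placed, a new band is seeded at the largest positive fit residual and the
    whole model is refit.  This resolves shoulders that plain local-maximum
    seeding misses.  An explicit ``init`` list of :class:`Band` bypasses the
    search.  A linear baseline (two extra parameters) can be co-fitted.

    Non-convergence is flagged on the returned :class:`BandFit` rather than
    raised, so a batch over many subjects survives a pathological window.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    lo, hi = window
    if not (spec.wavenumber[0] <= lo < hi <= spec.wavenumber[-1] + 1e-9):
        raise ValueError("window must lie inside the spectrum axis")
    m = (spec.wavenumber >= lo) & (spec.wavenumber <= hi)
    x, y = spec.wavenumber[m], spec.absorbance[m]
    if len(x) < 3 * n_bands + (2 if baseline else 0):
        raise ValueError("window has too few points for the requested band count")

    width = hi - lo
    sig_lo, sig_hi = 2.0, float(width)
    amp_hi = max(2.0 * float(y.max() - min(float(y.min()), 0.0)), 1e-12)
    nb = 2 if baseline else 0

    def fit_once(centers, sigmas, amps, k):
        """Bounded least-squares fit of k bands (+ optional baseline)."""

        def unpack(p):
            return p[:k], p[k : 2 * k], p[2 * k : 3 * k], p[3 * k :]

        def model(p):
            c, s, a, base = unpack(p)
            z = (x[None, :] - c[:, None]) / s[:, None]
            g = np.exp(-0.5 * z * z)
            if eta > 0:
                g = (1 - eta) * g + eta / (1.0 + z * z)
            out = (a[:, None] * g).sum(axis=0)
            if len(base):
                out = out + base[0] + base[1] * (x - lo)
            return out

        lower = np.concatenate([[lo] * k, [sig_lo] * k, [0.0] * k, [-np.inf] * nb])
        upper = np.concatenate([[hi] * k, [sig_hi] * k, [amp_hi] * k, [np.inf] * nb])
        p0 = np.clip(
            np.concatenate([centers, sigmas, amps, [0.0] * nb]),
            lower + 1e-9,
            np.where(np.isfinite(upper), upper - 1e-9, upper),
        )
        res = least_squares(
            lambda p: model(p) - y,
            p0,
            bounds=(lower, upper),
            method="trf",
            max_nfev=300 * (3 * k + nb),
        )
        return res, model, unpack

    sigma_default = max(2 * sig_lo, min(40.0, width / (2 * n_bands)))

    def smooth_resid(r):
        if len(r) >= 5:
            return np.convolve(r, np.ones(5) / 5, mode="same")
        return r

    if init == "auto":
        cand = _band_candidates(x, y)[:n_bands]
        if not cand:
            cand = [float(x[int(np.argmax(y))])]
        centers = sorted(cand)
        sigmas = [sigma_default] * len(centers)
        amps = [max(float(np.interp(c, x, y)), 1e-6) for c in centers]
        res, model, unpack = fit_once(centers, sigmas, amps, len(centers))
        # greedy growth: seed each additional band at the worst residual
        while len(centers) < n_bands:
            resid = smooth_resid(y - model(res.x))
            i_new = int(np.argmax(resid))
            c, s, a, base = unpack(res.x)
            centers = list(c) + [float(x[i_new])]
            sigmas = list(s) + [sigma_default]
            amps = list(a) + [max(float(resid[i_new]), 1e-6)]
            res, model, unpack = fit_once(centers, sigmas, amps, len(centers))
            centers = list(unpack(res.x)[0])
        best = res

        # split-merge refinement: a pair of bands collapsed onto one true
        # component wastes a degree of freedom that some shoulder needs, so
        # repeatedly move the weaker of the closest redundant pair to the
        # worst residual and keep the refit only if it lowers the cost
        dx = float(np.median(np.diff(x)))
        for _ in range(n_bands):
            c, s, a, base = unpack(best.x)
            order = np.argsort(c)
            c, s, a = c[order], s[order], a[order]
            pair = None
            for i in range(n_bands - 1):
                gap = c[i + 1] - c[i]
                if gap < max(3 * dx, 0.6 * min(s[i], s[i + 1])):
                    pair = i if a[i] < a[i + 1] else i + 1
                    break
            if pair is None:
                tiny = np.where(a < 1e-3 * max(float(y.max()), 1e-12))[0]
                pair = int(tiny[0]) if len(tiny) else None
            if pair is None:
                break
            resid = smooth_resid(y - model(best.x))
            i_new = int(np.argmax(resid))
            c2, s2, a2 = list(c), list(s), list(a)
            c2[pair] = float(x[i_new])
            s2[pair] = sigma_default
            a2[pair] = max(float(resid[i_new]), 1e-6)
            trial, t_model, t_unpack = fit_once(c2, s2, a2, n_bands)
            if trial.cost < best.cost * (1 - 1e-9):
                best, model, unpack = trial, t_model, t_unpack
            else:
                break

        # rescue sweeps: a misplaced band is detectable because the residual
        # RMS stays above the noise floor estimated from the smoother; try
        # relocating bands (weakest first) to the worst residual until the
        # fit reaches the floor or no move helps
        if len(y) >= 13:
            from scipy.signal import savgol_filter

            noise_est = float(np.std(y - savgol_filter(y, 13, 3)))
        else:
            noise_est = 0.0
        target_cost = 0.5 * len(y) * (1.1 * noise_est) ** 2
        for _sweep in range(3):
            if best.cost <= target_cost:
                break
            c, s, a, base = unpack(best.x)
            improved = False
            for j in np.argsort(a):
                resid = smooth_resid(y - model(best.x))
                i_new = int(np.argmax(resid))
                c2, s2, a2 = list(c), list(s), list(a)
                c2[j] = float(x[i_new])
                s2[j] = sigma_default
                a2[j] = max(float(resid[i_new]), 1e-6)
                trial, t_model, t_unpack = fit_once(c2, s2, a2, n_bands)
                if trial.cost < best.cost * (1 - 1e-6):
                    best, model, unpack = trial, t_model, t_unpack
                    improved = True
                    break
            if not improved:
                break
    else:
        if len(init) != n_bands:
            raise ValueError("init must supply exactly n_bands bands")
        centers = [b.center for b in init]
        sigmas = [b.sigma for b in init]
        amps = [b.amplitude for b in init]
        best, model, unpack = fit_once(centers, sigmas, amps, n_bands)

    # deterministic jittered restarts if the optimizer is unhappy
    rng = np.random.default_rng(0)
    attempt = 0
    while not best.success and attempt < max_restarts:
        attempt += 1
        c, s, a, base = unpack(best.x)
        c = np.clip(
            c + rng.uniform(-width / (2 * n_bands), width / (2 * n_bands), n_bands),
            lo,
            hi,
        )
        res, model, unpack = fit_once(list(c), list(s), list(a), n_bands)
        if res.cost < best.cost or res.success:
            best = res

    c, s, a, base = unpack(best.x)
    order = np.argsort(c)
    bands = [Band(float(c[i]), float(s[i]), float(a[i])) for i in order]
    resid = y - model(best.x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return BandFit(
        window=(float(lo), float(hi)),
        bands=bands,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        r_squared=r2,
        converged=bool(best.success),
        message=str(best.message),
    )
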