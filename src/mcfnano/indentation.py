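"""Hertzian conical-contact analysis of AFM nanoindentation records.

A rigid cone of half-angle alpha pressed a depth delta into an elastic
half-space of modulus E and Poisson ratio nu carries the force

    F = (2/pi) * E / (1 - nu^2) * tan(alpha) * delta^2

With E in GPa and delta in nm this evaluates directly in nN, since
GPa * nm^2 = 1e9 Pa * 1e-18 m^2 = 1e-9 N = 1 nN.  The fitting routine
jointly estimates the pre-contact baseline (linear drift), the contact
point z0 and E: for every candidate contact sample the baseline is the
least-squares line over the pre-contact samples and E is the closed-form
least-squares amplitude of the delta^2 regressor over the post-contact
samples; the candidate minimizing the total squared residual wins and z0
is then refined continuously between neighbouring samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ProbeParams",
    "ForceCurve",
    "HertzFit",
    "FitConfig",
    "hertz_force",
    "hertz_prefactor",
    "force_indentation",
    "fit_hertz_cone",
    "batch_fit",
]


@dataclass(frozen=True)
class ProbeParams:
    """Indenter geometry: cone half-angle (deg) and sample Poisson ratio."""

    half_angle_deg: float = 10.0
    poisson: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.half_angle_deg < 90):
            raise ValueError(
                f"half_angle_deg must be in (0, 90), got {self.half_angle_deg}"
            )
        if not (0 <= self.poisson < 0.5):
            raise ValueError(
                f"poisson must be in [0, 0.5), got {self.poisson}"
            )


def hertz_prefactor(probe: ProbeParams) -> float:
    """(2/pi) tan(alpha) / (1 - nu^2): F[nN] = prefactor * E[GPa] * d[nm]^2."""
    alpha = math.radians(probe.half_angle_deg)
    return (2.0 / math.pi) * math.tan(alpha) / (1.0 - probe.poisson**2)


def hertz_force(E_gpa: float, delta_nm, probe: ProbeParams):
    """Conical Hertz force (nN) at indentation depth ``delta_nm`` (nm).

    ``delta_nm`` may be a scalar or array; negative depths are rejected.
    """
    if E_gpa <= 0:
        raise ValueError(f"E_gpa must be > 0, got {E_gpa}")
    delta = np.asarray(delta_nm, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be >= 0")
    out = hertz_prefactor(probe) * E_gpa * delta**2
    return float(out) if np.isscalar(delta_nm) else out


@dataclass
class ForceCurve:
    """One indentation record: piezo displacement (nm) vs force (nN)."""

    displacement_nm: np.ndarray
    force_nN: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement_nm = np.asarray(self.displacement_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.displacement_nm.shape != self.force_nN.shape:
            raise ValueError("displacement and force must have equal length")
        if self.displacement_nm.size < 100:
            raise ValueError(
                f"curve must have >= 100 samples, got "
                f"{self.displacement_nm.size}"
            )
        if np.any(np.diff(self.displacement_nm) < 0):
            raise ValueError(
                "displacement must be monotone on the loading segment"
            )

    @property
    def curve_id(self) -> str:
        return str(self.metadata.get("curve_id", ""))


def force_indentation(
    curve: ForceCurve,
    z0_nm: float,
    stiffness_correction: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert displacement to indentation depth given a contact point.

    delta = (z - z0) - F / k_lever when a cantilever stiffness (nN/nm) is
    supplied, else delta = z - z0 (rigid-lever assumption, appropriate for
    the synthetic curves).  Samples with delta < 0 are dropped.
    """
    z = curve.displacement_nm
    if not (z[0] <= z0_nm <= z[-1]):
        raise ValueError(
            f"z0={z0_nm} nm lies outside the displacement span "
            f"[{z[0]}, {z[-1]}] nm"
        )
    delta = z - z0_nm
    if stiffness_correction is not None:
        if stiffness_correction <= 0:
            raise ValueError("stiffness_correction must be > 0 nN/nm")
        delta = delta - curve.force_nN / stiffness_correction
        keep = delta >= 0
        if np.any(np.diff(delta[keep]) < 0):
            raise ValueError(
                "stiffness correction yields a non-monotone indentation "
                "axis; check the cantilever stiffness value"
            )
    keep = delta >= 0
    return delta[keep], curve.force_nN[keep]


@dataclass
class HertzFit:
    """Result of a conical Hertz fit."""

    E_gpa: float
    z0_nm: float
    residual_nN: float
    fit_range: tuple[int, int]
    converged: bool
    baseline: tuple[float, float] = (0.0, 0.0)
    curve_id: str = ""


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the contact-point search and fit window.

    ``upper_fraction`` < 1 restricts the fitted post-contact window to the
    lower part of the force range; ``contact_detector`` may be ``"scan"``
    (joint residual scan, default) or ``"threshold"`` (first sustained
    baseline departure).
    """

    min_precontact_samples: int = 20
    min_postcontact_samples: int = 50
    upper_fraction: float = 1.0
    refine: bool = True
    contact_detector: str = "scan"
    threshold_factor: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.upper_fraction <= 1):
            raise ValueError("upper_fraction must be in (0, 1]")
        if self.contact_detector not in ("scan", "threshold"):
            raise ValueError("contact_detector must be 'scan' or 'threshold'")


def _candidate_scan(
    z: np.ndarray, f: np.ndarray, i_lo: int, i_hi: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Total SSE of the piecewise (line | line + c*(z-z0)^2) model for every
    candidate contact index in ``[i_lo, i_hi)``, in O(n) via prefix/suffix
    sums.  Returns (indices, sse, c, (a, b))."""
    n = z.size
    # prefix sums over j < i
    def pre(v):
        out = np.zeros(n + 1)
        np.cumsum(v, out=out[1:])
        return out

    P1, P2 = pre(z), pre(z * z)
    PF, PFz, PFF = pre(f), pre(f * z), pre(f * f)

    # suffix sums over j >= i
    def suf(v):
        out = np.zeros(n + 1)
        out[:-1] = np.cumsum(v[::-1])[::-1]
        return out

    T0 = suf(np.ones(n))
    T1, T2 = suf(z), suf(z * z)
    T3, T4 = suf(z**3), suf(z**4)
    U0, U1, U2 = suf(f), suf(f * z), suf(f * z * z)
    V = suf(f * f)

    idx = np.arange(i_lo, i_hi)
    m = idx.astype(float)  # number of pre-contact samples
    denom = m * P2[idx] - P1[idx] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (m * PFz[idx] - P1[idx] * PF[idx]) / denom
    b = np.where(denom > 0, b, 0.0)
    a = (PF[idx] - b * P1[idx]) / np.maximum(m, 1.0)
    sse_pre = PFF[idx] - a * PF[idx] - b * PFz[idx]

    w = z[idx]
    Sd2 = T2[idx] - 2 * w * T1[idx] + w**2 * T0[idx]
    Sd4 = (
        T4[idx] - 4 * w * T3[idx] + 6 * w**2 * T2[idx]
        - 4 * w**3 * T1[idx] + w**4 * T0[idx]
    )
    SFd2 = U2[idx] - 2 * w * U1[idx] + w**2 * U0[idx]
    Szd2 = T3[idx] - 2 * w * T2[idx] + w**2 * T1[idx]
    Nnum = SFd2 - a * Sd2 - b * Szd2
    Sr2 = (
        V[idx] - 2 * a * U0[idx] - 2 * b * U1[idx]
        + a**2 * T0[idx] + 2 * a * b * T1[idx] + b**2 * T2[idx]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        c = Nnum / Sd4
        sse_post = Sr2 - Nnum**2 / Sd4
    bad = (Sd4 <= 0) | (Nnum <= 0)
    sse = sse_pre + np.where(bad, Sr2, sse_post)
    c = np.where(bad, np.nan, c)
    return idx, sse, c, (a, b)


def _sse_at_z0(z, f, z0, a, b, min_post):
    """Direct residual evaluation for a continuous contact point."""
    r = f - a - b * z
    delta = z - z0
    post = delta > 0
    if post.sum() < min_post:
        return np.inf, np.nan
    d2 = delta[post] ** 2
    num = float(r[post] @ d2)
    den = float(d2 @ d2)
    if den <= 0 or num <= 0:
        return np.inf, np.nan
    c = num / den
    res_post = r[post] - c * d2
    sse = float(r[~post] @ r[~post]) + float(res_post @ res_post)
    return sse, c


def fit_hertz_cone(
    curve: ForceCurve,
    probe: ProbeParams,
    config: FitConfig = FitConfig(),
) -> HertzFit:
    """Fit the conical Hertz model with joint contact-point detection.

    Returns a :class:`HertzFit`; ``converged`` is False when no candidate
    contact point leaves at least ``min_postcontact_samples`` samples with
    a positive elastic amplitude (e.g. a pure-baseline record).
    """
    z = curve.displacement_nm
    f = curve.force_nN
    n = z.size
    if config.upper_fraction < 1.0:
        f_max = f.max()
        cut = np.searchsorted(
            f, config.upper_fraction * f_max, side="right"
        )
        cut = max(cut, config.min_precontact_samples
                  + config.min_postcontact_samples)
        z, f, n = z[:cut], f[:cut], min(cut, n)

    i_lo = config.min_precontact_samples
    i_hi = n - config.min_postcontact_samples
    fail = HertzFit(
        E_gpa=float("nan"), z0_nm=float("nan"), residual_nN=float("nan"),
        fit_range=(0, 0), converged=False, curve_id=curve.curve_id,
    )
    if i_hi <= i_lo:
        return fail

    if config.contact_detector == "threshold":
        base = np.polyfit(z[:i_lo], f[:i_lo], 1)
        resid = f - np.polyval(base, z)
        noise = float(np.std(resid[:i_lo])) or 1e-12
        above = resid > config.threshold_factor * noise
        run = np.convolve(above.astype(int), np.ones(5, int), "same")
        hits = np.nonzero(run >= 5)[0]
        if hits.size == 0 or hits[0] >= i_hi:
            return fail
        # the crossing lags true contact, so it only bounds z0 from above
        start = int(np.clip(hits[0], i_lo, i_hi - 1))
        hi2 = min(i_hi, start + max(5, n // 100))
        idx, sse, c, (a_all, b_all) = _candidate_scan(z, f, i_lo, hi2)
    else:
        idx, sse, c, (a_all, b_all) = _candidate_scan(z, f, i_lo, i_hi)

    valid = np.isfinite(sse) & np.isfinite(c) & (c > 0)
    if not valid.any():
        return fail
    k = int(np.flatnonzero(valid)[np.argmin(sse[valid])])
    i_best = int(idx[k])
    a, b = float(a_all[k]), float(b_all[k])
    z0 = float(z[i_best])
    c_best = float(c[k])
    sse_best = float(sse[k])

    if config.refine:
        lo = z[max(i_best - 1, 0)]
        hi = z[min(i_best + 1, n - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda w: _sse_at_z0(
                    z, f, w, a, b, config.min_postcontact_samples
                )[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-9 * (hi - lo) + 1e-12},
            )
            sse_r, c_r = _sse_at_z0(
                z, f, float(res.x), a, b, config.min_postcontact_samples
            )
            if np.isfinite(sse_r) and sse_r <= sse_best:
                z0, c_best, sse_best = float(res.x), c_r, sse_r

    E = c_best / hertz_prefactor(probe)
    if not np.isfinite(E) or E <= 0:
        return fail
    # the elastic signal must stand clear of the residual noise floor,
    # otherwise a pure-baseline record would "fit" a negligible modulus
    noise_rms = math.sqrt(max(sse_best, 0.0) / n)
    signal = c_best * (z[-1] - z0) ** 2
    if noise_rms > 0 and signal < 5.0 * noise_rms:
        return fail
    n_post = int(np.sum(z > z0))
    residual = math.sqrt(max(sse_best, 0.0) / n)
    return HertzFit(
        E_gpa=float(E),
        z0_nm=z0,
        residual_nN=residual,
        fit_range=(n - n_post, n),
        converged=True,
        baseline=(a, b),
        curve_id=curve.curve_id,
    )


def batch_fit(
    curves: list[ForceCurve],
    probe: ProbeParams,
    config: FitConfig = FitConfig(),
    groups: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit many curves; summarize converged moduli as mean +/- SD.

    ``groups`` optionally labels each curve (``"<group>-<load>"`` or any
    grouping key); summaries are per label, else one overall row.
    """
    if not curves:
        raise ValueError("batch_fit requires at least one curve")
    rows = []
    for j, curve in enumerate(curves):
        fit = fit_hertz_cone(curve, probe, config)
        rows.append(
            {
                "curve_id": fit.curve_id or f"curve{j}",
                "group": groups[j] if groups is not None else "all",
                "E_GPa": fit.E_gpa,
                "z0_nm": fit.z0_nm,
                "residual_nN": fit.residual_nN,
                "converged": fit.converged,
            }
        )
    fits = pd.DataFrame(rows)
    ok = fits[fits["converged"]]
    if ok.empty:
        warnings.warn("no curve converged; summary is empty", stacklevel=2)
        summary = pd.DataFrame(
            columns=["group", "mean_E_GPa", "sd_E_GPa", "n"]
        )
        return fits, summary
    summary = (
        ok.groupby("group")["E_GPa"]
        .agg(mean_E_GPa="mean", sd_E_GPa=lambda v: v.std(ddof=1) if len(v) > 1
             else 0.0, n="count")
        .reset_index()
    )
    return fits, summary
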