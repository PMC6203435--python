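"""Visual-pigment photochemistry fits: λmax templates and retinal-release kinetics.

Two in-vitro readouts are modeled:

* dark-state absorbance spectra are fit to the standard A1 (rhodopsin)
  visual-pigment template — the Govardovskii-type α-band expression with
  its β-band Gaussian — by least squares over λmax and an overall scale;
* retinal-release fluorescence traces (tryptophan fluorescence rising as
  all-trans retinal leaves the pocket after photobleaching) are fit to the
  first-order exponential y = y0 + a·(1 − e^(−b·t)), with half-life
  t½ = ln2/b and an r² > 0.95 quality gate.

Replicate groups are compared with Welch's two-tailed t test (unequal
variances), with the usual */**/*** significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

LN2 = float(np.log(2.0))

# A1 template constants (α-band exponential sum + β-band Gaussian)
_A1 = {
    "A": 69.7, "B": 28.0, "C": -14.9, "D": 0.674,
    "b": 0.922, "c": 1.104,
    "Abeta": 0.26,
}


def a1_template(wavelengths, lambda_max: float, beta_band: bool = True):
    """Relative absorbance of an A1 pigment with the given λmax (nm)."""
    lam = np.asarray(wavelengths, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_A1["A"] * (a - x))
        + np.exp(_A1["B"] * (_A1["b"] - x))
        + np.exp(_A1["C"] * (_A1["c"] - x))
        + _A1["D"]
    )
    if not beta_band:
        return alpha
    lmb = 189.0 + 0.315 * lambda_max
    bb = -40.5 + 0.195 * lambda_max
    beta = _A1["Abeta"] * np.exp(-(((lam - lmb) / bb) ** 2))
    return alpha + beta


@dataclass
class SpectrumFit:
    lambda_max: float
    scale: float
    rss: float
    n_points: int


@dataclass
class ReleaseFit:
    y0: float
    a: float
    b: float  # per min
    r2: float

    @property
    def t_half(self) -> float:
        return LN2 / self.b

    @property
    def passes_quality_gate(self) -> bool:
        return self.r2 > 0.95


def _scale_and_rss(template, y):
    denom = float(template @ template)
    scale = float(template @ y) / denom if denom > 0 else 0.0
    resid = y - scale * template
    return scale, float(resid @ resid)


def fit_a1_template(
    wavelengths,
    absorbance,
    window=(450.0, 550.0),
    grid_step: float = 0.1,
    beta_band: bool = True,
) -> SpectrumFit:
    """λmax by least squares against the A1 template.

    Grid search over the window at ``grid_step`` nm, then bounded local
    refinement.  The fit is invariant to overall absorbance scaling (scale
    is profiled out analytically).
    """
    lam = np.asarray(wavelengths, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if lam.size < 10:
        raise ValueError("need at least 10 spectral points")
    if not (np.isfinite(lam).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in spectrum")
    if lam.min() > window[0] or lam.max() < window[1]:
        raise ValueError("spectrum does not cover the search window")

    grid = np.arange(window[0], window[1] + grid_step / 2, grid_step)
    rss = np.empty(grid.size)
    for k, lm in enumerate(grid):
        _, rss[k] = _scale_and_rss(a1_template(lam, lm, beta_band), y)
    k0 = int(np.argmin(rss))

    def obj(lm):
        return _scale_and_rss(a1_template(lam, lm, beta_band), y)[1]

    lo = grid[max(k0 - 1, 0)]
    hi = grid[min(k0 + 1, grid.size - 1)]
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-4})
    lm_best = float(res.x) if res.fun <= rss[k0] else float(grid[k0])
    scale, best_rss = _scale_and_rss(a1_template(lam, lm_best, beta_band), y)
    return SpectrumFit(
        lambda_max=lm_best, scale=scale, rss=best_rss, n_points=lam.size
    )


def fit_retinal_release(time_min, fluorescence, b_bounds=(1e-4, 10.0)) -> ReleaseFit:
    """Nonlinear least squares for y = y0 + a(1 − e^(−b t)); t in minutes."""
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    rng_y = float(y.max() - y.min())
    if rng_y <= 0 or rng_y < 1e-12 * max(abs(y).max(), 1.0):
        raise ValueError("flat trace: rate constant unidentifiable")

    # start values: y0 = first point, a = range, b from log-linearized tail
    y0_0, a_0 = float(y[0]), rng_y
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - (y - y0_0) / (a_0 if a_0 > 0 else 1.0)
        ok = (frac > 1e-3) & (t > t[0])
        b_0 = (
            float(-np.polyfit(t[ok], np.log(frac[ok]), 1)[0])
            if ok.sum() >= 2
            else 0.1
        )
    b_0 = float(np.clip(b_0, b_bounds[0] * 2, b_bounds[1] / 2))

    def model(tt, y0, a, b):
        return y0 + a * (1.0 - np.exp(-b * tt))

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[y0_0, a_0, b_0],
            bounds=([-np.inf, 1e-12, b_bounds[0]], [np.inf, np.inf, b_bounds[1]]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"release fit did not converge: {exc}") from exc
    y0, a, b = (float(v) for v in popt)
    if b <= b_bounds[0] * 1.01 or b >= b_bounds[1] * 0.99:
        raise ValueError(f"rate constant at bound (b = {b:g} /min)")
    resid = y - model(t, y0, a, b)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return ReleaseFit(y0=y0, a=a, b=b, r2=max(min(r2, 1.0), 0.0))


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-tailed t test: (t, Welch–Satterthwaite df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise ValueError("zero variance in both groups with equal means")
        return np.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Figure convention: *p<0.05; **p<0.01; ***p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def replicate_summary(values) -> tuple[float, float, int]:
    """mean ± standard error with n, as reported for biological replicates."""
    v = np.asarray(list(values), dtype=float)
    n = v.size
    se = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(v.mean()), se, n
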