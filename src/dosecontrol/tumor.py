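"""Two-compartment leukemia dynamics and biphasic tumor-burden fitting.

The leukemic population is split into cancer stem cells (CSC) l1 and
differentiated cancer cells l2, with symmetric division:

    dl1/dt = lambda * l1,          lambda = (2*a1 - 1)*p1 - d1
    dl2/dt = gamma  * l1 + tau*l2, gamma  = 2*(1 - a1)*p1, tau = -d2

The linear system has the closed-form solution

    l1(t) = l1(0) e^{lambda t}
    l2(t) = l2(0) e^{tau t} + gamma l1(0) (e^{lambda t} - e^{tau t})/(lambda - tau)

(with the t*e^{lambda t} limit when tau == lambda).

Under effective therapy the BCR-ABL burden series decays biphasically: in
log10 scale, two intersecting straight lines.  The leftmost (steep) slope
entangles the decay of differentiated cancer cells with the recovery of the
healthy pool and is reported but never used for parameter estimation; the
rightmost slope beta reflects pure CSC decay against a recovered, constant
healthy pool, giving

    beta = log10(e) * [(2*a1 - 1)*p1 - d1]

so the CSC death rate under therapy is d1 = (2*a1 - 1)*p1 - beta/log10(e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, FitError

LOG10_E = float(np.log10(np.e))

#: default CSC self-renewal probability and division rate (1/day),
#: literature stem-cell estimates; overridable everywhere they appear.
DEFAULT_A1 = 0.87
DEFAULT_P1 = 0.45


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurdenSeries:
    """Longitudinal BCR-ABL ratio measurements for one patient (days)."""

    patient_id: str
    times: tuple
    burden: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        b = np.asarray(self.burden, dtype=float)
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "burden", tuple(b))
        if len(t) != len(b):
            raise ValueError("times and burden must have equal length")
        if len(t) < 3:
            raise ValueError("burden series needs at least 3 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(b <= 0):
            raise ValueError("burden must be positive (log10 must exist)")

    @property
    def log_burden(self) -> np.ndarray:
        return np.log10(np.asarray(self.burden))


@dataclass(frozen=True)
class BiphasicFit:
    """Two-line log10 fit: slope1/intercept1 left of the breakpoint,
    slope2/intercept2 right of it; pooled R^2 of the combined fit."""

    slope1: float
    intercept1: float
    slope2: float
    intercept2: float
    breakpoint: float
    r_squared: float
    n_segments: int = 2

    def predict_log10(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        left = self.intercept1 + self.slope1 * t
        right = self.intercept2 + self.slope2 * t
        return np.where(t <= self.breakpoint, left, right)


@dataclass(frozen=True)
class LeukemiaParams:
    """Rates of the two-compartment model (per day)."""

    a1: float
    p1: float
    d1: float
    d2: float = 0.05

    def __post_init__(self):
        if not 0 <= self.a1 <= 1:
            raise ValueError("self-renewal probability a1 must be in [0, 1]")
        if not self.p1 > 0:
            raise ValueError("division rate p1 must be positive")

    @property
    def lam(self) -> float:
        """Net CSC growth rate lambda (1/day)."""
        return (2 * self.a1 - 1) * self.p1 - self.d1

    @property
    def gamma(self) -> float:
        """Differentiation flux gamma (1/day), always >= 0."""
        return 2 * (1 - self.a1) * self.p1

    @property
    def tau(self) -> float:
        """Net rate of the differentiated compartment, -d2 (1/day)."""
        return -self.d2


@dataclass(frozen=True)
class LeukemiaState:
    l1: float
    l2: float
    t: float

    def __post_init__(self):
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("cell counts must be non-negative")


# ---------------------------------------------------------------------------
# closed-form dynamics
# ---------------------------------------------------------------------------

def trajectory(params: LeukemiaParams, l1_0: float, l2_0: float,
               t) -> LeukemiaState | list:
    """Closed-form solution of the two-compartment system at time(s) t (days)."""
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    lam, gam, tau = params.lam, params.gamma, params.tau
    l1 = l1_0 * np.exp(lam * t_arr)
    if abs(lam - tau) < 1e-12 * max(1.0, abs(lam)):
        # removable singularity: lambda == tau
        l2 = np.exp(lam * t_arr) * (l2_0 + gam * l1_0 * t_arr)
    else:
        l2 = (l2_0 * np.exp(tau * t_arr)
              + gam * l1_0 * (np.exp(lam * t_arr) - np.exp(tau * t_arr)) / (lam - tau))
    states = [LeukemiaState(l1=float(a), l2=float(max(b, 0.0)), t=float(tt))
              for a, b, tt in zip(l1, l2, t_arr)]
    return states[0] if scalar else states


# ---------------------------------------------------------------------------
# biphasic fitting
# ---------------------------------------------------------------------------

def _ols_line(t: np.ndarray, y: np.ndarray):
    """Least-squares line fit; returns (slope, intercept, sse)."""
    A = np.column_stack([t, np.ones_like(t)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _pooled_r2(sse: float, y: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if sse <= 1e-30 else 0.0
    return 1.0 - sse / sst


def _candidate_breakpoints(t: np.ndarray, max_candidates: int | None = None):
    """Integer-day candidates strictly inside the observed range that leave
    >= 2 points on each side."""
    lo = int(np.ceil(t[1]))          # >=2 points left requires bp >= t[1]
    hi = int(np.floor(t[-2]))        # >=2 points right requires bp < t[-2]...
    cands = [d for d in range(lo, hi + 1)
             if np.sum(t <= d) >= 2 and np.sum(t > d) >= 2]
    if max_candidates is not None and len(cands) > max_candidates:
        idx = np.unique(np.linspace(0, len(cands) - 1, max_candidates).astype(int))
        cands = [cands[i] for i in idx]
    return cands


def fit_biphasic(series: BurdenSeries, n_segments: int = 2,
                 continuity: bool = False) -> BiphasicFit:
    """Best two-line fit of log10(burden) over a 1-day breakpoint scan.

    For every candidate breakpoint on a 1-day grid, the two segments are
    fitted independently by least squares (four free parameters — the lines
    intersect but are not constrained to meet at the breakpoint unless
    ``continuity=True``); the breakpoint maximizing the pooled R^2 wins,
    ties broken by the earliest breakpoint.

    ``n_segments`` may be 1, 2 or 3; with anything other than 2 the segment
    count itself is chosen by fitting that many lines (3-line scans use a
    coarsened candidate grid).  Most callers want the default.
    """
    t = np.asarray(series.times, dtype=float)
    y = series.log_burden
    if n_segments == 1:
        s, i, sse = _ols_line(t, y)
        return BiphasicFit(slope1=s, intercept1=i, slope2=s, intercept2=i,
                           breakpoint=float(t[len(t) // 2]),
                           r_squared=_pooled_r2(sse, y), n_segments=1)
    if len(t) < 4:
        raise FitError("biphasic fit needs at least 4 points "
                       "(2 per segment)")
    if n_segments == 2:
        cands = _candidate_breakpoints(t)
        if not cands:
            raise FitError("no breakpoint leaves 2 points per segment")
        fits = []
        for bp in cands:
            left = t <= bp
            right = ~left
            if continuity:
                fit = _continuous_two_line(t, y, float(bp))
                if fit is None:
                    continue
                s1, i1, s2, i2, sse = fit
            else:
                s1, i1, sse1 = _ols_line(t[left], y[left])
                s2, i2, sse2 = _ols_line(t[right], y[right])
                sse = sse1 + sse2
            fits.append((sse, bp, s1, i1, s2, i2))
        sse, bp, s1, i1, s2, i2 = min(fits, key=lambda f: (f[0], f[1]))
        # SSE can tie across every split day falling in a sampling gap; of
        # the tied splits, report the one nearest the fitted lines'
        # intersection (the natural breakpoint of two intersecting lines),
        # which recovers the generating breakpoint on noiseless data.
        scale = max(sse, 1e-30)
        ties = [f for f in fits if f[0] <= sse + 1e-9 * scale]
        if len(ties) > 1 and abs(s1 - s2) > 0:
            cross = (i2 - i1) / (s1 - s2)
            sse, bp, s1, i1, s2, i2 = min(
                ties, key=lambda f: (abs(f[1] - cross), f[1]))
            if min(t2 for _, t2, *_ in ties) <= cross <= max(
                    t2 for _, t2, *_ in ties):
                bp = cross
        return BiphasicFit(slope1=s1, intercept1=i1, slope2=s2, intercept2=i2,
                           breakpoint=float(bp), r_squared=_pooled_r2(sse, y))
    if n_segments == 3:
        return _fit_three_lines(series)
    raise ValueError("n_segments must be 1, 2 or 3")


def _continuous_two_line(t, y, bp):
    """Two lines constrained to meet at the breakpoint (3 free params)."""
    left = t <= bp
    if left.sum() < 2 or (~left).sum() < 2:
        return None
    # y = c + s1*(t-bp) for t<=bp ; y = c + s2*(t-bp) for t>bp
    x = t - bp
    A = np.column_stack([np.ones_like(t),
                         np.where(left, x, 0.0),
                         np.where(left, 0.0, x)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    c, s1, s2 = coef
    resid = y - A @ coef
    return (float(s1), float(c - s1 * bp), float(s2), float(c - s2 * bp),
            float(resid @ resid))


def _fit_three_lines(series: BurdenSeries) -> BiphasicFit:
    """Three independent segments over a coarsened double breakpoint scan.

    Returned as a BiphasicFit whose slope1/slope2 are the first and *last*
    segments (the quantities the downstream estimation consumes)."""
    t = np.asarray(series.times, dtype=float)
    y = series.log_burden
    cands = _candidate_breakpoints(t, max_candidates=100)
    best = None
    for i, b1 in enumerate(cands):
        for b2 in cands[i + 1:]:
            m1 = t <= b1
            m2 = (t > b1) & (t <= b2)
            m3 = t > b2
            if m1.sum() < 2 or m2.sum() < 2 or m3.sum() < 2:
                continue
            s1, i1, e1 = _ols_line(t[m1], y[m1])
            _, _, e2 = _ols_line(t[m2], y[m2])
            s3, i3, e3 = _ols_line(t[m3], y[m3])
            sse = e1 + e2 + e3
            if best is None or sse < best[0] - 1e-15:
                best = (sse, b1, b2, s1, i1, s3, i3)
    if best is None:
        raise FitError("no 3-segment split leaves 2 points per segment")
    sse, b1, b2, s1, i1, s3, i3 = best
    return BiphasicFit(slope1=s1, intercept1=i1, slope2=s3, intercept2=i3,
                       breakpoint=float(b2), r_squared=_pooled_r2(sse, y),
                       n_segments=3)


def select_segments(series: BurdenSeries, candidates=(1, 2, 3)) -> BiphasicFit:
    """Model selection over segment counts by adjusted R^2."""
    n = len(series.times)
    best = None
    for k in candidates:
        try:
            fit = fit_biphasic(series, n_segments=k)
        except (FitError, ValueError):
            continue
        p = 2 * k  # free parameters
        if n - p - 1 <= 0:
            continue
        adj = 1.0 - (1.0 - fit.r_squared) * (n - 1) / (n - p - 1)
        if best is None or adj > best[0]:
            best = (adj, fit)
    if best is None:
        raise FitError("no segment count admits a fit")
    return best[1]


def slope_standard_errors(series: BurdenSeries, fit: BiphasicFit):
    """OLS standard errors of (slope1, slope2) from the fitted split."""
    t = np.asarray(series.times, dtype=float)
    y = series.log_burden
    out = []
    for mask, slope, intercept in (
            (t <= fit.breakpoint, fit.slope1, fit.intercept1),
            (t > fit.breakpoint, fit.slope2, fit.intercept2)):
        tt, yy = t[mask], y[mask]
        resid = yy - (intercept + slope * tt)
        dof = max(len(tt) - 2, 1)
        s2 = float(resid @ resid) / dof
        sxx = float(np.sum((tt - tt.mean()) ** 2))
        out.append(float(np.sqrt(s2 / sxx)) if sxx > 0 else np.inf)
    return tuple(out)


# ---------------------------------------------------------------------------
# death-rate extraction
# ---------------------------------------------------------------------------

def csc_death_rate(beta: float, a1: float = DEFAULT_A1,
                   p1: float = DEFAULT_P1) -> float:
    """CSC death rate d1 (1/day) from the rightmost log10 slope beta.

    Inverts beta = log10(e) * ((2*a1 - 1)*p1 - d1).
    """
    if not 0 <= a1 <= 1:
        raise ValueError("a1 must be in [0, 1]")
    if not p1 > 0:
        raise ValueError("p1 must be positive")
    d1 = (2 * a1 - 1) * p1 - beta / LOG10_E
    if d1 <= 0:
        raise EstimationError(
            f"implausible slope beta={beta:.4g}: implied CSC death rate "
            f"d1={d1:.4g} <= 0 (a decaying CSC population under therapy "
            f"requires d1 > (2*a1-1)*p1 for negative beta)")
    return float(d1)


def beta_from_death_rate(d1: float, a1: float = DEFAULT_A1,
                         p1: float = DEFAULT_P1) -> float:
    """Forward map: log10 burden slope implied by a CSC death rate."""
    return LOG10_E * ((2 * a1 - 1) * p1 - d1)
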