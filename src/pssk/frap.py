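"""FRAP (fluorescence recovery after photobleaching) normalisation and fits.

A trace carries the mean intensity of the bleached region, of a contiguous
unbleached region and of the whole nucleus, sampled before (t < 0) and
after (t >= 0) the bleach. Normalisation divides each region by the
whole-nucleus mean at the same time point (cancelling acquisition
photobleaching, which is multiplicative) and then scales so the pre-bleach
level equals 1.

Recovery is fitted with the single-exponential model

    y(t) = c - a * exp(b t),   b = -k  (k > 0 for a recovering trace)

where c = ymax is the recovery plateau and c - a = ymin the post-bleach
floor. Two half-time conventions are exposed and every output is tagged
with the one used:

* ``"reciprocal_ln2"``: t_half = 1 / (k ln 2)  — the convention used by
  the frapplot-style analysis this module mirrors;
* ``"ln2_over_k"``:     t_half = ln 2 / k      — the standard exponential
  half-life.

The two differ by the exact factor (ln 2)^2. Total recovery is
TR = (ymax - ymin) / (1 - ymin).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

HALF_TIME_CONVENTIONS = ("reciprocal_ln2", "ln2_over_k")


@dataclass(frozen=True)
class FrapTrace:
    """Raw or normalised intensities; bleach at t = 0, pre-bleach at t < 0."""

    time: np.ndarray
    bleached: np.ndarray
    unbleached: np.ndarray | None = None
    nucleus: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if (t < 0).sum() < 2:
            raise ValueError("need at least 2 pre-bleach samples")
        for name in ("bleached", "unbleached", "nucleus"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, float)
            if v.shape != t.shape:
                raise ValueError(f"{name} length mismatch")
            if np.any(v < 0):
                raise ValueError(f"{name} intensities must be >= 0")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "time", t)

    @classmethod
    def from_csv(cls, path) -> "FrapTrace":
        df = pd.read_csv(path)
        need = {"t", "bleached"}
        if need - set(df.columns):
            raise ValueError(f"{path}: need columns t, bleached")
        return cls(df["t"].to_numpy(),
                   df["bleached"].to_numpy(),
                   df["unbleached"].to_numpy() if "unbleached" in df else None,
                   df["nucleus"].to_numpy() if "nucleus" in df else None)


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Nucleus-ratio correction followed by pre-bleach scaling to 1."""
    if trace.nucleus is None:
        raise ValueError("normalisation needs the whole-nucleus channel")
    if np.any(trace.nucleus <= 0):
        raise ValueError("zero nucleus intensity")
    pre = trace.time < 0
    channels = {}
    for name in ("bleached", "unbleached"):
        v = getattr(trace, name)
        if v is None:
            channels[name] = None
            continue
        ratio = v / trace.nucleus
        channels[name] = ratio / ratio[pre].mean()
    return FrapTrace(trace.time, channels["bleached"],
                     channels["unbleached"],
                     np.ones_like(trace.nucleus))


@dataclass(frozen=True)
class FrapFitResult:
    """Parameters of y = c - a exp(-k t) plus derived kinetic quantities."""

    a: float
    k: float
    c: float
    residual_norm: float
    convention: str
    recovering: bool = True

    @property
    def b(self) -> float:
        return -self.k

    @property
    def ymax(self) -> float:
        return self.c

    @property
    def ymin(self) -> float:
        return self.c - self.a

    @property
    def t_half(self) -> float:
        return half_time(self.k, self.convention)

    @property
    def total_recovery(self) -> float:
        return total_recovery(self.ymax, self.ymin)

    def summary(self) -> str:
        flag = "" if self.recovering else "  [warning: no upward trend]"
        return (
            f"y(t) = c - a*exp(-k t): a = {self.a:.6g}, k = {self.k:.6g}/s, "
            f"c = {self.c:.6g}\n"
            f"t_half = {self.t_half:.6g} s ({self.convention}), "
            f"total recovery = {self.total_recovery:.4f}, "
            f"residual norm = {self.residual_norm:.3g}{flag}"
        )


class FrapRecoveryModel:
    """Nonlinear least-squares fit of the exponential recovery model.

    Uses only post-bleach samples (t >= 0). Initialisation: c from the mean
    of the last tenth of the trace, a from the bleach depth, k from the
    first crossing of the half-recovery level.
    """

    def __init__(self, trace: FrapTrace, convention: str = "reciprocal_ln2"):
        if convention not in HALF_TIME_CONVENTIONS:
            raise ValueError(f"convention must be one of "
                             f"{HALF_TIME_CONVENTIONS}")
        post = trace.time >= 0
        self.t = trace.time[post]
        self.y = trace.bleached[post]
        if len(self.t) < 10:
            raise ValueError("need at least 10 post-bleach points")
        self.convention = convention

    def fit(self) -> FrapFitResult:
        t, y = self.t, self.y
        tail = max(1, len(y) // 10)
        c0 = float(y[-tail:].mean())
        y0 = float(y[0])
        a0 = max(c0 - y0, 1e-6)
        half_level = 0.5 * (c0 + y0)
        above = np.nonzero(y >= half_level)[0]
        t_rough = t[above[0]] if len(above) and t[above[0]] > 0 \
            else (t[-1] - t[0]) / 4 or 1.0
        k0 = math.log(2.0) / t_rough
        model = lambda tt, a, k, c: c - a * np.exp(-k * tt)
        try:
            popt, _ = curve_fit(model, t, y, p0=[a0, k0, c0], maxfev=20000)
            a, k, c = (float(v) for v in popt)
        except RuntimeError:
            a, k, c = a0, k0, c0
        resid = float(np.linalg.norm(y - model(t, a, k, c)))
        # non-recovering trace: no significant upward trend
        recovering = (a > 1e-4 * max(abs(c), 1.0)) and k > 0
        if not recovering:
            warnings.warn("trace shows no recovery; fit is degenerate")
        return FrapFitResult(a, k, c, resid, self.convention, recovering)


def fit_recovery(trace: FrapTrace,
                 convention: str = "reciprocal_ln2") -> FrapFitResult:
    return FrapRecoveryModel(trace, convention).fit()


def half_time(k: float, convention: str = "reciprocal_ln2") -> float:
    """Recovery half-time under an explicit convention (seconds)."""
    if k <= 0:
        raise ValueError("half time requires k > 0")
    if convention == "reciprocal_ln2":
        return 1.0 / (k * math.log(2.0))
    if convention == "ln2_over_k":
        return math.log(2.0) / k
    raise ValueError(f"convention must be one of {HALF_TIME_CONVENTIONS}")


def total_recovery(ymax: float, ymin: float) -> float:
    """TR = (ymax - ymin) / (1 - ymin); the mobile fraction estimate."""
    if ymin >= 1:
        raise ValueError("total recovery undefined for ymin >= 1")
    return (ymax - ymin) / (1.0 - ymin)
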