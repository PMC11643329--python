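"""EMSA quantification: fraction bound per lane and Hill binding-curve fits.

Lane signals (background-subtracted band intensities) are converted to
fraction bound by dividing the bound-band signal by the total signal of the
lane.  Binding curves are fitted with the Hill form

    f(c) = c^n / (Kd^n + c^n)

yielding the dissociation constant Kd (nM) and the Hill coefficient n;
``n = 1`` is simple binding, ``n > 1`` cooperative.  Triplicate series can be
fitted jointly (pooled points) or per replicate with a mean ± SD summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import FitError, RecordError

__all__ = [
    "BindingSeries",
    "HillFitResult",
    "HillModel",
    "fraction_bound",
    "fit_hill",
    "fit_hill_replicates",
]


@dataclass
class BindingSeries:
    """Per-lane band intensities over a protein titration.

    ``bound`` may be 1D (one shifted band) or 2D (lanes × shifted bands, e.g.
    separate single-factor and two-factor complexes); ``free`` is the free
    probe band per lane.  With multiple shifted bands, "bound" sums all of
    them unless a band is selected explicitly in :func:`fraction_bound`.
    """

    concentrations_nm: np.ndarray
    bound: np.ndarray
    free: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_nm = np.asarray(self.concentrations_nm, dtype=float)
        self.bound = np.asarray(self.bound, dtype=float)
        self.free = np.asarray(self.free, dtype=float)
        n = len(self.concentrations_nm)
        if self.bound.shape[0] != n or self.free.shape != (n,):
            raise ValueError("bound/free lane counts must match concentrations")
        if np.any(self.concentrations_nm < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(self.concentrations_nm) < 0):
            raise ValueError("concentrations must be ascending")
        if np.any(self.bound < 0) or np.any(self.free < 0):
            raise ValueError("band signals must be >= 0")


def fraction_bound(series: BindingSeries, band: int | None = None) -> np.ndarray:
    """Fraction bound per lane: bound signal / (bound + free) in [0, 1].

    With several shifted bands, all are summed unless ``band`` selects one.
    """
    if series.bound.ndim == 2:
        bound = series.bound[:, band] if band is not None else series.bound.sum(axis=1)
    else:
        if band not in (None, 0):
            raise ValueError("series has a single bound band")
        bound = series.bound
    total = bound + series.free
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise RecordError(f"zero total signal in lane(s) {zero.tolist()}")
    return bound / total


@dataclass
class HillFitResult:
    """Fitted Hill binding curve with standard errors."""

    kd_nm: float
    hill_n: float
    bse: dict[str, float]
    rss: float
    n_obs: int
    warning: str | None = None

    def summary(self) -> str:
        lines = [
            "Hill binding fit:  f(c) = c^n / (Kd^n + c^n)",
            f"  n points:         {self.n_obs}",
            f"  Kd:               {self.kd_nm:10.3f} nM (se {self.bse['kd_nm']:.3f})",
            f"  Hill coefficient: {self.hill_n:10.3f}    (se {self.bse['hill_n']:.3f})",
            f"  residual SS:      {self.rss:.3e}",
        ]
        if self.warning:
            lines.append(f"  WARNING: {self.warning}")
        return "\n".join(lines)


class HillModel:
    """Hill binding model for a titration of fraction-bound values.

    Usage::

        result = HillModel(conc_nm, fractions).fit()
        result.kd_nm, result.hill_n
    """

    def __init__(self, concentrations_nm, fractions):
        self.c = np.asarray(concentrations_nm, dtype=float)
        self.f = np.asarray(fractions, dtype=float)
        if self.c.shape != self.f.shape:
            raise ValueError("concentrations and fractions must align")
        if len(self.c) < 4:
            raise ValueError("need at least 4 concentrations for a Hill fit")

    @staticmethod
    def _model(c: np.ndarray, kd: float, n: float) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(c > 0, c**n / (kd**n + np.where(c > 0, c, 1.0) ** n), 0.0)
        return out

    def fit(self) -> HillFitResult:
        pos = self.c > 0
        if pos.sum() < 3:
            raise FitError("need at least 3 nonzero concentrations")
        # Kd start: concentration where f crosses 0.5 (interpolated).
        order = np.argsort(self.c)
        c_s, f_s = self.c[order], self.f[order]
        above = np.flatnonzero(f_s >= 0.5)
        kd0 = float(c_s[above[0]]) if above.size else float(np.median(c_s[pos]))
        kd0 = max(kd0, float(c_s[pos].min()) * 0.1)
        try:
            popt, pcov = curve_fit(
                self._model, self.c, self.f, p0=[kd0, 1.0],
                bounds=([1e-12, 0.05], [np.inf, 20.0]), maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"Hill fit did not converge: {exc}") from exc
        perr = np.sqrt(np.diag(pcov))
        rss = float(((self.f - self._model(self.c, *popt)) ** 2).sum())
        warning = None
        cmax = float(self.c.max())
        cmin = float(self.c[pos].min())
        if not (cmin / 100.0 <= popt[0] <= cmax * 100.0):
            warning = (
                f"Kd {popt[0]:.3g} nM lies far outside the titrated range "
                f"[{cmin:g}, {cmax:g}] nM; treat with caution"
            )
        return HillFitResult(
            kd_nm=float(popt[0]), hill_n=float(popt[1]),
            bse={"kd_nm": float(perr[0]), "hill_n": float(perr[1])},
            rss=rss, n_obs=len(self.c), warning=warning,
        )


def fit_hill(concentrations_nm, fractions) -> HillFitResult:
    """Least-squares Hill fit; see :class:`HillModel`."""
    return HillModel(concentrations_nm, fractions).fit()


def fit_hill_replicates(
    concentrations_nm, fraction_replicates, mode: str = "joint"
):
    """Fit replicate titrations jointly or per replicate.

    ``mode="joint"`` pools all points into one fit and returns a single
    :class:`HillFitResult`; ``mode="per_replicate"`` fits each series and
    returns ``(results, mean_kd, sd_kd, mean_n, sd_n)``.
    """
    c = np.asarray(concentrations_nm, dtype=float)
    reps = [np.asarray(f, dtype=float) for f in fraction_replicates]
    if mode == "joint":
        return HillModel(np.tile(c, len(reps)), np.concatenate(reps)).fit()
    if mode != "per_replicate":
        raise ValueError("mode must be 'joint' or 'per_replicate'")
    results = [HillModel(c, f).fit() for f in reps]
    kds = np.array([r.kd_nm for r in results])
    ns = np.array([r.hill_n for r in results])
    return (results, float(kds.mean()), float(kds.std(ddof=1)) if len(kds) > 1 else 0.0,
            float(ns.mean()), float(ns.std(ddof=1)) if len(ns) > 1 else 0.0)
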