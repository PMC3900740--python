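"""Saturation-isotherm fitting of contour-count titrations.

Background-corrected peak-to-trough contour counts H at Na⁺ concentration c
are fitted per peak region to the single-site hyperbola

    H(c) = h_max · c / (c + K_D,app)

by least squares, with a nonparametric bootstrap over titration points for
the uncertainty of the apparent dissociation constant.  The model/results
split follows the statsmodels idiom: :class:`TitrationModel` holds the data,
``fit()`` returns a :class:`FitResult` carrying estimates, intervals and a
``summary()`` table.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class NoSignalError(ValueError):
    """All counts are zero; the constant is not identifiable."""


class InsufficientDataError(ValueError):
    """Fewer than three distinct concentrations."""


class PropagationError(ValueError):
    """Ratio requested from a non-converged fit."""


@dataclass(frozen=True)
class TitrationSeries:
    """Contour counts per region across a concentration ladder at one pH."""

    ph: float
    concentrations: tuple[float, ...]
    counts: dict[str, tuple[float, ...]]     # region id -> peak-to-trough per conc.
    corrected: bool = False

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")
        for region, vals in self.counts.items():
            if len(vals) != len(conc):
                raise ValueError(f"region {region}: counts do not match the ladder")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(
            self, "counts", {r: tuple(float(v) for v in v_) for r, v_ in self.counts.items()}
        )

    @property
    def regions(self) -> list[str]:
        return sorted(self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"ph": self.ph, "na_mM": c, "region": region, "peak_to_trough": v,
             "corrected": self.corrected}
            for region, vals in sorted(self.counts.items())
            for c, v in zip(self.concentrations, vals)
        ]
        return pd.DataFrame(rows)


def background_correct(
    series: TitrationSeries, control_counts: dict[str, int]
) -> TitrationSeries:
    """Zero the control background: corrected = max(0, raw − control) per region.

    The control counts are those observed in the same regions of the
    sodium-free half-split control map.
    """
    missing = set(series.counts) - set(control_counts)
    if missing:
        raise KeyError(f"control counts missing for regions: {sorted(missing)}")
    corrected = {
        region: tuple(max(0.0, v - control_counts[region]) for v in vals)
        for region, vals in series.counts.items()
    }
    return replace(series, counts=corrected, corrected=True)


# ---------------------------------------------------------------------------
def _hyperbola(c: np.ndarray, kd: float, h_max: float) -> np.ndarray:
    return h_max * c / (c + kd)


def _fit_core(conc: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Grid-seeded least squares for (kd, h_max); returns (kd, h_max, rss)."""
    # closed-form h_max for a trial kd keeps the grid search one-dimensional
    kd_grid = np.logspace(-1.5, 5, 261)
    best = (np.nan, np.nan, np.inf)
    for kd in kd_grid:
        x = conc / (conc + kd)
        sxx = float(np.sum(x * x))
        if sxx == 0:
            continue
        h = max(float(np.sum(y * x) / sxx), 1e-12)
        rss = float(np.sum((y - h * x) ** 2))
        if rss < best[2]:
            best = (kd, h, rss)
    kd0, h0, _ = best

    def resid(p):
        return _hyperbola(conc, p[0], p[1]) - y

    sol = least_squares(
        resid, x0=[kd0, h0], bounds=([1e-9, 1e-12], [np.inf, np.inf]), xtol=1e-12
    )
    kd, h = float(sol.x[0]), float(sol.x[1])
    return kd, h, float(np.sum(sol.fun**2))


@dataclass(frozen=True)
class FitResult:
    """Fitted apparent dissociation constant for one region."""

    region_id: str
    kd_app: float                 # mM
    h_max: float                  # contour levels
    rss: float
    ci_low: float                 # mM, bootstrap 68% interval
    ci_high: float
    n_boot: int
    seed: int
    ph: float = np.nan
    kd_samples: np.ndarray = field(default=None, repr=False, compare=False)

    conc_range: tuple[float, float] = (0.0, np.inf)

    @property
    def converged(self) -> bool:
        return np.isfinite(self.kd_app) and self.kd_app > 0

    @property
    def well_determined(self) -> bool:
        """False when the bootstrap interval spans more than ~two orders of
        magnitude or the estimate escapes the measured concentration range —
        both signal an unidentifiable (e.g. flat) titration."""
        pos = [c for c in self.conc_range if c > 0 and np.isfinite(c)]
        lo = min(pos) if pos else 0.0
        hi = max(self.conc_range)
        return (
            self.converged
            and self.ci_high / max(self.ci_low, 1e-300) < 100.0
            and lo / 10.0 <= self.kd_app <= hi * 10.0
        )

    def conf_int(self) -> tuple[float, float]:
        return self.ci_low, self.ci_high

    def summary(self) -> str:
        lines = [
            "Na+ titration fit (single-site saturation)",
            "=" * 44,
            f"region:            {self.region_id}",
            f"pH:                {self.ph}",
            f"K_D,app [mM]:      {self.kd_app:.4g}",
            f"68% CI [mM]:       [{self.ci_low:.4g}, {self.ci_high:.4g}]  "
            f"(bootstrap, n={self.n_boot})",
            f"h_max [levels]:    {self.h_max:.4g}",
            f"RSS:               {self.rss:.4g}",
            f"well determined:   {self.well_determined}",
        ]
        return "\n".join(lines)


class TitrationModel:
    """Least-squares model for one region's contour-count titration.

    Parameters
    ----------
    concentrations : array-like
        Na⁺ concentrations in mM (any order; at least 3 distinct values).
    counts : array-like
        Background-corrected peak-to-trough contour counts.
    region_id : str, optional
        Label carried through to the results.
    """

    def __init__(self, concentrations, counts, region_id: str = "", ph: float = np.nan):
        conc = np.asarray(concentrations, dtype=float)
        y = np.asarray(counts, dtype=float)
        if conc.shape != y.shape or conc.ndim != 1:
            raise ValueError("concentrations and counts must be equal-length 1D arrays")
        order = np.argsort(conc, kind="stable")
        self.concentrations = conc[order]
        self.counts = y[order]
        self.region_id = region_id
        self.ph = ph
        if np.unique(self.concentrations).size < 3:
            raise InsufficientDataError("need at least 3 distinct concentrations")
        if not np.any(self.counts > 0):
            raise NoSignalError("all counts are zero")

    @classmethod
    def from_series(cls, series: TitrationSeries, region_id: str) -> "TitrationModel":
        if not series.corrected:
            raise ValueError("series must be background-corrected before fitting")
        return cls(
            series.concentrations, series.counts[region_id], region_id=region_id,
            ph=series.ph,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, region_id: str) -> "TitrationModel":
        sub = df[df["region"] == region_id]
        ph = float(sub["ph"].iloc[0]) if "ph" in sub else np.nan
        return cls(sub["na_mM"].to_numpy(), sub["peak_to_trough"].to_numpy(),
                   region_id=region_id, ph=ph)

    def fit(self, n_boot: int = 500, seed: int = 0) -> FitResult:
        """Point fit plus a bootstrap over titration points (deterministic in seed)."""
        kd, h, rss = _fit_core(self.concentrations, self.counts)
        rng = np.random.default_rng(seed)
        n = self.concentrations.size
        samples = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            c_b, y_b = self.concentrations[idx], self.counts[idx]
            if np.unique(c_b).size < 3 or not np.any(y_b > 0):
                continue
            samples.append(_fit_core(c_b, y_b)[0])
        samples = np.asarray(samples) if samples else np.array([kd])
        lo, hi = np.percentile(samples, [16.0, 84.0])
        return FitResult(
            region_id=self.region_id,
            kd_app=kd,
            h_max=h,
            rss=rss,
            ci_low=float(min(lo, kd)),
            ci_high=float(max(hi, kd)),
            n_boot=n_boot,
            seed=seed,
            ph=self.ph,
            kd_samples=samples,
            conc_range=(
                float(self.concentrations[self.concentrations > 0].min()),
                float(self.concentrations.max()),
            ),
        )


def fit_titration(
    series: TitrationSeries, region_id: str, seed: int = 0, n_boot: int = 500
) -> FitResult:
    """Fit one region of a background-corrected titration series."""
    return TitrationModel.from_series(series, region_id).fit(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RatioResult:
    """Fold change between two apparent dissociation constants."""

    ratio: float
    ci_low: float
    ci_high: float


def kd_ratio(fit_acid: FitResult, fit_base: FitResult) -> RatioResult:
    """K_D,app(acid) / K_D,app(base) with a bootstrap-propagated interval."""
    if not (fit_acid.converged and fit_base.converged):
        raise PropagationError("both fits must have converged")
    ratio = fit_acid.kd_app / fit_base.kd_app
    sa, sb = fit_acid.kd_samples, fit_base.kd_samples
    if sa is not None and sb is not None and len(sa) > 1 and len(sb) > 1:
        m = min(len(sa), len(sb))
        samples = sa[:m] / np.maximum(sb[:m], 1e-300)
        lo, hi = np.percentile(samples, [16.0, 84.0])
    else:
        lo = hi = ratio
    return RatioResult(ratio=float(ratio),
                       ci_low=float(min(lo, ratio)), ci_high=float(max(hi, ratio)))


@dataclass(frozen=True)
class ConsistencyReport:
    """Across-region agreement of apparent constants at one pH."""

    kd_values: dict[str, float]
    spread: float                  # max/min ratio
    flagged: bool                  # True when spread exceeds 2-fold

    def summary(self) -> str:
        per = ", ".join(f"{r}={v:.3g} mM" for r, v in sorted(self.kd_values.items()))
        flag = "INCONSISTENT (>2-fold)" if self.flagged else "consistent"
        return f"K_D,app per region: {per}; spread {self.spread:.2f}x — {flag}"


def consistency_report(fits: list[FitResult]) -> ConsistencyReport:
    if len(fits) < 2:
        raise ValueError("need at least 2 region fits")
    kd = {f.region_id: f.kd_app for f in fits}
    vals = np.array(list(kd.values()))
    spread = float(vals.max() / vals.min())
    return ConsistencyReport(kd_values=kd, spread=spread, flagged=spread > 2.0)
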