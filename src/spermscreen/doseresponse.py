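"""Four-parameter logistic (4PL) dose-response fitting.

Confirmed hits are retested on 8-point, 3-fold dilution series (10 µM top
concentration, two replicates per point) and summarised by the 4PL model

    y(x) = bottom + (top - bottom) / (1 + (x / ec50)^hill),

which for hill > 0 and top > bottom decreases with dose — the screen's
inhibition convention; induction data are fitted with top and bottom
swapped by the caller.  Efficacy is reported as percent maximal reduction
referenced to the control scale (DMSO = 100), i.e. 100 - bottom for
inhibition fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseData",
    "FourPLFit",
    "dilution_series",
    "fourpl",
    "fit_4pl",
    "efficacy",
    "simulate_response",
]

MAX_HILL = 10.0
XTOL = 1e-8
MAX_ITER = 500


def dilution_series(top_conc: float = 10.0, n: int = 8, factor: float = 3.0) -> np.ndarray:
    """Geometric dilution series top/factor^k, k = 0..n-1 (descending)."""
    if top_conc <= 0 or factor <= 1 or n < 2:
        raise ValueError("need top_conc > 0, factor > 1, n >= 2")
    return top_conc / factor ** np.arange(n, dtype=float)


@dataclass
class DoseResponseData:
    """Long-form dose-response observations (replicates as separate rows)."""

    concentrations: np.ndarray   # µM, one entry per observation
    responses: np.ndarray        # % of control or % events

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        if len(np.unique(self.concentrations)) < 4:
            raise ValueError("need >= 4 distinct concentrations to fit a 4PL")


@dataclass
class FourPLFit:
    top: float
    bottom: float
    ec50: float
    hill: float
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return fourpl(np.asarray(x, dtype=float), self.top, self.bottom, self.ec50, self.hill)


def fourpl(x, top: float, bottom: float, ec50: float, hill: float):
    """The 4PL response curve (decreasing in x for hill > 0, top > bottom)."""
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** hill)


def _initial_guess(conc: np.ndarray, resp: np.ndarray) -> tuple:
    """Mean-response initialisation: top and bottom from the extreme mean
    responses, EC50 at the concentration nearest the half response, hill 1."""
    means = pd.Series(resp).groupby(pd.Series(conc)).mean()
    top0, bot0 = float(means.max()), float(means.min())
    mid = 0.5 * (top0 + bot0)
    ec50_0 = float(means.index[np.argmin(np.abs(means.values - mid))])
    return top0, bot0, ec50_0, 1.0


def fit_4pl(data: DoseResponseData) -> FourPLFit:
    """Ordinary least-squares 4PL fit, optimising EC50 on the log scale.

    Parameters are (top, bottom, log EC50, hill) with hill bounded in
    (0, 10]; convergence is declared at relative parameter change below
    1e-8.  A non-converged fit is returned (not raised) with the flag set.
    """
    conc, resp = data.concentrations, data.responses
    top0, bot0, ec50_0, hill0 = _initial_guess(conc, resp)

    def residuals(theta):
        top, bottom, log_ec50, hill = theta
        return fourpl(conc, top, bottom, np.exp(log_ec50), hill) - resp

    span = max(top0 - bot0, 1.0)
    lower = [bot0 - 10 * span, bot0 - 10 * span, np.log(conc.min()) - 15.0, 1e-6]
    upper = [top0 + 10 * span, top0 + 10 * span, np.log(conc.max()) + 15.0, MAX_HILL]
    result = least_squares(
        residuals,
        x0=[top0, bot0, np.log(ec50_0), hill0],
        bounds=(lower, upper),
        xtol=XTOL,
        ftol=None,
        gtol=None,
        max_nfev=MAX_ITER * 4,
    )
    top, bottom, log_ec50, hill = result.x
    return FourPLFit(
        top=float(top),
        bottom=float(bottom),
        ec50=float(np.exp(log_ec50)),
        hill=float(hill),
        rss=float(2.0 * result.cost),
        converged=bool(result.status > 0),
    )


def efficacy(fit: FourPLFit, direction: str = "inhibition") -> float:
    """Percent maximal effect on the control-anchored scale.

    Inhibition: % max reduction = 100 - bottom (the response floor below
    the DMSO = 100 reference), clamped to [0, 100].  Induction (AR): the
    fitted plateau (top), clamped to [0, 100].
    """
    if direction == "inhibition":
        return float(np.clip(100.0 - fit.bottom, 0.0, 100.0))
    if direction == "induction":
        return float(np.clip(fit.top, 0.0, 100.0))
    raise ValueError(f"unknown direction: {direction!r}")


def simulate_response(
    concentrations: np.ndarray,
    top: float,
    bottom: float,
    ec50: float,
    hill: float,
    cv: float = 0.05,
    n_replicates: int = 2,
    rng: "np.random.Generator | None" = None,
) -> DoseResponseData:
    """Noisy observations from a known 4PL curve (for recovery studies).

    Noise is multiplicative Gaussian with coefficient of variation ``cv``
    applied to the top-of-scale response, matching plate-level measurement
    error that does not shrink to zero at full inhibition.
    """
    rng = rng if rng is not None else np.random.default_rng()
    conc = np.repeat(np.asarray(concentrations, dtype=float), n_replicates)
    clean = fourpl(conc, top, bottom, ec50, hill)
    noisy = clean + rng.normal(0.0, cv * max(abs(top), abs(bottom)), size=conc.shape)
    return DoseResponseData(concentrations=conc, responses=noisy)


def fit_table(df: pd.DataFrame, direction: str = "inhibition") -> pd.DataFrame:
    """Fit every compound in a long-form table (compound_id, conc_um,
    response) and return one summary row per compound."""
    rows = []
    for cpd, grp in df.groupby("compound_id"):
        data = DoseResponseData(
            concentrations=grp["conc_um"].to_numpy(float),
            responses=grp["response"].to_numpy(float),
        )
        fit = fit_4pl(data)
        rows.append(
            {
                "compound_id": cpd,
                "top": fit.top,
                "bottom": fit.bottom,
                "ec50_um": fit.ec50,
                "hill": fit.hill,
                "efficacy_pct": efficacy(fit, direction),
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
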