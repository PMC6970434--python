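"""Ordinary least-squares regression linking α1,3GT carriage to stool antigen.

The study question is whether the diversity of α1,3GT-positive bacteria in a
subject's metagenome (number of detected species, or raw hit counts) predicts
the amount of α-Gal antigen measured in stool.  Exactly one simple linear
regression is specified; the p-value is the two-sided t-test on the slope with
n−2 degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Simple OLS of y on x with slope p-value and R².

    Requires n >= 3 and non-constant x (the slope test is undefined otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        slope_stderr=float(res.stderr),
        n=int(n),
    )


def write_regression_json(result: RegressionResult, path: str | Path) -> None:
    payload = {
        "slope": float(f"{result.slope:.6g}"),
        "intercept": float(f"{result.intercept:.6g}"),
        "r_squared": float(f"{result.r_squared:.6g}"),
        "p_value": float(f"{result.p_value:.6g}"),
        "n": result.n,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def plot_regression(x, y, result: RegressionResult, path: str | Path,
                    xlabel: str = "n species with α1,3GT genes",
                    ylabel: str = "stool antigen") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, color="steelblue")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, color="orange",
            label=f"R² = {result.r_squared:.3f}, P = {result.p_value:.4f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
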