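"""Agreement statistics between measurement series.

Used to compare manual per-slice segmentations against the automated
connected-components mask (or one analyst against another): Bland-Altman
bias and 95 % limits of agreement, ordinary least-squares regression of
one series on the other with Pearson correlation, and per-analyst
deviance summaries against a reference reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class AgreementInputError(ValueError):
    """Series unusable for the requested agreement statistic."""


@dataclass
class AgreementResult:
    """Bland-Altman and regression agreement between series a and b.

    Differences are ``b - a``; limits of agreement are
    ``bias +/- 1.96 x SD`` of the differences (the standard 95 % band).
    ``slope``/``intercept`` are the OLS fit of b on a.
    """

    n: int
    bias: Optional[float] = None
    loa_low: Optional[float] = None
    loa_high: Optional[float] = None
    slope: Optional[float] = None
    intercept: Optional[float] = None
    pearson_r: Optional[float] = None
    means: Optional[np.ndarray] = field(default=None, repr=False)
    diffs: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {k: (None if v is None else float(v))
                for k, v in (("n", self.n), ("bias", self.bias),
                             ("loa_low", self.loa_low), ("loa_high", self.loa_high),
                             ("slope", self.slope), ("intercept", self.intercept),
                             ("pearson_r", self.pearson_r))}


def _as_pair(a, b, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise AgreementInputError(f"series lengths differ: {a.size} vs {b.size}")
    if a.size < min_n:
        raise AgreementInputError(f"need at least {min_n} pairs, got {a.size}")
    return a, b


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement: bias and 95 % limits of b - a."""
    a, b = _as_pair(a, b, min_n=2)
    d = b - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        n=a.size, bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        means=(a + b) / 2.0, diffs=d,
    )


def regression_agreement(a, b) -> AgreementResult:
    """OLS regression of b on a plus Pearson correlation."""
    a, b = _as_pair(a, b, min_n=3)
    if np.ptp(a) == 0:
        raise AgreementInputError("series a is constant; regression is degenerate")
    fit = stats.linregress(a, b)
    return AgreementResult(n=a.size, slope=float(fit.slope),
                           intercept=float(fit.intercept),
                           pearson_r=float(fit.rvalue))


def compare_series(a, b) -> AgreementResult:
    """Full agreement panel: Bland-Altman plus regression on the same pairs."""
    ba = bland_altman(a, b)
    reg = regression_agreement(a, b)
    ba.slope, ba.intercept, ba.pearson_r = reg.slope, reg.intercept, reg.pearson_r
    return ba


def analyst_deviance(series_by_analyst: Mapping[str, "pd.Series"],
                     reference: Optional[str] = None) -> pd.DataFrame:
    """Per-analyst deviation from a reference per-slice series.

    ``series_by_analyst`` maps analyst id to a Series indexed by slice.
    The reference defaults to the across-analyst mean; pass an analyst
    id to designate an expert as reference instead.  Slices missing
    from any series are dropped pairwise (logged).  Returns one row per
    analyst with median/quartile/range of the per-slice differences.
    """
    if not series_by_analyst:
        raise AgreementInputError("no analyst series given")
    frame = pd.DataFrame({k: pd.Series(v) for k, v in series_by_analyst.items()})
    aligned = frame.dropna()
    if aligned.empty:
        raise AgreementInputError("no slices shared by all analysts")
    if len(aligned) < len(frame):
        logger.info("analyst_deviance: dropped %d slices not shared by all analysts",
                    len(frame) - len(aligned))
    if reference is None:
        ref = aligned.mean(axis=1)
        ref_name = "mean"
    else:
        if reference not in aligned.columns:
            raise AgreementInputError(f"reference analyst {reference!r} not found")
        ref = aligned[reference]
        ref_name = reference
    rows = []
    for analyst in aligned.columns:
        d = aligned[analyst] - ref
        rows.append({
            "analyst": analyst, "reference": ref_name, "n": int(d.size),
            "median": float(d.median()), "q1": float(d.quantile(0.25)),
            "q3": float(d.quantile(0.75)), "min": float(d.min()),
            "max": float(d.max()),
        })
    return pd.DataFrame(rows).set_index("analyst")


def bland_altman_plot(result: AgreementResult, path, title: str = "Bland-Altman") -> None:
    """Save the classic mean-vs-difference plot with bias and limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.means is None or result.diffs is None:
        raise AgreementInputError("result carries no per-pair data; use bland_altman()")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=12, alpha=0.7)
    ax.axhline(result.bias, color="k", lw=1)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="tab:blue", lw=1, ls="--")
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (b - a)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
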