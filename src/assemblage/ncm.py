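"""Sloan neutral community model: occurrence frequency vs metacommunity
abundance, least-squares estimation of Nm, goodness of fit, binomial
confidence bands, and per-OTU partition relative to the prediction."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc

from .io import OtuTable, relative_abundance

logger = logging.getLogger(__name__)


def predicted_frequency(p: np.ndarray, nm: float, d: float) -> np.ndarray:
    """P(occurrence) = 1 - BetaCDF(d; Nm*p, Nm*(1-p))."""
    p = np.asarray(p, dtype=float)
    a = np.maximum(nm * p, 1e-12)
    b = np.maximum(nm * (1.0 - p), 1e-12)
    return 1.0 - betainc(a, b, np.clip(d, 0.0, 1.0))


def _wilson_band(phat: np.ndarray, n: int, z: float = 1.959964) -> tuple:
    """Wilson score interval around a (possibly non-integer) proportion.

    The band is used as a prediction region for an observed frequency out of
    ``n`` samples, so the endpoints are widened to include the saturated
    outcomes 0 and 1 whenever those outcomes are not themselves rare
    (probability > 2.5%) under the predicted proportion — a plain Wilson CI
    never reaches the boundaries and would flag e.g. f = 1 at a predicted
    0.999 as a deviation.
    """
    denom = 1.0 + z ** 2 / n
    center = (phat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    lower = np.clip(center - half, 0, 1)
    upper = np.clip(center + half, 0, 1)
    with np.errstate(divide="ignore"):
        upper = np.where(phat ** n > 0.025, 1.0, upper)
        lower = np.where((1 - phat) ** n > 0.025, 0.0, lower)
    return lower, upper


def _fit_nm(p: np.ndarray, f: np.ndarray, d: float) -> float:
    def sse(log_nm: float) -> float:
        pred = predicted_frequency(p, np.exp(log_nm), d)
        return float(((f - pred) ** 2).sum())

    res = minimize_scalar(sse, bounds=(np.log(1e-2), np.log(1e9)),
                          method="bounded",
                          options={"xatol": 1e-8})
    return float(np.exp(res.x))


@dataclass
class NcmFit:
    nm: float
    m: float
    r_squared: float
    detection_limit: float
    nm_ci: tuple[float, float] | None
    n_bootstrap: int
    n_samples: int
    mean_reads: float
    per_otu: pd.DataFrame  # p, frequency, predicted, lower, upper, class

    def summary(self) -> dict:
        return {
            "Nm": self.nm,
            "m": self.m,
            "r_squared": self.r_squared,
            "detection_limit": self.detection_limit,
            "nm_ci_lower": None if self.nm_ci is None else self.nm_ci[0],
            "nm_ci_upper": None if self.nm_ci is None else self.nm_ci[1],
            "n_bootstrap": self.n_bootstrap,
            "n_samples": self.n_samples,
            "fraction_within": float((self.per_otu["class"] == "within").mean()),
            "fraction_above": float((self.per_otu["class"] == "above").mean()),
            "fraction_below": float((self.per_otu["class"] == "below").mean()),
        }


def fit_ncm(table: OtuTable, detection_limit: float | None = None,
            n_bootstrap: int = 1000, seed: int | None = None) -> NcmFit:
    """Fit the neutral model to occurrence frequency vs mean relative
    abundance.

    Nm is estimated by bounded least squares on untransformed frequencies;
    the detection limit defaults to 1 / mean reads per sample; the 95% band
    around the fitted curve is a Wilson binomial interval at the number of
    samples; the Nm confidence interval is a percentile bootstrap over OTUs.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rel = relative_abundance(table)
    totals = table.data.sum(axis=0)
    keep = totals > 0
    rel = rel.loc[:, keep]
    n_samples = table.n_samples
    mean_reads = float(table.sample_sums().mean())
    d = detection_limit if detection_limit is not None else 1.0 / mean_reads

    p = rel.mean(axis=0).to_numpy()
    f = (table.data.loc[:, keep] > 0).mean(axis=0).to_numpy()
    if np.all(f == 1.0):
        warnings.warn("every OTU occurs in every sample; NCM fit is degenerate")

    nm = _fit_nm(p, f, d)
    pred = predicted_frequency(p, nm, d)
    sst = float(((f - f.mean()) ** 2).sum())
    sse = float(((f - pred) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan

    lower, upper = _wilson_band(pred, n_samples)
    tol = 1e-9
    cls = np.where(f > upper + tol, "above",
                   np.where(f < lower - tol, "below", "within"))

    nm_ci = None
    if n_bootstrap and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n_otus = len(p)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n_otus, size=n_otus)
            boots[b] = _fit_nm(p[idx], f[idx], d)
        nm_ci = (float(np.percentile(boots, 2.5)),
                 float(np.percentile(boots, 97.5)))

    per_otu = pd.DataFrame({
        "p": p, "frequency": f, "predicted": pred,
        "lower": lower, "upper": upper, "class": cls,
    }, index=rel.columns)
    return NcmFit(nm=nm, m=nm / mean_reads, r_squared=r2, detection_limit=d,
                  nm_ci=nm_ci, n_bootstrap=n_bootstrap or 0,
                  n_samples=n_samples, mean_reads=mean_reads, per_otu=per_otu)


def classify_otus_vs_prediction(fit: NcmFit) -> pd.Series:
    """Per-OTU class relative to the fitted 95% band: above / within / below."""
    f = fit.per_otu["frequency"]
    tol = 1e-9
    cls = np.where(f > fit.per_otu["upper"] + tol, "above",
                   np.where(f < fit.per_otu["lower"] - tol, "below", "within"))
    return pd.Series(cls, index=fit.per_otu.index, name="class")
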