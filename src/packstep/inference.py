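"""Post-fit interpretation: log-RSS curves and updated movement kernels.

The log relative selection strength (log-RSS) compares the selection
weight of a location at covariate value x1 against a reference x2, all
other terms equal: for a linear-in-parameters model it is the sum over
terms involving the focus covariate of beta * (g(x1) - g(x2)),
including interactions frozen at stated conditioning values.  Curves
are computed on the standardized scale and reported against raw
kilometers via the stored scaling constants, with delta-method 95%
intervals from the coefficient covariance.

Fitted movement modifiers update the tentative kernel in closed form:
the ln-step-length modifier of a diel class adds to the gamma shape,
the step-length coefficient (per km) subtracts from the gamma rate, and
the seasonal turn-cosine modifier adds to the von Mises concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Scalers, TentativeKernel
from .fit import FitResult

Z95 = 1.959963984540054


@dataclass
class RSSCurve:
    focus: str
    x1_raw: np.ndarray  # raw units (km)
    x1_std: np.ndarray
    x2_std: float
    conditioning: dict[str, float]
    log_rss: np.ndarray
    se: np.ndarray

    @property
    def lower(self) -> np.ndarray:
        return self.log_rss - Z95 * self.se

    @property
    def upper(self) -> np.ndarray:
        return self.log_rss + Z95 * self.se

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x1_raw": self.x1_raw,
                "x1_std": self.x1_std,
                "log_rss": self.log_rss,
                "se": self.se,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def log_rss(
    fit: FitResult,
    focus: str,
    x1,
    x2: float = 0.0,
    conditioning: dict[str, float] | None = None,
    scalers: Scalers | None = None,
    x1_is_raw: bool = False,
) -> RSSCurve:
    """Log-RSS of the focus covariate at x1 versus reference x2.

    ``x1`` is a grid of standardized values, or raw kilometers when
    ``x1_is_raw`` (needs ``scalers``); ``x2`` is standardized.
    ``conditioning`` freezes interacting covariates at standardized
    values (e.g. neighbor distance at its min/0/max for
    inside/border/outside contrasts); terms not mentioned default to 0
    (their mean).  Interval: delta method on the linear-predictor
    difference.
    """
    terms = fit.spec.terms
    involved = [
        t
        for t in terms
        if t == focus or (":" in t and focus in t.split(":"))
    ]
    if not involved:
        raise ValueError(
            f"{focus!r} not in the fitted model; available terms: {terms}"
        )
    conditioning = conditioning or {}
    x1 = np.atleast_1d(np.asarray(x1, float))
    if x1_is_raw:
        if scalers is None or focus not in scalers.moments:
            raise ValueError("raw x1 values need scaling constants for the focus")
        x1_std = scalers.scale(focus, x1)
        x1_raw = x1
    else:
        x1_std = x1
        x1_raw = (
            scalers.unscale(focus, x1)
            if scalers is not None and focus in scalers.moments
            else x1.copy()
        )

    # contrast vector a(z): log-RSS = beta' a, var = a' cov a
    a = np.zeros((len(x1_std), len(terms)))
    dz = x1_std - x2
    for t in involved:
        j = terms.index(t)
        if t == focus:
            a[:, j] = dz
        else:
            parts = t.split(":")
            other = parts[0] if parts[1] == focus else parts[1]
            a[:, j] = dz * conditioning.get(other, 0.0)
    values = a @ fit.estimates
    var = np.einsum("ij,jk,ik->i", a, fit.cov, a)
    return RSSCurve(
        focus=focus,
        x1_raw=x1_raw,
        x1_std=x1_std,
        x2_std=float(x2),
        conditioning=dict(conditioning),
        log_rss=values,
        se=np.sqrt(np.clip(var, 0, None)),
    )


@dataclass
class UpdatedKernel:
    """Movement kernel for one diel or seasonal class after updating."""

    condition: str
    shape: float
    rate: float  # 1/km
    kappa: float
    valid: bool = True
    note: str = ""

    @property
    def scale(self) -> float:
        return 1.0 / self.rate if self.rate > 0 else np.nan

    @property
    def mean_step_km(self) -> float:
        return self.shape * self.scale


def update_kernels(
    fit: FitResult, tentative: TentativeKernel
) -> dict[str, UpdatedKernel]:
    """Closed-form kernel updates from fitted movement modifiers.

    Per diel class c: shape = k0 + beta_lnl(c), rate = 1/theta0 - beta_l
    (step length enters in km, so its coefficient shifts the gamma rate
    with a negative sign).  Per season s: kappa = kappa0 + beta_cos(s);
    a negative updated kappa flags a reversal preference rather than an
    error.  Non-positive shape or rate flags the class invalid.
    """
    terms = fit.spec.terms
    beta_l = fit.coef("step_length_km") if "step_length_km" in terms else 0.0
    rate0 = 1.0 / tentative.scale
    out: dict[str, UpdatedKernel] = {}
    for t in terms:
        if t.startswith("log_sl:"):
            cls = t.split(":")[1]
            shape = tentative.shape + fit.coef(t)
            rate = rate0 - beta_l
            valid = shape > 0 and rate > 0
            out[cls] = UpdatedKernel(
                condition=cls,
                shape=shape,
                rate=rate,
                kappa=tentative.kappa,
                valid=valid,
                note="" if valid else "non-positive updated shape or rate",
            )
        elif t.startswith("cos_ta:"):
            cls = t.split(":")[1]
            kappa = tentative.kappa + fit.coef(t)
            out[cls] = UpdatedKernel(
                condition=cls,
                shape=tentative.shape,
                rate=rate0 - beta_l,
                kappa=kappa,
                valid=(tentative.shape > 0 and rate0 - beta_l > 0),
                note="reversal preference (kappa < 0)" if kappa < 0 else "",
            )
    return out


def kernel_table(kernels: dict[str, UpdatedKernel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": k.condition,
                "shape": k.shape,
                "rate_per_km": k.rate,
                "scale_km": k.scale,
                "mean_step_km": k.mean_step_km,
                "kappa": k.kappa,
                "valid": k.valid,
                "note": k.note,
            }
            for k in kernels.values()
        ]
    )


def report(
    fits: dict[str, FitResult],
    rss_curves: list[RSSCurve] = (),
    kernels: dict[str, UpdatedKernel] | None = None,
    out_dir=None,
) -> str:
    """Human-readable Markdown report; tables also written as TSV when
    ``out_dir`` is given."""
    from pathlib import Path

    lines = ["# Step-selection analysis report", ""]
    for name, res in fits.items():
        lines += [f"## Model: {name}", ""]
        lines += [
            f"strata: {res.n_strata} (dropped {res.n_dropped}); "
            f"logLik: {res.loglik:.2f}; BIC: {res.bic:.2f}; "
            f"estimator: {res.method}; converged: {res.converged}",
            "",
            "| Term | Estimate | Std. error |",
            "| --- | ---: | ---: |",
        ]
        for t, b, s in zip(res.spec.terms, res.estimates, res.se):
            lines.append(f"| {t} | {b:.2f} | {s:.2f} |")
        lines.append("")
        if out_dir is not None:
            res.table().to_csv(
                Path(out_dir) / f"coefficients_{name}.tsv", sep="\t", index=False
            )
    for curve in rss_curves:
        cond = ", ".join(f"{k}={v:g}" for k, v in curve.conditioning.items()) or "none"
        lines += [
            f"## log-RSS: {curve.focus} (x2 = {curve.x2_std:g}, conditioning: {cond})",
            "",
        ]
        df = curve.frame()
        lines += [
            "| x1 (km) | log-RSS | 95% lo | 95% hi |",
            "| ---: | ---: | ---: | ---: |",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"| {r.x1_raw:.2f} | {r.log_rss:.3f} | {r.lower:.3f} | {r.upper:.3f} |"
            )
        lines.append("")
        if out_dir is not None:
            df.to_csv(
                Path(out_dir) / f"rss_{curve.focus.replace(':', '_')}.tsv",
                sep="\t",
                index=False,
            )
    if kernels:
        lines += ["## Updated movement kernels", ""]
        kt = kernel_table(kernels)
        lines += [
            "| Condition | Shape | Rate (1/km) | Mean step (km) | kappa | Valid |",
            "| --- | ---: | ---: | ---: | ---: | --- |",
        ]
        for _, r in kt.iterrows():
            lines.append(
                f"| {r.condition} | {r['shape']:.3f} | {r.rate_per_km:.3f} | "
                f"{r.mean_step_km:.3f} | {r.kappa:.3f} | {r.valid} |"
            )
        lines.append("")
        if out_dir is not None:
            kt.to_csv(Path(out_dir) / "updated_kernels.tsv", sep="\t", index=False)
    text = "\n".join(lines)
    if out_dir is not None:
        (Path(out_dir) / "report.md").write_text(text)
    return text
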