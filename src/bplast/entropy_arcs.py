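"""Behavioral entropy and developmental-arc mixed models.

Within each observation interval (hour or day) an individual's occupancy
of the k behavioral clusters defines a probability distribution; its
Shannon entropy H = -sum_i p_i log p_i (nats by default) measures how
diverse the behavioral repertoire was during that interval.  The
developmental arc of entropy (or of a single-metric CoV) is then modelled
over observation hours with linear and quadratic mixed models — fixed
effects of time (and time squared), mother identity, tank position and
tank system; random intercepts, slopes (and quadratic terms) per
individual — compared by AIC/BIC, with the quadratic vertex giving the
hour of peak plasticity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .metrics import IntervalSpec

__all__ = [
    "occupancy",
    "shannon_entropy",
    "entropy_table",
    "ArcFit",
    "fit_arc_models",
    "ModelSelection",
    "select_model",
    "quadratic_vertex",
    "PeakEstimate",
    "peak_time",
]

log = logging.getLogger(__name__)


def occupancy(
    clusters: pd.DataFrame,
    interval: IntervalSpec,
    k: int,
    label_col: str = "cluster",
) -> pd.DataFrame:
    """Per-(individual, interval) cluster-occupancy counts.

    ``clusters`` is a long frame with columns individual_id, day_index,
    time_s and a 1..k integer label column.  Returns one row per
    (individual_id, interval_index) with a ``counts`` length-k array
    column, ``probs`` (counts / total) and ``n_frames``.  Intervals with
    no frames simply do not appear.
    """
    df = clusters
    labels = df[label_col].to_numpy()
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"cluster labels must lie in 1..{k}")
    idx = interval.index_for(df["day_index"].to_numpy(), df["time_s"].to_numpy())
    out = []
    frame = pd.DataFrame({"individual_id": df["individual_id"].to_numpy(), "interval": idx, "label": labels})
    for (ind, iv), g in frame.groupby(["individual_id", "interval"], sort=True):
        counts = np.bincount(g["label"].to_numpy(), minlength=k + 1)[1:]
        total = counts.sum()
        out.append(
            {
                "individual_id": ind,
                "interval_index": int(iv),
                "counts": counts,
                "probs": counts / total,
                "n_frames": int(total),
            }
        )
    return pd.DataFrame(out)


def shannon_entropy(probs: np.ndarray, base: float | None = None) -> float:
    """H = -sum p log p with 0 log 0 := 0; natural log unless ``base`` given."""
    p = np.asarray(probs, dtype=float)
    if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a probability distribution")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def entropy_table(
    clusters: pd.DataFrame,
    interval: IntervalSpec,
    k: int,
    label_col: str = "cluster",
    covariates: pd.DataFrame | None = None,
    min_frames_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-individual, per-interval behavioral entropy (nats).

    Intervals with fewer than ``min_frames_frac`` of the nominal frame
    count are dropped (an hour of mostly-missing tracking does not support
    an occupancy distribution).  ``covariates`` may supply one row per
    individual_id with mother_id / tank_position / tank_system to merge in.
    """
    occ = occupancy(clusters, interval, k, label_col=label_col)
    min_frames = max(1, int(np.ceil(min_frames_frac * interval.nominal_frames)))
    short = occ["n_frames"] < min_frames
    if short.any():
        log.info("dropping %d short intervals from entropy table", int(short.sum()))
        occ = occ[~short]
    occ = occ.reset_index(drop=True)
    ent = occ[["individual_id", "interval_index", "n_frames"]].copy()
    ent["entropy_nats"] = [shannon_entropy(p) for p in occ["probs"]]
    if covariates is not None:
        ent = ent.merge(covariates, on="individual_id", how="left")
    return ent


@dataclass
class ArcFit:
    """One mixed-model fit of a plasticity response over developmental time.

    Fixed-effect time coefficients are on the standardized time axis
    ``z = (hour - center) / scale``; ``peak_hour`` maps the quadratic
    vertex back to raw observation hours.
    """

    form: str                      # "linear" | "quadratic"
    response: str
    params: pd.Series
    beta1: float                   # fixed effect of z
    beta2: float | None            # fixed effect of z^2 (quadratic only)
    center: float
    scale: float
    aic: float
    bic: float
    llf: float
    converged: bool
    n_obs: int
    n_individuals: int
    re_cov: np.ndarray = field(repr=False, default=None)
    bse: pd.Series = field(repr=False, default=None)

    @property
    def peak_hour(self) -> float | None:
        """Vertex of the quadratic arc in raw observation hours (None if no peak)."""
        if self.form != "quadratic" or self.beta2 is None or self.beta2 >= 0:
            return None
        z_star = quadratic_vertex(self.beta1, self.beta2)
        return self.center + self.scale * z_star

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "response": self.response,
            "params": {k: float(v) for k, v in self.params.items()},
            "beta1": self.beta1,
            "beta2": self.beta2,
            "time_center": self.center,
            "time_scale": self.scale,
            "aic": self.aic,
            "bic": self.bic,
            "llf": self.llf,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_individuals": self.n_individuals,
            "peak_hour": self.peak_hour,
        }


def quadratic_vertex(beta1: float, beta2: float) -> float:
    """Stationary point -beta1 / (2 beta2) of beta1*t + beta2*t^2."""
    if beta2 == 0:
        raise ValueError("vertex undefined for beta2 = 0")
    return -beta1 / (2.0 * beta2)


def _prepare(df: pd.DataFrame, response: str, interval: IntervalSpec) -> tuple[pd.DataFrame, float, float]:
    d = df.dropna(subset=[response]).copy()
    hour = interval.hour_of_interval(d["interval_index"].to_numpy())
    center = float(hour.mean())
    scale = float(hour.std())
    if scale == 0:
        raise ValueError("time covariate has zero variance")
    d["_z"] = (hour - center) / scale
    d["_z2"] = d["_z"] ** 2
    return d, center, scale


def _covariate_terms(d: pd.DataFrame, use: bool) -> str:
    if not use:
        return ""
    terms = []
    for col in ("mother_id", "tank_position", "tank_system"):
        if col in d.columns and d[col].nunique() > 1:
            terms.append(f" + C({col})")
    return "".join(terms)


def fit_arc_models(
    df: pd.DataFrame,
    response: str = "entropy_nats",
    form: str = "quadratic",
    interval: IntervalSpec = IntervalSpec("hour"),
    covariates: bool = True,
) -> ArcFit:
    """Fit one linear or quadratic mixed model of a plasticity response.

    Time enters standardized (centered at the mean observation hour and
    scaled by its sd) for numerical stability of the quadratic random
    effects.  Random-effect structure per individual: intercept + slope
    (linear) or intercept + slope + quadratic (quadratic), unstructured
    covariance.  Fits use maximum likelihood so AIC/BIC are comparable
    across the two mean structures.  A non-converged fit is returned
    flagged, never silently.
    """
    if form not in ("linear", "quadratic"):
        raise ValueError("form must be 'linear' or 'quadratic'")
    d, center, scale = _prepare(df, response, interval)
    n_ind = d["individual_id"].nunique()
    if n_ind < 5:
        raise ValueError("need at least 5 individuals for a mixed arc model")
    cov_terms = _covariate_terms(d, covariates)
    if form == "quadratic":
        formula = f"{response} ~ _z + _z2{cov_terms}"
        re_formula = "~_z + _z2"
    else:
        formula = f"{response} ~ _z{cov_terms}"
        re_formula = "~_z"
    model = smf.mixedlm(formula, d, groups=d["individual_id"], re_formula=re_formula)
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # near-boundary variance components are routine here; convergence is
        # reported through the `converged` flag instead of warning spam
        warnings.simplefilter("ignore", ConvergenceWarning)
        res = model.fit(reml=False, method="lbfgs", maxiter=500)
    converged = bool(getattr(res, "converged", False))
    if not converged:
        log.warning("%s mixed model for %s did not converge cleanly", form, response)
    return ArcFit(
        form=form,
        response=response,
        params=res.params,
        beta1=float(res.params["_z"]),
        beta2=float(res.params["_z2"]) if form == "quadratic" else None,
        center=center,
        scale=scale,
        aic=float(res.aic),
        bic=float(res.bic),
        llf=float(res.llf),
        converged=converged,
        n_obs=int(res.nobs),
        n_individuals=int(n_ind),
        re_cov=np.asarray(res.cov_re),
        bse=res.bse,
    )


@dataclass
class ModelSelection:
    """AIC/BIC comparison of the linear and quadratic arcs on the same data."""

    winner_aic: str
    winner_bic: str
    delta_aic: float  # AIC(linear) - AIC(quadratic); > 0 favors quadratic
    delta_bic: float
    agree: bool
    tie: bool

    def to_dict(self) -> dict:
        return {
            "winner_aic": self.winner_aic,
            "winner_bic": self.winner_bic,
            "delta_aic": self.delta_aic,
            "delta_bic": self.delta_bic,
            "criteria_agree": self.agree,
            "tie": self.tie,
        }


def select_model(linear_fit: ArcFit, quadratic_fit: ArcFit) -> ModelSelection:
    """Pick the arc shape by AIC (headline), reporting BIC alongside.

    When the two criteria disagree the AIC winner is reported with the
    disagreement flagged rather than hidden.
    """
    if linear_fit.response != quadratic_fit.response or linear_fit.n_obs != quadratic_fit.n_obs:
        raise ValueError("model selection requires fits on identical data")
    da = linear_fit.aic - quadratic_fit.aic
    db = linear_fit.bic - quadratic_fit.bic
    wa = "quadratic" if da > 0 else "linear"
    wb = "quadratic" if db > 0 else "linear"
    sel = ModelSelection(
        winner_aic=wa,
        winner_bic=wb,
        delta_aic=float(da),
        delta_bic=float(db),
        agree=wa == wb,
        tie=bool(da == 0),
    )
    if not sel.agree:
        log.warning(
            "AIC and BIC disagree for %s (dAIC=%.2f, dBIC=%.2f)",
            linear_fit.response,
            da,
            db,
        )
    return sel


@dataclass
class PeakEstimate:
    """Quadratic-arc vertex in observation hours with a bootstrap CI."""

    peak_hour: float | None
    ci_low: float | None
    ci_high: float | None
    n_boot: int

    def to_dict(self) -> dict:
        return {
            "peak_hour": self.peak_hour,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
        }


def peak_time(
    fit: ArcFit,
    df: pd.DataFrame,
    interval: IntervalSpec = IntervalSpec("hour"),
    n_boot: int = 500,
    seed: int = 0,
    ci: float = 0.95,
) -> PeakEstimate:
    """Peak hour of a concave quadratic arc with an individual-bootstrap CI.

    Individuals (not rows) are resampled with replacement, preserving the
    within-individual dependence, and the population quadratic is refit by
    OLS on each resample to locate its vertex; the CI is the percentile
    interval of those vertices.  Resamples whose refit curvature is
    non-negative carry no interior peak and are excluded (their fraction
    is logged).
    """
    if fit.form != "quadratic":
        raise ValueError("peak_time requires a quadratic fit")
    if fit.beta2 is None or fit.beta2 >= 0:
        return PeakEstimate(None, None, None, 0)
    d, center, scale = _prepare(df, fit.response, interval)
    inds = d["individual_id"].unique()
    groups = {i: g for i, g in d.groupby("individual_id")}
    rng = np.random.default_rng(seed)
    peaks = []
    for _ in range(n_boot):
        chosen = rng.choice(inds, size=len(inds), replace=True)
        boot = pd.concat([groups[i] for i in chosen], ignore_index=True)
        X = np.column_stack([np.ones(len(boot)), boot["_z"], boot["_z2"]])
        beta, *_ = np.linalg.lstsq(X, boot[fit.response].to_numpy(), rcond=None)
        if beta[2] < 0:
            peaks.append(center + scale * quadratic_vertex(beta[1], beta[2]))
    if len(peaks) < n_boot:
        log.info("%d/%d bootstrap resamples had no interior peak", n_boot - len(peaks), n_boot)
    alpha = (1 - ci) / 2
    lo, hi = (
        (float(np.quantile(peaks, alpha)), float(np.quantile(peaks, 1 - alpha)))
        if peaks
        else (None, None)
    )
    return PeakEstimate(peak_hour=fit.peak_hour, ci_low=lo, ci_high=hi, n_boot=len(peaks))
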