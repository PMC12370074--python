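"""Single-species, single-season occupancy model with imperfect detection.

The data unit is an encounter history: for each cell (site) a vector of
detection (1) / non-detection (0) outcomes over up to five spatial
replicates, with unequal effort handled by skipping not-surveyed slots.
The model has a site-level habitat-use probability psi and per-replicate
detection probabilities p_j (either constant, p(.), or survey-specific,
p(survey)). The site likelihood is

    L_i = psi * prod_j p_j^{y_ij} (1-p_j)^{1-y_ij}  +  (1-psi) * I[no detection],

maximized on the logit scale by quasi-Newton iteration from multiple
starts. Standard errors come from the numerically differenced observed
information, mapped back to the probability scale by the delta method.
Also provided: conditional (site-specific) occupancy, naive occupancy,
derived habitat area, and AIC model-comparison machinery.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._util import round_half_up, sigmoid, logit

_BOUNDARY_LOGIT = 10.0  # |logit| beyond this is treated as a boundary estimate


@dataclass
class SingleModelSpec:
    """Model structure: psi(.) with p(.) or p(survey)."""

    detection_structure: str = "survey_specific"  # or "constant"
    max_replicates: int = 5

    def __post_init__(self):
        if self.detection_structure not in ("constant", "survey_specific"):
            raise ValueError("detection_structure must be 'constant' or 'survey_specific'")

    @property
    def k(self) -> int:
        return 1 + (1 if self.detection_structure == "constant" else self.max_replicates)

    @property
    def label(self) -> str:
        return "psi(.),p(.)" if self.detection_structure == "constant" else "psi(.),p(survey)"


@dataclass
class OccupancyFit:
    """MLEs, uncertainty and information-criterion bookkeeping for one model."""

    model: str
    species: str
    psi: float
    psi_se: float
    p: np.ndarray
    p_se: np.ndarray
    log_lik: float
    k: int
    n_sites: int
    converged: bool
    boundary: bool

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_lik

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.k

    @property
    def label(self) -> str:
        return self.model


def site_likelihood(history_row, psi: float, p_vector) -> float:
    """Likelihood of one site's history; reference (scalar) implementation.

    Not-surveyed slots (NaN) contribute no factor. Used directly by the
    enumeration tests; the fitter uses an equivalent vectorized form.
    """
    if not 0 <= psi <= 1:
        raise ValueError("psi must lie in [0, 1]")
    p = np.asarray(p_vector, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("detection probabilities must lie in [0, 1]")
    y = np.asarray(history_row, dtype=float)
    mask = ~np.isnan(y)
    yo = y[mask]
    po = p[: len(y)][mask]
    occ = psi * float(np.prod(np.where(yo == 1, po, 1 - po)))
    return occ + (1 - psi) * float(np.all(yo == 0))


def _aggregate(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique encounter-history rows and their multiplicities."""
    enc = np.where(np.isnan(values), -1, values).astype(np.int8)
    uniq, counts = np.unique(enc, axis=0, return_counts=True)
    return uniq, counts


def _nll_factory(values: np.ndarray, constant_p: bool):
    uniq, counts = _aggregate(values)
    mask = uniq >= 0
    y1 = uniq == 1
    no_det = ~(y1.any(axis=1))
    n_rep = values.shape[1]

    def nll(theta: np.ndarray) -> float:
        psi = sigmoid(theta[0])
        p = sigmoid(theta[1:])
        if constant_p:
            p = np.repeat(p, n_rep)
        logp = np.log(np.clip(p, 1e-300, 1))
        log1mp = np.log(np.clip(1 - p, 1e-300, 1))
        site_logdet = np.where(mask, np.where(y1, logp, log1mp), 0.0).sum(axis=1)
        lik = psi * np.exp(site_logdet) + (1 - psi) * no_det
        return -float(np.dot(counts, np.log(np.clip(lik, 1e-300, None))))

    return nll


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def fit(
    history,
    spec: SingleModelSpec | None = None,
    n_random_starts: int = 10,
    seed: int = 0,
    compute_se: bool = True,
) -> OccupancyFit:
    """Maximum-likelihood fit of the occupancy model to one encounter history.

    Optimizes on the logit scale (quasi-Newton, gradient tolerance 1e-8)
    from a naive-occupancy-based start plus ``n_random_starts`` seeded
    random starts, keeping the best optimum. Boundary estimates are
    reported with SEs flagged NaN rather than raising.
    """
    spec = spec or SingleModelSpec()
    values = np.asarray(history.values, dtype=float)
    if values.ndim != 2:
        raise ValueError("history.values must be a 2-D matrix")
    n_sites = values.shape[0]
    n_par = spec.k
    constant_p = spec.detection_structure == "constant"
    nll = _nll_factory(values, constant_p)

    naive = naive_occupancy(history)
    det_rate = float(np.nanmean(values)) if np.isfinite(np.nanmean(values)) else 0.0
    psi0 = np.clip(naive * 1.5 + 0.02, 0.02, 0.98)
    p0 = np.clip(det_rate / max(psi0, 1e-3), 0.02, 0.9)
    starts = [np.concatenate([[logit(psi0)], np.full(n_par - 1, logit(p0))])]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(rng.uniform(-2.5, 2.5, size=n_par))

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", options={"gtol": 1e-8, "maxiter": 500})
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("occupancy fit failed to converge from any start")

    theta = best.x
    psi_hat = float(sigmoid(theta[0]))
    p_hat = sigmoid(theta[1:])
    if constant_p:
        p_hat = np.repeat(p_hat, spec.max_replicates)
    boundary = bool(np.any(np.abs(theta) > _BOUNDARY_LOGIT))

    psi_se = np.nan
    p_se = np.full(spec.max_replicates, np.nan)
    if compute_se and not boundary:
        try:
            hess = _numeric_hessian(nll, theta)
            cov = np.linalg.inv(hess)
            d = np.sqrt(np.clip(np.diag(cov), 0, None))
            psi_se = float(psi_hat * (1 - psi_hat) * d[0])
            raw = sigmoid(theta[1:]) * (1 - sigmoid(theta[1:])) * d[1:]
            p_se = np.repeat(raw, spec.max_replicates) if constant_p else raw
        except np.linalg.LinAlgError:
            pass

    return OccupancyFit(
        model=spec.label,
        species=getattr(history, "species", ""),
        psi=psi_hat,
        psi_se=psi_se,
        p=np.asarray(p_hat, dtype=float),
        p_se=np.asarray(p_se, dtype=float),
        log_lik=-float(best.fun),
        k=n_par,
        n_sites=n_sites,
        converged=any_success,
        boundary=boundary,
    )


def conditional_psi(fit: OccupancyFit, history) -> np.ndarray:
    """Per-site probability of use given its observed history.

    Sites with at least one detection are used with certainty; for
    never-detected sites the probability is the Bayes update of psi by the
    site's surveyed non-detections.
    """
    values = np.asarray(history.values, dtype=float)
    detected = np.nansum(values, axis=1) > 0
    mask = ~np.isnan(values)
    prod_miss = np.prod(np.where(mask, 1 - fit.p[None, : values.shape[1]], 1.0), axis=1)
    cond = fit.psi * prod_miss / (1 - fit.psi + fit.psi * prod_miss)
    return np.where(detected, 1.0, cond)


def naive_occupancy(history) -> float:
    """Proportion of surveyed sites with at least one detection."""
    values = np.asarray(history.values, dtype=float)
    if values.shape[0] == 0:
        raise ValueError("history has no sites")
    return float(np.mean(np.nansum(values, axis=1) > 0))


def percent_increase(psi_hat: float, naive: float) -> float:
    """Percent increase of the model estimate over the naive proportion."""
    if naive <= 0:
        raise ValueError("naive occupancy must be positive")
    return round_half_up(100.0 * (psi_hat - naive) / naive, 0)


def area_used(psi_hat: float, total_area_km2: float) -> float:
    """Estimated habitat area used: psi_hat x available area, in km^2."""
    if total_area_km2 <= 0:
        raise ValueError("total area must be positive")
    return round_half_up(psi_hat * total_area_km2, 2)


def aic_table(fits: list, competing_delta: float = 2.0) -> pd.DataFrame:
    """Model-comparison table: AIC, deltaAIC, Akaike weights, deviance.

    Accepts fit objects (anything with ``label``, ``log_lik`` and ``k``
    attributes) or ``(label, log_lik, k)`` tuples. Models with deltaAIC
    below ``competing_delta`` are flagged as competing.
    """
    if not fits:
        raise ValueError("at least one fitted model is required")
    rows = []
    for f in fits:
        if isinstance(f, tuple):
            label, log_lik, k = f
        else:
            label, log_lik, k = f.label, f.log_lik, f.k
        dev = -2.0 * log_lik
        rows.append({"model": label, "aic": dev + 2 * k, "k": int(k), "deviance": dev})
    df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["model_likelihood"] = np.exp(-df["delta_aic"] / 2.0)
    df["weight"] = df["model_likelihood"] / df["model_likelihood"].sum()
    df["competing"] = df["delta_aic"] < competing_delta
    return df[["model", "aic", "delta_aic", "weight", "model_likelihood", "k", "deviance", "competing"]]
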