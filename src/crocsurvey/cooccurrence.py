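"""Two-species co-occurrence occupancy model (species interaction factor).

Each cell is in one of four latent states — both species present, A only,
B only, neither — with probabilities (psi_AB, psi_A - psi_AB, psi_B -
psi_AB, 1 - psi_A - psi_B + psi_AB), where psi_AB = phi * psi_A * psi_B
and phi is the species interaction factor (phi > 1: aggregation, phi = 1:
independence, phi < 1: avoidance). Detection is imperfect: where a species
occurs alone it is detected per replicate with probability p; where both
co-occur the joint replicate outcome has P(both detected) = delta * r_A *
r_B with margins r_A, r_B (delta is the detection interaction factor).

Internally the likelihood is parameterized in conditional form — psi_A,
psi_{B|A present}, psi_{B|A absent} for occupancy, and r_A, P(B detected |
A detected), P(B detected | A not detected) for co-presence detection —
which is unconstrained on the logit scale and automatically satisfies
every feasibility bound; phi, delta and psi_AB are derived quantities with
delta-method standard errors, and the phi confidence interval is Wald on
the log scale. This matches the published model structure: the
unconstrained form has K = 8 parameters, the phi = 1 (independence) form
K = 7, the p = r constrained form K = 6.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._util import sigmoid, logit
from .occupancy import _numeric_hessian, aic_table

BOTH, A_ONLY, B_ONLY, NEITHER = 0, 1, 2, 3
_BOUNDARY_LOGIT = 10.0


@dataclass
class PairParams:
    """Natural-scale parameters of the two-species model.

    Detection entries may be scalars (constant across replicates, the
    fitted form) or per-replicate vectors (as in the synthetic generator).
    """

    psi_A: float
    psi_B: float
    phi: float
    p_A: float | np.ndarray
    p_B: float | np.ndarray
    r_A: float | np.ndarray = None
    r_B: float | np.ndarray = None
    delta: float = 1.0

    def __post_init__(self):
        if self.r_A is None:
            self.r_A = self.p_A
        if self.r_B is None:
            self.r_B = self.p_B

    def _rep(self, name: str, j: int) -> float:
        v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
        return float(v[j]) if len(v) > 1 else float(v[0])


def state_probs(psi_A: float, psi_B: float, phi: float) -> np.ndarray:
    """Four-state probabilities (both, A-only, B-only, neither); sums to 1."""
    for name, v in (("psi_A", psi_A), ("psi_B", psi_B)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    psi_ab = phi * psi_A * psi_B
    if psi_ab > min(psi_A, psi_B) + 1e-12:
        raise ValueError(
            "violated bound phi*psi_A*psi_B <= min(psi_A, psi_B): joint occupancy "
            "cannot exceed either marginal"
        )
    if 1 - psi_A - psi_B + psi_ab < -1e-12:
        raise ValueError(
            "violated bound 1 - psi_A - psi_B + phi*psi_A*psi_B >= 0: the "
            "neither-species state probability is negative"
        )
    v = np.array([psi_ab, psi_A - psi_ab, psi_B - psi_ab, 1 - psi_A - psi_B + psi_ab])
    return np.clip(v, 0.0, 1.0)


def replicate_probs(state: int, y_A: int, y_B: int, params: PairParams, j: int = 0) -> float:
    """Probability of the joint replicate outcome (y_A, y_B) in a latent state.

    An absent species cannot be detected (no false positives).
    """
    if state == BOTH:
        ra, rb = params._rep("r_A", j), params._rep("r_B", j)
        p11 = params.delta * ra * rb
        table = {
            (1, 1): p11,
            (1, 0): ra - p11,
            (0, 1): rb - p11,
            (0, 0): 1 - ra - rb + p11,
        }
        prob = table[(y_A, y_B)]
        if prob < -1e-12 or prob > 1 + 1e-12:
            raise ValueError("joint detection probability outside [0, 1]; delta infeasible")
        return max(prob, 0.0)
    if state == A_ONLY:
        if y_B == 1:
            return 0.0
        pa = params._rep("p_A", j)
        return pa if y_A == 1 else 1 - pa
    if state == B_ONLY:
        if y_A == 1:
            return 0.0
        pb = params._rep("p_B", j)
        return pb if y_B == 1 else 1 - pb
    if state == NEITHER:
        return float(y_A == 0 and y_B == 0)
    raise ValueError(f"unknown latent state {state!r}")


def pair_site_likelihood(row_A, row_B, params: PairParams) -> float:
    """Likelihood of one cell's joint history; reference implementation.

    Sums over the four latent states the state probability times the
    product of replicate outcome probabilities; not-surveyed slots (NaN)
    contribute no factor. The fitter uses an equivalent aggregated form
    checked against this one in the tests.
    """
    ya = np.asarray(row_A, dtype=float)
    yb = np.asarray(row_B, dtype=float)
    if ya.shape != yb.shape:
        raise ValueError("the two species' rows must be aligned")
    mask = ~np.isnan(ya)
    if not np.array_equal(mask, ~np.isnan(yb)):
        raise ValueError("the two species' rows must share the survey pattern")
    sp = state_probs(params.psi_A, params.psi_B, params.phi)
    total = 0.0
    for state in (BOTH, A_ONLY, B_ONLY, NEITHER):
        prod = 1.0
        for j in np.flatnonzero(mask):
            prod *= replicate_probs(state, int(ya[j]), int(yb[j]), params, j)
            if prod == 0.0:
                break
        total += sp[state] * prod
    return float(total)


@dataclass
class PairFit:
    """MLEs and uncertainty for the two-species model."""

    label: str
    psi_A: float
    psi_B: float
    phi: float
    psi_AB: float
    p_A: float
    p_B: float
    r_A: float
    r_B: float
    delta: float
    se: dict
    phi_ci: tuple[float, float]
    log_lik: float
    k: int
    n_sites: int
    converged: bool
    boundary: bool
    data_fingerprint: str

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_lik

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.k


def _sufficient_stats(va: np.ndarray, vb: np.ndarray):
    """Aggregate joint histories to (k, sA, sB, n11) multiplicity classes.

    With detection constant across replicates these four counts are
    sufficient for the site likelihood.
    """
    mask = ~np.isnan(va)
    if not np.array_equal(mask, ~np.isnan(vb)):
        raise ValueError("the two histories must share the survey pattern")
    k = mask.sum(axis=1)
    sa = np.nansum(va, axis=1).astype(int)
    sb = np.nansum(vb, axis=1).astype(int)
    n11 = np.nansum((va == 1) & (vb == 1), axis=1).astype(int)
    stats = np.stack([k, sa, sb, n11], axis=1)
    uniq, counts = np.unique(stats, axis=0, return_counts=True)
    return uniq, counts


def _unpack(theta: np.ndarray, constrain: bool, fix_phi_1: bool) -> dict:
    i = 0
    if fix_phi_1:
        psi_a = sigmoid(theta[i]); psi_ba = psi_bb = sigmoid(theta[i + 1]); i += 2
    else:
        psi_a = sigmoid(theta[i]); psi_ba = sigmoid(theta[i + 1]); psi_bb = sigmoid(theta[i + 2]); i += 3
    if constrain:
        r_a = sigmoid(theta[i]); q1 = sigmoid(theta[i + 1]); q0 = sigmoid(theta[i + 2]); i += 3
        r_b = r_a * q1 + (1 - r_a) * q0
        p_a, p_b = r_a, r_b
    else:
        p_a = sigmoid(theta[i]); p_b = sigmoid(theta[i + 1])
        r_a = sigmoid(theta[i + 2]); q1 = sigmoid(theta[i + 3]); q0 = sigmoid(theta[i + 4]); i += 5
        r_b = r_a * q1 + (1 - r_a) * q0
    psi_b = psi_a * psi_ba + (1 - psi_a) * psi_bb
    psi_ab = psi_a * psi_ba
    phi = 1.0 if fix_phi_1 else psi_ab / max(psi_a * psi_b, 1e-300)
    p11 = r_a * q1
    delta = p11 / max(r_a * r_b, 1e-300)
    return {
        "psi_A": float(psi_a), "psi_B": float(psi_b), "psi_AB": float(psi_ab),
        "phi": float(phi), "p_A": float(p_a), "p_B": float(p_b),
        "r_A": float(r_a), "r_B": float(r_b), "delta": float(delta),
        "P11": float(p11), "P10": float(r_a * (1 - q1)),
        "P01": float((1 - r_a) * q0), "P00": float((1 - r_a) * (1 - q0)),
    }


def _nll_factory(uniq, counts, constrain: bool, fix_phi_1: bool):
    k, sa, sb, n11 = uniq.T
    n10 = sa - n11
    n01 = sb - n11
    n00 = k - sa - sb + n11
    a_clean = sb == 0  # A-only state possible only with no B detections
    b_clean = sa == 0
    none_det = (sa == 0) & (sb == 0)

    def nll(theta: np.ndarray) -> float:
        q = _unpack(theta, constrain, fix_phi_1)
        lg = lambda v: np.log(max(v, 1e-300))
        l_both = np.exp(
            n11 * lg(q["P11"]) + n10 * lg(q["P10"]) + n01 * lg(q["P01"]) + n00 * lg(q["P00"])
        )
        l_a = a_clean * np.exp(sa * lg(q["p_A"]) + (k - sa) * lg(1 - q["p_A"]))
        l_b = b_clean * np.exp(sb * lg(q["p_B"]) + (k - sb) * lg(1 - q["p_B"]))
        lik = (
            q["psi_AB"] * l_both
            + (q["psi_A"] - q["psi_AB"]) * l_a
            + (q["psi_B"] - q["psi_AB"]) * l_b
            + (1 - q["psi_A"] - q["psi_B"] + q["psi_AB"]) * none_det
        )
        return -float(np.dot(counts, np.log(np.clip(lik, 1e-300, None))))

    return nll


def _fingerprint(hist_A, hist_B) -> str:
    h = hashlib.sha256()
    for arr in (hist_A.values, hist_B.values, hist_A.cell_ids):
        h.update(np.ascontiguousarray(np.nan_to_num(arr, nan=-1.0)).tobytes())
    return h.hexdigest()[:16]


def fit_pair(
    hist_A,
    hist_B,
    constrain_p_eq_r: bool = False,
    fix_phi: float | None = None,
    n_random_starts: int = 10,
    seed: int = 0,
    compute_se: bool = True,
) -> PairFit:
    """Maximum-likelihood fit of the two-species co-occurrence model.

    ``fix_phi=1`` fits the independence model (one fewer occupancy
    parameter); ``constrain_p_eq_r`` ties detection given sole presence to
    detection given co-presence. Returns the fit with a log-scale Wald 95%
    CI for phi and delta-method SEs for all derived quantities.
    """
    if fix_phi is not None and fix_phi != 1:
        raise ValueError("only fix_phi=1 (independence) is supported")
    va = np.asarray(hist_A.values, dtype=float)
    vb = np.asarray(hist_B.values, dtype=float)
    if va.shape != vb.shape or not np.array_equal(hist_A.cell_ids, hist_B.cell_ids):
        raise ValueError("histories must be aligned on the same cells")
    for name, v in (("A", va), ("B", vb)):
        if np.nansum(v) == 0:
            raise ValueError(
                f"species {name} was never detected; fit a single-species model instead"
            )
    fix_phi_1 = fix_phi is not None
    uniq, counts = _sufficient_stats(va, vb)
    nll = _nll_factory(uniq, counts, constrain_p_eq_r, fix_phi_1)
    n_occ = 2 if fix_phi_1 else 3
    n_det = 3 if constrain_p_eq_r else 5
    n_par = n_occ + n_det

    naive_a = float(np.mean(np.nansum(va, axis=1) > 0))
    naive_b = float(np.mean(np.nansum(vb, axis=1) > 0))
    pa0 = float(np.clip(np.nanmean(va) / max(naive_a, 1e-3), 0.02, 0.9))
    pb0 = float(np.clip(np.nanmean(vb) / max(naive_b, 1e-3), 0.02, 0.9))
    la, lb = logit(np.clip(naive_a * 1.8 + 0.02, 0.02, 0.95)), logit(
        np.clip(naive_b * 1.8 + 0.02, 0.02, 0.95))
    occ0 = [la, lb] if fix_phi_1 else [la, lb, lb]
    det0 = (
        [logit(pa0), logit(pb0), logit(pb0)]
        if constrain_p_eq_r
        else [logit(pa0), logit(pb0), logit(pa0), logit(pb0), logit(pb0)]
    )
    starts = [np.array(occ0 + det0, dtype=float)]
    rng = np.random.default_rng(seed)
    for _ in range(n_random_starts):
        starts.append(rng.uniform(-2.5, 2.5, size=n_par))

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", options={"gtol": 1e-8, "maxiter": 800})
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("two-species fit failed to converge from any start")

    theta = best.x
    q = _unpack(theta, constrain_p_eq_r, fix_phi_1)
    boundary = bool(np.any(np.abs(theta) > _BOUNDARY_LOGIT))

    se: dict[str, float] = {name: np.nan for name in
                            ("psi_A", "psi_B", "phi", "psi_AB", "p_A", "p_B", "r_A", "r_B", "delta")}
    phi_ci = (np.nan, np.nan)
    if compute_se and not boundary:
        try:
            cov = np.linalg.inv(_numeric_hessian(nll, theta))

            def dm(fun) -> float:
                h = 1e-5 * (1 + np.abs(theta))
                g = np.empty_like(theta)
                for i in range(len(theta)):
                    e = np.zeros_like(theta); e[i] = h[i]
                    g[i] = (fun(theta + e) - fun(theta - e)) / (2 * h[i])
                return float(np.sqrt(max(g @ cov @ g, 0.0)))

            for name in se:
                if fix_phi_1 and name == "phi":
                    se[name] = 0.0
                    continue
                se[name] = dm(lambda t, n=name: _unpack(t, constrain_p_eq_r, fix_phi_1)[n])
            if not fix_phi_1 and q["phi"] > 0:
                se_logphi = dm(
                    lambda t: float(np.log(max(_unpack(t, constrain_p_eq_r, fix_phi_1)["phi"], 1e-300)))
                )
                phi_ci = (
                    float(q["phi"] * np.exp(-1.959964 * se_logphi)),
                    float(q["phi"] * np.exp(+1.959964 * se_logphi)),
                )
        except np.linalg.LinAlgError:
            pass
    if fix_phi_1:
        phi_ci = (1.0, 1.0)

    label = "psiA,psiB,phi{},{}delta".format(
        "=1" if fix_phi_1 else "(.)", "p=r," if constrain_p_eq_r else "pA,pB,rA,rB,"
    )
    return PairFit(
        label=label,
        psi_A=q["psi_A"], psi_B=q["psi_B"], phi=q["phi"], psi_AB=q["psi_AB"],
        p_A=q["p_A"], p_B=q["p_B"], r_A=q["r_A"], r_B=q["r_B"], delta=q["delta"],
        se=se, phi_ci=phi_ci,
        log_lik=-float(best.fun), k=n_par, n_sites=va.shape[0],
        converged=any_success, boundary=boundary,
        data_fingerprint=_fingerprint(hist_A, hist_B),
    )


@dataclass
class IndependenceComparison:
    """AIC comparison of the free-phi and phi=1 models plus a verdict."""

    delta_aic: float
    weight_free: float
    weight_phi1: float
    competing: bool
    verdict: str  # co-occurrence | avoidance | independent
    table: object


def compare_independence(fit_free: PairFit, fit_phi1: PairFit) -> IndependenceComparison:
    """Compare the interaction model against forced independence.

    The verdict is 'independent' when the models compete (deltaAIC < 2) or
    the phi confidence interval overlaps 1; otherwise 'co-occurrence' for
    phi > 1 and 'avoidance' for phi < 1.
    """
    if fit_free.data_fingerprint != fit_phi1.data_fingerprint:
        raise ValueError("the two fits were not computed on the same data")
    table = aic_table([fit_free, fit_phi1])
    delta = float(abs(fit_free.aic - fit_phi1.aic))
    w = dict(zip(table["model"], table["weight"]))
    competing = delta < 2.0
    lo, hi = fit_free.phi_ci
    ci_overlaps_1 = (np.isnan(lo) or np.isnan(hi)) or (lo <= 1.0 <= hi)
    if fit_free.aic >= fit_phi1.aic or competing or ci_overlaps_1:
        verdict = "independent"
    else:
        verdict = "co-occurrence" if fit_free.phi > 1 else "avoidance"
    return IndependenceComparison(
        delta_aic=delta,
        weight_free=float(w[fit_free.label]),
        weight_phi1=float(w[fit_phi1.label]),
        competing=competing,
        verdict=verdict,
        table=table,
    )
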