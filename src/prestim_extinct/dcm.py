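"""Deterministic bilinear dynamic causal modelling for two visual regions.

The scientific question is *where* a prestimulus fluctuation expresses
itself: 16 models form a 4 x 4 factorial over which intrinsic (self) and
which extrinsic (between-region) connections the seen-prestimulus input
may modulate.  All models share identical driving inputs (prestimulus
boxcar and stimulus stick into both regions), so seen/unseen differences
can only be explained through connectivity modulation.  Each model is
inverted with variational Laplace (regularised Gauss-Newton ascent on the
free energy under Gaussian assumptions, with a noise log-precision
hyperparameter); the free energies feed softmax model posteriors, family
inference with equalised family priors, and the two-step search (intrinsic
families first, then extrinsic structure within the winning family).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from . import forward
from .config import FINE_DT, TR, HemodynamicParams

log = logging.getLogger(__name__)

INTRINSIC_LEVELS = ("both", "left", "right", "neither")
EXTRINSIC_LEVELS = ("both", "left_to_right", "right_to_left", "neither")

#: index of the modulatory (seen-prestimulus) input among the three inputs
MOD_INPUT = 2


@dataclass(frozen=True)
class DCMModel:
    """One cell of the factorial: which connections the seen-prestimulus
    input may modulate."""

    intrinsic_level: str
    extrinsic_level: str
    index: int = -1

    def __post_init__(self) -> None:
        if self.intrinsic_level not in INTRINSIC_LEVELS:
            raise ValueError(f"unknown intrinsic level {self.intrinsic_level!r}")
        if self.extrinsic_level not in EXTRINSIC_LEVELS:
            raise ValueError(f"unknown extrinsic level {self.extrinsic_level!r}")

    @property
    def name(self) -> str:
        return f"int-{self.intrinsic_level}_ext-{self.extrinsic_level}"

    def b_mask(self) -> np.ndarray:
        """2x2 boolean mask of modulable connections (row = target region,
        col = source region; region 0 = left, 1 = right)."""
        m = np.zeros((2, 2), dtype=bool)
        m[0, 0] = self.intrinsic_level in ("both", "left")
        m[1, 1] = self.intrinsic_level in ("both", "right")
        m[1, 0] = self.extrinsic_level in ("both", "left_to_right")
        m[0, 1] = self.extrinsic_level in ("both", "right_to_left")
        return m


@dataclass
class ModelSpace:
    """The 16-model factorial with its two family partitions."""

    models: list[DCMModel]
    intrinsic_families: dict[str, list[int]]
    extrinsic_families: dict[str, list[int]]


def enumerate_model_space() -> ModelSpace:
    """All 16 (intrinsic, extrinsic) combinations in deterministic order."""
    models = []
    for i, intr in enumerate(INTRINSIC_LEVELS):
        for j, extr in enumerate(EXTRINSIC_LEVELS):
            models.append(DCMModel(intr, extr, index=4 * i + j))
    intr_fam = {
        lev: [m.index for m in models if m.intrinsic_level == lev]
        for lev in INTRINSIC_LEVELS
    }
    extr_fam = {
        lev: [m.index for m in models if m.extrinsic_level == lev]
        for lev in EXTRINSIC_LEVELS
    }
    return ModelSpace(models, intr_fam, extr_fam)


# --------------------------------------------------------------------------
# priors and parameter packing
# --------------------------------------------------------------------------

_A_ENTRIES = [(0, 0), (1, 1), (0, 1), (1, 0)]
_C_ENTRIES = [(0, 0), (1, 0), (0, 1), (1, 1)]  # (region, input) for inputs 1-2


@dataclass
class DCMPriors:
    """Gaussian shrinkage priors over the free parameters of one model."""

    names: list[str]
    mu0: np.ndarray
    var0: np.ndarray
    lambda0: float = 0.0  # prior mean of observation log-precision
    v_lambda0: float = 1.0  # and its prior variance
    a_diag_mean: float = -0.5

    def precision(self) -> np.ndarray:
        return np.diag(1.0 / self.var0)


def default_priors(
    model: DCMModel,
    a_diag_var: float = 1.0 / 256,
    a_off_var: float = 1.0 / 16,
    b_var: float = 1.0 / 16,
    c_var: float = 1.0,
    hemo_var: float = 1.0 / 64,
) -> DCMPriors:
    """Shrinkage priors: A diagonal around -0.5 Hz (tight), off-diagonal
    and modulations around 0, small log-scaling freedom on kappa and tau."""
    names: list[str] = []
    mu0: list[float] = []
    var0: list[float] = []
    for i, j in _A_ENTRIES:
        names.append(f"A[{i},{j}]")
        mu0.append(-0.5 if i == j else 0.0)
        var0.append(a_diag_var if i == j else a_off_var)
    mask = model.b_mask()
    for i, j in _A_ENTRIES:
        if mask[i, j]:
            names.append(f"B3[{i},{j}]")
            mu0.append(0.0)
            var0.append(b_var)
    for i, j in _C_ENTRIES:
        names.append(f"C[{i},{j}]")
        mu0.append(0.0)
        var0.append(c_var)
    for pname in ("kappa", "tau"):
        for r in range(2):
            names.append(f"log_scale_{pname}[{r}]")
            mu0.append(0.0)
            var0.append(hemo_var)
    return DCMPriors(names, np.array(mu0), np.array(var0))


def unpack_theta(theta: np.ndarray, model: DCMModel):
    """theta -> (A, B-list, C, hemo log-scales (2 x 2: kappa row, tau row))."""
    A = np.zeros((2, 2))
    k = 0
    for i, j in _A_ENTRIES:
        A[i, j] = theta[k]
        k += 1
    B3 = np.zeros((2, 2))
    mask = model.b_mask()
    for i, j in _A_ENTRIES:
        if mask[i, j]:
            B3[i, j] = theta[k]
            k += 1
    C = np.zeros((2, 3))
    for i, j in _C_ENTRIES:
        C[i, j] = theta[k]
        k += 1
    scales = np.array([[theta[k], theta[k + 1]], [theta[k + 2], theta[k + 3]]])
    return A, [np.zeros((2, 2)), np.zeros((2, 2)), B3], C, scales


def _theta_stable(theta: np.ndarray, model: DCMModel, margin: float = 0.0) -> bool:
    A, B, _, _ = unpack_theta(theta, model)
    for M in (A, A + B[MOD_INPUT]):
        if np.max(np.real(np.linalg.eigvals(M))) >= -margin:
            return False
    return True


def predict_bold(
    model: DCMModel,
    A: np.ndarray,
    B3: np.ndarray,
    C: np.ndarray,
    inputs: np.ndarray,
    tr: float = TR,
    fine_dt: float = FINE_DT,
    hemo: HemodynamicParams | None = None,
    hemo_scales: np.ndarray | None = None,
) -> np.ndarray:
    """Forward BOLD prediction for one model; entries of ``B3`` outside the
    model's mask are forced to zero, so masked connections can have no
    effect.  Shares the integrator with the data generator."""
    B3 = np.where(model.b_mask(), np.asarray(B3, float), 0.0)
    C = np.asarray(C, float)
    if C.shape == (2, 2):  # driving inputs only; modulatory input drives nothing
        C = np.column_stack([C, np.zeros(2)])
    hemo_arr = forward.hemo_arrays(hemo or HemodynamicParams(), 2, hemo_scales)
    return forward.predict_bold_scans(
        A,
        [np.zeros((2, 2)), np.zeros((2, 2)), B3],
        C,
        inputs,
        fine_dt,
        tr,
        hemo_arr,
        check_stability=False,
    )


def _predict_theta(theta, model, U, tr, fine_dt, hemo_base):
    A, B, C, scales = unpack_theta(theta, model)
    hemo_arr = forward.hemo_arrays(hemo_base, 2, scales)
    return forward.predict_bold_scans(
        A, B, C, U, fine_dt, tr, hemo_arr, check_stability=False
    )


# --------------------------------------------------------------------------
# variational Laplace
# --------------------------------------------------------------------------


@dataclass
class DCMFit:
    """Posterior over one model's parameters plus its evidence bound."""

    model: DCMModel
    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    names: list[str]
    free_energy: float
    log_precision: float
    trace: list[float]
    converged: bool
    predicted: np.ndarray
    n_effective: int

    def posterior(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.posterior_mean[i]), float(self.posterior_cov[i, i])

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "free_energy": self.free_energy,
            "log_precision": self.log_precision,
            "converged": self.converged,
            "parameters": {
                n: {
                    "mean": float(self.posterior_mean[i]),
                    "sd": float(np.sqrt(self.posterior_cov[i, i])),
                }
                for i, n in enumerate(self.names)
            },
        }


def _update_lambda(lam, e2, N, lam0, v0, n_steps=8, bounds=(-8.0, 12.0)):
    for _ in range(n_steps):
        pi = np.exp(lam)
        grad = -0.5 * pi * e2 + 0.5 * N - (lam - lam0) / v0
        curv = -0.5 * pi * e2 - 1.0 / v0
        lam = float(np.clip(lam - grad / curv, *bounds))
    return lam


def variational_laplace(
    data: np.ndarray,
    model: DCMModel,
    inputs: np.ndarray,
    tr: float = TR,
    fine_dt: float = FINE_DT,
    priors: Optional[DCMPriors] = None,
    hemo_base: Optional[HemodynamicParams] = None,
    confounds: Optional[np.ndarray] = None,
    max_iter: int = 128,
    f_tol: float = 1e-2,
    converge_streak: int = 4,
) -> DCMFit:
    """Invert one DCM on a two-region series.

    Gauss-Newton ascent on the variational free energy with Levenberg-style
    damping (doubled whenever a proposal would decrease F, halved on
    acceptance), finite-difference sensitivities, and interleaved Newton
    updates of the observation log-precision.  Confound columns (e.g.
    per-run constants and drift basis) are projected out of both data and
    prediction; the projector is model-independent so free energies remain
    comparable.  Proposals yielding an unstable neural system are rejected
    through the damping mechanism, never clipped.
    """
    y = np.asarray(data, float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("data must be (n_scans, 2)")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(inputs)):
        raise ValueError("data and inputs must be finite")
    n_sub = round(tr / fine_dt)
    if inputs.shape[0] != y.shape[0] * n_sub:
        raise ValueError("inputs are not time-aligned with the data")
    priors = priors or default_priors(model)
    hemo_base = hemo_base or HemodynamicParams()

    n = y.shape[0]
    if confounds is not None and confounds.size:
        Q, _ = np.linalg.qr(np.asarray(confounds, float))

        def proj(v):
            return v - Q @ (Q.T @ v)

        n_eff = 2 * (n - Q.shape[1])
    else:

        def proj(v):
            return v

        n_eff = 2 * n

    y_r = proj(y)
    mu0, var0 = priors.mu0, priors.var0
    P0 = priors.precision()
    sign0, logdet_P0 = np.linalg.slogdet(P0)
    p = len(mu0)
    h = np.maximum(1e-3 * np.sqrt(var0), 1e-4)

    def fwd(theta):
        g = _predict_theta(theta, model, inputs, tr, fine_dt, hemo_base)
        return g if np.all(np.isfinite(g)) else None

    def jacobian(theta):
        J = np.empty((2 * n, p))
        for i in range(p):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[i]
            tm[i] -= h[i]
            gp, gm = fwd(tp), fwd(tm)
            if gp is None or gm is None:
                return None
            J[:, i] = proj((gp - gm) / (2 * h[i])).ravel()
        return J

    def free_energy(dmu, e2, lam, H):
        v_lam = 1.0 / (0.5 * np.exp(lam) * e2 + 1.0 / priors.v_lambda0)
        _, logdet_H = np.linalg.slogdet(H)
        return float(
            -0.5 * np.exp(lam) * e2
            + 0.5 * n_eff * (lam - np.log(2 * np.pi))
            - 0.5 * dmu @ P0 @ dmu
            + 0.5 * (logdet_P0 - logdet_H)
            - 0.5 * (lam - priors.lambda0) ** 2 / priors.v_lambda0
            + 0.5 * np.log(v_lam / priors.v_lambda0)
        )

    mu = mu0.copy()
    lam = priors.lambda0
    g = fwd(mu)
    if g is None:
        raise RuntimeError("forward model diverged at the prior mean")
    e = (y_r - proj(g)).ravel()
    e2 = float(e @ e)
    lam = _update_lambda(lam, e2, n_eff, priors.lambda0, priors.v_lambda0)
    J = jacobian(mu)
    if J is None:
        raise RuntimeError("sensitivity evaluation diverged at the prior mean")
    H = np.exp(lam) * J.T @ J + P0
    F_cur = free_energy(mu - mu0, e2, lam, H)
    trace = [F_cur]
    predicted = g

    nu = 0.5  # Levenberg damping
    streak = 0
    converged = False
    for _ in range(max_iter):
        pi = np.exp(lam)
        grad = pi * J.T @ e - P0 @ (mu - mu0)
        Hd = H + nu * np.diag(np.diag(H))
        try:
            step = np.linalg.solve(Hd, grad)
        except np.linalg.LinAlgError:
            nu *= 2
            continue
        mu_new = mu + step
        ok = _theta_stable(mu_new, model)
        g_new = fwd(mu_new) if ok else None
        if g_new is None:
            nu = min(nu * 2, 1e8)
            continue
        e_new = (y_r - proj(g_new)).ravel()
        e2_new = float(e_new @ e_new)
        lam_new = _update_lambda(lam, e2_new, n_eff, priors.lambda0, priors.v_lambda0)
        J_new = jacobian(mu_new)
        if J_new is None:
            nu = min(nu * 2, 1e8)
            continue
        H_new = np.exp(lam_new) * J_new.T @ J_new + P0
        F_new = free_energy(mu_new - mu0, e2_new, lam_new, H_new)
        if F_new > F_cur:
            dF = F_new - F_cur
            mu, lam, e, e2, J, H, F_cur = mu_new, lam_new, e_new, e2_new, J_new, H_new, F_new
            predicted = g_new
            trace.append(F_cur)
            nu = max(nu / 2, 1e-4)
            streak = streak + 1 if dF < f_tol else 0
        else:
            nu = min(nu * 2, 1e8)
            streak += 1 if abs(F_new - F_cur) < f_tol else 0
        if streak >= converge_streak:
            converged = True
            break
    if not converged:
        log.info("model %s: not converged after %d iterations", model.name, max_iter)

    Sigma = np.linalg.inv(H)
    return DCMFit(
        model=model,
        posterior_mean=mu,
        posterior_cov=Sigma,
        names=list(priors.names),
        free_energy=F_cur,
        log_precision=lam,
        trace=trace,
        converged=converged,
        predicted=predicted,
        n_effective=n_eff,
    )


# --------------------------------------------------------------------------
# model and family comparison
# --------------------------------------------------------------------------


def compare_models(free_energies: Sequence[float] | Sequence[DCMFit]) -> np.ndarray:
    """Posterior model probabilities under a uniform prior:
    ``softmax`` of the free energies (log-sum-exp stabilised)."""
    if len(free_energies) == 0:
        raise ValueError("no fits to compare")
    F = np.array(
        [f.free_energy if isinstance(f, DCMFit) else float(f) for f in free_energies]
    )
    return np.exp(F - logsumexp(F))


def family_inference(
    model_posteriors: np.ndarray, partition: dict[str, list[int]]
) -> dict[str, float]:
    """Family posteriors with prior mass equalised across families.

    ``model_posteriors`` are posteriors under a uniform model prior; they
    are reweighted so each family carries equal prior probability (members
    of large families are down-weighted), then summed per family.
    """
    post = np.asarray(model_posteriors, float)
    idx_all = sorted(i for members in partition.values() for i in members)
    if idx_all != list(range(len(post))):
        raise ValueError("partition must cover every model exactly once")
    weighted = np.empty_like(post)
    for members in partition.values():
        weighted[members] = post[members] / len(members)
    weighted /= weighted.sum()
    return {fam: float(weighted[members].sum()) for fam, members in partition.items()}


@dataclass
class ComparisonResult:
    """Outcome of the two-step factorial family search."""

    space: ModelSpace
    free_energies: np.ndarray
    model_posteriors: np.ndarray  # uniform prior over all 16
    intrinsic_family_posteriors: dict[str, float]  # step 1
    winning_intrinsic: str
    within_family_posteriors: dict[str, float]  # step 2, over extrinsic levels
    winning_model_index: int
    fits: list[DCMFit] = field(default=None, repr=False)

    @property
    def winning_model(self) -> DCMModel:
        return self.space.models[self.winning_model_index]

    def to_dict(self) -> dict:
        return {
            "free_energies": {
                m.name: float(self.free_energies[m.index]) for m in self.space.models
            },
            "model_posteriors": {
                m.name: float(self.model_posteriors[m.index]) for m in self.space.models
            },
            "intrinsic_family_posteriors": self.intrinsic_family_posteriors,
            "winning_intrinsic_family": self.winning_intrinsic,
            "within_family_posteriors": self.within_family_posteriors,
            "winning_model": self.winning_model.name,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def _argmax_with_tiebreak(values: dict[str, float], what: str) -> str:
    keys = list(values)
    arr = np.array([values[k] for k in keys])
    best = float(arr.max())
    ties = [k for k, v in zip(keys, arr) if abs(v - best) < 1e-12]
    if len(ties) > 1:
        warnings.warn(
            f"{what} posterior tie between {ties}; picking the first in "
            "enumeration order",
            stacklevel=3,
        )
    return ties[0]


def two_step_search(
    data: np.ndarray,
    inputs: np.ndarray,
    tr: float = TR,
    fine_dt: float = FINE_DT,
    space: Optional[ModelSpace] = None,
    hemo_base: Optional[HemodynamicParams] = None,
    confounds: Optional[np.ndarray] = None,
    priors_factory=default_priors,
    keep_fits: bool = True,
    **vl_kwargs,
) -> ComparisonResult:
    """Fit all 16 models once, then (1) compare intrinsic families
    (averaging over extrinsic uncertainty), (2) compare the four extrinsic
    variants inside the winning intrinsic family."""
    space = space or enumerate_model_space()
    fits = []
    for m in space.models:
        log.info("inverting model %s (%d/%d)", m.name, m.index + 1, len(space.models))
        fits.append(
            variational_laplace(
                data,
                m,
                inputs,
                tr=tr,
                fine_dt=fine_dt,
                priors=priors_factory(m),
                hemo_base=hemo_base,
                confounds=confounds,
                **vl_kwargs,
            )
        )
    F = np.array([f.free_energy for f in fits])
    post = compare_models(F)
    fam_post = family_inference(post, space.intrinsic_families)
    win_fam = _argmax_with_tiebreak(fam_post, "intrinsic family")
    members = space.intrinsic_families[win_fam]
    within = compare_models(F[members])
    within_post = {
        space.models[m].extrinsic_level: float(q) for m, q in zip(members, within)
    }
    win_ext = _argmax_with_tiebreak(within_post, "extrinsic model")
    win_idx = next(
        m
        for m in members
        if space.models[m].extrinsic_level == win_ext
    )
    return ComparisonResult(
        space=space,
        free_energies=F,
        model_posteriors=post,
        intrinsic_family_posteriors=fam_post,
        winning_intrinsic=win_fam,
        within_family_posteriors=within_post,
        winning_model_index=win_idx,
        fits=fits if keep_fits else None,
    )


# --------------------------------------------------------------------------
# connectivity report
# --------------------------------------------------------------------------

_CONNECTIONS = [
    ("left_self", 0, 0),
    ("right_self", 1, 1),
    ("left_to_right", 1, 0),
    ("right_to_left", 0, 1),
]


def connectivity_report(fit: DCMFit) -> "pd.DataFrame":
    """Baseline (A) vs seen-prestimulus (A + B) connection strengths.

    For intrinsic connections, reports the percent change in
    self-inhibition, ``-100 * B_ii / A_ii`` (undefined when ``A_ii`` is 0);
    for extrinsic connections, whether the modulation switches the sign of
    the coupling (e.g. mildly inhibitory at baseline to excitatory before
    seen trials).
    """
    import pandas as pd

    if not fit.converged:
        warnings.warn("reporting from a non-converged fit", stacklevel=2)
    A, B, _, _ = unpack_theta(fit.posterior_mean, fit.model)
    B3 = B[MOD_INPUT]
    rows = []
    for name, i, j in _CONNECTIONS:
        a, b = float(A[i, j]), float(B3[i, j])
        row = {
            "connection": name,
            "baseline": a,
            "modulation": b,
            "modulated": a + b,
        }
        if i == j:
            row["self_inhibition_change_pct"] = (
                None if a == 0 else -100.0 * b / a
            )
            row["sign_switch"] = None
        else:
            row["self_inhibition_change_pct"] = None
            row["sign_switch"] = bool(np.sign(a) != np.sign(a + b) and b != 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
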