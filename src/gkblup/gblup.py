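"""Bayesian GBLUP with kernel-structured line and G-by-E random effects.

The observation model for line j in environment i is

    y_ij = mu + E_i + g_j + gE_ij + eps_ij

with g ~ N(0, var_g * K), the genotype-by-environment effects
gE ~ N(0, var_ge * Omega) where Omega = (Z_E Z_E') .* (Z_g K Z_g') (Hadamard
product of the environment- and line-incidence expansions of K), and iid
Gaussian noise. Environment effects are parameterized as sum-to-zero
deviations so the intercept stays identifiable; mu, E and all three variance
components get the usual flat / scaled-inverse-chi-square priors and the
model is fit by Gibbs sampling (see ``_sampler``).

Held-out records are predicted by the Rao-Blackwellized rule: for each
retained draw the conditional mean of the test-record random effects given
the training-record effects is a fixed linear map of the draw, so the
posterior-mean prediction is that map applied to the posterior-mean
coordinates.

``conditional_mean_oracle`` is the closed-form Gaussian conditional mean at
fixed variance components; it serves as an independent check on the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from ._sampler import gibbs_chain
from .kernels import PSD_TOL, KernelMatrix

__all__ = [
    "DesignMatrices",
    "ModelSpec",
    "ModelFit",
    "build_design",
    "build_gxe_covariance",
    "fit_gibbs",
    "predict",
    "conditional_mean_oracle",
]

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class DesignMatrices:
    """0/1 incidence of records onto environments (Z_E) and lines (Z_g)."""

    Z_E: np.ndarray
    Z_g: np.ndarray
    env_labels: tuple
    line_ids: tuple

    def __post_init__(self):
        Z_E = np.asarray(self.Z_E, dtype=float)
        Z_g = np.asarray(self.Z_g, dtype=float)
        for Z, name in ((Z_E, "Z_E"), (Z_g, "Z_g")):
            if Z.ndim != 2:
                raise ValueError(f"{name} must be 2-dimensional")
            if not np.all((Z == 0) | (Z == 1)):
                raise ValueError(f"{name} must be a 0/1 incidence matrix")
            if not np.all(Z.sum(axis=1) == 1):
                raise ValueError(f"every row of {name} must have exactly one 1")
        if Z_E.shape[0] != Z_g.shape[0]:
            raise ValueError("Z_E and Z_g must have the same number of records")
        object.__setattr__(self, "Z_E", Z_E)
        object.__setattr__(self, "Z_g", Z_g)
        object.__setattr__(self, "env_labels", tuple(self.env_labels))
        object.__setattr__(self, "line_ids", tuple(self.line_ids))

    @property
    def n_records(self) -> int:
        return self.Z_E.shape[0]


def build_design(phenotypes: pd.DataFrame, line_ids, env_labels=None) -> DesignMatrices:
    """Incidence matrices for long-format records against a line ordering."""
    lines = tuple(str(l) for l in line_ids)
    line_pos = {l: i for i, l in enumerate(lines)}
    if env_labels is None:
        env_labels = tuple(sorted(phenotypes["env"].astype(str).unique()))
    else:
        env_labels = tuple(str(e) for e in env_labels)
    env_pos = {e: i for i, e in enumerate(env_labels)}
    n = len(phenotypes)
    Z_E = np.zeros((n, len(env_labels)))
    Z_g = np.zeros((n, len(lines)))
    for r, (l, e) in enumerate(zip(phenotypes["line"].astype(str),
                                   phenotypes["env"].astype(str))):
        if l not in line_pos:
            raise KeyError(f"phenotyped line {l!r} absent from kernel lines")
        if e not in env_pos:
            raise KeyError(f"environment {e!r} absent from environment labels")
        Z_E[r, env_pos[e]] = 1.0
        Z_g[r, line_pos[l]] = 1.0
    return DesignMatrices(Z_E=Z_E, Z_g=Z_g, env_labels=env_labels, line_ids=lines)


def build_gxe_covariance(Z_E: np.ndarray, Z_g: np.ndarray, K: KernelMatrix | np.ndarray) -> np.ndarray:
    """G-by-E covariance structure Omega = (Z_E Z_E') .* (Z_g K Z_g')."""
    Km = K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    Z_E = np.asarray(Z_E, dtype=float)
    Z_g = np.asarray(Z_g, dtype=float)
    if Z_E.shape[0] != Z_g.shape[0]:
        raise ValueError("Z_E and Z_g disagree on the number of records")
    if Z_g.shape[1] != Km.shape[0]:
        raise ValueError(
            f"Z_g has {Z_g.shape[1]} line columns but K is {Km.shape[0]}x{Km.shape[1]}"
        )
    return (Z_E @ Z_E.T) * (Z_g @ Km @ Z_g.T)


@dataclass(frozen=True)
class ModelSpec:
    """MCMC and prior settings for the Gibbs sampler.

    ``prior_R2`` is the proportion of phenotypic variance assigned a priori to
    the random terms, split equally between the line and G-by-E effects; each
    variance gets a scaled-inverse-chi-square prior with ``prior_df`` degrees
    of freedom whose mode matches that allocation (the convention of standard
    Bayesian genomic-prediction software).
    """

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    prior_df: float = 5.0
    prior_R2: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.burn_in) // self.thin < 1:
            raise ValueError("chain settings retain no draws")
        if self.prior_df <= 0:
            raise ValueError("prior_df must be positive")
        if not 0.0 < self.prior_R2 < 1.0:
            raise ValueError("prior_R2 must lie in (0, 1)")


@dataclass
class ModelFit:
    """Posterior summaries and the state needed to predict new records."""

    mu_hat: float
    env_effects: pd.Series
    var_g: float
    var_ge: float
    var_e: float
    yhat_train: np.ndarray
    samples: pd.DataFrame
    spec: ModelSpec
    # prediction state (internal record order)
    _beta_mean: np.ndarray = field(repr=False, default=None)
    _d1_mean: np.ndarray = field(repr=False, default=None)
    _d2_mean: np.ndarray = field(repr=False, default=None)
    _T1: np.ndarray = field(repr=False, default=None)
    _T2: np.ndarray = field(repr=False, default=None)
    _rec_lines: tuple = field(repr=False, default=None)
    _rec_envs: tuple = field(repr=False, default=None)
    _env_labels: tuple = field(repr=False, default=None)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _env_design(envs, env_labels) -> np.ndarray:
    """Intercept + sum-to-zero environment contrasts."""
    I = len(env_labels)
    pos = {e: i for i, e in enumerate(env_labels)}
    X = np.zeros((len(envs), I))
    X[:, 0] = 1.0
    last = I - 1
    for r, e in enumerate(envs):
        i = pos[e]
        if i < last:
            X[r, 1 + i] = 1.0
        else:
            X[r, 1:] = -1.0
    return X


def _beta_to_env_effects(beta, env_labels) -> pd.Series:
    I = len(env_labels)
    if I == 1:
        return pd.Series([0.0], index=list(env_labels))
    alpha = beta[1:I]
    eff = np.concatenate([alpha, [-alpha.sum()]])
    return pd.Series(eff, index=list(env_labels))


def _truncated_eigh(C, name):
    evals, evecs = np.linalg.eigh(C)
    top = max(float(evals[-1]), 0.0)
    if evals[0] < -PSD_TOL * max(1.0, top):
        raise ValueError(
            f"{name} covariance is not positive semidefinite "
            f"(min eigenvalue {evals[0]:.3e})"
        )
    keep = evals > _RANK_TOL * max(top, 1.0)
    return evecs[:, keep], evals[keep]


def _balanced_layout(lines, envs, line_order, env_labels):
    """Return (line_index, env_index) arrays if every line has exactly one
    record in every environment, else None."""
    lpos = {l: i for i, l in enumerate(line_order)}
    epos = {e: i for i, e in enumerate(env_labels)}
    li = np.array([lpos[l] for l in lines])
    ei = np.array([epos[e] for e in envs])
    counts = np.zeros((len(env_labels), len(line_order)), dtype=int)
    np.add.at(counts, (ei, li), 1)
    if np.all(counts == 1):
        return li, ei
    return None


def fit_gibbs(
    phenotypes: pd.DataFrame,
    K: KernelMatrix,
    spec: ModelSpec,
    design: DesignMatrices | None = None,
    method: str = "auto",
) -> ModelFit:
    """Fit the kernel GBLUP by Gibbs sampling.

    ``phenotypes`` is a long-format frame with columns ``line``, ``env``,
    ``value``; every line must be present in ``K``. The fit is bit-identical
    for identical inputs and ``spec.seed``.

    ``method`` selects the sampler internals: ``"balanced"`` uses the shared
    Kronecker eigenbasis (requires every line observed once per environment),
    ``"general"`` the per-covariance eigenbases, and ``"auto"`` (default)
    picks the former whenever the layout allows. Both sample the same
    posterior.
    """
    if method not in ("auto", "balanced", "general"):
        raise ValueError(f"unknown method {method!r}")
    ph = phenotypes.reset_index(drop=True)
    for col in ("line", "env", "value"):
        if col not in ph.columns:
            raise ValueError(f"phenotypes missing required column {col!r}")
    y_all = np.asarray(ph["value"], dtype=float)
    if np.isnan(y_all).any():
        raise ValueError("training phenotypes contain missing values")
    rec_lines = [str(l) for l in ph["line"]]
    rec_envs = [str(e) for e in ph["env"]]
    kset = set(K.line_ids)
    for l in rec_lines:
        if l not in kset:
            raise KeyError(f"phenotyped line {l!r} absent from kernel")
    # training lines in kernel order; environments sorted
    train_lines = [l for l in K.line_ids if l in set(rec_lines)]
    if design is not None:
        env_labels = design.env_labels
    else:
        env_labels = tuple(sorted(set(rec_envs)))
    I = len(env_labels)
    Jt = len(train_lines)
    n = len(ph)

    Ktr = K.subset(train_lines).K
    rng = np.random.default_rng(spec.seed)

    bal = None
    if method != "general":
        bal = _balanced_layout(rec_lines, rec_envs, train_lines, env_labels)
        if bal is None and method == "balanced":
            raise ValueError(
                "balanced sampler requires every line observed exactly once "
                "in every environment"
            )
    if bal is not None:
        li, ei = bal
        order = np.lexsort((li, ei))  # env-major, line-minor
        evals, evecs = np.linalg.eigh(Ktr)
        top = max(float(evals[-1]), 0.0)
        if evals[0] < -PSD_TOL * max(1.0, top):
            raise ValueError(
                f"kernel not positive semidefinite (min eigenvalue {evals[0]:.3e})"
            )
        keep = evals > _RANK_TOL * max(top, 1.0)
        U = evecs[:, keep]
        S = evals[keep]
        r = len(S)
        # orthonormal Q with first column proportional to 1/sqrt(I)
        A = np.concatenate([np.full((I, 1), 1.0 / np.sqrt(I)), np.eye(I)[:, : I - 1]], axis=1)
        Q, _ = np.linalg.qr(A)
        V1 = np.kron(Q[:, :1], U)          # n x r
        lam1 = I * S
        V2 = np.kron(Q, U)                  # n x (I*r)
        lam2 = np.tile(S, I)
        M = np.zeros((1, 1))                # unused: selector path
        MT = np.zeros((1, 1))
        selector = True
        mean_diag_c1 = float(np.mean(np.diag(Ktr)))
    else:
        order = np.arange(n)
        dsg = design if design is not None else build_design(
            ph, train_lines, env_labels
        )
        C1 = dsg.Z_g @ Ktr @ dsg.Z_g.T
        C2 = (dsg.Z_E @ dsg.Z_E.T) * C1
        V1, lam1 = _truncated_eigh(C1, "line-effect")
        V2, lam2 = _truncated_eigh(C2, "G-by-E")
        M = np.ascontiguousarray(V1.T @ V2)
        MT = np.ascontiguousarray(M.T)
        selector = False
        mean_diag_c1 = float(np.mean(np.diag(C1)))

    y = y_all[order]
    envs_o = [rec_envs[i] for i in order]
    lines_o = [rec_lines[i] for i in order]
    X = _env_design(envs_o, env_labels)
    q = X.shape[1]

    B1 = V1.T @ y
    B2 = V2.T @ y
    A1 = np.ascontiguousarray(V1.T @ X)
    A2 = np.ascontiguousarray(V2.T @ X)
    XtX = X.T @ X
    XtXinv = np.linalg.inv(XtX)
    Lbeta = np.linalg.cholesky(XtXinv)
    Xty = X.T @ y
    yty = float(y @ y)

    vy = float(np.var(y, ddof=1)) if n > 1 else 0.0
    df0 = float(spec.prior_df)
    R2 = spec.prior_R2
    mode_scale = (df0 + 2.0) / df0
    v_each = max(vy * R2 / 2.0, 1e-8)
    S0g = max(v_each / max(mean_diag_c1, 1e-12) * mode_scale, 1e-8)
    S0ge = max(v_each * mode_scale, 1e-8)
    S0e = max(vy * (1.0 - R2) * mode_scale, 1e-8)

    beta_init, *_ = np.linalg.lstsq(X, y, rcond=None)
    vg0 = max(v_each, 1e-8)
    vge0 = vg0
    ve0 = max(vy * (1.0 - R2), 1e-8)

    m1, m2 = len(lam1), len(lam2)
    z1 = rng.standard_normal((spec.n_iter, m1))
    z2 = rng.standard_normal((spec.n_iter, m2))
    zb = rng.standard_normal((spec.n_iter, q))
    chi_g = rng.chisquare(df0 + m1, spec.n_iter)
    chi_ge = rng.chisquare(df0 + m2, spec.n_iter)
    chi_e = rng.chisquare(df0 + n, spec.n_iter)

    var_draws, beta_mean, d1_mean, d2_mean = gibbs_chain(
        B1, B2, A1, A2, lam1, lam2, M, MT, selector,
        XtX, XtXinv, Lbeta, Xty, yty,
        df0, S0g, S0ge, S0e, n,
        spec.n_iter, spec.burn_in, spec.thin,
        z1, z2, zb, chi_g, chi_ge, chi_e,
        beta_init, vg0, vge0, ve0,
    )

    s1 = np.sqrt(lam1)
    s2 = np.sqrt(lam2)
    yhat_sorted = X @ beta_mean + V1 @ (s1 * d1_mean) + V2 @ (s2 * d2_mean)
    yhat_train = np.empty(n)
    yhat_train[order] = yhat_sorted

    with np.errstate(divide="ignore"):
        T1 = V1 / s1
        T2 = V2 / s2

    samples = pd.DataFrame(var_draws, columns=["var_g", "var_ge", "var_e"])
    return ModelFit(
        mu_hat=float(beta_mean[0]),
        env_effects=_beta_to_env_effects(beta_mean, env_labels),
        var_g=float(samples["var_g"].mean()),
        var_ge=float(samples["var_ge"].mean()),
        var_e=float(samples["var_e"].mean()),
        yhat_train=yhat_train,
        samples=samples,
        spec=spec,
        _beta_mean=beta_mean,
        _d1_mean=d1_mean,
        _d2_mean=d2_mean,
        _T1=T1,
        _T2=T2,
        _rec_lines=tuple(lines_o),
        _rec_envs=tuple(envs_o),
        _env_labels=env_labels,
    )


def predict(fit: ModelFit, K: KernelMatrix, test_records: pd.DataFrame) -> pd.DataFrame:
    """Conditional-mean predictions for (line, environment) records.

    Test lines need only be present in ``K`` (genotyped); their random
    effects are obtained by projecting the posterior-mean effect coordinates
    through the kernel cross-covariances. Returns a frame with columns
    ``line``, ``env``, ``y_hat``.
    """
    test = test_records.reset_index(drop=True)
    t_lines = [str(l) for l in test["line"]]
    t_envs = [str(e) for e in test["env"]]
    for e in t_envs:
        if e not in fit._env_labels:
            raise ValueError(f"environment {e!r} was not present in training data")
    t_idx = K.index_of(t_lines)
    r_idx = K.index_of(fit._rec_lines)
    Kcross = K.K[np.ix_(t_idx, r_idx)]                      # n_test x n_train
    env_arr = np.array(fit._rec_envs)
    mask = (np.array(t_envs)[:, None] == env_arr[None, :])
    P1 = Kcross @ fit._T1
    P2 = (Kcross * mask) @ fit._T2
    X_test = _env_design(t_envs, fit._env_labels)
    y_hat = X_test @ fit._beta_mean + P1 @ fit._d1_mean + P2 @ fit._d2_mean
    return pd.DataFrame({"line": t_lines, "env": t_envs, "y_hat": y_hat})


def conditional_mean_oracle(
    y_train: np.ndarray,
    C_full: np.ndarray,
    var_e: float,
    fixed_effects: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    """Closed-form Gaussian conditional mean at fixed variance components.

    ``C_full`` is the total genetic covariance over all records (training and
    test), ``fixed_effects`` the fixed-effect surface ``m`` over all records,
    and ``test_idx`` the positions of test records. Returns

        m_test + C_ts (C_tt + var_e I)^{-1} (y_train - m_train)
    """
    C = np.asarray(C_full, dtype=float)
    m = np.asarray(fixed_effects, dtype=float)
    n_all = C.shape[0]
    test_idx = np.asarray(test_idx, dtype=int)
    train_idx = np.setdiff1d(np.arange(n_all), test_idx)
    y_train = np.asarray(y_train, dtype=float)
    if len(y_train) != len(train_idx):
        raise ValueError("y_train length does not match the training index set")
    A = C[np.ix_(train_idx, train_idx)] + var_e * np.eye(len(train_idx))
    try:
        cf = scipy.linalg.cho_factor(A)
        alpha = scipy.linalg.cho_solve(cf, y_train - m[train_idx])
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular training covariance (C + var_e I)") from exc
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("singular training covariance (C + var_e I)") from exc
    return m[test_idx] + C[np.ix_(test_idx, train_idx)] @ alpha
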