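"""Hierarchical Bayesian Poisson models for areal mortality counts.

The data model is ``Y_it | psi_it ~ Poisson(E_it * exp(psi_it))`` where E_it
are expected counts and psi_it is the latent log relative risk.  Two process
models are provided:

* spatial (single period, BYM convolution):
      psi_i = alpha + x_i' beta + mu_i + upsilon_i
* spatiotemporal (additive space-time):
      psi_it = alpha + x_it' beta + mu_i + upsilon_i + gamma_t + phi_t

with mu an intrinsic CAR (ICAR) field over the neighborhood graph (each
mu_i conditionally normal around the mean of its neighbors, precision
tau_mu * m_i), upsilon and phi iid normal heterogeneity terms, and gamma a
first-order random walk in time.  The intrinsic priors are improper; the
model is identified by sum-to-zero recentring of mu and gamma every sweep,
with the subtracted means absorbed into the intercept.

Inference is a self-contained Metropolis-within-Gibbs sampler: adaptive
random-walk Metropolis for alpha, beta and the latent fields (latent sites
are updated in vectorized blocks over a graph coloring, so no two units
updated together are neighbors), and conjugate Gamma draws for all
precisions.  Precision hyperpriors follow the logGamma(a, b)-on-log-precision
convention, implemented as Gamma(shape a, rate b) on the precision itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .areal_data import AdjacencyGraph
from .survey_aggregation import ArealPanel

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "PosteriorSamples",
    "ModelFit",
    "poisson_loglik",
    "icar_log_kernel",
    "rw1_log_kernel",
    "BymGibbsSampler",
    "fit_spatial_bym",
    "fit_spatiotemporal",
    "posterior_summaries",
    "rr_from_coefficient",
]


@dataclass
class ModelSpec:
    """Model structure and prior constants.

    Precision hyperpriors are (shape, rate) pairs of Gamma distributions on
    the precision.  ``tau0`` is the prior precision of the intercept,
    ``beta_precision`` that of each regression coefficient (default
    Normal(0, 1000) slab).
    """

    covariates: list[str] = field(default_factory=list)
    temporal: bool = True
    tau_mu_prior: tuple[float, float] = (1.0, 5e-5)
    tau_upsilon_prior: tuple[float, float] = (1.0, 5e-5)
    tau_gamma_prior: tuple[float, float] = (1.0, 1e-3)
    tau_phi_prior: tuple[float, float] = (1.0, 5e-4)
    tau0: float = 0.001
    beta_precision: float = 0.001

    def __post_init__(self) -> None:
        for name in ("tau_mu_prior", "tau_upsilon_prior", "tau_gamma_prior", "tau_phi_prior"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"{name}: shape and rate must be positive")
        if self.tau0 <= 0 or self.beta_precision <= 0:
            raise ValueError("tau0 and beta_precision must be positive")


@dataclass
class McmcConfig:
    n_iter: int = 20000
    burn_in: int = 10000
    thin: int = 5
    n_chains: int = 2
    target_accept: float = 0.44
    adapt_interval: int = 50
    initial_scale: float = 0.1
    min_ess: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @classmethod
    def smoke(cls, n_iter: int = 3000, burn_in: int = 1000, thin: int = 2) -> "McmcConfig":
        """Short single-chain settings for smoke runs and simulation studies."""
        return cls(n_iter=n_iter, burn_in=burn_in, thin=thin, n_chains=1)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws (chains concatenated) plus sampler metadata."""

    draws: dict[str, np.ndarray]  # name -> (S, ...) arrays
    psi: np.ndarray  # (S, I, T) latent log relative risk
    loglik: np.ndarray  # (S, n_included) pointwise log-likelihood
    included_cells: np.ndarray  # flat (I*T) indices of cells in the likelihood
    meta: dict

    @property
    def n_draws(self) -> int:
        return self.psi.shape[0]


@dataclass
class ModelFit:
    """Posterior summaries, smoothed relative risks and evaluation inputs."""

    samples: PosteriorSamples
    unit_ids: list[str]
    periods: list[str]
    covariate_names: list[str]
    Y: np.ndarray
    E: np.ndarray
    rr_mean: np.ndarray  # (I, T) posterior mean of exp(psi)
    rr_lower: np.ndarray
    rr_upper: np.ndarray
    loglik_at_mean: float  # plug-in log-likelihood at the posterior mean psi

    def summary(self, variance_scale: str = "variance") -> pd.DataFrame:
        """Posterior mean and central 95% credible interval per parameter.

        Variance components are the draws of 1/tau summarized on the
        variance scale, or on the natural-log scale with
        ``variance_scale="log"``.
        """
        rows = {}
        draws = self.samples.draws
        rows["intercept"] = draws["alpha"]
        for k, name in enumerate(self.covariate_names):
            rows[f"beta:{name}"] = draws["beta"][:, k]
        for tau_name, label in [
            ("tau_mu", "var_spatial_structured"),
            ("tau_upsilon", "var_spatial_iid"),
            ("tau_gamma", "var_temporal_rw1"),
            ("tau_phi", "var_temporal_iid"),
        ]:
            if tau_name in draws:
                v = 1.0 / draws[tau_name]
                rows[label] = np.log(v) if variance_scale == "log" else v
        return posterior_summaries(rows)

    def rr_frame(self) -> pd.DataFrame:
        I, T = self.rr_mean.shape
        return pd.DataFrame(
            {
                "unit_id": np.repeat(self.unit_ids, T),
                "period": np.tile(self.periods, I),
                "rr_mean": self.rr_mean.ravel(),
                "rr_lower": self.rr_lower.ravel(),
                "rr_upper": self.rr_upper.ravel(),
            }
        )


def poisson_loglik(Y, E, psi) -> np.ndarray:
    """Pointwise Poisson log-likelihood Y*(log E + psi) - E*exp(psi) - lgamma(Y+1).

    Weighted (non-integer) counts are admissible through the log-gamma term.
    Degenerate cells with E=0 and Y=0 contribute exactly zero.
    """
    Y = np.asarray(Y, dtype=float)
    E = np.asarray(E, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite linear predictor psi")
    if np.any((E <= 0) & (Y > 0)):
        raise ValueError("cell with Y > 0 requires E > 0")
    mask = E > 0
    safe_e = np.where(mask, E, 1.0)
    out = Y * (np.log(safe_e) + psi) - safe_e * np.exp(psi) - gammaln(Y + 1)
    return np.where(mask, out, 0.0)


def icar_log_kernel(mu, graph: AdjacencyGraph, tau_mu: float) -> float:
    """Log density kernel of the intrinsic CAR prior (up to a constant).

    (n - G)/2 * log(tau) - tau/2 * sum over edges (mu_i - mu_j)^2, where G is
    the number of connected components (the rank deficiency of the intrinsic
    precision).  Translation invariant within each component.
    """
    mu = np.asarray(mu, dtype=float)
    edges = graph.edges()
    if not edges:
        raise ValueError("ICAR prior needs a graph with at least one edge")
    if mu.size != graph.n_units:
        raise ValueError("mu length must equal the number of units")
    i, j = np.array(edges).T
    ss = float(((mu[i] - mu[j]) ** 2).sum())
    rank = graph.n_units - graph.n_components
    return 0.5 * rank * np.log(tau_mu) - 0.5 * tau_mu * ss


def rw1_log_kernel(gamma, tau_gamma: float) -> float:
    """Log density kernel of the first-order random-walk prior (up to a constant)."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size < 2:
        raise ValueError("RW1 prior needs at least 2 time points")
    ss = float((np.diff(gamma) ** 2).sum())
    return 0.5 * (gamma.size - 1) * np.log(tau_gamma) - 0.5 * tau_gamma * ss


def rr_from_coefficient(posterior_mean_beta: float) -> float:
    """Relative risk per unit covariate increase: exp of the coefficient."""
    if not np.isfinite(posterior_mean_beta):
        raise ValueError("coefficient must be finite")
    return float(np.exp(posterior_mean_beta))


def posterior_summaries(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Posterior mean with empirical 2.5% / 97.5% quantiles per parameter."""
    rows = []
    for name, d in draws.items():
        d = np.asarray(d, dtype=float)
        if d.size < 2:
            raise ValueError(f"{name}: need at least 2 draws")
        rows.append(
            {
                "parameter": name,
                "mean": d.mean(),
                "lower_2.5": np.percentile(d, 2.5),
                "upper_97.5": np.percentile(d, 97.5),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


class BymGibbsSampler:
    """Metropolis-within-Gibbs sampler for the BYM-type Poisson models.

    Latent fields are updated site-wise but vectorized over color classes of
    the relevant conditional-independence graph (spatial graph for mu, the
    time chain for gamma); iid blocks (upsilon, phi) update all sites at
    once.  Proposal scales adapt toward the target acceptance rate during
    burn-in only, so the post-burn-in kernel is fixed.
    """

    def __init__(
        self,
        Y: np.ndarray,
        E: np.ndarray,
        X: np.ndarray | None,
        graph: AdjacencyGraph,
        spec: ModelSpec,
        cfg: McmcConfig,
        seed: int,
    ):
        self.Y = np.asarray(Y, dtype=float)
        self.E = np.asarray(E, dtype=float)
        self.I, self.T = self.Y.shape
        self.graph = graph
        self.spec = spec
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.temporal = spec.temporal
        if self.temporal and self.T < 2:
            raise ValueError("temporal model needs at least 2 periods")
        if graph.n_units != self.I:
            raise ValueError("graph size does not match panel units")
        labels = graph.component_labels()
        sizes = np.bincount(labels)
        if (sizes < 2).any():
            bad = [graph.unit_ids[i] for i in np.flatnonzero(sizes[labels] < 2)]
            raise ValueError(f"CAR component(s) of size 1 (isolated units): {bad}")
        if np.any((self.E <= 0) & (self.Y > 0)):
            bad = np.argwhere((self.E <= 0) & (self.Y > 0))[0]
            raise ValueError(f"cell {tuple(bad)} has Y > 0 but E <= 0")
        self.mask = self.E > 0
        self.p = 0 if X is None else X.shape[2]
        self.X = np.zeros((self.I, self.T, 0)) if X is None else np.asarray(X, dtype=float)

        # graph structure for the ICAR updates
        edges = np.array(graph.edges(), dtype=int).reshape(-1, 2)
        self.edge_i, self.edge_j = edges[:, 0], edges[:, 1]
        self.W_binary = np.zeros((self.I, self.I))
        self.W_binary[self.edge_i, self.edge_j] = 1.0
        self.W_binary[self.edge_j, self.edge_i] = 1.0
        self.deg = self.W_binary.sum(axis=1)
        coloring = nx.greedy_color(graph.to_networkx(), strategy="largest_first")
        n_colors = max(coloring.values()) + 1
        self.mu_colors = [
            np.array([u for u, c in coloring.items() if c == k], dtype=int)
            for k in range(n_colors)
        ]
        self.icar_rank = self.I - graph.n_components
        self.comp_labels = graph.component_labels()
        # RW1 structure matrix: path-graph Laplacian over the T periods
        K = np.zeros((self.T, self.T))
        for t in range(self.T - 1):
            K[t, t] += 1.0
            K[t + 1, t + 1] += 1.0
            K[t, t + 1] -= 1.0
            K[t + 1, t] -= 1.0
        self._rw1_structure = K

        self._init_state()
        self._init_adaptation()

    # ---------------------------------------------------------------- state

    def _init_state(self) -> None:
        with np.errstate(divide="ignore"):
            rate = self.Y[self.mask].sum() / max(self.E[self.mask].sum(), 1e-12)
        self.alpha = float(np.log(max(rate, 1e-8)))
        self.beta = np.zeros(self.p)
        self.mu = np.zeros(self.I)
        self.ups = np.zeros(self.I)
        self.gamma = np.zeros(self.T)
        self.phi = np.zeros(self.T)
        self.tau_mu = 10.0
        self.tau_ups = 10.0
        self.tau_gamma = 10.0
        self.tau_phi = 10.0
        self._refresh_psi()

    def _refresh_psi(self) -> None:
        psi = self.alpha + self.mu[:, None] + self.ups[:, None]
        if self.p:
            psi = psi + self.X @ self.beta
        if self.temporal:
            psi = psi + self.gamma[None, :] + self.phi[None, :]
        self.psi = psi

    def _init_adaptation(self) -> None:
        s = self.cfg.initial_scale
        self.s_alpha = s
        self.s_beta = np.full(self.p, s)
        self.s_mu = np.full(self.I, s)
        self.s_ups = np.full(self.I, s)
        self.s_gamma = np.full(self.T, s)
        self.s_phi = np.full(self.T, s)
        self._acc = {k: 0.0 for k in ("alpha", "beta", "mu", "ups", "gamma", "phi")}
        self._try = {k: 0.0 for k in self._acc}
        self._batch_acc = {k: np.zeros_like(v, dtype=float) for k, v in [
            ("alpha", np.zeros(1)), ("beta", np.zeros(self.p)),
            ("mu", np.zeros(self.I)), ("ups", np.zeros(self.I)),
            ("gamma", np.zeros(self.T)), ("phi", np.zeros(self.T)),
        ]}
        self._batch_n = 0
        self._n_batches = 0
        self._scale_sigma = {k: 1.0 for k in ("mu", "ups", "gamma", "phi")}
        self._scale_acc = {k: 0 for k in self._scale_sigma}
        self._scale_try = {k: 0 for k in self._scale_sigma}
        self._scale_batch_acc = {k: 0 for k in self._scale_sigma}

    # -------------------------------------------------------------- updates

    def _lam(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            lam = np.where(self.mask, self.E * np.exp(self.psi), 0.0)
        return lam

    def _update_alpha(self) -> None:
        d = self.s_alpha * self.rng.standard_normal()
        masked_y = np.where(self.mask, self.Y, 0.0)
        with np.errstate(over="ignore"):
            dll = d * masked_y.sum() - np.expm1(d) * self._lam().sum()
        dlp = -0.5 * self.spec.tau0 * ((self.alpha + d) ** 2 - self.alpha**2)
        if np.log(self.rng.random()) < dll + dlp:
            self.alpha += d
            self.psi += d
            self._batch_acc["alpha"][0] += 1
            self._acc["alpha"] += 1
        self._try["alpha"] += 1

    def _update_beta(self) -> None:
        for k in range(self.p):
            d = self.s_beta[k] * self.rng.standard_normal()
            x = self.X[:, :, k]
            with np.errstate(over="ignore"):
                dll = float(
                    np.sum(
                        np.where(
                            self.mask,
                            self.Y * x * d - self._lam() * np.expm1(x * d),
                            0.0,
                        )
                    )
                )
            b = self.beta[k]
            dlp = -0.5 * self.spec.beta_precision * ((b + d) ** 2 - b**2)
            if np.log(self.rng.random()) < dll + dlp:
                self.beta[k] = b + d
                self.psi += x * d
                self._batch_acc["beta"][k] += 1
                self._acc["beta"] += 1
            self._try["beta"] += 1

    def _row_sums(self) -> tuple[np.ndarray, np.ndarray]:
        masked_y = np.where(self.mask, self.Y, 0.0)
        return masked_y.sum(axis=1), self._lam().sum(axis=1)

    def _col_sums(self) -> tuple[np.ndarray, np.ndarray]:
        masked_y = np.where(self.mask, self.Y, 0.0)
        return masked_y.sum(axis=0), self._lam().sum(axis=0)

    def _update_mu(self) -> None:
        for idx in self.mu_colors:
            row_y, row_lam = self._row_sums()
            d = self.s_mu[idx] * self.rng.standard_normal(idx.size)
            with np.errstate(over="ignore"):
                dll = d * row_y[idx] - np.expm1(d) * row_lam[idx]
            nbsum = self.W_binary[idx] @ self.mu
            dlp = -0.5 * self.tau_mu * (
                self.deg[idx] * d**2 + 2 * d * (self.deg[idx] * self.mu[idx] - nbsum)
            )
            accept = np.log(self.rng.random(idx.size)) < dll + dlp
            sel = idx[accept]
            self.mu[sel] += d[accept]
            self.psi[sel, :] += d[accept][:, None]
            self._batch_acc["mu"][sel] += 1
            self._acc["mu"] += accept.sum()
            self._try["mu"] += idx.size

    def _update_ups(self) -> None:
        row_y, row_lam = self._row_sums()
        d = self.s_ups * self.rng.standard_normal(self.I)
        with np.errstate(over="ignore"):
            dll = d * row_y - np.expm1(d) * row_lam
        dlp = -0.5 * self.tau_ups * ((self.ups + d) ** 2 - self.ups**2)
        accept = np.log(self.rng.random(self.I)) < dll + dlp
        self.ups[accept] += d[accept]
        self.psi[accept, :] += d[accept][:, None]
        self._batch_acc["ups"][accept] += 1
        self._acc["ups"] += accept.sum()
        self._try["ups"] += self.I

    def _update_gamma(self) -> None:
        # parity coloring of the RW1 chain: odd and even t are conditionally
        # independent blocks
        for parity in (0, 1):
            idx = np.arange(parity, self.T, 2)
            if idx.size == 0:
                continue
            col_y, col_lam = self._col_sums()
            d = self.s_gamma[idx] * self.rng.standard_normal(idx.size)
            with np.errstate(over="ignore"):
                dll = d * col_y[idx] - np.expm1(d) * col_lam[idx]
            k_t = np.where((idx > 0) & (idx < self.T - 1), 2.0, 1.0)
            nbsum = np.zeros(idx.size)
            has_prev = idx > 0
            nbsum[has_prev] += self.gamma[idx[has_prev] - 1]
            has_next = idx < self.T - 1
            nbsum[has_next] += self.gamma[idx[has_next] + 1]
            dlp = -0.5 * self.tau_gamma * (
                k_t * d**2 + 2 * d * (k_t * self.gamma[idx] - nbsum)
            )
            accept = np.log(self.rng.random(idx.size)) < dll + dlp
            sel = idx[accept]
            self.gamma[sel] += d[accept]
            self.psi[:, sel] += d[accept][None, :]
            self._batch_acc["gamma"][sel] += 1
            self._acc["gamma"] += accept.sum()
            self._try["gamma"] += idx.size

    def _update_phi(self) -> None:
        col_y, col_lam = self._col_sums()
        d = self.s_phi * self.rng.standard_normal(self.T)
        with np.errstate(over="ignore"):
            dll = d * col_y - np.expm1(d) * col_lam
        dlp = -0.5 * self.tau_phi * ((self.phi + d) ** 2 - self.phi**2)
        accept = np.log(self.rng.random(self.T)) < dll + dlp
        self.phi[accept] += d[accept]
        self.psi[:, accept] += d[accept][None, :]
        self._batch_acc["phi"][accept] += 1
        self._acc["phi"] += accept.sum()
        self._try["phi"] += self.T

    def _scale_moves(self) -> None:
        # joint scaling move per random-effect block: (f, tau) ->
        # (f*exp(eps/2), tau*exp(-eps)) leaves the Gaussian kernel exponent
        # invariant, so the acceptance ratio reduces to the likelihood
        # change, the Gamma hyperprior ratio and a -eps volume term; this
        # mixes the funnel between a field and its precision that
        # conditional conjugate draws alone traverse extremely slowly
        blocks = [
            ("mu", self.mu, "tau_mu", self.spec.tau_mu_prior, "row"),
            ("ups", self.ups, "tau_ups", self.spec.tau_upsilon_prior, "row"),
        ]
        if self.temporal:
            blocks += [
                ("gamma", self.gamma, "tau_gamma", self.spec.tau_gamma_prior, "col"),
                ("phi", self.phi, "tau_phi", self.spec.tau_phi_prior, "col"),
            ]
        for name, field, tau_name, (a, b), axis in blocks:
            eps = self._scale_sigma[name] * self.rng.standard_normal()
            g = np.exp(0.5 * eps)
            d = field * (g - 1.0)
            if axis == "row":
                sum_y, sum_lam = self._row_sums()
            else:
                sum_y, sum_lam = self._col_sums()
            with np.errstate(over="ignore"):
                dll = float(np.sum(d * sum_y - np.expm1(d) * sum_lam))
            tau = getattr(self, tau_name)
            dlp = (a - 1.0) * (-eps) - b * tau * np.expm1(-eps)
            accepted = np.log(self.rng.random()) < dll + dlp - eps
            if accepted:
                field *= g
                setattr(self, tau_name, tau * np.exp(-eps))
                if axis == "row":
                    self.psi += d[:, None]
                else:
                    self.psi += d[None, :]
            self._scale_acc[name] += accepted
            self._scale_try[name] += 1
            self._scale_batch_acc[name] += accepted

    def _update_splits(self) -> None:
        # the likelihood identifies only the sums mu + ups and gamma + phi;
        # the split between structured and unstructured components is a
        # likelihood-flat direction that single-site moves traverse slowly.
        # Gibbs-draw the shift c in (mu+c, ups-c) from its exact Gaussian
        # full conditional (precision tau_mu*L + tau_ups*I, L the graph
        # Laplacian), leaving psi untouched; same for (gamma+c, phi-c)
        # with the RW1 structure matrix.
        L = np.diag(self.deg) - self.W_binary
        prec = self.tau_mu * L + self.tau_ups * np.eye(self.I)
        rhs = self.tau_ups * self.ups - self.tau_mu * (L @ self.mu)
        c = self._gaussian_solve_draw(prec, rhs)
        self.mu += c
        self.ups -= c
        if self.temporal:
            K = self._rw1_structure
            prec = self.tau_gamma * K + self.tau_phi * np.eye(self.T)
            rhs = self.tau_phi * self.phi - self.tau_gamma * (K @ self.gamma)
            c = self._gaussian_solve_draw(prec, rhs)
            self.gamma += c
            self.phi -= c

    def _gaussian_solve_draw(self, prec: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        """One draw from N(prec^-1 rhs, prec^-1) via Cholesky."""
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        z = self.rng.standard_normal(rhs.size)
        return mean + np.linalg.solve(chol.T, z)

    def _update_levels(self) -> None:
        # exact Gibbs exchange of the unidentified level between the
        # intercept and each iid block: (alpha, v) -> (alpha + c, v - c)
        # leaves psi (hence the likelihood) unchanged, and c has a normal
        # full conditional from the alpha and block priors; this move mixes
        # the slow intercept/field-mean direction in one draw
        tau0 = self.spec.tau0
        for block, tau, size in (
            (self.ups, self.tau_ups, self.I),
            (self.phi, self.tau_phi, self.T) if self.temporal else (None, None, 0),
        ):
            if block is None:
                continue
            prec = tau0 + size * tau
            mean = (tau * block.sum() - tau0 * self.alpha) / prec
            c = self.rng.normal(mean, 1.0 / np.sqrt(prec))
            block -= c
            self.alpha += c

    def _recenter(self) -> None:
        # global sum-to-zero for mu and gamma; the subtracted means are
        # absorbed into the intercept, so psi is unchanged (a pure
        # reparameterization the translation-invariant priors permit)
        m = self.mu.mean()
        self.mu -= m
        self.alpha += m
        if self.temporal:
            g = self.gamma.mean()
            self.gamma -= g
            self.alpha += g
        self._refresh_psi()  # kill accumulated float drift in psi

    def _update_taus(self) -> None:
        a, b = self.spec.tau_mu_prior
        ss = float(((self.mu[self.edge_i] - self.mu[self.edge_j]) ** 2).sum())
        self.tau_mu = self.rng.gamma(a + 0.5 * self.icar_rank, 1.0 / (b + 0.5 * ss))
        a, b = self.spec.tau_upsilon_prior
        self.tau_ups = self.rng.gamma(
            a + 0.5 * self.I, 1.0 / (b + 0.5 * float(self.ups @ self.ups))
        )
        if self.temporal:
            a, b = self.spec.tau_gamma_prior
            ssg = float((np.diff(self.gamma) ** 2).sum())
            self.tau_gamma = self.rng.gamma(a + 0.5 * (self.T - 1), 1.0 / (b + 0.5 * ssg))
            a, b = self.spec.tau_phi_prior
            self.tau_phi = self.rng.gamma(
                a + 0.5 * self.T, 1.0 / (b + 0.5 * float(self.phi @ self.phi))
            )

    def _adapt(self) -> None:
        self._n_batches += 1
        step = min(0.25, 1.0 / np.sqrt(self._n_batches))
        n = self._batch_n
        target = self.cfg.target_accept

        def tune(scales, acc):
            rate = acc / n
            return scales * np.exp(step * (rate - target))

        self.s_alpha = float(tune(np.array([self.s_alpha]), self._batch_acc["alpha"])[0])
        self.s_beta = tune(self.s_beta, self._batch_acc["beta"])
        self.s_mu = tune(self.s_mu, self._batch_acc["mu"])
        self.s_ups = tune(self.s_ups, self._batch_acc["ups"])
        if self.temporal:
            self.s_gamma = tune(self.s_gamma, self._batch_acc["gamma"])
            self.s_phi = tune(self.s_phi, self._batch_acc["phi"])
        for name, acc in self._scale_batch_acc.items():
            self._scale_sigma[name] *= float(np.exp(step * (acc / n - target)))
            self._scale_batch_acc[name] = 0
        for v in self._batch_acc.values():
            v[:] = 0
        self._batch_n = 0

    # ---------------------------------------------------------------- sweep

    def sweep(self, adapt: bool = False) -> None:
        self._update_alpha()
        if self.p:
            self._update_beta()
        self._update_mu()
        self._update_ups()
        if self.temporal:
            self._update_gamma()
            self._update_phi()
        self._scale_moves()
        self._update_splits()
        self._update_levels()
        self._recenter()
        self._update_taus()
        self._batch_n += 1
        if adapt and self._batch_n >= self.cfg.adapt_interval:
            self._adapt()

    def pointwise_loglik(self) -> np.ndarray:
        """Full pointwise log-likelihood over the included (E>0) cells."""
        ll = poisson_loglik(self.Y, self.E, self.psi)
        return ll.ravel()[self.mask.ravel()]

    # resimulation of counts given the current state; used for prior/posterior
    # consistency checks of the sampler itself
    def draw_counts(self) -> np.ndarray:
        lam = self._lam()
        return np.where(self.mask, self.rng.poisson(lam), 0.0)

    def set_counts(self, Y: np.ndarray) -> None:
        Y = np.asarray(Y, dtype=float)
        if np.any((self.E <= 0) & (Y > 0)):
            raise ValueError("cell with Y > 0 requires E > 0")
        self.Y = Y

    def draw_state_from_prior(self) -> None:
        """Draw precisions and latent state from the (constrained) prior."""
        rng = self.rng
        a, b = self.spec.tau_mu_prior
        self.tau_mu = rng.gamma(a, 1.0 / b)
        a, b = self.spec.tau_upsilon_prior
        self.tau_ups = rng.gamma(a, 1.0 / b)
        if self.temporal:
            a, b = self.spec.tau_gamma_prior
            self.tau_gamma = rng.gamma(a, 1.0 / b)
            a, b = self.spec.tau_phi_prior
            self.tau_phi = rng.gamma(a, 1.0 / b)
        self.alpha = rng.normal(0.0, 1.0 / np.sqrt(self.spec.tau0))
        if self.p:
            self.beta = rng.normal(0.0, 1.0 / np.sqrt(self.spec.beta_precision), self.p)
        self.mu = _icar_draw(self.graph, self.tau_mu, rng)
        self.ups = rng.normal(0.0, 1.0 / np.sqrt(self.tau_ups), self.I)
        if self.temporal:
            steps = rng.normal(0.0, 1.0 / np.sqrt(self.tau_gamma), self.T - 1)
            g = np.concatenate([[0.0], np.cumsum(steps)])
            self.gamma = g - g.mean()
            self.phi = rng.normal(0.0, 1.0 / np.sqrt(self.tau_phi), self.T)
        self._refresh_psi()

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: float(self._acc[k] / self._try[k])
            for k in self._acc
            if self._try[k] > 0
        }


def _icar_draw(graph: AdjacencyGraph, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic CAR prior restricted to the sum-zero subspace.

    Eigen-decomposition of the graph Laplacian Q = D - W; coefficients on
    non-null eigenvectors have variance 1/(tau * eigenvalue); null-space
    directions (one per component) are fixed at zero, then each component is
    recentred.
    """
    n = graph.n_units
    W = np.zeros((n, n))
    for i, j in graph.edges():
        W[i, j] = W[j, i] = 1.0
    D = np.diag(W.sum(axis=1))
    evals, evecs = np.linalg.eigh(D - W)
    keep = evals > 1e-10
    coef = rng.standard_normal(int(keep.sum())) / np.sqrt(tau * evals[keep])
    x = evecs[:, keep] @ coef
    labels = graph.component_labels()
    for comp in range(labels.max() + 1):
        sel = labels == comp
        x[sel] -= x[sel].mean()
    return x


def _run_chains(
    Y, E, X, graph, spec: ModelSpec, cfg: McmcConfig, seed: int
) -> PosteriorSamples:
    all_draws: list[dict[str, np.ndarray]] = []
    acc_rates = []
    for chain in range(cfg.n_chains):
        sampler = BymGibbsSampler(Y, E, X, graph, spec, cfg, seed=seed + 1000 * chain)
        keep_alpha, keep_beta = [], []
        keep_mu, keep_ups, keep_gamma, keep_phi = [], [], [], []
        keep_taus = {k: [] for k in ("tau_mu", "tau_upsilon", "tau_gamma", "tau_phi")}
        keep_psi, keep_ll = [], []
        for it in range(cfg.n_iter):
            sampler.sweep(adapt=it < cfg.burn_in)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                keep_alpha.append(sampler.alpha)
                keep_beta.append(sampler.beta.copy())
                keep_mu.append(sampler.mu.copy())
                keep_ups.append(sampler.ups.copy())
                keep_taus["tau_mu"].append(sampler.tau_mu)
                keep_taus["tau_upsilon"].append(sampler.tau_ups)
                if spec.temporal:
                    keep_gamma.append(sampler.gamma.copy())
                    keep_phi.append(sampler.phi.copy())
                    keep_taus["tau_gamma"].append(sampler.tau_gamma)
                    keep_taus["tau_phi"].append(sampler.tau_phi)
                keep_psi.append(sampler.psi.copy())
                keep_ll.append(sampler.pointwise_loglik())
        chain_draws = {
            "alpha": np.array(keep_alpha),
            "beta": np.array(keep_beta),
            "mu": np.array(keep_mu),
            "upsilon": np.array(keep_ups),
            "tau_mu": np.array(keep_taus["tau_mu"]),
            "tau_upsilon": np.array(keep_taus["tau_upsilon"]),
            "psi": np.array(keep_psi),
            "loglik": np.array(keep_ll),
        }
        if spec.temporal:
            chain_draws.update(
                gamma=np.array(keep_gamma),
                phi=np.array(keep_phi),
                tau_gamma=np.array(keep_taus["tau_gamma"]),
                tau_phi=np.array(keep_taus["tau_phi"]),
            )
        all_draws.append(chain_draws)
        acc_rates.append(sampler.acceptance_rates())

    names = [k for k in all_draws[0] if k not in ("psi", "loglik")]
    draws = {k: np.concatenate([c[k] for c in all_draws], axis=0) for k in names}
    psi = np.concatenate([c["psi"] for c in all_draws], axis=0)
    loglik = np.concatenate([c["loglik"] for c in all_draws], axis=0)
    mask = np.asarray(E) > 0
    meta = {
        "n_chains": cfg.n_chains,
        "n_iter": cfg.n_iter,
        "burn_in": cfg.burn_in,
        "thin": cfg.thin,
        "seed": seed,
        "acceptance_rates": acc_rates,
        "warnings": [],
    }
    meta.update(_convergence_diagnostics(all_draws, cfg, meta))
    return PosteriorSamples(
        draws=draws,
        psi=psi,
        loglik=loglik,
        included_cells=np.flatnonzero(mask.ravel()),
        meta=meta,
    )


def _convergence_diagnostics(all_draws, cfg: McmcConfig, meta: dict) -> dict:
    """Split-Rhat and bulk ESS for the intercept and precisions via ArviZ."""
    import arviz as az

    diag = {}
    scalars = [k for k in all_draws[0] if all_draws[0][k].ndim == 1]
    for name in scalars:
        stacked = np.stack([c[name] for c in all_draws])  # (chains, S)
        try:
            diag.setdefault("ess", {})[name] = float(az.ess(stacked))
            if stacked.shape[0] > 1:
                diag.setdefault("rhat", {})[name] = float(az.rhat(stacked))
        except Exception:  # diagnostics must never sink a fit
            continue
    if cfg.min_ess is not None and "ess" in diag:
        low = {k: v for k, v in diag["ess"].items() if v < cfg.min_ess}
        if low:
            msg = f"effective sample size below {cfg.min_ess}: {low}"
            warnings.warn(msg)
            meta["warnings"].append(msg)
    return diag


def _finalize_fit(
    panel: ArealPanel, samples: PosteriorSamples, covariate_names: list[str]
) -> ModelFit:
    with np.errstate(over="ignore"):
        rr_draws = np.exp(samples.psi)
    psi_mean = samples.psi.mean(axis=0)
    ll_at_mean = float(poisson_loglik(panel.Y, panel.E, psi_mean).sum())
    return ModelFit(
        samples=samples,
        unit_ids=list(panel.unit_ids),
        periods=list(panel.periods),
        covariate_names=covariate_names,
        Y=panel.Y.copy(),
        E=panel.E.copy(),
        rr_mean=rr_draws.mean(axis=0),
        rr_lower=np.percentile(rr_draws, 2.5, axis=0),
        rr_upper=np.percentile(rr_draws, 97.5, axis=0),
        loglik_at_mean=ll_at_mean,
    )


def _select_covariates(panel: ArealPanel, spec: ModelSpec) -> np.ndarray | None:
    if not spec.covariates:
        return None
    missing = [c for c in spec.covariates if c not in panel.covariate_names]
    if missing:
        raise ValueError(f"covariates not in panel: {missing}")
    idx = [panel.covariate_names.index(c) for c in spec.covariates]
    return panel.X[:, :, idx]


def fit_spatial_bym(
    panel: ArealPanel,
    graph: AdjacencyGraph,
    spec: ModelSpec | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> ModelFit:
    """Fit the single-period spatial BYM model psi_i = alpha + x'beta + mu_i + ups_i."""
    spec = spec or ModelSpec(temporal=False)
    if spec.temporal:
        spec = ModelSpec(
            covariates=spec.covariates,
            temporal=False,
            tau_mu_prior=spec.tau_mu_prior,
            tau_upsilon_prior=spec.tau_upsilon_prior,
            tau0=spec.tau0,
            beta_precision=spec.beta_precision,
        )
    mcmc = mcmc or McmcConfig()
    if len(panel.periods) != 1:
        raise ValueError("spatial BYM expects a single-period panel")
    if panel.E is None:
        raise ValueError("expected counts not computed")
    X = _select_covariates(panel, spec)
    samples = _run_chains(panel.Y, panel.E, X, graph, spec, mcmc, seed)
    return _finalize_fit(panel, samples, list(spec.covariates))


def fit_spatiotemporal(
    panel: ArealPanel,
    graph: AdjacencyGraph,
    spec: ModelSpec | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> ModelFit:
    """Fit the additive space-time model psi_it = alpha + x'beta + mu_i + ups_i + gamma_t + phi_t."""
    spec = spec or ModelSpec(temporal=True)
    if not spec.temporal:
        raise ValueError("spec.temporal must be True for the spatiotemporal model")
    mcmc = mcmc or McmcConfig()
    if len(panel.periods) < 2:
        raise ValueError("spatiotemporal model needs at least 2 periods")
    if panel.E is None:
        raise ValueError("expected counts not computed")
    X = _select_covariates(panel, spec)
    samples = _run_chains(panel.Y, panel.E, X, graph, spec, mcmc, seed)
    return _finalize_fit(panel, samples, list(spec.covariates))
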