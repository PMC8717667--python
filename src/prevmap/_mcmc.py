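"""Metropolis-within-Gibbs engine for hierarchical Poisson models.

Latent Gaussian fields are updated by single-site adaptive random-walk
Metropolis, vectorized over graph-coloring classes (sites within a class
are conditionally independent given the rest, so the whole class is
proposed and accepted element-wise in one numpy pass). Precision
parameters get conjugate Gamma Gibbs updates; intrinsic fields are
recentered after every sweep to impose the sum-to-zero constraints.

Internal module: the public modelling surface lives in :mod:`prevmap.models`.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix

TARGET_ACCEPT = 0.44  # single-site RW optimum


def greedy_color_classes(A: csr_matrix) -> list[np.ndarray]:
    """Partition graph nodes into independent sets (greedy coloring)."""
    import networkx as nx

    g = nx.from_scipy_sparse_array(A)
    coloring = nx.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values(), default=0) + 1
    return [
        np.fromiter(
            (v for v, c in coloring.items() if c == col), dtype=int
        )
        for col in range(n_colors)
    ]


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat for an array of shape (n_chains, n_draws)."""
    n_chains, n_draws = chains.shape
    if n_draws < 4:
        return np.nan
    half = n_draws // 2
    seq = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = seq.shape
    means = seq.mean(axis=1)
    w = seq.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ess_geyer(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    n_chains, n_draws = chains.shape
    if n_draws < 4:
        return float(n_chains * n_draws)
    centered = chains - chains.mean(axis=1, keepdims=True)
    var = centered.var(axis=1, ddof=0).mean()
    if var <= 0:
        return float(n_chains * n_draws)
    max_lag = min(n_draws - 1, 1000)
    rho = np.zeros(max_lag + 1)
    rho[0] = 1.0
    for lag in range(1, max_lag + 1):
        acov = np.mean(
            [
                (c[:-lag] * c[lag:]).mean()
                for c in centered
            ]
        )
        rho[lag] = acov / var
    # sum consecutive pairs while positive
    tau = 1.0
    lag = 1
    while lag + 1 <= max_lag:
        pair = rho[lag] + rho[lag + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        lag += 2
    return float(n_chains * n_draws / max(tau, 1.0))


class ChainData:
    """Immutable per-fit data shared by all chains."""

    def __init__(
        self,
        y: np.ndarray,
        E: np.ndarray,
        mask: np.ndarray,
        X: np.ndarray | None,
        A: csr_matrix | None,
        Ndiag: np.ndarray | None,
        n_components: int,
        Kt: np.ndarray | None,
        Ks_int: np.ndarray | None,
        Kt_int: np.ndarray | None,
        rank_delta: int,
        effects: tuple[str, ...],
    ) -> None:
        self.y = y.astype(float)
        self.E = E.astype(float)
        self.mask = mask.astype(float)
        self.X = X
        self.A = A
        self.Ndiag = Ndiag
        self.n_components = n_components
        self.Kt = Kt
        self.Ks_int = Ks_int
        self.Kt_int = Kt_int
        self.rank_delta = rank_delta
        self.effects = effects
        self.n, self.T = y.shape
        self.ym = self.y * self.mask
        self.y_row = self.ym.sum(axis=1)
        self.y_col = self.ym.sum(axis=0)
        self.y_tot = float(self.ym.sum())
        self.logE = np.where(self.E > 0, np.log(np.maximum(self.E, 1e-300)), 0.0)
        if A is not None:
            self.space_colors = greedy_color_classes(A)
        else:
            self.space_colors = [np.arange(self.n)]
        # delta coloring: product of spatial coloring (if spatially structured)
        # and time parity (if temporally structured)
        if "delta" in effects:
            s_classes = (
                self.space_colors
                if Ks_int is not None and _has_offdiag(Ks_int)
                else [np.arange(self.n)]
            )
            t_par = (
                [np.arange(0, self.T, 2), np.arange(1, self.T, 2)]
                if Kt_int is not None and _has_offdiag(Kt_int)
                else [np.arange(self.T)]
            )
            self.delta_classes = [
                (sc, tc) for sc in s_classes for tc in t_par
            ]
        else:
            self.delta_classes = []


def _has_offdiag(K: np.ndarray) -> bool:
    return bool(np.any(K - np.diag(np.diag(K))))


class ChainState:
    def __init__(self, data: ChainData, cfg, rng: np.random.Generator) -> None:
        n, T = data.n, data.T
        self.rng = rng
        p = 0 if data.X is None else data.X.shape[1]
        with np.errstate(divide="ignore"):
            tot_E = float((data.E * data.mask).sum())
        self.alpha = float(np.log(max(data.y_tot, 0.5) / max(tot_E, 1e-12)))
        self.beta = np.zeros(p)
        r = np.where(
            data.mask > 0,
            np.log((data.ym + 0.5) / np.maximum(data.E, 1e-12)) - self.alpha,
            0.0,
        )
        noise = 0.05
        self.fields: dict[str, np.ndarray] = {}
        if "u" in data.effects:
            u0 = r.mean(axis=1)
            u0 = u0 - u0.mean()
            self.fields["u"] = 0.5 * u0 + np.sqrt(noise) * rng.standard_normal(n)
        if "v" in data.effects:
            self.fields["v"] = np.sqrt(noise) * rng.standard_normal(n)
        if "gamma" in data.effects:
            self.fields["gamma"] = np.sqrt(noise) * rng.standard_normal(T)
        if "phi" in data.effects:
            p0 = r.mean(axis=0)
            p0 = p0 - p0.mean()
            self.fields["phi"] = 0.5 * p0 + np.sqrt(noise) * rng.standard_normal(T)
        if "delta" in data.effects:
            self.fields["delta"] = np.sqrt(noise) * rng.standard_normal((n, T))
        self.sigma2: dict[str, float] = {}
        for name in data.effects:
            fixed = cfg.sigma2_fixed.get(name)
            self.sigma2[name] = float(fixed) if fixed is not None else 0.05
            if fixed is not None and fixed == 0.0:
                self.fields[name] = np.zeros_like(self.fields[name])
        # adaptive step sizes (log scale)
        self.log_step: dict[str, np.ndarray | float] = {
            "alpha": np.log(0.1),
            "beta": np.full(p, np.log(0.1)),
        }
        for name, f in self.fields.items():
            self.log_step[name] = np.full(f.shape, np.log(0.3))

    def eta(self, data: ChainData) -> np.ndarray:
        """Linear predictor minus the log-E offset (i.e. log relative risk)."""
        out = np.full((data.n, data.T), self.alpha)
        if data.X is not None and self.beta.size:
            out += (data.X @ self.beta)[:, None]
        if "u" in self.fields:
            out += self.fields["u"][:, None]
        if "v" in self.fields:
            out += self.fields["v"][:, None]
        if "gamma" in self.fields:
            out += self.fields["gamma"][None, :]
        if "phi" in self.fields:
            out += self.fields["phi"][None, :]
        if "delta" in self.fields:
            out += self.fields["delta"]
        return out


def _metropolis_vec(
    rng: np.random.Generator,
    current: np.ndarray,
    log_step,
    dlp_fn,
    adapt_rate: float,
):
    """Element-wise RW Metropolis on a vector; returns accepted deltas.

    ``dlp_fn(d)`` returns the change in log-posterior for element-wise
    perturbations ``d``. Step sizes adapt toward the single-site target
    acceptance rate using the Rao-Blackwellized acceptance probability.
    """
    step = np.exp(log_step)
    d = step * rng.standard_normal(current.shape)
    dlp = dlp_fn(d)
    p_acc = np.exp(np.minimum(dlp, 0.0))
    accept = rng.random(current.shape) < p_acc
    if adapt_rate > 0:
        log_step += adapt_rate * (p_acc - TARGET_ACCEPT)
        np.clip(log_step, -10.0, 3.0, out=log_step)
    return np.where(accept, d, 0.0)


def _quad_form_icar(A: csr_matrix, Ndiag: np.ndarray, u: np.ndarray) -> float:
    return float(u @ (Ndiag * u) - u @ (A @ u))


def run_chain(data: ChainData, cfg, seed_seq: np.random.SeedSequence):
    """Run one MCMC chain; returns a dict of stored draw arrays."""
    rng = np.random.default_rng(seed_seq)
    state = ChainState(data, cfg, rng)
    n, T = data.n, data.T
    like_w = 0.0 if cfg.prior_only else 1.0
    n_keep = (cfg.n_iterations - cfg.n_burnin) // cfg.thinning
    p = state.beta.size

    store = {
        "alpha": np.empty(n_keep),
        "beta": np.empty((n_keep, p)),
    }
    for name in data.effects:
        store[name] = np.empty((n_keep,) + state.fields[name].shape)
        store[f"sigma2_{name}"] = np.empty(n_keep)

    a0, b0 = cfg.gamma_shape, cfg.gamma_rate
    kt_diag = np.diag(data.Kt) if data.Kt is not None else None
    ks_int_diag = np.diag(data.Ks_int) if data.Ks_int is not None else None
    kt_int_diag = np.diag(data.Kt_int) if data.Kt_int is not None else None

    kept = 0
    for it in range(cfg.n_iterations):
        in_burn = it < cfg.n_burnin
        adapt = min(0.25, 5.0 / np.sqrt(it + 10.0)) if in_burn else 0.0

        # --- intercept and covariate coefficients -------------------------
        eta = state.eta(data)
        Ee_tot = float((data.E * np.exp(eta) * data.mask).sum())

        def dlp_alpha(d):
            dd = float(d)
            prior = (
                -((state.alpha + dd) ** 2 - state.alpha**2)
                / (2.0 * cfg.intercept_prior_var)
            )
            return like_w * (dd * data.y_tot - (np.exp(dd) - 1.0) * Ee_tot) + prior

        la = np.atleast_1d(np.asarray(state.log_step["alpha"], dtype=float))
        d = _metropolis_vec(rng, np.atleast_1d(state.alpha), la, lambda dv: np.array([dlp_alpha(dv[0])]), adapt)
        state.log_step["alpha"] = float(la[0])
        state.alpha += float(d[0])

        for k in range(p):
            eta = state.eta(data)
            Ee_rows = (data.E * np.exp(eta) * data.mask).sum(axis=1)
            xk = data.X[:, k]

            def dlp_beta(dv, xk=xk, Ee_rows=Ee_rows, k=k):
                dd = float(dv[0])
                ll = float(
                    np.sum(
                        data.y_row * dd * xk
                        - Ee_rows * (np.exp(dd * xk) - 1.0)
                    )
                )
                bk = state.beta[k]
                prior = -(((bk + dd) ** 2 - bk**2) / (2.0 * cfg.beta_prior_var))
                return np.array([like_w * ll + prior])

            lsk = np.atleast_1d(np.asarray(state.log_step["beta"][k], dtype=float))
            d = _metropolis_vec(rng, np.atleast_1d(state.beta[k]), lsk, dlp_beta, adapt)
            state.log_step["beta"][k] = float(lsk[0])
            state.beta[k] += float(d[0])

        # --- unstructured spatial v --------------------------------------
        if "v" in state.fields and state.sigma2["v"] > 0:
            eta = state.eta(data)
            Ee_rows = (data.E * np.exp(eta) * data.mask).sum(axis=1)
            v = state.fields["v"]
            tau = 1.0 / state.sigma2["v"]

            def dlp_v(d):
                ll = data.y_row * d - Ee_rows * (np.exp(d) - 1.0)
                prior = -0.5 * tau * ((v + d) ** 2 - v**2)
                return like_w * ll + prior

            v += _metropolis_vec(rng, v, state.log_step["v"], dlp_v, adapt)

        # --- structured spatial u (ICAR) ---------------------------------
        if "u" in state.fields and state.sigma2["u"] > 0:
            eta = state.eta(data)
            Ee_rows = (data.E * np.exp(eta) * data.mask).sum(axis=1)
            u = state.fields["u"]
            tau = 1.0 / state.sigma2["u"]
            for cls in data.space_colors:
                s_cls = (data.A @ u)[cls]
                u_c = u[cls]
                N_c = data.Ndiag[cls]

                def dlp_u(d, cls=cls, s_cls=s_cls, u_c=u_c, N_c=N_c):
                    ll = data.y_row[cls] * d - Ee_rows[cls] * (np.exp(d) - 1.0)
                    prior = -0.5 * tau * (
                        N_c * ((u_c + d) ** 2 - u_c**2) - 2.0 * d * s_cls
                    )
                    return like_w * ll + prior

                ls = state.log_step["u"][cls].copy()
                u[cls] += _metropolis_vec(rng, u_c, ls, dlp_u, adapt)
                state.log_step["u"][cls] = ls

        # --- unstructured temporal gamma ---------------------------------
        if "gamma" in state.fields and state.sigma2["gamma"] > 0:
            eta = state.eta(data)
            Ee_cols = (data.E * np.exp(eta) * data.mask).sum(axis=0)
            g = state.fields["gamma"]
            tau = 1.0 / state.sigma2["gamma"]

            def dlp_g(d):
                ll = data.y_col * d - Ee_cols * (np.exp(d) - 1.0)
                prior = -0.5 * tau * ((g + d) ** 2 - g**2)
                return like_w * ll + prior

            g += _metropolis_vec(rng, g, state.log_step["gamma"], dlp_g, adapt)

        # --- structured temporal phi (RW1) -------------------------------
        if "phi" in state.fields and state.sigma2["phi"] > 0:
            eta = state.eta(data)
            Ee_cols = (data.E * np.exp(eta) * data.mask).sum(axis=0)
            ph = state.fields["phi"]
            tau = 1.0 / state.sigma2["phi"]
            for cls in (np.arange(0, T, 2), np.arange(1, T, 2)):
                s_cls = (data.Kt @ ph)[cls] - kt_diag[cls] * ph[cls]
                ph_c = ph[cls]

                def dlp_ph(d, cls=cls, s_cls=s_cls, ph_c=ph_c):
                    ll = data.y_col[cls] * d - Ee_cols[cls] * (np.exp(d) - 1.0)
                    prior = -0.5 * tau * (
                        kt_diag[cls] * ((ph_c + d) ** 2 - ph_c**2)
                        + 2.0 * d * s_cls
                    )
                    return like_w * ll + prior

                ls = state.log_step["phi"][cls].copy()
                ph[cls] += _metropolis_vec(rng, ph_c, ls, dlp_ph, adapt)
                state.log_step["phi"][cls] = ls

        # --- space-time interaction delta --------------------------------
        if "delta" in state.fields and state.sigma2["delta"] > 0:
            eta = state.eta(data)
            Ee = data.E * np.exp(eta) * data.mask
            D = state.fields["delta"]
            tau = 1.0 / state.sigma2["delta"]
            diag_outer = np.outer(ks_int_diag, kt_int_diag)
            for sc, tc in data.delta_classes:
                M = data.Ks_int @ D @ data.Kt_int
                S = M - diag_outer * D
                ix = np.ix_(sc, tc)
                D_c = D[ix]
                S_c = S[ix]
                K_c = diag_outer[ix]

                def dlp_d(d, D_c=D_c, S_c=S_c, K_c=K_c, ix=ix):
                    ll = data.ym[ix] * d - Ee[ix] * (np.exp(d) - 1.0)
                    prior = -0.5 * tau * (
                        K_c * ((D_c + d) ** 2 - D_c**2) + 2.0 * d * S_c
                    )
                    return like_w * ll + prior

                ls = state.log_step["delta"][ix].copy()
                D[ix] += _metropolis_vec(rng, D_c, ls, dlp_d, adapt)
                state.log_step["delta"][ix] = ls

        # --- sum-to-zero recentering -------------------------------------
        if cfg.sum_to_zero:
            if "u" in state.fields:
                state.fields["u"] -= state.fields["u"].mean()
            if "phi" in state.fields:
                state.fields["phi"] -= state.fields["phi"].mean()
            if "delta" in state.fields:
                D = state.fields["delta"]
                D -= D.mean(axis=1, keepdims=True)
                D -= D.mean(axis=0, keepdims=True)

        # --- precision (variance) Gibbs updates --------------------------
        for name in data.effects:
            if name in cfg.sigma2_fixed:
                continue
            f = state.fields[name]
            if name == "v":
                rank, q = n, float(f @ f)
            elif name == "u":
                rank = n - data.n_components
                q = _quad_form_icar(data.A, data.Ndiag, f)
            elif name == "gamma":
                rank, q = T, float(f @ f)
            elif name == "phi":
                rank, q = T - 1, float(f @ data.Kt @ f)
            else:  # delta
                rank = data.rank_delta
                q = float(np.sum(f * (data.Ks_int @ f @ data.Kt_int)))
            q = max(q, 0.0)
            if cfg.hyperprior == "gamma":
                tau = rng.gamma(a0 + 0.5 * rank, 1.0 / (b0 + 0.5 * q))
            else:  # uniform on the standard deviation, truncated at the bound
                shape = 0.5 * rank - 0.5
                if shape <= 0:
                    shape = 1e-3
                lo = 1.0 / cfg.uniform_sd_bound**2
                tau = lo
                for _ in range(100):
                    cand = rng.gamma(shape, 1.0 / (0.5 * q + 1e-12))
                    if cand >= lo:
                        tau = cand
                        break
            state.sigma2[name] = 1.0 / max(tau, 1e-12)

        # --- store --------------------------------------------------------
        if not in_burn and (it - cfg.n_burnin) % cfg.thinning == 0 and kept < n_keep:
            store["alpha"][kept] = state.alpha
            store["beta"][kept] = state.beta
            for name in data.effects:
                store[name][kept] = state.fields[name]
                store[f"sigma2_{name}"][kept] = state.sigma2[name]
            kept += 1

    return store
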