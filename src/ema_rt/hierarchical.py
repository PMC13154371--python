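"""Bayesian multilevel log-normal exponential-decay model for EMA RTs.

Observation model, for each trial ``n`` of subject ``i(n)`` answering with
Likert option ``r(n)`` at normalized time ``t_n ∈ [0, 1]``:

    RT_n ~ LogNormal(eta_n, sigma_log)
    eta_n = theta_a(i) * exp(-theta_b(i) * t_n) + theta_c(i, r)

Amplitude and decay rate are log-linked with responder-group moderation
(g(i) ∈ {0, 1}, nonresponder reference) and optional subject deviations:

    log theta_a(i) = beta0_a + beta1_a g(i) + sigma_a z_a(i)
    log theta_b(i) = beta0_b + beta1_b g(i) + sigma_b z_b(i)

The asymptote (on the log-RT scale) decomposes into group-moderated
baseline, subject intercept, option main effect with a hard sum-to-zero
constraint, and a subject × option cell residual:

    theta_c(i,r) = beta0_c + beta1_c g(i) + u_c(i) + alpha_c(r) + eps_c(i,r)

Priors: beta0* ~ N(mu_emp, 3^2), beta1* ~ N(0, 3^2), alpha_c(r) ~ N(0, 1),
sigma_a, sigma_b, sigma_subj, sigma_cell ~ HalfNormal(1.5),
sigma_log ~ HalfNormal(1).  Random effects use the non-centered
parameterization; scales are sampled on the log scale with the Jacobian
correction.  Sensitivity variants swap in a Student-t observation model on
log RT (nu = 4) or Student-t priors on the beta coefficients.

Nested random-effects variants ("none", "b_only", "a_and_b", "b_and_c",
"full") are compared by PSIS-LOO with moderation terms omitted; group
effects are summarized as responder/nonresponder ratios exp(beta1) with
95% credible intervals and the posterior probability of an increase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ema_rt.nuts import sample_nuts

N_OPTIONS = 7

VARIANTS = {
    "none": frozenset(),
    "b_only": frozenset("b"),
    "a_and_b": frozenset("ab"),
    "b_and_c": frozenset("bc"),
    "full": frozenset("abc"),
}


@dataclass(frozen=True)
class PriorScales:
    beta0: float = 3.0
    beta1: float = 3.0
    alpha: float = 1.0
    sigma_re: float = 1.5     # half-normal scale for sigma_a/b/subj/cell
    sigma_log: float = 1.0    # half-normal scale for the residual SD


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.95
    max_treedepth: int = 10
    seed: int = 0


@dataclass(frozen=True)
class HierarchicalSpec:
    """Configuration of one model fit."""

    variant: str = "b_and_c"
    moderated: bool = True
    likelihood: str = "lognormal"      # "lognormal" | "student_t"
    prior_family: str = "normal"       # "normal" | "student_t" (on betas)
    student_nu: float = 4.0
    mu_emp: dict | None = None         # {"a":..,"b":..,"c":..}; data-derived if None
    prior_scales: PriorScales = field(default_factory=PriorScales)
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.likelihood not in ("lognormal", "student_t"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.prior_family not in ("normal", "student_t"):
            raise ValueError(f"unknown prior family {self.prior_family!r}")


@dataclass(frozen=True)
class PosteriorGroupEffect:
    item: str
    parameter: str            # "theta_a" | "theta_b" | "exp_theta_c"
    ratio_median: float
    cri_low: float
    cri_high: float
    p_increase: float


def empirical_centers(y: np.ndarray, t: np.ndarray) -> dict:
    """Scale-matched prior centers from the data.

    beta0_c centers at the mean log RT; beta0_a at the log of the observed
    early-minus-late drop in mean log RT (floored at 0.05); beta0_b at
    log 3, a moderate decay over unit time.
    """
    early = y[t <= 0.25]
    late = y[t >= 0.75]
    drop = float(early.mean() - late.mean()) if early.size and late.size \
        else 0.05
    return {"a": math.log(max(drop, 0.05)),
            "b": math.log(3.0),
            "c": float(y.mean())}


class DecayModel:
    """Data container + differentiable log posterior for one model fit.

    Use :func:`build` to construct from EMA records and responder labels.
    """

    def __init__(self, y, t, obs_i, obs_r, g_sub, subject_ids, item,
                 spec: HierarchicalSpec, audit: dict):
        self.y = np.asarray(y, dtype=float)
        self.t = np.asarray(t, dtype=float)
        self.obs_i = np.asarray(obs_i, dtype=np.intp)
        self.obs_r = np.asarray(obs_r, dtype=np.intp)
        self.g_sub = np.asarray(g_sub, dtype=float)
        self.subject_ids = list(subject_ids)
        self.item = item
        self.spec = spec
        self.audit = audit
        self.n_obs = self.y.size
        self.n_sub = len(subject_ids)
        self.cell_index = self.obs_i * N_OPTIONS + self.obs_r
        self.g_obs = self.g_sub[self.obs_i]
        self.random = VARIANTS[spec.variant]
        if spec.mu_emp is None:
            self.mu_emp = empirical_centers(self.y, self.t)
        else:
            self.mu_emp = dict(spec.mu_emp)
        self._layout()

    # ---------------------------------------------------------- layout
    def _layout(self):
        S, R = self.n_sub, N_OPTIONS
        names = [("beta0_a", 1), ("beta0_b", 1), ("beta0_c", 1)]
        if self.spec.moderated:
            names += [("beta1_a", 1), ("beta1_b", 1), ("beta1_c", 1)]
        names += [("alpha_free", R - 1), ("s_log", 1)]
        if "a" in self.random:
            names += [("z_a", S), ("s_a", 1)]
        if "b" in self.random:
            names += [("z_b", S), ("s_b", 1)]
        if "c" in self.random:
            names += [("u_c", S), ("s_subj", 1),
                      ("eps_c", S * R), ("s_cell", 1)]
        self.slices = {}
        pos = 0
        for name, size in names:
            self.slices[name] = slice(pos, pos + size)
            pos += size
        self.n_params = pos

    def _get(self, x, name, default=0.0):
        if name not in self.slices:
            return default
        sl = self.slices[name]
        return float(x[sl.start]) if sl.stop - sl.start == 1 else x[sl]

    # ------------------------------------------------- log posterior
    def logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        # extreme positions (possible during step-size probing) are treated
        # as zero-density rather than overflowing
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 100.0:
            return -np.inf, np.zeros(self.n_params)
        with np.errstate(over="ignore", invalid="ignore"):
            return self._logp_and_grad(x)

    def _logp_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        S, R, N = self.n_sub, N_OPTIONS, self.n_obs
        sc = self.spec.prior_scales
        grad = np.zeros(self.n_params)
        sl = self.slices

        b0a = self._get(x, "beta0_a")
        b0b = self._get(x, "beta0_b")
        b0c = self._get(x, "beta0_c")
        b1a = self._get(x, "beta1_a")
        b1b = self._get(x, "beta1_b")
        b1c = self._get(x, "beta1_c")
        alpha_free = x[sl["alpha_free"]]
        alpha = np.append(alpha_free, -alpha_free.sum())
        s_log = self._get(x, "s_log")
        sigma_log = math.exp(s_log)

        log_a = b0a + b1a * self.g_sub
        log_b = b0b + b1b * self.g_sub
        c_sub = b0c + b1c * self.g_sub
        if "a" in self.random:
            z_a = x[sl["z_a"]]
            sigma_a = math.exp(float(x[sl["s_a"].start]))
            log_a = log_a + sigma_a * z_a
        if "b" in self.random:
            z_b = x[sl["z_b"]]
            sigma_b = math.exp(float(x[sl["s_b"].start]))
            log_b = log_b + sigma_b * z_b
        if "c" in self.random:
            u_c = x[sl["u_c"]]
            sigma_subj = math.exp(float(x[sl["s_subj"].start]))
            eps_c = x[sl["eps_c"]].reshape(S, R)
            sigma_cell = math.exp(float(x[sl["s_cell"].start]))
            c_cell = (c_sub + sigma_subj * u_c)[:, None] + alpha[None, :] \
                + sigma_cell * eps_c
        else:
            c_cell = c_sub[:, None] + alpha[None, :] \
                + np.zeros((S, R))

        A = np.exp(log_a)
        B = np.exp(log_b)
        decay = A[self.obs_i] * np.exp(-B[self.obs_i] * self.t)
        eta = decay + c_cell.reshape(-1)[self.cell_index]
        resid = self.y - eta

        # --- likelihood and d logp / d eta ------------------------------
        if self.spec.likelihood == "lognormal":
            logp = -N * s_log - 0.5 * float(resid @ resid) / sigma_log ** 2
            e = resid / sigma_log ** 2
            dlogp_dslog = -N + float(resid @ resid) / sigma_log ** 2
        else:  # student_t on log RT
            nu = self.spec.student_nu
            q = nu * sigma_log ** 2 + resid ** 2
            logp = -N * s_log \
                - 0.5 * (nu + 1) * float(np.sum(np.log1p(
                    resid ** 2 / (nu * sigma_log ** 2))))
            e = (nu + 1) * resid / q
            dlogp_dslog = -N + (nu + 1) * float(np.sum(resid ** 2 / q))

        # --- accumulate likelihood gradients ----------------------------
        q_a = e * decay                       # d eta / d log_a(i) per obs
        q_b = -q_a * B[self.obs_i] * self.t   # d eta / d log_b(i) per obs
        Ga = np.bincount(self.obs_i, weights=q_a, minlength=S)
        Gb = np.bincount(self.obs_i, weights=q_b, minlength=S)
        Gcell = np.bincount(self.cell_index, weights=e,
                            minlength=S * R).reshape(S, R)
        Gsub = Gcell.sum(axis=1)
        Gr = Gcell.sum(axis=0)

        grad[sl["beta0_a"].start] += Ga.sum()
        grad[sl["beta0_b"].start] += Gb.sum()
        grad[sl["beta0_c"].start] += Gsub.sum()
        if self.spec.moderated:
            grad[sl["beta1_a"].start] += float(self.g_sub @ Ga)
            grad[sl["beta1_b"].start] += float(self.g_sub @ Gb)
            grad[sl["beta1_c"].start] += float(self.g_sub @ Gsub)
        grad[sl["alpha_free"]] += Gr[:-1] - Gr[-1]
        grad[sl["s_log"].start] += dlogp_dslog
        if "a" in self.random:
            grad[sl["z_a"]] += sigma_a * Ga
            grad[sl["s_a"].start] += sigma_a * float(z_a @ Ga)
        if "b" in self.random:
            grad[sl["z_b"]] += sigma_b * Gb
            grad[sl["s_b"].start] += sigma_b * float(z_b @ Gb)
        if "c" in self.random:
            grad[sl["u_c"]] += sigma_subj * Gsub
            grad[sl["s_subj"].start] += sigma_subj * float(u_c @ Gsub)
            grad[sl["eps_c"]] += sigma_cell * Gcell.reshape(-1)
            grad[sl["s_cell"].start] += sigma_cell * float(
                eps_c.reshape(-1) @ Gcell.reshape(-1))

        # --- priors ------------------------------------------------------
        def beta_prior(val, center, scale, idx):
            nonlocal logp
            d = val - center
            if self.spec.prior_family == "normal":
                logp += -0.5 * d ** 2 / scale ** 2
                grad[idx] += -d / scale ** 2
            else:
                nu = self.spec.student_nu
                logp += -0.5 * (nu + 1) * math.log1p(d ** 2 / (nu * scale ** 2))
                grad[idx] += -(nu + 1) * d / (nu * scale ** 2 + d ** 2)

        beta_prior(b0a, self.mu_emp["a"], sc.beta0, sl["beta0_a"].start)
        beta_prior(b0b, self.mu_emp["b"], sc.beta0, sl["beta0_b"].start)
        beta_prior(b0c, self.mu_emp["c"], sc.beta0, sl["beta0_c"].start)
        if self.spec.moderated:
            beta_prior(b1a, 0.0, sc.beta1, sl["beta1_a"].start)
            beta_prior(b1b, 0.0, sc.beta1, sl["beta1_b"].start)
            beta_prior(b1c, 0.0, sc.beta1, sl["beta1_c"].start)

        # alpha prior applies to the full constrained vector
        logp += -0.5 * float(alpha @ alpha) / sc.alpha ** 2
        grad[sl["alpha_free"]] += (-alpha[:-1] + alpha[-1]) / sc.alpha ** 2

        def halfnormal_scale(s_val, sigma_val, tau, idx):
            nonlocal logp
            logp += -0.5 * sigma_val ** 2 / tau ** 2 + s_val  # + Jacobian
            grad[idx] += -sigma_val ** 2 / tau ** 2 + 1.0

        halfnormal_scale(s_log, sigma_log, sc.sigma_log, sl["s_log"].start)

        def std_normal(vec, slc):
            nonlocal logp
            logp += -0.5 * float(vec @ vec)
            grad[slc] += -vec

        if "a" in self.random:
            std_normal(z_a, sl["z_a"])
            halfnormal_scale(float(x[sl["s_a"].start]), sigma_a,
                             sc.sigma_re, sl["s_a"].start)
        if "b" in self.random:
            std_normal(z_b, sl["z_b"])
            halfnormal_scale(float(x[sl["s_b"].start]), sigma_b,
                             sc.sigma_re, sl["s_b"].start)
        if "c" in self.random:
            std_normal(u_c, sl["u_c"])
            std_normal(eps_c.reshape(-1), sl["eps_c"])
            halfnormal_scale(float(x[sl["s_subj"].start]), sigma_subj,
                             sc.sigma_re, sl["s_subj"].start)
            halfnormal_scale(float(x[sl["s_cell"].start]), sigma_cell,
                             sc.sigma_re, sl["s_cell"].start)

        if not math.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros(self.n_params)
        return logp, grad

    # ---------------------------------------------------- initial point
    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = 0.1 * rng.standard_normal(self.n_params)
        sl = self.slices
        x[sl["beta0_a"].start] += self.mu_emp["a"]
        x[sl["beta0_b"].start] += self.mu_emp["b"]
        x[sl["beta0_c"].start] += self.mu_emp["c"]
        for name in ("s_log", "s_a", "s_b", "s_subj", "s_cell"):
            if name in sl:
                x[sl[name].start] = math.log(0.3) \
                    + 0.1 * rng.standard_normal()
        return x

    # --------------------------------------------------------- derived
    def subject_params(self, flat: np.ndarray) -> dict:
        """Per-draw derived quantities from flat draws (ndraw, n_params).

        Returns theta_a, theta_b (ndraw, S) and theta_c (ndraw, S, R).
        """
        S, R = self.n_sub, N_OPTIONS
        sl = self.slices
        nd = flat.shape[0]

        def col(name, default=0.0):
            if name not in sl:
                return np.full(nd, default)
            return flat[:, sl[name].start]

        log_a = col("beta0_a")[:, None] \
            + col("beta1_a")[:, None] * self.g_sub[None, :]
        log_b = col("beta0_b")[:, None] \
            + col("beta1_b")[:, None] * self.g_sub[None, :]
        c = col("beta0_c")[:, None] \
            + col("beta1_c")[:, None] * self.g_sub[None, :]
        if "a" in self.random:
            log_a = log_a + np.exp(col("s_a"))[:, None] * flat[:, sl["z_a"]]
        if "b" in self.random:
            log_b = log_b + np.exp(col("s_b"))[:, None] * flat[:, sl["z_b"]]
        af = flat[:, sl["alpha_free"]]
        alpha = np.concatenate([af, -af.sum(axis=1, keepdims=True)], axis=1)
        theta_c = c[:, :, None] + alpha[:, None, :]
        if "c" in self.random:
            theta_c = theta_c \
                + (np.exp(col("s_subj"))[:, None]
                   * flat[:, sl["u_c"]])[:, :, None] \
                + np.exp(col("s_cell"))[:, None, None] \
                * flat[:, sl["eps_c"]].reshape(nd, S, R)
        return {"theta_a": np.exp(log_a), "theta_b": np.exp(log_b),
                "theta_c": theta_c, "alpha": alpha,
                "sigma_log": np.exp(col("s_log"))}

    def eta_draws(self, flat: np.ndarray) -> np.ndarray:
        """Linear predictor per draw and observation (ndraw, N)."""
        d = self.subject_params(flat)
        A = d["theta_a"][:, self.obs_i]
        B = d["theta_b"][:, self.obs_i]
        C = d["theta_c"].reshape(flat.shape[0], -1)[:, self.cell_index]
        return A * np.exp(-B * self.t[None, :]) + C

    def pointwise_loglik(self, flat: np.ndarray) -> np.ndarray:
        """Log density of each observed RT per draw (ndraw, N).

        Includes the Jacobian to the RT scale, so values are densities of
        RT (not of log RT) and comparable across likelihood families.
        """
        from scipy.special import gammaln

        eta = self.eta_draws(flat)
        sigma = self.subject_params(flat)["sigma_log"][:, None]
        resid = self.y[None, :] - eta
        if self.spec.likelihood == "lognormal":
            return (-np.log(sigma) - 0.5 * math.log(2 * math.pi)
                    - 0.5 * resid ** 2 / sigma ** 2 - self.y[None, :])
        nu = self.spec.student_nu
        const = (gammaln((nu + 1) / 2) - gammaln(nu / 2)
                 - 0.5 * math.log(nu * math.pi))
        return (const - np.log(sigma)
                - 0.5 * (nu + 1) * np.log1p(resid ** 2 / (nu * sigma ** 2))
                - self.y[None, :])


def build(records: pd.DataFrame, labels: pd.DataFrame,
          spec: HierarchicalSpec) -> DecayModel:
    """Assemble a :class:`DecayModel` from single-item EMA records.

    ``records`` must contain exactly one item (fit per item, or pass the
    output of :func:`averaged_outcome`); every subject must appear in
    ``labels``; subjects with fewer than 4 observations are excluded and
    listed in ``model.audit``.
    """
    items = records["item"].unique()
    if len(items) != 1:
        raise ValueError(
            f"records contain {len(items)} items; fit one item at a time "
            "or use averaged_outcome()")
    item = str(items[0])
    counts = records.groupby("subject_id").size()
    small = sorted(counts[counts < 4].index)
    kept = records[~records["subject_id"].isin(small)]
    label_map = dict(zip(labels["subject_id"], labels["is_responder"]))
    subjects = sorted(kept["subject_id"].unique())
    unlabeled = [s for s in subjects if s not in label_map]
    if unlabeled:
        raise ValueError(f"subjects without responder label: {unlabeled}")
    sub_index = {s: k for k, s in enumerate(subjects)}

    t_max = kept["day_index"].max()
    if t_max <= 0:
        raise ValueError("need at least two distinct day indices")
    y = np.log(kept["rt_seconds"].to_numpy(dtype=float))
    t = kept["day_index"].to_numpy(dtype=float) / float(t_max)
    obs_i = kept["subject_id"].map(sub_index).to_numpy()
    obs_r = kept["likert"].to_numpy(dtype=int) - 1
    g_sub = np.array([label_map[s] for s in subjects], dtype=float)
    audit = {"excluded_small_subjects": small, "n_obs": int(len(kept)),
             "t_max": int(t_max)}
    return DecayModel(y, t, obs_i, obs_r, g_sub, subjects, item, spec, audit)


# ------------------------------------------------------------------ sampling
@dataclass
class Posterior:
    """Posterior draws plus diagnostics for one fit."""

    model: DecayModel
    spec: HierarchicalSpec
    draws: np.ndarray            # (chains, n_draws, n_params)
    chain_stats: list
    rhat_max: float
    ess_min: float
    divergence_frac: float
    reliable: bool
    warnings: list[str]

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_inference_data(self, log_likelihood: bool = True):
        """ArviZ InferenceData with named scalars + pointwise log-likelihood."""
        import arviz as az

        C, D, _ = self.draws.shape
        post = {}
        for name, slc in self.model.slices.items():
            width = slc.stop - slc.start
            if width == 1:
                key = {"s_log": "sigma_log", "s_a": "sigma_a",
                       "s_b": "sigma_b", "s_subj": "sigma_subj",
                       "s_cell": "sigma_cell"}.get(name, name)
                vals = self.draws[:, :, slc.start]
                post[key] = np.exp(vals) if name.startswith("s_") else vals
            else:
                post[name] = self.draws[:, :, slc]
        groups = {"posterior": post}
        if log_likelihood:
            ll = self.model.pointwise_loglik(self.flat)
            groups["log_likelihood"] = {
                "rt": ll.reshape(C, D, -1)}
        return az.from_dict(**groups)


def _scalar_names(model: DecayModel) -> list[str]:
    return [n for n, s in model.slices.items() if s.stop - s.start == 1]


def sample(model: DecayModel, spec: HierarchicalSpec | None = None,
           ) -> Posterior:
    """Draw from the posterior with NUTS; flag unreliable results.

    Chains run sequentially with seeds forked deterministically from
    ``spec.mcmc.seed``.  A divergence fraction above 5% or any split R-hat
    above 1.05 on the scalar parameters marks the result unreliable (a
    warning, not an error — the pipeline continues).
    """
    import arviz as az

    spec = spec or model.spec
    mc = spec.mcmc
    seeds = np.random.SeedSequence(mc.seed).spawn(mc.chains)
    draws = np.empty((mc.chains, mc.draws, model.n_params))
    stats = []
    for c in range(mc.chains):
        rng = np.random.default_rng(seeds[c])
        x0 = model.initial_point(rng)
        d, st = sample_nuts(model.logp_and_grad, x0, mc.warmup, mc.draws,
                            rng, target_accept=mc.target_accept,
                            max_treedepth=mc.max_treedepth)
        draws[c] = d
        stats.append(st)

    scalar_idx = {n: model.slices[n].start for n in _scalar_names(model)}
    ds = {n: draws[:, :, i] for n, i in scalar_idx.items()}
    rhat = az.rhat(az.convert_to_dataset(ds))
    ess = az.ess(az.convert_to_dataset(ds))
    rhat_max = float(max(rhat[v].values.max() for v in rhat.data_vars))
    ess_min = float(min(ess[v].values.min() for v in ess.data_vars))
    div_frac = sum(s.n_divergent for s in stats) / (mc.chains * mc.draws)

    warns = []
    if div_frac > 0.05:
        warns.append(f"divergence fraction {div_frac:.3f} > 0.05")
    if rhat_max > 1.05:
        warns.append(f"max R-hat {rhat_max:.3f} > 1.05")
    for w in warns:
        warnings.warn(f"unreliable posterior: {w}", stacklevel=2)
    return Posterior(model=model, spec=spec, draws=draws, chain_stats=stats,
                     rhat_max=rhat_max, ess_min=ess_min,
                     divergence_frac=div_frac, reliable=not warns,
                     warnings=warns)


def fit(records: pd.DataFrame, labels: pd.DataFrame,
        spec: HierarchicalSpec) -> Posterior:
    """build + sample in one call."""
    return sample(build(records, labels, spec), spec)


# ------------------------------------------------------------- comparison
def compare_loo(fits: list[tuple[str, Posterior]]) -> pd.DataFrame:
    """PSIS-LOO comparison of variants fit to identical observations.

    Returns one row per variant with elpd_loo, se, p_loo and the fraction
    of observations with Pareto k <= 0.7, sorted best first.
    """
    import arviz as az

    y_ref = fits[0][1].model.y
    rows = []
    for name, post in fits:
        if post.model.y.shape != y_ref.shape \
                or not np.allclose(post.model.y, y_ref):
            raise ValueError(
                f"variant {name!r} was fit to different observations")
        idata = post.to_inference_data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = az.loo(idata, pointwise=True)
        k = np.asarray(loo.pareto_k)
        rows.append({
            "variant": name,
            "elpd_loo": float(loo.elpd_loo),
            "se": float(loo.se),
            "p_loo": float(loo.p_loo),
            "frac_pareto_k_le_0_7": float(np.mean(k <= 0.7)),
        })
    return (pd.DataFrame(rows)
            .sort_values("elpd_loo", ascending=False)
            .reset_index(drop=True))


# ---------------------------------------------------------- group effects
_EFFECT_SLOT = {"theta_a": "beta1_a", "theta_b": "beta1_b",
                "exp_theta_c": "beta1_c"}


def group_effect_summary(posterior: Posterior,
                         parameter: str) -> PosteriorGroupEffect:
    """Responder/nonresponder ratio summary for one parameter.

    For the log-linked theta_a and theta_b the ratio is exp(beta1)
    draw-by-draw; for the additive log-RT asymptote the group effect
    exponentiates to a multiplicative RT ratio, reported as
    "exp_theta_c".  A ratio of 1 means no group difference on the
    original scale.
    """
    if parameter not in _EFFECT_SLOT:
        raise ValueError(f"unknown parameter {parameter!r}")
    if not posterior.spec.moderated:
        raise ValueError("group effects require a moderated fit")
    slot = _EFFECT_SLOT[parameter]
    beta1 = posterior.flat[:, posterior.model.slices[slot].start]
    ratio = np.exp(beta1)
    lo, med, hi = np.percentile(ratio, [2.5, 50, 97.5])
    return PosteriorGroupEffect(
        item=posterior.model.item, parameter=parameter,
        ratio_median=float(med), cri_low=float(lo), cri_high=float(hi),
        p_increase=float(np.mean(ratio > 1.0)))


# ------------------------------------------------------------------- PPC
def ppc_binned(posterior: Posterior, n_bins: int = 10,
               n_ppc_draws: int = 500, seed: int = 0,
               interval: float = 0.94) -> pd.DataFrame:
    """Binned posterior predictive check on the original RT scale.

    Observations are binned by normalized time; per posterior draw the
    model simulates replicate RTs and the per-bin mean is summarized by
    its predictive median and central ``interval`` (default 94%) band,
    against the observed per-bin mean.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    model = posterior.model
    rng = np.random.default_rng(seed)
    flat = posterior.flat
    take = min(n_ppc_draws, flat.shape[0])
    idx = rng.choice(flat.shape[0], size=take, replace=False)
    sub = flat[idx]

    eta = model.eta_draws(sub)
    sigma = model.subject_params(sub)["sigma_log"][:, None]
    if posterior.spec.likelihood == "lognormal":
        noise = rng.standard_normal(eta.shape)
    else:
        noise = rng.standard_t(posterior.spec.student_nu, size=eta.shape)
    rt_rep = np.exp(eta + sigma * noise)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, model.t, side="right") - 1,
                     0, n_bins - 1)
    obs_rt = np.exp(model.y)
    lo_q, hi_q = 50 * (1 - interval), 50 * (1 + interval)
    rows = []
    for b in range(n_bins):
        mask = bin_of == b
        if not mask.any():
            continue
        rep_means = rt_rep[:, mask].mean(axis=1)
        lo, med, hi = np.percentile(rep_means, [lo_q, 50, hi_q])
        obs_mean = float(obs_rt[mask].mean())
        rows.append({
            "bin": b,
            "t_mid": float(0.5 * (edges[b] + edges[b + 1])),
            "n_obs": int(mask.sum()),
            "observed_mean_rt": obs_mean,
            "predictive_median": float(med),
            "interval_low": float(lo),
            "interval_high": float(hi),
            "covered": bool(lo <= obs_mean <= hi),
        })
    return pd.DataFrame(rows)


def prior_predictive(model: DecayModel, n_draws: int = 200,
                     seed: int = 0) -> np.ndarray:
    """Simulate RTs from the prior (data ignored): (n_draws, N) array.

    Draws every parameter block from its prior (half-normal scales,
    standard-normal latents, the configured beta/alpha priors) and pushes
    them through the observation model.
    """
    rng = np.random.default_rng(seed)
    sc = model.spec.prior_scales
    flat = np.empty((n_draws, model.n_params))
    for name, sl in model.slices.items():
        width = sl.stop - sl.start
        if name.startswith("s_"):
            tau = sc.sigma_log if name == "s_log" else sc.sigma_re
            sigma = np.abs(rng.normal(0.0, tau, (n_draws, width)))
            flat[:, sl] = np.log(np.maximum(sigma, 1e-6))
        elif name.startswith("beta0"):
            mu = model.mu_emp[name[-1]]
            flat[:, sl] = rng.normal(mu, sc.beta0, (n_draws, width))
        elif name.startswith("beta1"):
            flat[:, sl] = rng.normal(0.0, sc.beta1, (n_draws, width))
        elif name == "alpha_free":
            flat[:, sl] = rng.normal(0.0, sc.alpha, (n_draws, width))
        else:  # non-centered latents
            flat[:, sl] = rng.standard_normal((n_draws, width))
    eta = model.eta_draws(flat)
    sigma_log = model.subject_params(flat)["sigma_log"][:, None]
    with np.errstate(over="ignore"):  # wide priors may overflow to inf
        return np.exp(eta + sigma_log * rng.standard_normal(eta.shape))


# ------------------------------------------------------------ sensitivity
def sensitivity_suite(records: pd.DataFrame, labels: pd.DataFrame,
                      base_spec: HierarchicalSpec) -> pd.DataFrame:
    """Refit under alternative specifications; summarize group effects.

    Rows: the base (selected) specification, the full random-effects
    variant, a Student-t observation model on log RT, and Student-t priors
    on the beta coefficients.  A refit failing the reliability gate is
    flagged but does not stop the suite.
    """
    specs = [
        ("base", base_spec),
        ("full_random_effects", replace(base_spec, variant="full")),
        ("student_t_likelihood", replace(base_spec, likelihood="student_t")),
        ("student_t_priors", replace(base_spec, prior_family="student_t")),
    ]
    rows = []
    for name, spec in specs:
        post = fit(records, labels, spec)
        for par in ("theta_b", "exp_theta_c"):
            eff = group_effect_summary(post, par)
            rows.append({
                "specification": name, "parameter": par,
                "ratio_median": eff.ratio_median,
                "cri_low": eff.cri_low, "cri_high": eff.cri_high,
                "p_increase": eff.p_increase,
                "reliable": post.reliable,
                "flags": "; ".join(post.warnings),
            })
    return pd.DataFrame(rows)


# ------------------------------------------------------- averaged outcome
def averaged_outcome(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse items to one record per (subject, day).

    RT is averaged across the items available that day; the averaged
    Likert score is mapped back to a 1..7 option index by 7 equal-width
    bins over [1, 7] (right-open except the last), so the averaged outcome
    keeps the response-option structure of the item-level models.
    """
    g = records.groupby(["subject_id", "day_index"], sort=True)
    out = g.agg(rt_seconds=("rt_seconds", "mean"),
                mean_score=("likert", "mean")).reset_index()
    out["likert"] = bin_average_score(out["mean_score"].to_numpy())
    out["item"] = "average"
    return out[["subject_id", "item", "day_index", "likert", "rt_seconds"]]


def bin_average_score(scores) -> np.ndarray:
    """7 equal-width bins over [1, 7], right-open except the last bin."""
    scores = np.asarray(scores, dtype=float)
    width = 6.0 / 7.0
    return np.minimum(np.floor((scores - 1.0) / width), 6).astype(int) + 1
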