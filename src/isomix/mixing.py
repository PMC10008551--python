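"""Concentration-dependent Bayesian mixing model for palaeodiet reconstruction.

Estimates the caloric contribution vector α of a configured set of
food groups from a consumer group's collagen δ13C, δ15N and carbonate
δ13C (mean ± sd), in the FRUITS family of models:

* each food source is split into macronutrient *fractions* (protein,
  energy) with per-fraction isotopic signals and caloric
  concentrations;
* each dietary proxy mixes fraction-level signals through a *routing*
  (collagen carbon mostly from dietary protein; nitrogen entirely so;
  carbonate carbon from the whole diet, weighted by calories);
* a diet-to-tissue offset Δ with its own uncertainty is added per
  proxy;
* user-declared linear inequality priors on α (e.g. "cereals supply at
  least 30% of calories") sharpen otherwise weakly identified systems.

Inference is random-walk Metropolis on the additive-logistic transform
of the simplex, with source signals, offsets and concentrations
treated as latent values redrawn from their priors at every proposal
and accepted jointly with α.  The base prior on α is uniform on the
simplex; inequality priors are enforced by rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd

__all__ = [
    "FoodSource",
    "ProxyTarget",
    "Constraint",
    "MixingProblem",
    "McmcSettings",
    "DietPosterior",
    "build_problem",
    "forward_model",
    "sample_posterior",
    "summarize_posterior",
    "default_sources",
    "default_offsets",
    "default_routing",
    "problem_from_config",
]

RHAT_LIMIT = 1.05


@dataclass(frozen=True)
class FoodSource:
    """A food group with per-macronutrient signals and caloric concentrations.

    ``signals``: fraction -> proxy -> (mean ‰, sd ‰).
    ``concentrations``: fraction -> (caloric fraction in [0,1], sd);
    concentrations must sum to 1 across fractions.
    """

    name: str
    signals: Mapping[str, Mapping[str, tuple[float, float]]]
    concentrations: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        total = sum(c for c, _ in self.concentrations.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: fraction concentrations sum to {total}, not 1")
        for frac, sig in self.signals.items():
            for proxy, (_, sd) in sig.items():
                if sd < 0:
                    raise ValueError(f"{self.name}/{frac}/{proxy}: negative sd")


@dataclass(frozen=True)
class ProxyTarget:
    """Consumer group mean ± sd for one proxy."""

    name: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.name}: target sd must be > 0")


@dataclass(frozen=True)
class Constraint:
    """Linear inequality prior  Σ_k coeffs[k]·α_k ≥ lower."""

    coeffs: Mapping[str, float]
    lower: float
    label: str = ""

    @classmethod
    def at_least(cls, source: str, value: float) -> "Constraint":
        return cls(coeffs={source: 1.0}, lower=value, label=f"{source} >= {value}")

    @classmethod
    def at_most(cls, source: str, value: float) -> "Constraint":
        return cls(coeffs={source: -1.0}, lower=-value, label=f"{source} <= {value}")


#: routing value meaning "weight fractions by their caloric share in the diet"
WHOLE_DIET = "whole_diet"


@dataclass
class MixingProblem:
    """Validated, array-compiled mixing problem.

    Built through :func:`build_problem`; the compiled arrays are

    - ``C``  (K, F)    caloric concentration means, ``C_sd`` their sds
    - ``S``  (K, F, P) signal means, ``S_sd`` their sds (0 where undefined)
    - ``R``  (P, F)    routing weights; rows flagged in ``whole_diet``
      use caloric-share weights instead
    - ``A`` (m, K), ``b`` (m,)  inequality priors  A α ≥ b
    """

    sources: list[FoodSource]
    proxies: list[ProxyTarget]
    offsets: dict[str, tuple[float, float]]
    routing: dict[str, object]
    constraints: list[Constraint] = field(default_factory=list)

    source_names: list[str] = field(init=False)
    fraction_names: list[str] = field(init=False)
    proxy_names: list[str] = field(init=False)
    C: np.ndarray = field(init=False)
    C_sd: np.ndarray = field(init=False)
    S: np.ndarray = field(init=False)
    S_sd: np.ndarray = field(init=False)
    S_mask: np.ndarray = field(init=False)
    R: np.ndarray = field(init=False)
    whole_diet: np.ndarray = field(init=False)
    target_mean: np.ndarray = field(init=False)
    target_sd: np.ndarray = field(init=False)
    offset_mean: np.ndarray = field(init=False)
    offset_sd: np.ndarray = field(init=False)
    A: np.ndarray = field(init=False)
    b: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.source_names = [s.name for s in self.sources]
        fracs: list[str] = []
        for s in self.sources:
            for f in s.concentrations:
                if f not in fracs:
                    fracs.append(f)
        self.fraction_names = fracs
        self.proxy_names = [p.name for p in self.proxies]
        K, F, P = len(self.sources), len(fracs), len(self.proxies)

        self.C = np.zeros((K, F))
        self.C_sd = np.zeros((K, F))
        self.S = np.zeros((K, F, P))
        self.S_sd = np.zeros((K, F, P))
        self.S_mask = np.zeros((K, F, P), dtype=bool)
        for k, s in enumerate(self.sources):
            for f_name, (c, c_sd) in s.concentrations.items():
                f = fracs.index(f_name)
                self.C[k, f] = c
                self.C_sd[k, f] = c_sd
            for f_name, sig in s.signals.items():
                f = fracs.index(f_name)
                for p_name, (m, sd) in sig.items():
                    if p_name not in self.proxy_names:
                        continue
                    p = self.proxy_names.index(p_name)
                    self.S[k, f, p] = m
                    self.S_sd[k, f, p] = sd
                    self.S_mask[k, f, p] = True

        self.R = np.zeros((P, F))
        self.whole_diet = np.zeros(P, dtype=bool)
        for p, name in enumerate(self.proxy_names):
            if name not in self.routing:
                raise ValueError(f"no routing declared for proxy {name}")
            spec = self.routing[name]
            if spec == WHOLE_DIET:
                self.whole_diet[p] = True
                self.R[p] = 1.0  # all fractions participate, weighted by calories
                continue
            total = 0.0
            for f_name, w in spec.items():  # type: ignore[union-attr]
                if f_name not in fracs:
                    raise ValueError(f"routing for {name} references unknown fraction {f_name}")
                self.R[p, fracs.index(f_name)] = w
                total += w
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"routing weights for {name} sum to {total}, not 1")

        # every (source, fraction, proxy) reached by routing must have a signal
        for p in range(P):
            for f in range(F):
                if self.R[p, f] <= 0:
                    continue
                for k in range(K):
                    if self.C[k, f] > 0 and not self.S_mask[k, f, p]:
                        raise ValueError(
                            f"source {self.source_names[k]} lacks a "
                            f"{self.proxy_names[p]} signal for fraction {fracs[f]}"
                        )

        self.target_mean = np.array([p.mean for p in self.proxies])
        self.target_sd = np.array([p.sd for p in self.proxies])
        self.offset_mean = np.zeros(P)
        self.offset_sd = np.zeros(P)
        for p, name in enumerate(self.proxy_names):
            if name in self.offsets:
                self.offset_mean[p], self.offset_sd[p] = self.offsets[name]

        m = len(self.constraints)
        self.A = np.zeros((m, K))
        self.b = np.zeros(m)
        for i, con in enumerate(self.constraints):
            for s_name, coef in con.coeffs.items():
                if s_name not in self.source_names:
                    raise ValueError(f"constraint references unknown source {s_name}")
                self.A[i, self.source_names.index(s_name)] = coef
            self.b[i] = con.lower

    # -- helpers -----------------------------------------------------------

    def satisfies(self, alpha: np.ndarray) -> np.ndarray:
        """Boolean mask: does each α row satisfy every inequality prior?"""
        alpha = np.atleast_2d(alpha)
        if self.A.size == 0:
            return np.ones(alpha.shape[0], dtype=bool)
        return np.all(alpha @ self.A.T >= self.b - 1e-12, axis=1)


def build_problem(
    sources: Sequence[FoodSource],
    proxies: Sequence[ProxyTarget],
    offsets: Mapping[str, tuple[float, float]],
    routing: Mapping[str, object],
    priors: Sequence[Constraint] = (),
    feasibility_draws: int = 20_000,
    seed: int = 0,
) -> MixingProblem:
    """Validate and compile a mixing problem.

    Raises if fewer than two sources or no proxies are given, or if the
    inequality priors leave no feasible point on the simplex (checked
    by uniform-Dirichlet sampling).
    """
    if len(sources) < 2:
        raise ValueError("at least 2 sources required")
    if len(proxies) < 1:
        raise ValueError("at least 1 proxy required")
    problem = MixingProblem(
        sources=list(sources),
        proxies=list(proxies),
        offsets=dict(offsets),
        routing=dict(routing),
        constraints=list(priors),
    )
    if problem.constraints:
        rng = np.random.default_rng(seed)
        alphas = rng.dirichlet(np.ones(len(sources)), size=feasibility_draws)
        ok = problem.satisfies(alphas)
        if not ok.any():
            sat_each = alphas @ problem.A.T >= problem.b - 1e-12
            rates = sat_each.mean(axis=0)
            worst = [
                problem.constraints[i].label or f"constraint {i}"
                for i in np.argsort(rates)[: max(1, (rates < 1.0).sum())]
            ]
            raise ValueError(f"infeasible prior constraint system; check: {worst}")
    return problem


# -- forward model -----------------------------------------------------------

def forward_model(
    alpha: np.ndarray,
    problem: MixingProblem,
    signals: np.ndarray | None = None,
    offsets: np.ndarray | None = None,
    concentrations: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted proxy means for contribution vector(s) α.

    For proxy i with explicit routing weights R over fractions f:

        pred_i = Δ_i + Σ_f R_{i,f} · (Σ_k α_k c_{k,f} s_{k,f,i}) / (Σ_k α_k c_{k,f})

    For a whole-diet proxy the fraction weights are the caloric shares
    Σ_k α_k c_{k,f} themselves (which sum to 1), so the division
    cancels and the prediction is the concentration-weighted mean over
    the entire diet.  ``signals``/``offsets``/``concentrations``
    override the stored means (used for latent draws during sampling).

    α may be a single (K,) vector or a batch (..., K).
    """
    S = problem.S if signals is None else signals
    off = problem.offset_mean if offsets is None else offsets
    C = problem.C if concentrations is None else concentrations
    a = np.asarray(alpha, dtype=float)
    squeeze = a.ndim == 1
    a = np.atleast_2d(a)  # (B, K)

    # caloric mass per fraction: (B, F) ; C may be (K,F) or batched (B,K,F)
    if C.ndim == 2:
        mass = a @ C
        num = np.einsum("bk,kf,kfp->bfp", a, C, S) if S.ndim == 3 else np.einsum(
            "bk,kf,bkfp->bfp", a, C, S
        )
    else:
        mass = np.einsum("bk,bkf->bf", a, C)
        num = np.einsum("bk,bkf,bkfp->bfp", a, C, S) if S.ndim == 4 else np.einsum(
            "bk,bkf,kfp->bfp", a, C, S
        )

    P = len(problem.proxy_names)
    pred = np.empty((a.shape[0], P))
    for p in range(P):
        if problem.whole_diet[p]:
            pred[:, p] = num[:, :, p].sum(axis=1)  # Σ_f Σ_k α c s ; Σ mass = 1
        else:
            w = problem.R[p]  # (F,)
            active = w > 0
            if np.any(mass[:, active] <= 0):
                raise ValueError(
                    f"zero total concentration in a fraction routed to {problem.proxy_names[p]}"
                )
            frac_mean = num[:, active, p] / mass[:, active]
            pred[:, p] = frac_mean @ w[active]
    pred = pred + (off if np.ndim(off) <= 1 else off)
    return pred[0] if squeeze else pred


# -- posterior sampling ------------------------------------------------------

@dataclass(frozen=True)
class McmcSettings:
    seed: int
    chains: int = 4
    iterations: int = 4000  # post burn-in, per chain
    burn_in: int = 2000
    thinning: int = 1
    initial_step: float = 0.4
    target_accept: float = 0.30

    def __post_init__(self) -> None:
        for name in ("chains", "iterations", "burn_in", "thinning"):
            if getattr(self, name) <= 0 and name != "burn_in":
                raise ValueError(f"{name} must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class DietPosterior:
    """Posterior draws of caloric contributions with diagnostics."""

    source_names: list[str]
    chain_draws: np.ndarray  # (chains, draws, K)
    rhat: np.ndarray
    ess: np.ndarray
    accept_rate: float
    settings: McmcSettings

    @property
    def draws(self) -> np.ndarray:
        """(n, K) pooled post burn-in, thinned draws."""
        c, t, k = self.chain_draws.shape
        return self.chain_draws.reshape(c * t, k)

    @property
    def converged(self) -> bool:
        return bool(np.all(self.rhat <= RHAT_LIMIT))


def _softmax_alpha(z: np.ndarray) -> np.ndarray:
    """(B, K-1) free logits (last logit pinned at 0) -> (B, K) simplex points."""
    full = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _draw_latents(problem: MixingProblem, rng: np.random.Generator, batch: int):
    """Fresh latent signals, offsets and concentrations from their priors."""
    S = problem.S + problem.S_sd * rng.standard_normal((batch, *problem.S.shape))
    off = problem.offset_mean + problem.offset_sd * rng.standard_normal(
        (batch, len(problem.proxy_names))
    )
    if np.any(problem.C_sd > 0):
        C = problem.C + problem.C_sd * rng.standard_normal((batch, *problem.C.shape))
        C = np.clip(C, 1e-6, None)
        C /= C.sum(axis=2, keepdims=True)  # renormalise fractions within source
    else:
        C = np.repeat(problem.C[None], batch, axis=0)
    return S, off, C


def _log_target(
    problem: MixingProblem,
    alpha: np.ndarray,
    S: np.ndarray,
    off: np.ndarray,
    C: np.ndarray,
) -> np.ndarray:
    """Log posterior kernel per chain: likelihood + simplex Jacobian, −inf off-prior."""
    B = alpha.shape[0]
    logp = np.full(B, -np.inf)
    ok = problem.satisfies(alpha)
    if not ok.any():
        return logp
    pred = forward_model(alpha[ok], problem, signals=S[ok], offsets=off[ok], concentrations=C[ok])
    resid = (pred - problem.target_mean) / problem.target_sd
    loglik = -0.5 * np.sum(resid**2, axis=1)
    jac = np.sum(np.log(np.clip(alpha[ok], 1e-300, None)), axis=1)
    logp[ok] = loglik + jac
    return logp


def sample_posterior(problem: MixingProblem, settings: McmcSettings) -> DietPosterior:
    """Sample the contribution posterior by adaptive random-walk Metropolis.

    The chain state is (z, latent signals/offsets/concentrations); the
    latents are proposed fresh from their priors each iteration so the
    prior terms cancel in the acceptance ratio and source/offset
    uncertainty is fully propagated.  Step sizes adapt per chain during
    burn-in toward ~30% acceptance and are frozen afterwards.  Warns
    (and flags the posterior unconverged) if split R-hat exceeds 1.05.
    """
    rng = np.random.default_rng(settings.seed)
    K = len(problem.source_names)
    B = settings.chains

    if K == 1:
        draws = np.ones((B, settings.iterations // settings.thinning, 1))
        return DietPosterior(
            source_names=list(problem.source_names),
            chain_draws=draws,
            rhat=np.ones(1),
            ess=np.full(1, float(draws.shape[0] * draws.shape[1])),
            accept_rate=1.0,
            settings=settings,
        )

    # initialise inside the constraint set
    z = np.zeros((B, K - 1))
    alpha0 = _softmax_alpha(z)
    if not problem.satisfies(alpha0).all():
        cand = rng.dirichlet(np.ones(K), size=4000)
        good = cand[problem.satisfies(cand)]
        if len(good) == 0:
            raise ValueError("could not initialise chains inside the constraint set")
        pick = good[rng.integers(0, len(good), size=B)]
        z = np.log(np.clip(pick[:, :-1], 1e-9, None)) - np.log(np.clip(pick[:, -1:], 1e-9, None))

    S, off, C = _draw_latents(problem, rng, B)
    alpha = _softmax_alpha(z)
    logp = _log_target(problem, alpha, S, off, C)

    step = np.full(B, settings.initial_step)
    total = settings.burn_in + settings.iterations
    kept: list[np.ndarray] = []
    accepted = np.zeros(B)
    window_acc = np.zeros(B)
    n_accept_post = 0
    n_post = 0

    for it in range(total):
        # (1) random-walk update of z with the latents held fixed
        z_prop = z + step[:, None] * rng.standard_normal((B, K - 1))
        alpha_prop = _softmax_alpha(z_prop)
        logp_prop = _log_target(problem, alpha_prop, S, off, C)
        accept = np.log(rng.random(B)) < logp_prop - logp
        z[accept] = z_prop[accept]
        logp[accept] = logp_prop[accept]
        accepted += accept
        window_acc += accept

        # (2) independence refresh of the latent signals/offsets from their
        # priors with α held fixed (prior terms cancel in the ratio)
        alpha_cur = _softmax_alpha(z)
        S_p, off_p, C_p = _draw_latents(problem, rng, B)
        logp_lat = _log_target(problem, alpha_cur, S_p, off_p, C_p)
        acc_lat = np.log(rng.random(B)) < logp_lat - logp
        S[acc_lat] = S_p[acc_lat]
        off[acc_lat] = off_p[acc_lat]
        C[acc_lat] = C_p[acc_lat]
        logp[acc_lat] = logp_lat[acc_lat]

        if it < settings.burn_in:
            if (it + 1) % 50 == 0:
                rate = window_acc / 50.0
                step *= np.exp(0.6 * (rate - settings.target_accept))
                step = np.clip(step, 1e-3, 5.0)
                window_acc[:] = 0.0
        else:
            n_post += B
            n_accept_post += int(accept.sum())
            if (it - settings.burn_in) % settings.thinning == 0:
                kept.append(_softmax_alpha(z).copy())

    chain_draws = np.stack(kept, axis=1)  # (chains, draws, K)
    idata = az.from_dict(posterior={"alpha": chain_draws})
    if B >= 2:
        rhat = np.asarray(az.rhat(idata)["alpha"]).ravel()
    else:
        rhat = np.ones(K)  # split R-hat needs multiple chains
    ess = np.asarray(az.ess(idata)["alpha"]).ravel()
    post = DietPosterior(
        source_names=list(problem.source_names),
        chain_draws=chain_draws,
        rhat=rhat,
        ess=ess,
        accept_rate=n_accept_post / max(n_post, 1),
        settings=settings,
    )
    if not post.converged:
        warnings.warn(
            "MCMC did not converge: max R-hat "
            f"{float(np.nanmax(rhat)):.3f} > {RHAT_LIMIT} "
            f"(ESS min {float(np.nanmin(ess)):.0f}); increase iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return post


def summarize_posterior(
    posterior: DietPosterior, problem: MixingProblem | None = None
) -> pd.DataFrame:
    """Mean/median and equal-tailed 68%/95% intervals per source.

    When the problem is supplied, rows for the derived caloric
    protein-vs-energy macronutrient split are appended (per-draw caloric
    share of each fraction, using mean concentrations).
    """
    draws = posterior.draws
    rows = []

    def _quantile_rows(name: str, kind: str, values: np.ndarray) -> dict:
        q = np.quantile(values, [0.025, 0.16, 0.5, 0.84, 0.975])
        return {
            "name": name,
            "kind": kind,
            "mean": float(values.mean()),
            "median": float(q[2]),
            "ci68_low": float(q[1]),
            "ci68_high": float(q[3]),
            "ci95_low": float(q[0]),
            "ci95_high": float(q[4]),
        }

    for k, name in enumerate(posterior.source_names):
        rows.append(_quantile_rows(name, "source", draws[:, k]))
    if problem is not None:
        shares = draws @ problem.C  # (n, F): caloric share per macronutrient fraction
        for f, frac in enumerate(problem.fraction_names):
            rows.append(_quantile_rows(frac, "macronutrient", shares[:, f]))
    return pd.DataFrame(rows).set_index("name")


def interval_coverage_study(
    base: MixingProblem,
    n_replicates: int = 100,
    seed: int = 0,
    level: float = 0.95,
    settings: McmcSettings | None = None,
) -> dict:
    """Simulation-based calibration of the posterior credible intervals.

    For each replicate a true α is drawn uniformly from the simplex and
    latent signals/offsets/concentrations from their priors; synthetic
    consumer targets are the forward predictions plus Gaussian noise at
    the target sds.  The posterior is then sampled and we record
    whether each α_k falls inside its equal-tailed credible interval.
    A well-calibrated sampler attains ≈ ``level`` pooled coverage.
    """
    rng = np.random.default_rng(seed)
    K = len(base.source_names)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    hits = np.zeros((n_replicates, K), dtype=bool)
    for r in range(n_replicates):
        alpha = rng.dirichlet(np.ones(K))
        S = base.S + base.S_sd * rng.standard_normal(base.S.shape)
        off = base.offset_mean + base.offset_sd * rng.standard_normal(base.offset_mean.shape)
        C = np.clip(base.C + base.C_sd * rng.standard_normal(base.C.shape), 1e-6, None)
        C /= C.sum(axis=1, keepdims=True)
        pred = forward_model(alpha, base, signals=S, offsets=off, concentrations=C)
        y = pred + base.target_sd * rng.standard_normal(len(base.proxy_names))
        proxies = [
            ProxyTarget(n, float(y[i]), float(base.target_sd[i]))
            for i, n in enumerate(base.proxy_names)
        ]
        problem = MixingProblem(
            sources=base.sources,
            proxies=proxies,
            offsets=base.offsets,
            routing=base.routing,
            constraints=base.constraints,
        )
        rep_seed = int(rng.integers(2**31 - 1))
        if settings is None:
            rep_settings = McmcSettings(seed=rep_seed, iterations=2000, burn_in=1500)
        else:
            rep_settings = replace(settings, seed=rep_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post = sample_posterior(problem, rep_settings)
        lo, hi = np.quantile(post.draws, [lo_q, hi_q], axis=0)
        hits[r] = (alpha >= lo) & (alpha <= hi)
    return {
        "level": level,
        "n_replicates": n_replicates,
        "pooled_coverage": float(hits.mean()),
        "per_source_coverage": dict(zip(base.source_names, hits.mean(axis=0).tolist())),
    }


# -- defaults and configuration ----------------------------------------------

PROXY_COLL_C = "d13C_coll"
PROXY_N = "d15N"
PROXY_CARB_C = "d13C_carb"


def default_sources() -> list[FoodSource]:
    """The seven food groups of a late-medieval south-Italian economy.

    Signal and concentration values are package defaults chosen from
    the general FRUITS literature (C3 vs C4 photosynthetic endmembers,
    trophic-level δ15N, marine enrichment); they are configuration, not
    measured data, and are meant to be overridden with site-specific
    food values where available.
    """

    def src(name, p13, e13, p15, cp, sd13=0.5, sd15=0.5, csd=0.03):
        return FoodSource(
            name=name,
            signals={
                "protein": {PROXY_COLL_C: (p13, sd13), PROXY_N: (p15, sd15), PROXY_CARB_C: (p13, sd13)},
                "energy": {PROXY_COLL_C: (e13, sd13), PROXY_CARB_C: (e13, sd13)},
            },
            concentrations={"protein": (cp, csd), "energy": (1.0 - cp, csd)},
        )

    return [
        src("C3 plants", -26.0, -26.5, 3.0, 0.15),
        src("C4 cereals", -11.0, -11.5, 2.5, 0.12),
        src("cattle", -21.5, -22.5, 7.5, 0.60),
        src("ovicaprid", -21.5, -23.0, 6.5, 0.55),
        src("pig", -21.5, -23.5, 7.0, 0.45),
        src("poultry", -21.0, -23.0, 10.0, 0.60),
        src("marine fish", -12.5, -14.5, 12.0, 0.80),
    ]


def default_offsets() -> dict[str, tuple[float, float]]:
    """Diet-to-tissue offsets Δ (mean ‰, sd ‰) per proxy."""
    return {
        PROXY_COLL_C: (4.8, 0.5),
        PROXY_N: (5.5, 0.5),
        PROXY_CARB_C: (10.1, 1.0),
    }


def default_routing() -> dict[str, object]:
    """Macronutrient routing: collagen C 75% protein / 25% energy;
    N all protein; carbonate C the caloric whole diet."""
    return {
        PROXY_COLL_C: {"protein": 0.75, "energy": 0.25},
        PROXY_N: {"protein": 1.0},
        PROXY_CARB_C: WHOLE_DIET,
    }


def problem_from_config(cfg: Mapping) -> MixingProblem:
    """Build a problem from a YAML/JSON-style nested mapping.

    Schema::

        sources:
          - name: C3 plants
            signals: {protein: {d13C_coll: [-26.0, 0.5], ...}, energy: {...}}
            concentrations: {protein: [0.15, 0.03], energy: [0.85, 0.03]}
        proxies:
          - {name: d13C_coll, mean: -19.0, sd: 0.7}
        offsets: {d13C_coll: [4.8, 0.5], ...}
        routing: {d13C_coll: {protein: 0.75, energy: 0.25}, d13C_carb: whole_diet}
        priors:
          - {coeffs: {"C3 plants": 1.0}, lower: 0.3}
    """
    sources = [
        FoodSource(
            name=s["name"],
            signals={
                f: {p: tuple(v) for p, v in sig.items()} for f, sig in s["signals"].items()
            },
            concentrations={f: tuple(v) for f, v in s["concentrations"].items()},
        )
        for s in cfg["sources"]
    ]
    proxies = [ProxyTarget(name=p["name"], mean=p["mean"], sd=p["sd"]) for p in cfg["proxies"]]
    offsets = {k: tuple(v) for k, v in cfg.get("offsets", {}).items()}
    routing = {
        k: (v if v == WHOLE_DIET else dict(v)) for k, v in cfg["routing"].items()
    }
    priors = [
        Constraint(coeffs=dict(c["coeffs"]), lower=float(c["lower"]), label=c.get("label", ""))
        for c in cfg.get("priors", [])
    ]
    return build_problem(sources, proxies, offsets, routing, priors)
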