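"""Bayesian calibration of the trimineral external-standard model.

Component 1 of the two-part system.  Standard mixtures of known composition
are measured on the instrument; this module fits the generative model

    I_lj ~ Normal(lambda_lj,  kappa * lambda_lj),
    lambda_lj = Lambda_j * k_l pi_lj / sum_i k_i pi_ij,

to those measurements, estimating the reference intensity ratios (k2, k3;
k1 = 1 pinned), the heteroskedastic noise scale kappa, and one expected total
intensity Lambda_j per analysed subsample (mount).  Priors are deliberately
diffuse: k2, k3 ~ Uniform(0.01, 100); Lambda_j flat on the positive axis by
default (the likelihood anchors each Lambda_j at its run's observed total);
kappa ~ Gamma(0.001, 0.001) truncated to (0.001, 1e3).

Two prior choices here are load-bearing.  The classic BUGS-style vague
Gamma(0.001, 0.001) prior - available via ``lambda_prior='gamma'`` for
sensitivity analysis - has a density spike at zero that, applied to a
mean-scale parameter like Lambda, rewards collapsing every Lambda_j toward
zero while kappa inflates to pass the residuals off as noise; that
degenerate ridge can dominate the well-fitting posterior mode, especially
on misspecified data.  The flat Lambda prior removes the mechanism, and the
kappa support bound (kappa = 1e3 already means a noise SD equal to the peak
height itself) is a weakly-informative physical backstop.  On well-specified
calibration data the two Lambda priors give practically identical
(k2, k3, kappa) posteriors.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme run as
several independent chains (vectorised across chains); the contract is the
posterior itself, verified by Gelman-Rubin diagnostics, effective sample
sizes, and posterior-predictive (Bayesian) p-values.

Usage follows the fit/results idiom::

    model = CalibrationModel(samples)
    res = model.fit(MCMCConfig(iterations=200_000, seed=1))
    print(res.summary())
    res.to_json("calibration.json")
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from .model import CalibrationSample, RIRSet

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "CalibrationFit",
    "CalibrationModel",
    "fit_calibration",
    "gelman_rubin",
    "compute_bayesian_p_values",
    "ConvergenceWarning",
]

MINERAL_LABELS = ("aragonite", "lmc", "hmc")

K_LO, K_HI = 0.01, 100.0
# kappa support: Var(I) = kappa*lambda, so kappa ~ 1e3 already means a noise
# SD comparable to the peak height itself - far beyond any usable instrument.
# The upper bound is load-bearing: together with the Lambda prior's density
# spike at zero, an unbounded kappa admits a degenerate posterior ridge
# (Lambda_j -> 0, kappa -> infinity) that can dominate the well-fitting mode.
KAPPA_LO, KAPPA_HI = 1e-3, 1e3
LAMBDA_GAMMA_SHAPE = 0.001
LAMBDA_GAMMA_RATE = 0.001


class ConvergenceWarning(UserWarning):
    """Raised (as a warning, never silently) when chains have not mixed."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``iterations`` is the total Monte Carlo iteration count summed over
    chains (the convention used when quoting run length for this model);
    each chain therefore runs ``iterations // chains`` sweeps.  A seed is
    mandatory: calibration results must be reproducible.
    """

    seed: int
    iterations: int = 500_000
    chains: int = 4
    burn_fraction: float = 0.5
    thin: int = 10
    kappa_prior: str = "gamma"  # "gamma" (default) or "uniform"
    lambda_prior: str = "flat"  # "flat" (default) or "gamma"
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if not (0 < self.burn_fraction < 1):
            raise ValueError("burn_fraction must be in (0, 1)")
        if self.iterations // self.chains <= 10 * self.thin:
            raise ValueError("iterations too small for burn-in + thinning")
        if self.kappa_prior not in ("uniform", "gamma"):
            raise ValueError("kappa_prior must be 'uniform' or 'gamma'")
        if self.lambda_prior not in ("flat", "gamma"):
            raise ValueError("lambda_prior must be 'flat' or 'gamma'")

    @property
    def sweeps_per_chain(self) -> int:
        return self.iterations // self.chains

    @property
    def burn_sweeps(self) -> int:
        return int(self.sweeps_per_chain * self.burn_fraction)


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained post-burn-in draws, shape (chains, draws) / (chains, draws, runs)."""

    k2: np.ndarray
    k3: np.ndarray
    kappa: np.ndarray
    lam: np.ndarray
    run_ids: tuple[tuple[str, str], ...]

    @property
    def n_chains(self) -> int:
        return self.k2.shape[0]

    @property
    def n_draws(self) -> int:
        return self.k2.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        a = getattr(self, name)
        return a.reshape(-1, *a.shape[2:])


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor (Brooks-Gelman-Rubin R-hat).

    ``chains`` has shape (n_chains, n_draws).  Values near 1 indicate the
    between-chain variance is consistent with the within-chain variance.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains too short")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def _effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size via arviz (rank-normalised)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(chains, dtype=float)))


@dataclass(frozen=True)
class CalibrationFit:
    """Results of the Bayesian calibration (or plug-in published values).

    Point estimates are posterior means; ``var_k2``, ``var_k3`` and
    ``cov_k2k3`` are the posterior variances/covariance of (k2, k3) used by
    the delta-method calibration-error term downstream.
    """

    k2: float
    k3: float
    kappa: float
    var_k2: float
    var_k3: float
    cov_k2k3: float
    ci95: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.var_k2 < 0 or self.var_k3 < 0:
            raise ValueError("posterior variances must be >= 0")
        bound = np.sqrt(self.var_k2 * self.var_k3)
        if abs(self.cov_k2k3) > bound + 1e-12:
            raise ValueError("covariance violates Cauchy-Schwarz bound")
        for p in (self.diagnostics.get("bayes_p") or {}).values():
            if p is not None and not (0 <= p <= 1):
                raise ValueError("Bayesian p-values must lie in [0, 1]")

    @classmethod
    def from_values(
        cls, k2, k3, kappa, var_k2=0.0, var_k3=0.0, cov_k2k3=0.0, **meta
    ) -> "CalibrationFit":
        """Build a fit from externally supplied parameter values."""
        return cls(k2, k3, kappa, var_k2, var_k3, cov_k2k3, meta=meta)

    @property
    def rirs(self) -> RIRSet:
        return RIRSet.from_values(self.k2, self.k3)

    @property
    def k_cov(self) -> np.ndarray:
        """2x2 posterior covariance of (k2, k3)."""
        return np.array(
            [[self.var_k2, self.cov_k2k3], [self.cov_k2k3, self.var_k3]]
        )

    def to_dict(self) -> dict:
        return {
            "k2": self.k2,
            "k3": self.k3,
            "kappa": self.kappa,
            "var_k2": self.var_k2,
            "var_k3": self.var_k3,
            "cov_k2k3": self.cov_k2k3,
            "ci95": self.ci95,
            "diagnostics": self.diagnostics,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationFit":
        return cls(
            k2=d["k2"],
            k3=d["k3"],
            kappa=d["kappa"],
            var_k2=d["var_k2"],
            var_k3=d["var_k3"],
            cov_k2k3=d["cov_k2k3"],
            ci95=d.get("ci95", {}),
            diagnostics=d.get("diagnostics", {}),
            meta=d.get("meta", {}),
        )

    def to_json(self, path) -> None:
        from .io import write_calibration_params

        write_calibration_params(self, path)

    def summary(self) -> str:
        lines = [
            "Trimineral XRD calibration fit",
            "=" * 46,
            f"{'param':<8}{'mean':>10}{'2.5%':>10}{'97.5%':>10}{'R-hat':>8}",
        ]
        rhat = self.diagnostics.get("rhat", {})
        for name, val in (("k2", self.k2), ("k3", self.k3), ("kappa", self.kappa)):
            lo, hi = self.ci95.get(name, (float("nan"), float("nan")))
            r = rhat.get(name, float("nan"))
            lines.append(f"{name:<8}{val:>10.3f}{lo:>10.3f}{hi:>10.3f}{r:>8.3f}")
        lines.append("-" * 46)
        lines.append(
            f"cov(k2,k3) = {self.cov_k2k3:.4g}   "
            f"var(k2) = {self.var_k2:.4g}   var(k3) = {self.var_k3:.4g}"
        )
        bp = self.diagnostics.get("bayes_p")
        if bp:
            parts = [
                f"{m}: {('%.3f' % p) if p is not None else 'n/a'}"
                for m, p in bp.items()
            ]
            lines.append("Bayesian p-values  " + "  ".join(parts))
        return "\n".join(lines)


def _flatten_runs(samples):
    """Flatten CalibrationSamples into per-run arrays.

    Returns run ids, composition matrix P (M, 3), height matrix I (M, 3) and
    the likelihood inclusion mask.  A mineral enters the likelihood for a run
    only when its known weight fraction is positive (at pi = 0 the stated
    variance kappa*lambda degenerates) and its peak was actually recorded
    (an explicit 0 counts as recorded; NA/absent is excluded).
    """
    run_ids, P, I, mask = [], [], [], []
    for s in samples:
        for rid, pk in s.replicates:
            run_ids.append((s.sample_id, rid))
            P.append(s.composition.fractions)
            I.append(pk.heights)
            mask.append((s.composition.fractions > 0) & ~pk.absent)
    if not run_ids:
        raise ValueError("calibration dataset contains no measurements")
    return tuple(run_ids), np.array(P), np.array(I), np.array(mask)


def _check_design(P: np.ndarray) -> None:
    """Warn when the design cannot identify k2/k3 (posteriors ~ priors).

    Identification requires each non-reference mineral to be linked to the
    reference through co-occurring mixtures (directly or transitively).
    """
    present = P > 0
    adj = np.zeros((3, 3), dtype=bool)
    for row in present:
        idx = np.flatnonzero(row)
        for a in idx:
            adj[a, idx] = True
    reach = np.eye(3, dtype=bool) | adj
    for _ in range(3):
        reach = reach | (reach @ reach)
    missing = [MINERAL_LABELS[l] for l in (1, 2) if present[:, l].any()
               and not reach[0, l]]
    never = [MINERAL_LABELS[l] for l in (1, 2) if not present[:, l].any()]
    if missing or never:
        warnings.warn(
            "calibration design is uninformative for "
            f"{missing + never}: posterior will track the prior",
            UserWarning,
            stacklevel=3,
        )


class _Posterior:
    """Vectorised-over-chains log-density pieces for the calibration model."""

    def __init__(self, P, I, mask, kappa_prior="gamma", lambda_prior="flat"):
        self.P = P  # (M, 3) known weight fractions
        self.I = I  # (M, 3) observed heights
        self.mask = mask  # (M, 3) likelihood inclusion
        self.kappa_prior = kappa_prior
        self.lambda_prior = lambda_prior
        self.n_runs = P.shape[0]

    def loglik_runs(self, k2, k3, kappa, lam):
        """Per-run log likelihood, shape (C, M).

        k2, k3, kappa: (C,);  lam: (C, M).
        """
        K = np.stack([np.ones_like(k2), k2, k3], axis=-1)  # (C, 3)
        num = K[:, None, :] * self.P[None]  # (C, M, 3)
        denom = num.sum(axis=2, keepdims=True)
        lam_l = lam[:, :, None] * num / denom  # (C, M, 3)
        var = kappa[:, None, None] * lam_l
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = -0.5 * (np.log(2 * np.pi * var) + (self.I[None] - lam_l) ** 2 / var)
        ll = np.where(self.mask[None], ll, 0.0)
        return ll.sum(axis=2)

    def expected_intensities(self, k2, k3, lam):
        """lambda_lj for given parameters; same shapes as loglik_runs."""
        K = np.stack([np.ones_like(k2), k2, k3], axis=-1)
        num = K[:, None, :] * self.P[None]
        return lam[:, :, None] * num / num.sum(axis=2, keepdims=True)

    def logprior_lam(self, lam):
        if self.lambda_prior == "gamma":
            return (LAMBDA_GAMMA_SHAPE - 1) * np.log(lam) - LAMBDA_GAMMA_RATE * lam
        return np.zeros_like(lam)  # flat on (0, inf); likelihood anchors Lambda

    def logprior_kappa(self, kappa):
        if self.kappa_prior == "gamma":
            return (0.001 - 1) * np.log(kappa) - 0.001 * kappa
        return np.zeros_like(kappa)  # uniform on (KAPPA_LO, KAPPA_HI)


def _moment_init(P, I, mask):
    """Crude moment estimates of (k2, k3, kappa) used to start the chains."""
    k_hat = np.ones(3)
    ref_ok = (P[:, 0] > 0) & mask[:, 0] & (I[:, 0] > 0)
    for l in (1, 2):
        rows = ref_ok & (P[:, l] > 0) & mask[:, l] & (I[:, l] > 0)
        if rows.any():
            ratios = (I[rows, l] / P[rows, l]) / (I[rows, 0] / P[rows, 0])
            k_hat[l] = np.clip(np.median(ratios), 0.02, 90.0)
    lam0 = np.array(
        [I[m][mask[m]].sum() if mask[m].any() else 1000.0 for m in range(len(I))]
    )
    lam0 = np.maximum(lam0, 1.0)
    num = k_hat[None] * P
    lam_l = lam0[:, None] * num / num.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (I - lam_l) ** 2 / lam_l
    # median of kappa * chi^2_1 is ~0.455 kappa
    kappa0 = float(np.nanmedian(np.where(mask & (lam_l > 0), resid, np.nan))) / 0.455
    if not np.isfinite(kappa0) or kappa0 <= 0:
        kappa0 = 10.0
    return k_hat, lam0, max(kappa0, 1.0)


class CalibrationModel:
    """Bayesian calibration model for a set of standard mixtures.

    Parameters
    ----------
    samples : sequence of CalibrationSample
        At least two mixtures of known composition, each with one or more
        replicate peak-height measurements.
    """

    def __init__(self, samples):
        samples = list(samples)
        if len(samples) < 2:
            raise ValueError("calibration needs >= 2 samples of known composition")
        self.samples = samples
        self.run_ids, self.P, self.I, self.mask = _flatten_runs(samples)
        _check_design(self.P)
        self._post = None

    # -- sampling ---------------------------------------------------------

    def fit(self, config: MCMCConfig) -> CalibrationFit:
        """Run the MCMC and return a CalibrationFit (draws on ``.draws``)."""
        post = _Posterior(self.P, self.I, self.mask, config.kappa_prior,
                          config.lambda_prior)
        rng = np.random.default_rng(config.seed)
        C, M = config.chains, post.n_runs

        k_hat, lam0, kappa0 = _moment_init(self.P, self.I, self.mask)
        k2 = np.clip(k_hat[1] * np.exp(rng.normal(0, 0.25, C)), K_LO * 2, K_HI / 2)
        k3 = np.clip(k_hat[2] * np.exp(rng.normal(0, 0.25, C)), K_LO * 2, K_HI / 2)
        kappa = np.clip(kappa0 * np.exp(rng.normal(0, 0.5, C)), KAPPA_LO * 10, KAPPA_HI / 10)
        lam = lam0[None] * np.exp(rng.normal(0, 0.05, (C, M)))

        # adaptive proposal scales (log-scale for positive parameters)
        s_k2 = np.full(C, 0.1 * max(k_hat[1], 0.1))
        s_k3 = np.full(C, 0.1 * max(k_hat[2], 0.1))
        s_kap = np.full(C, 0.4)
        s_lam = np.full(C, 0.05)

        sweeps = config.sweeps_per_chain
        burn = config.burn_sweeps
        kept = (sweeps - burn) // config.thin
        out_k2 = np.empty((C, kept))
        out_k3 = np.empty((C, kept))
        out_kap = np.empty((C, kept))
        out_lam = np.empty((C, kept, M))

        ll_runs = post.loglik_runs(k2, k3, kappa, lam)  # (C, M)
        adapt_win = 100
        acc = {"k2": np.zeros(C), "k3": np.zeros(C),
               "kap": np.zeros(C), "lam": np.zeros(C)}
        kept_i = 0

        # independence-proposal anchor for Lambda_j: observed run totals.
        # The diffuse Gamma(0.001, 0.001) prior spikes at zero, which opens a
        # degenerate (huge-kappa, tiny-Lambda) basin that pure random-walk
        # updates escape only exponentially slowly; an occasional jump back
        # to the data-anchored scale (with full MH correction) fixes mixing.
        ind_mu = np.log(lam0)  # (M,)
        ind_sd = 0.25
        p_ind = 0.1

        def _log_q_ind(x):
            lx = np.log(x)
            return -lx - (lx - ind_mu[None]) ** 2 / (2 * ind_sd**2)

        for t in range(sweeps):
            # Lambda_j: log random walk mixed with independence proposals;
            # runs are conditionally independent given (k2, k3, kappa)
            use_ind = rng.random((C, M)) < p_ind
            prop_rw = lam * np.exp(rng.normal(0, 1, (C, M)) * s_lam[:, None])
            prop_ind = np.exp(ind_mu[None] + rng.normal(0, ind_sd, (C, M)))
            prop = np.where(use_ind, prop_ind, prop_rw)
            ll_prop = post.loglik_runs(k2, k3, kappa, prop)
            corr_rw = np.log(prop) - np.log(lam)  # log-scale Jacobian
            corr_ind = _log_q_ind(lam) - _log_q_ind(prop)
            logr = (
                ll_prop - ll_runs
                + post.logprior_lam(prop) - post.logprior_lam(lam)
                + np.where(use_ind, corr_ind, corr_rw)
            )
            take = np.log(rng.random((C, M))) < logr
            lam = np.where(take, prop, lam)
            ll_runs = np.where(take, ll_prop, ll_runs)
            acc["lam"] += take.mean(axis=1)

            # k2, k3: Gaussian random walk on the natural scale
            for name, cur, scale in (("k2", k2, s_k2), ("k3", k3, s_k3)):
                prop = cur + rng.normal(0, 1, C) * scale
                ok = (prop > K_LO) & (prop < K_HI)
                prop_eval = np.where(ok, prop, cur)
                k2p = prop_eval if name == "k2" else k2
                k3p = prop_eval if name == "k3" else k3
                ll_prop = post.loglik_runs(k2p, k3p, kappa, lam)
                logr = ll_prop.sum(axis=1) - ll_runs.sum(axis=1)
                take = ok & (np.log(rng.random(C)) < logr)
                if name == "k2":
                    k2 = np.where(take, prop, k2)
                else:
                    k3 = np.where(take, prop, k3)
                ll_runs = np.where(take[:, None], ll_prop, ll_runs)
                acc[name] += take

            # kappa: log random walk
            prop = kappa * np.exp(rng.normal(0, 1, C) * s_kap)
            ok = (prop > KAPPA_LO) & (prop < KAPPA_HI)
            prop_eval = np.where(ok, prop, kappa)
            ll_prop = post.loglik_runs(k2, k3, prop_eval, lam)
            logr = (
                ll_prop.sum(axis=1) - ll_runs.sum(axis=1)
                + post.logprior_kappa(prop_eval) - post.logprior_kappa(kappa)
                + np.log(prop_eval) - np.log(kappa)
            )
            take = ok & (np.log(rng.random(C)) < logr)
            kappa = np.where(take, prop, kappa)
            ll_runs = np.where(take[:, None], ll_prop, ll_runs)
            acc["kap"] += take

            # adapt proposal scales during burn-in only
            if t < burn and (t + 1) % adapt_win == 0:
                for key, scale, hi in (("k2", s_k2, 5.0), ("k3", s_k3, 5.0),
                                       ("kap", s_kap, 2.0), ("lam", s_lam, 0.5)):
                    rate = acc[key] / adapt_win
                    scale *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    np.clip(scale, 1e-4, hi, out=scale)
                    acc[key][:] = 0.0
            if t == burn - 1:
                for key in acc:
                    acc[key][:] = 0.0

            if t >= burn and (t - burn) % config.thin == 0 and kept_i < kept:
                out_k2[:, kept_i] = k2
                out_k3[:, kept_i] = k3
                out_kap[:, kept_i] = kappa
                out_lam[:, kept_i] = lam
                kept_i += 1

        draws = PosteriorDraws(
            out_k2[:, :kept_i], out_k3[:, :kept_i], out_kap[:, :kept_i],
            out_lam[:, :kept_i], self.run_ids,
        )
        # post-burn-in acceptance rates, useful when diagnosing mixing
        self.acceptance_rates_ = {
            k: v / max(sweeps - burn, 1) for k, v in acc.items()
        }
        self._post = post
        return self._summarise(draws, config, rng)

    # -- summaries --------------------------------------------------------

    def _summarise(self, draws, config, rng) -> CalibrationFit:
        pooled = {n: draws.pooled(n) for n in ("k2", "k3", "kappa")}
        ci95 = {
            n: [float(q) for q in np.quantile(v, [0.025, 0.975])]
            for n, v in pooled.items()
        }
        rhat = {n: gelman_rubin(getattr(draws, n)) for n in ("k2", "k3", "kappa")}
        ess = {n: _effective_sample_size(getattr(draws, n))
               for n in ("k2", "k3", "kappa")}
        bad = {n: r for n, r in rhat.items() if r > config.rhat_threshold}
        if bad:
            warnings.warn(
                f"chains may not have converged (R-hat > "
                f"{config.rhat_threshold}): {bad}",
                ConvergenceWarning,
                stacklevel=3,
            )
        bayes_p = compute_bayesian_p_values(draws, self.samples, rng=rng)
        kk = np.stack([pooled["k2"], pooled["k3"]])
        cov = np.cov(kk)
        fit = CalibrationFit(
            k2=float(pooled["k2"].mean()),
            k3=float(pooled["k3"].mean()),
            kappa=float(pooled["kappa"].mean()),
            var_k2=float(cov[0, 0]),
            var_k3=float(cov[1, 1]),
            cov_k2k3=float(cov[0, 1]),
            ci95=ci95,
            diagnostics={
                "rhat": rhat,
                "ess": ess,
                "bayes_p": bayes_p,
                "converged": not bad,
            },
            meta={
                "created": datetime.now(timezone.utc).isoformat(),
                "seed": config.seed,
                "iterations": config.iterations,
                "chains": config.chains,
                "burn_fraction": config.burn_fraction,
                "thin": config.thin,
                "kappa_prior": config.kappa_prior,
                "n_samples": len(self.samples),
                "n_runs": len(self.run_ids),
                "dataset_hash": self.dataset_hash(),
            },
        )
        fit.__dict__["draws"] = draws  # frozen dataclass: attach via __dict__
        return fit

    def dataset_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.P).tobytes())
        h.update(np.ascontiguousarray(self.I).tobytes())
        h.update(json.dumps(self.run_ids).encode())
        return h.hexdigest()[:16]


def fit_calibration(samples, config: MCMCConfig) -> tuple[CalibrationFit, PosteriorDraws]:
    """Functional wrapper: fit the calibration model, return (fit, draws)."""
    fit = CalibrationModel(samples).fit(config)
    return fit, fit.draws


def compute_bayesian_p_values(
    draws: PosteriorDraws, samples, rng=None, max_draws: int = 2000
) -> dict:
    """Posterior-predictive p-values, one per mineral.

    The discrepancy statistic for mineral l is the sum over calibration runs
    of squared residuals scaled by their standard deviation,
    T_l = sum_j (I_lj - lambda_lj)^2 / (kappa * lambda_lj).  For each retained
    posterior draw, T_l is evaluated on the data and on a replicate dataset
    simulated from that draw; p_l is the fraction of draws where the
    replicate statistic is at least as large.  Values near 0.5 indicate the
    noise model reproduces the observed scatter; a mineral absent from every
    mixture yields ``None``.
    """
    rng = np.random.default_rng(rng)
    run_ids, P, I, mask = _flatten_runs(samples)
    if run_ids != tuple(draws.run_ids):
        raise ValueError("draws were produced from a different dataset")
    pooled_k2 = draws.pooled("k2")
    pooled_k3 = draws.pooled("k3")
    pooled_kap = draws.pooled("kappa")
    pooled_lam = draws.pooled("lam")
    n = len(pooled_k2)
    idx = np.arange(n)
    if n > max_draws:
        idx = rng.choice(n, size=max_draws, replace=False)
    K = np.stack(
        [np.ones(len(idx)), pooled_k2[idx], pooled_k3[idx]], axis=-1
    )  # (D, 3)
    num = K[:, None, :] * P[None]  # (D, M, 3)
    lam_l = pooled_lam[idx][:, :, None] * num / num.sum(axis=2, keepdims=True)
    var = pooled_kap[idx][:, None, None] * lam_l
    with np.errstate(divide="ignore", invalid="ignore"):
        t_data = np.where(mask[None], (I[None] - lam_l) ** 2 / var, 0.0)
        rep = rng.normal(lam_l, np.sqrt(np.where(var > 0, var, 1.0)))
        t_rep = np.where(mask[None], (rep - lam_l) ** 2 / var, 0.0)
    out = {}
    for l, label in enumerate(MINERAL_LABELS):
        if not mask[:, l].any():
            out[label] = None
            continue
        td = t_data[:, :, l].sum(axis=1)
        tr = t_rep[:, :, l].sum(axis=1)
        out[label] = float(np.mean(tr >= td))
    return out
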