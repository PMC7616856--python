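"""Maximum-likelihood (naive Bayes) decoding of the attentional state.

Per-trial features are extracted from five modalities — spike counts in the
1 s epoch before the first luminance change, LFP–LFP phase-locking value
(PLV), LFP–LFP relative phase, within-trial spike–field PPC, and the mean
LFP phase of spiking. Likelihoods are fitted per condition with the family
matching the feature: Poisson for counts, Gaussian for other non-angular
quantities, von Mises for angles; priors are flat. Decoding is
leave-one-trial-out: for each trial the likelihoods are refitted without it
and the posterior is evaluated on the held-out features; population
posteriors multiply per-signal posteriors (products taken in log space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, i0e, i1e

from .spectral import pairwise_consistency
from .stats import RandTestResult, shuffle_correlation_test

KAPPA_MAX = 1e3
SIGMA_FLOOR_FRAC = 1e-6


# ---------------------------------------------------------------------------
# trial features


def trial_plv(phasors_a: np.ndarray, phasors_b: np.ndarray) -> float:
    """|mean over samples of exp(i(phiA - phiB))| for one epoch."""
    a, b = np.asarray(phasors_a), np.asarray(phasors_b)
    if a.size == 0:
        raise ValueError("empty epoch")
    rel = a * np.conj(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.nan_to_num(rel / np.abs(rel))
    return float(np.abs(u.mean()))


def trial_relphase(phasors_a: np.ndarray, phasors_b: np.ndarray) -> float:
    """Angle of the time-averaged conjugate product over one epoch."""
    a, b = np.asarray(phasors_a), np.asarray(phasors_b)
    if a.size == 0:
        raise ValueError("empty epoch")
    m = (a * np.conj(b)).mean()
    if m == 0:
        raise ValueError("zero-amplitude epoch; relative phase undefined")
    return float(np.angle(m))


def trial_spikefield_ppc(spike_phases: np.ndarray) -> float:
    """All-pairs PPC of pooled spike phases within one trial."""
    ph = np.asarray(spike_phases, dtype=float)
    if len(ph) < 2:
        raise ValueError("need >= 2 pooled spikes in the epoch")
    return float(pairwise_consistency(np.exp(1j * ph)))


# ---------------------------------------------------------------------------
# likelihood families


def _vm_kappa_from_r(r: float) -> float:
    """ML concentration for a mean resultant length (truncated approximation
    plus Newton refinement on A(kappa) = I1/I0 = r)."""
    if r <= 0:
        return 0.0
    if r >= 1:
        return KAPPA_MAX
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    for _ in range(10):
        a = i1e(k) / i0e(k)
        da = 1 - a**2 - a / k if k > 0 else 0.5
        if da == 0:
            break
        step = (a - r) / da
        k -= step
        if not np.isfinite(k) or k <= 0:
            return max(k, 1e-12) if np.isfinite(k) else KAPPA_MAX
        if abs(step) < 1e-10:
            break
    return float(min(k, KAPPA_MAX))


@dataclass
class Likelihood:
    family: str  # vonmises | poisson | gaussian
    params: dict

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "poisson":
            lam = p["lam"]
            if lam == 0:
                return np.where(x == 0, 0.0, -np.inf)
            return x * np.log(lam) - lam - gammaln(x + 1)
        if self.family == "gaussian":
            mu, sigma = p["mu"], p["sigma"]
            return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma * np.sqrt(2 * np.pi))
        if self.family == "vonmises":
            mu, kappa = p["mu"], p["kappa"]
            log_i0 = np.log(i0e(kappa)) + kappa
            return kappa * np.cos(x - mu) - np.log(2 * np.pi) - log_i0
        raise ValueError(f"unknown family {self.family!r}")


def fit_likelihood(values: np.ndarray, family: str, sigma_floor: float | None = None) -> Likelihood:
    """Fit one condition's likelihood.

    Poisson: lambda = sample mean. Gaussian: sample mean and SD (SD floored
    at a small fraction of the feature scale when degenerate). von Mises:
    circular-mean location, ML concentration from the mean resultant length
    (capped for degenerate samples).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 training values per condition")
    if family == "poisson":
        return Likelihood("poisson", {"lam": float(v.mean())})
    if family == "gaussian":
        mu, sigma = float(v.mean()), float(v.std(ddof=1))
        floor = sigma_floor if sigma_floor is not None else SIGMA_FLOOR_FRAC * max(
            1.0, abs(mu)
        )
        return Likelihood("gaussian", {"mu": mu, "sigma": max(sigma, floor)})
    if family == "vonmises":
        z = np.exp(1j * v).mean()
        return Likelihood(
            "vonmises", {"mu": float(np.angle(z)), "kappa": _vm_kappa_from_r(abs(z))}
        )
    raise ValueError(f"unknown family {family!r}")


FAMILY_BY_MODALITY = {
    "rate": "poisson",
    "lfp_plv": "gaussian",
    "lfp_relphase": "vonmises",
    "spike_ppc": "gaussian",
    "spike_phase": "vonmises",
}


@dataclass
class DecoderModel:
    """Per-signal, per-condition likelihoods with flat priors."""

    likelihoods: dict  # {(signal, condition): Likelihood}
    conditions: tuple = ("toward", "away")


def decode_trial(
    model: DecoderModel,
    features: dict,
    rng: np.random.Generator | None = None,
) -> tuple[dict, str]:
    """Posterior over conditions for one trial's features (Eq. of Bayes with
    flat priors, per-signal posteriors multiplied in log space).

    ``features`` maps signal id -> observed value. Posterior ties are broken
    by a seeded coin flip. If every condition has zero likelihood the
    posterior is uniform (flagged by equal posteriors).
    """
    logp = {c: 0.0 for c in model.conditions}
    for sig, x in features.items():
        for c in model.conditions:
            logp[c] += float(model.likelihoods[(sig, c)].logpdf(np.asarray(x)))
    vals = np.array([logp[c] for c in model.conditions])
    if np.all(np.isneginf(vals)):
        post = np.full(len(vals), 1.0 / len(vals))
    else:
        vals = vals - vals.max()
        w = np.exp(vals)
        post = w / w.sum()
    posterior = dict(zip(model.conditions, post))
    best = post.max()
    top = [c for c, p in zip(model.conditions, post) if p == best]
    if len(top) > 1:
        rng = rng if rng is not None else np.random.default_rng()
        pred = top[rng.integers(len(top))]
    else:
        pred = top[0]
    return posterior, pred


def _fit_model(features: np.ndarray, labels: np.ndarray, family: str) -> DecoderModel:
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    lks = {}
    conds = ("toward", "away")
    for c in conds:
        sel = labels == c
        for s in range(feats.shape[1]):
            lks[(s, c)] = fit_likelihood(feats[sel, s], family)
    return DecoderModel(likelihoods=lks, conditions=conds)


def loo_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    family: str,
    seed: int | None = 0,
    return_errors: bool = False,
):
    """Leave-one-trial-out decoding accuracy.

    ``features``: ``(n_trials,)`` or ``(n_trials, n_signals)``; ``labels``
    in {"toward", "away"} with >= 2 trials per condition. For each trial the
    per-signal likelihoods are refitted on the remaining trials and the
    held-out trial is decoded by the product posterior.
    """
    feats = np.asarray(features, dtype=float)
    if feats.ndim == 1:
        feats = feats[:, None]
    labels = np.asarray(labels)
    n = len(labels)
    for c in ("toward", "away"):
        if np.sum(labels == c) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 trials")
    rng = np.random.default_rng(seed)
    errors = np.zeros(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = _fit_model(feats[keep], labels[keep], family)
        _, pred = decode_trial(model, {s: feats[i, s] for s in range(feats.shape[1])}, rng)
        errors[i] = int(pred != labels[i])
    acc = 1.0 - errors.mean()
    if return_errors:
        return float(acc), errors
    return float(acc)


def accuracy_vs_ncells(
    features: np.ndarray,
    labels: np.ndarray,
    family: str,
    n_range: list[int],
    n_subsamples: int = 50,
    seed: int | None = 0,
) -> dict:
    """Mean jackknife accuracy as a function of population size.

    For each ``n`` draws ``n_subsamples`` seeded random signal subsets and
    averages their leave-one-out accuracies. Sizes exceeding the population
    are skipped (recorded as NaN).
    """
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    n_signals = feats.shape[1]
    rng = np.random.default_rng(seed)
    curve = {}
    for n in n_range:
        if n > n_signals:
            curve[n] = np.nan
            continue
        accs = []
        draws = 1 if n == n_signals else n_subsamples
        for _ in range(draws):
            cols = rng.choice(n_signals, size=n, replace=False)
            accs.append(loo_accuracy(feats[:, cols], labels, family, seed=int(rng.integers(2**31))))
        curve[n] = float(np.mean(accs))
    return curve


def trial_error_correlation(
    su_errors: np.ndarray,
    population_errors: np.ndarray,
    n_randomizations: int = 1000,
    seed: int | None = None,
) -> RandTestResult:
    """Spearman rho between a unit's and the population's per-trial decoding
    errors, with a shuffle-null p-value."""
    a = np.asarray(su_errors)
    b = np.asarray(population_errors)
    if len(a) != len(b):
        raise ValueError("error vectors must share the trial index")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant error vector: rho undefined")
    return shuffle_correlation_test(a, b, n_randomizations=n_randomizations, seed=seed)


def poisson_bayes_accuracy(lam_a: float, lam_b: float, n_units: int = 1, kmax: int = 500) -> float:
    """Analytic accuracy of the ideal observer for two Poisson conditions.

    For ``n_units`` i.i.d. units the total count is sufficient; accuracy is
    the average over both classes of the probability of the ML decision,
    with ties split evenly. Serves as the calibration oracle for the
    decoder.
    """
    la, lb = lam_a * n_units, lam_b * n_units
    k = np.arange(kmax + 1)
    logpa = k * np.log(la) - la - gammaln(k + 1)
    logpb = k * np.log(lb) - lb - gammaln(k + 1)
    pa, pb = np.exp(logpa), np.exp(logpb)
    pick_a = logpa > logpb
    tie = logpa == logpb
    acc = 0.5 * (pa[pick_a].sum() + pb[~pick_a & ~tie].sum()) + 0.5 * (
        0.5 * pa[tie].sum() + 0.5 * pb[tie].sum()
    )
    return float(acc)
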