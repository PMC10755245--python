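"""Product-of-coefficients mediation with bias-corrected bootstrap CIs.

For exposure x, mediator(s) m and outcome y (covariates C partialled into
every sub-model), the linear system

    m_j = a_j x + C g + e      y = c' x + sum_j b_j m_j + C h + e
    y   = c  x + C f + e                           (total-effect model)

gives the indirect effect (ACME) a_j * b_j per mediator, the direct effect
tau' = c', and the total effect tau = c; with OLS throughout the identity
tau = tau' + sum_j a_j b_j holds exactly. Mediators are parallel (no
m1 -> m2 path). Inference is by nonparametric case resampling with
bias-corrected (BC) percentile intervals. The proportion mediated is
PM = 100 * (tau - tau') / tau, flagged unstable when tau is near zero or
tau and tau' disagree in sign (suppression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import as_2d


def proportion_mediated(tau: float, tau_prime: float, tol: float = 1e-8):
    """PM = 100 * (tau - tau') / tau; returns (pm, unstable flag)."""
    if tau == 0:
        raise ValueError("proportion mediated undefined for tau = 0")
    pm = 100.0 * (tau - tau_prime) / tau
    unstable = abs(tau) < tol or np.sign(tau) != np.sign(tau_prime)
    return pm, bool(unstable)


def _bc_ci(boot: np.ndarray, point: float, level: float) -> tuple[float, float]:
    """Bias-corrected percentile interval (no acceleration constant)."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        return np.nan, np.nan
    prop = np.mean(boot < point)
    prop = min(max(prop, 1.0 / (boot.size + 1)), boot.size / (boot.size + 1.0))
    z0 = stats.norm.ppf(prop)
    za = stats.norm.ppf((1.0 - level) / 2.0)
    lo = stats.norm.cdf(2.0 * z0 + za)
    hi = stats.norm.cdf(2.0 * z0 - za)
    return tuple(np.quantile(boot, [lo, hi]))


def _paths(x, M, y, C) -> dict:
    """Point estimates of all mediation paths by least squares."""
    n = x.size
    base = [np.ones(n), x]
    if C.size:
        base.append(C)
    Xc = np.column_stack(base)
    a = np.empty(M.shape[1])
    for j in range(M.shape[1]):
        a[j] = np.linalg.lstsq(Xc, M[:, j], rcond=None)[0][1]
    tau = np.linalg.lstsq(Xc, y, rcond=None)[0][1]
    Xfull = np.column_stack([Xc[:, :2], M, Xc[:, 2:]])
    coef = np.linalg.lstsq(Xfull, y, rcond=None)[0]
    tau_prime = coef[1]
    b = coef[2 : 2 + M.shape[1]]
    return {"a": a, "b": b, "acme": a * b, "tau": tau, "tau_prime": tau_prime}


@dataclass
class MediationResults:
    """Point estimates, bootstrap CIs and the proportion-mediated statistic.

    ``acme`` has one entry per mediator; ``total_indirect`` is their sum
    (equal to ``acme[0]`` for a single mediator).
    """

    mediator_names: list[str]
    tau: float
    tau_prime: float
    acme: np.ndarray
    total_indirect: float
    pm: float
    pm_unstable: bool
    ci: dict = field(default_factory=dict)  # name -> (low, high)
    acme_p: np.ndarray | None = None        # bootstrap two-sided sign p per mediator
    n_boot: int = 0
    seed: int = 0
    n: int = 0

    def summary(self) -> str:
        lines = [
            f"Mediation ({len(self.mediator_names)} parallel mediator(s)), "
            f"n = {self.n}, {self.n_boot} bootstrap resamples (seed {self.seed})",
            f"  total effect   tau  = {self.tau: .4f}  CI {self._fmt('tau')}",
            f"  direct effect  tau' = {self.tau_prime: .4f}  CI {self._fmt('tau_prime')}",
        ]
        for j, name in enumerate(self.mediator_names):
            pj = "" if self.acme_p is None else f"  p = {self.acme_p[j]:.3f}"
            lines.append(
                f"  ACME[{name}] = {self.acme[j]: .4f}  CI {self._fmt(f'acme_{name}')}{pj}"
            )
        if len(self.mediator_names) > 1:
            lines.append(
                f"  total indirect = {self.total_indirect: .4f}  "
                f"CI {self._fmt('total_indirect')}"
            )
        flag = "  [unstable]" if self.pm_unstable else ""
        lines.append(f"  proportion mediated = {self.pm:.2f}%{flag}")
        return "\n".join(lines)

    def _fmt(self, key: str) -> str:
        lo, hi = self.ci.get(key, (np.nan, np.nan))
        return f"[{lo: .4f}, {hi: .4f}]"

    def to_json_dict(self) -> dict:
        return {
            "mediators": self.mediator_names,
            "tau": self.tau,
            "tau_prime": self.tau_prime,
            "acme": list(map(float, self.acme)),
            "total_indirect": self.total_indirect,
            "pm_percent": self.pm,
            "pm_unstable": self.pm_unstable,
            "ci": {k: [float(v[0]), float(v[1])] for k, v in self.ci.items()},
            "acme_p": None if self.acme_p is None else list(map(float, self.acme_p)),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n": self.n,
        }


class MediationModel:
    """Linear mediation model with one or two parallel mediators.

    ``mediators`` is a mapping name -> vector (insertion order kept).
    Covariates are included in every sub-model.
    """

    def __init__(self, x, y, mediators: dict, covariates=None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.mediator_names = list(mediators)
        self.M = np.column_stack(
            [np.asarray(mediators[k], dtype=float) for k in self.mediator_names]
        )
        self.C, _ = as_2d(covariates)
        n = self.x.size
        if self.y.size != n or self.M.shape[0] != n:
            raise ValueError("x, mediators and y must have equal length")
        if self.C.size and self.C.shape[0] != n:
            raise ValueError("covariate rows do not match")
        if n < 10:
            raise ValueError("need at least 10 observations")
        for name, v in [("x", self.x), ("y", self.y)] + [
            (nm, self.M[:, j]) for j, nm in enumerate(self.mediator_names)
        ]:
            if np.std(v) == 0:
                raise ValueError(f"zero variance in {name}")
        if self.M.shape[1] > 1:
            r = np.corrcoef(self.M, rowvar=False)
            if np.any(np.abs(r[np.triu_indices_from(r, k=1)]) > 1 - 1e-10):
                raise ValueError("mediators are collinear")

    def fit(
        self, n_boot: int = 1000, seed: int = 0, ci_level: float = 0.95
    ) -> MediationResults:
        if n_boot < 100:
            warnings.warn("n_boot < 100: bootstrap intervals will be unreliable")
        n = self.x.size
        est = _paths(self.x, self.M, self.y, self.C)

        rng = np.random.default_rng(seed)
        nmed = self.M.shape[1]
        boot = {
            "tau": np.empty(n_boot),
            "tau_prime": np.empty(n_boot),
            "acme": np.empty((n_boot, nmed)),
        }
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Cb = self.C[idx] if self.C.size else self.C
            try:
                eb = _paths(self.x[idx], self.M[idx], self.y[idx], Cb)
            except np.linalg.LinAlgError:  # degenerate resample
                eb = {"tau": np.nan, "tau_prime": np.nan, "acme": np.full(nmed, np.nan)}
            boot["tau"][b] = eb["tau"]
            boot["tau_prime"][b] = eb["tau_prime"]
            boot["acme"][b] = eb["acme"]

        ci = {
            "tau": _bc_ci(boot["tau"], est["tau"], ci_level),
            "tau_prime": _bc_ci(boot["tau_prime"], est["tau_prime"], ci_level),
        }
        acme_p = np.empty(nmed)
        for j, name in enumerate(self.mediator_names):
            ci[f"acme_{name}"] = _bc_ci(boot["acme"][:, j], est["acme"][j], ci_level)
            bj = boot["acme"][:, j]
            bj = bj[np.isfinite(bj)]
            # two-sided bootstrap sign test for ACME != 0
            acme_p[j] = min(1.0, 2.0 * min(np.mean(bj < 0), np.mean(bj > 0))
                            + 2.0 * np.mean(bj == 0))
        total = boot["acme"].sum(axis=1)
        ci["total_indirect"] = _bc_ci(total, float(est["acme"].sum()), ci_level)

        pm, unstable = proportion_mediated(est["tau"], est["tau_prime"])
        return MediationResults(
            mediator_names=self.mediator_names,
            tau=float(est["tau"]),
            tau_prime=float(est["tau_prime"]),
            acme=est["acme"],
            total_indirect=float(est["acme"].sum()),
            pm=pm,
            pm_unstable=unstable,
            ci=ci,
            acme_p=acme_p,
            n_boot=n_boot,
            seed=seed,
            n=n,
        )


def mediate(
    x, m, y, covariates=None, n_boot: int = 1000, seed: int = 0
) -> MediationResults:
    """Single-mediator wrapper around :class:`MediationModel`."""
    return MediationModel(x, y, {"m": m}, covariates).fit(n_boot=n_boot, seed=seed)


def mediate_two(
    x, m1, m2, y, covariates=None, n_boot: int = 1000, seed: int = 0
) -> MediationResults:
    """Two parallel mediators (no m1 -> m2 path)."""
    return MediationModel(x, y, {"m1": m1, "m2": m2}, covariates).fit(
        n_boot=n_boot, seed=seed
    )
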