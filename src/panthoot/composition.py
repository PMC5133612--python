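"""Phase-presence models: which calls lack a build-up or let-down, and why.

Presence of each droppable phase is modelled as a mixed-effects logistic
regression with fixed effects for context (0 = travel, 1 = feeding), age
(years, continuous) and Elo rank (numeric position), and a random intercept
per caller:

    logit P(present_ij) = b0 + b1*feeding_ij + b2*age_j + b3*rank_j + u_j,
    u_j ~ N(0, sigma^2).

The marginal likelihood integrates the random intercept out by Gauss-Hermite
quadrature and is maximized with L-BFGS-B under sigma >= 0. Wald standard
errors come from the fixed-effect block of the numerical Hessian at the
optimum (with sigma held at its estimate). This maximum-likelihood fit is
hand-written because the available Python mixed-model backends for binomial
responses are approximate-Bayesian and materially understate the posterior
spread at these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special
from scipy.stats import norm

PRESENCE_COLUMNS = {"build-up": "has_buildup", "let-down": "has_letdown"}
FIXED_EFFECTS = ("intercept", "context", "age_years", "elo_rank")


class PhasePresenceModel:
    """Random-intercept logistic model of one phase's presence/absence."""

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        groups: np.ndarray,
        phase: str = "",
        exog_names: tuple[str, ...] = FIXED_EFFECTS,
        n_quad: int = 25,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        self.groups = np.asarray(groups)
        self.phase = phase
        self.exog_names = tuple(exog_names)
        if self.endog.ndim != 1 or self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog shapes disagree")
        uniq = np.unique(self.groups)
        if uniq.size < 2:
            raise ValueError("need at least two callers for a random intercept")
        vals = np.unique(self.endog)
        if not np.all(np.isin(vals, [0.0, 1.0])) or vals.size < 2:
            raise ValueError("response must contain both 0s and 1s")
        self._group_idx = [np.flatnonzero(self.groups == g) for g in uniq]
        nodes, wts = hermegauss(n_quad)
        self._nodes = nodes
        self._logw = np.log(wts / wts.sum())

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, phase: str, **kwargs) -> "PhasePresenceModel":
        """Build from a per-call metadata table (one row per call)."""
        if phase not in PRESENCE_COLUMNS:
            raise ValueError(f"no presence model for phase {phase!r}")
        present = data[PRESENCE_COLUMNS[phase]].astype(float).to_numpy()
        context = (data["context"] == "feeding").astype(float).to_numpy()
        exog = np.column_stack(
            [
                np.ones(len(data)),
                context,
                data["age_years"].astype(float).to_numpy(),
                data["elo_rank"].astype(float).to_numpy(),
            ]
        )
        return cls(present, exog, data["caller_id"].to_numpy(), phase=phase, **kwargs)

    # -- likelihood ---------------------------------------------------------

    def _nloglike(self, params: np.ndarray) -> float:
        beta, sigma = params[:-1], params[-1]
        eta = self.exog @ beta
        ll = 0.0
        for idx in self._group_idx:
            e = eta[idx][:, None] + sigma * self._nodes[None, :]
            # log Bernoulli likelihood at each quadrature node
            lp = np.where(
                self.endog[idx][:, None] == 1.0,
                -np.logaddexp(0.0, -e),
                -np.logaddexp(0.0, e),
            ).sum(axis=0)
            ll += special.logsumexp(lp + self._logw)
        return -ll

    def _beta_hessian(self, beta: np.ndarray, sigma: float, eps: float = 1e-4) -> np.ndarray:
        p = beta.size
        f = lambda b: self._nloglike(np.r_[b, sigma])
        H = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1):
                def point(di: float, dj: float) -> float:
                    b = beta.copy()
                    b[i] += di * eps
                    b[j] += dj * eps
                    return f(b)

                H[i, j] = H[j, i] = (
                    point(1, 1) - point(1, -1) - point(-1, 1) + point(-1, -1)
                ) / (4 * eps * eps)
        return H

    def fit(self) -> "PhasePresenceResults":
        p = self.exog.shape[1]
        # start from the pooled logistic solution direction: zeros + modest sigma
        x0 = np.r_[np.zeros(p), 0.3]
        x0[0] = special.logit(np.clip(self.endog.mean(), 0.01, 0.99))
        res = optimize.minimize(
            self._nloglike,
            x0,
            method="L-BFGS-B",
            bounds=[(None, None)] * p + [(0.0, None)],
        )
        beta, sigma = res.x[:p], float(res.x[p])
        H = self._beta_hessian(beta, sigma)
        try:
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            separation = bool(np.any(~np.isfinite(bse)) or np.any(bse > 50))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
            separation = True
        return PhasePresenceResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            vc_sd=sigma,
            llf=-float(res.fun),
            converged=bool(res.success),
            possible_separation=separation,
        )


@dataclass
class PhasePresenceResults:
    """Coefficient table, Wald inference and diagnostics for one fit."""

    model: PhasePresenceModel
    params: pd.Series
    bse: pd.Series
    vc_sd: float
    llf: float
    converged: bool
    possible_separation: bool

    @property
    def n_calls(self) -> int:
        return self.model.endog.size

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Phase-presence model: {self.model.phase or '(unnamed phase)'}",
            f"  calls: {self.n_calls}   callers: {len(self.model._group_idx)}",
            f"  random-intercept sd (caller): {self.vc_sd:.3f}",
            f"  log-likelihood: {self.llf:.2f}   converged: {self.converged}",
        ]
        if self.possible_separation:
            lines.append("  WARNING: possible (quasi-)separation; SEs unreliable")
        lines.append(f"  {'term':<12}{'beta':>9}{'se':>8}{'z':>8}{'P':>9}{'95% CI':>20}")
        for name in self.params.index:
            lines.append(
                f"  {name:<12}{self.params[name]:>9.3f}{self.bse[name]:>8.3f}"
                f"{self.zvalues[name]:>8.2f}{self.pvalues[name]:>9.3g}"
                f"   [{ci.loc[name, 'lower']:>6.2f}, {ci.loc[name, 'upper']:>6.2f}]"
            )
        return "\n".join(lines)


def fit_presence_model(data: pd.DataFrame, phase: str) -> PhasePresenceResults:
    """Convenience wrapper: build from a metadata table and fit."""
    return PhasePresenceModel.from_dataframe(data, phase).fit()


def presence_rates(data: pd.DataFrame) -> pd.DataFrame:
    """Percentage of calls containing each droppable phase, per context."""
    rows = []
    for phase, col in PRESENCE_COLUMNS.items():
        for context in ("travel", "feeding"):
            sel = data[data["context"] == context]
            n = len(sel)
            rows.append(
                {
                    "phase": phase,
                    "context": context,
                    "n_calls": n,
                    "n_present": int(sel[col].sum()) if n else 0,
                    "percent_present": 100.0 * sel[col].mean() if n else np.nan,
                }
            )
    return pd.DataFrame(rows)
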