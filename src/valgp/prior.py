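"""Gaussian-process priors for the latent utility vector.

The latent per-state utility vector u (population *median* utilities) gets a
multivariate-normal prior

    u | beta, sigma^2  ~  N(u0 + H beta~, C0 + sigma^2 A)

where H has rows h(x) = (1, x), beta~ = (gamma0, beta) stacks the intercept
and the five level slopes, A is the kernel correlation matrix, and (u0, C0)
carry information from previously analysed countries: zero for a fresh
("single") analysis, or the posterior moments of another country's fit for a
"combined" analysis.  Moments from several countries add elementwise.

Full health is anchored at utility 1 by exact Gaussian conditioning of the
joint prior, so that a respondent valuing full health trades no time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .states import (
    FULL_HEALTH,
    HealthState,
    RoughnessParams,
    correlation_matrix,
    design_matrix,
    parse_state,
)

if TYPE_CHECKING:  # pragma: no cover
    from .inference import PosteriorDraws

PSD_TOL = 1e-10


def _symmetrize_clip(mat: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues to zero."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() < -tol * max(1.0, w.max()):
        raise np.linalg.LinAlgError(
            f"matrix is not PSD within tolerance (min eigenvalue {w.min():.3e})"
        )
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


@dataclass
class PriorSpec:
    """Prior moments (u0, C0) of the latent utility vector over a state list.

    source is one of ``"flat"`` (no prior information: u0 = 0, C0 = 0),
    ``"informative"`` (moments of one previous fit) or ``"multi-country"``
    (summed moments of several fits).
    """

    states: list[HealthState]
    u0_mean: np.ndarray
    C0: np.ndarray
    source: str = "flat"

    def __post_init__(self) -> None:
        n = len(self.states)
        self.u0_mean = np.asarray(self.u0_mean, dtype=float).reshape(n)
        self.C0 = np.asarray(self.C0, dtype=float).reshape(n, n)
        if not np.allclose(self.C0, self.C0.T, atol=1e-8):
            raise ValueError("C0 must be symmetric")
        if self.source == "flat" and (np.any(self.u0_mean) or np.any(self.C0)):
            raise ValueError("flat prior requires zero u0_mean and C0")

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.states]

    def index_of(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"state {code} not covered by this prior") from None

    def subset(self, states: Sequence[HealthState]) -> "PriorSpec":
        """Restrict to (and reorder by) the given states."""
        idx = [self.index_of(s.code) for s in states]
        return PriorSpec(
            states=list(states),
            u0_mean=self.u0_mean[idx],
            C0=self.C0[np.ix_(idx, idx)],
            source=self.source,
        )

    # -- serialization: mean CSV + square covariance CSV + JSON sidecar ------

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        codes = self.codes
        pd.DataFrame({"state": codes, "mean": self.u0_mean}).to_csv(
            prefix.with_suffix(".mean.csv"), index=False
        )
        pd.DataFrame(self.C0, index=codes, columns=codes).to_csv(
            prefix.with_suffix(".cov.csv"), index_label="state"
        )
        prefix.with_suffix(".json").write_text(
            json.dumps({"source": self.source, "n_states": len(codes)}, indent=2)
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "PriorSpec":
        prefix = Path(prefix)
        mean = pd.read_csv(prefix.with_suffix(".mean.csv"), dtype={"state": str})
        cov = pd.read_csv(prefix.with_suffix(".cov.csv"), dtype={"state": str}).set_index(
            "state"
        )
        meta = json.loads(prefix.with_suffix(".json").read_text())
        states = [parse_state(c) for c in mean["state"]]
        return cls(
            states=states,
            u0_mean=mean["mean"].to_numpy(),
            C0=cov.loc[mean["state"], mean["state"]].to_numpy(),
            source=meta.get("source", "informative"),
        )


def flat_prior(states: Sequence[HealthState]) -> PriorSpec:
    """No-information prior: u0 = 0, C0 = 0 (single-country analysis)."""
    states = list(states)
    if not states:
        raise ValueError("need at least one state")
    n = len(states)
    return PriorSpec(states=states, u0_mean=np.zeros(n), C0=np.zeros((n, n)), source="flat")


def informative_prior_from_draws(
    draws: "PosteriorDraws", states: Sequence[HealthState]
) -> PriorSpec:
    """Summarize a previous country's fit into an informative prior.

    u0 is the per-state posterior mean of the population-median utility
    draws and C0 their sample covariance (symmetrized, eigenvalue-clipped).
    Every requested state must have been part of the previous fit.
    """
    states = list(states)
    missing = [s.code for s in states if s.code not in draws.state_index]
    if missing:
        raise KeyError(f"states not present in the supplied draws: {missing}")
    idx = [draws.state_index.index(s.code) for s in states]
    u_samples = draws.u[:, idx]  # (n_draws, n_states)
    u0 = u_samples.mean(axis=0)
    if u_samples.shape[0] < 2:
        C0 = np.zeros((len(states), len(states)))
    else:
        C0 = _symmetrize_clip(np.cov(u_samples, rowvar=False).reshape(len(states), len(states)))
    return PriorSpec(states=states, u0_mean=u0, C0=C0, source="informative")


def combine_priors(specs: Sequence[PriorSpec]) -> PriorSpec:
    """Pool priors from n countries by summing their moments elementwise.

    The n-country generalisation adds the per-country prior means and
    covariances; an empty list degenerates to the flat prior (which then
    requires a state list, so it is an error here), and a single spec is
    returned unchanged apart from the source tag.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("combine_priors needs at least one spec (or use flat_prior)")
    codes0 = specs[0].codes
    for sp in specs[1:]:
        if sp.codes != codes0:
            raise ValueError("all priors must be over the same ordered state list")
    if len(specs) == 1:
        sp = specs[0]
        return PriorSpec(sp.states, sp.u0_mean.copy(), sp.C0.copy(), source=sp.source)
    u0 = np.sum([sp.u0_mean for sp in specs], axis=0)
    C0 = np.sum([sp.C0 for sp in specs], axis=0)
    return PriorSpec(specs[0].states, u0, C0, source="multi-country")


def prior_moments(
    spec: PriorSpec,
    gamma0: float,
    beta: np.ndarray,
    sigma2: float,
    b: RoughnessParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Unanchored prior mean and covariance of u over spec.states.

    mean = u0 + gamma0 + X beta  (X rows are raw level vectors)
    cov  = C0 + sigma^2 A
    """
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    beta = np.asarray(beta, dtype=float).reshape(5)
    H = design_matrix(spec.states)
    beta_full = np.concatenate(([float(gamma0)], beta))
    mean = spec.u0_mean + H @ beta_full
    A = correlation_matrix(spec.states, b)
    cov = spec.C0 + sigma2 * A
    return mean, (cov + cov.T) / 2.0


def condition_full_health(
    mean: np.ndarray,
    cov: np.ndarray,
    full_health_index: int,
    value: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian conditioning on u[full_health_index] = value (default 1).

    Returns the full-length mean/cov with the anchored coordinate fixed at
    ``value`` with zero variance and the remaining coordinates replaced by
    their conditional moments.  A zero row/column at the anchor (already
    degenerate prior) leaves the other coordinates untouched.
    """
    mean = np.asarray(mean, dtype=float).copy()
    cov = np.asarray(cov, dtype=float).copy()
    n = mean.shape[0]
    a = full_health_index
    if not 0 <= a < n:
        raise IndexError(f"anchor index {a} out of range for {n} states")
    var_a = cov[a, a]
    if var_a <= PSD_TOL:
        mean[a] = value
        cov[a, :] = 0.0
        cov[:, a] = 0.0
        return mean, cov
    k = cov[:, a] / var_a  # regression weights onto the anchored coordinate
    mean = mean + k * (value - mean[a])
    cov = cov - np.outer(k, cov[a, :])
    cov = (cov + cov.T) / 2.0
    mean[a] = value
    cov[a, :] = 0.0
    cov[:, a] = 0.0
    return mean, cov
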