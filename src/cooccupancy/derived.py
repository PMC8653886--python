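"""Posterior derived quantities: occurrence probabilities, conditionals, curves.

All quantities are computed draw-by-draw from the joint state distribution
psi(z) implied by each posterior sample, then summarized (posterior mean and
an equal-tailed credible interval).  "Occurrence probability" of a species is
the marginal Pr(z_s = 1) averaged over the surveyed sites — a finite-sample
average, not a new-site prediction.  Conditioning is on the *latent* presence
state of the other species (the natural model quantity); see the methods note
for the relation to conditioning on detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy import FitResult, ModelSpec, StudyData, _Design, enumerate_states

__all__ = [
    "OccurrenceSummary",
    "marginal_occupancy",
    "conditional_occupancy",
    "response_curve",
    "detection_summary",
]

_CHUNK = 128


@dataclass
class OccurrenceSummary:
    species: str
    mean: float
    lo: float
    hi: float
    level: float
    convention: str = "site-averaged posterior marginal"

    def __post_init__(self):
        eps = 1e-12
        if not (-eps <= self.lo <= self.mean + eps and
                self.mean - eps <= self.hi <= 1 + eps):
            raise ValueError("occurrence summary outside [0,1] ordering")


def _psi_draws(fit: FitResult, data: StudyData, draws: np.ndarray) -> np.ndarray:
    """State probabilities per draw and site, (D, N, 2^S)."""
    design = _Design(fit.spec, data)
    out = []
    for i in range(0, len(draws), _CHUNK):
        logw = design.log_state_weights(draws[i : i + _CHUNK])
        logw = logw - np.logaddexp.reduce(logw, axis=2, keepdims=True)
        out.append(np.exp(logw))
    return np.concatenate(out)


def _summarize(vals: np.ndarray, species: str, level: float) -> OccurrenceSummary:
    a = (1 - level) / 2
    lo, hi = np.quantile(vals, [a, 1 - a])
    return OccurrenceSummary(species, float(vals.mean()), float(lo), float(hi), level)


def marginal_occupancy(
    fit: FitResult, data: StudyData, species: str, level: float = 0.80
) -> OccurrenceSummary:
    """Site-averaged posterior marginal occurrence probability of one species."""
    if species not in fit.spec.species:
        raise ValueError(f"unknown species {species!r}")
    s = fit.spec.species.index(species)
    Z = enumerate_states(len(fit.spec.species)).astype(float)
    psi = _psi_draws(fit, data, fit.draws_flat())
    per_draw = (psi @ Z[:, s]).mean(axis=1)           # (D,)
    return _summarize(per_draw, species, level)


def _conditional_from_psi(
    psi: np.ndarray, Z: np.ndarray, s: int, s2: int, present: bool
) -> np.ndarray:
    """Pr(z_s = 1 | z_s2 = state) per draw x site from psi (D, N, 2^S)."""
    cond = Z[:, s2] == (1.0 if present else 0.0)
    num = psi[:, :, cond & (Z[:, s] == 1.0)].sum(axis=2)
    den = psi[:, :, cond].sum(axis=2)
    return num / den


def conditional_occupancy(
    fit: FitResult,
    data: StudyData,
    target: str,
    conditioner: str,
    state: str = "present",
    level: float = 0.80,
) -> OccurrenceSummary:
    """Occurrence probability of ``target`` given the latent state of ``conditioner``."""
    if target == conditioner:
        raise ValueError("target and conditioner must differ")
    if state not in ("present", "absent"):
        raise ValueError("state must be 'present' or 'absent'")
    sp = fit.spec.species
    s, s2 = sp.index(target), sp.index(conditioner)
    Z = enumerate_states(len(sp)).astype(float)
    psi = _psi_draws(fit, data, fit.draws_flat())
    per_draw = _conditional_from_psi(psi, Z, s, s2, state == "present").mean(axis=1)
    return _summarize(per_draw, target, level)


def response_curve(
    fit: FitResult,
    data: StudyData,
    target: str,
    covariate: str,
    conditioner: str | None = None,
    state: str = "present",
    grid_n: int = 100,
    scaling: dict | None = None,
    level: float = 0.80,
) -> pd.DataFrame:
    """Occurrence probability of ``target`` along one covariate's observed range.

    The covariate runs on a standardized grid spanning its observed values;
    all other continuous covariates are held at 0 (their mean) and trail at
    its modal value.  With a ``conditioner``, the curve is the conditional
    occurrence given that species' latent state.  ``scaling`` (the map from
    :func:`cooccupancy.ingest.standardize_covariates`) labels the grid in
    original units.  Returns columns x_std, x_orig, mean, lo, hi.
    """
    spec = fit.spec
    in_occ = covariate in spec.occupancy[target]
    in_pair = any(
        covariate in terms and target in pair for pair, terms in spec.pairs.items()
    )
    if not (in_occ or in_pair):
        raise ValueError(f"covariate {covariate!r} is not in {target!r}'s model")
    obs = data.covariates[covariate].to_numpy(dtype=float)
    grid = np.linspace(obs.min(), obs.max(), grid_n)

    cov = data.covariates.copy()
    for c in cov.columns:
        if c != "site_id":
            cov[c] = 0.0
    cov = cov.iloc[: len(grid)].reset_index(drop=True)
    while len(cov) < len(grid):  # small studies: tile rows to cover the grid
        cov = pd.concat([cov, cov]).iloc[: len(grid)].reset_index(drop=True)
    cov[covariate] = grid
    trail_mode = int(np.round(data.trail.mean()))
    grid_data = StudyData(
        y=np.zeros((len(spec.species), len(grid), 1)),
        species=spec.species,
        sites=tuple(f"g{i}" for i in range(len(grid))),
        covariates=cov,
        trail=np.full(len(grid), trail_mode),
        dog_activity=np.zeros((len(grid), 1)),
    )
    Z = enumerate_states(len(spec.species)).astype(float)
    psi = _psi_draws(fit, grid_data, fit.draws_flat())    # (D, G, 2^S)
    s = spec.species.index(target)
    if conditioner is None:
        vals = psi @ Z[:, s]
    else:
        s2 = spec.species.index(conditioner)
        vals = _conditional_from_psi(psi, Z, s, s2, state == "present")
    a = (1 - level) / 2
    lo, hi = np.quantile(vals, [a, 1 - a], axis=0)
    x_orig = grid
    if scaling and covariate in scaling:
        x_orig = grid * scaling[covariate]["sd"] + scaling[covariate]["mean"]
    return pd.DataFrame(
        {
            "x_std": grid,
            "x_orig": x_orig,
            "mean": vals.mean(axis=0),
            "lo": lo,
            "hi": hi,
        }
    )


def detection_summary(fit: FitResult, level: float = 0.80) -> pd.DataFrame:
    """Posterior mean and credible interval for every detection coefficient."""
    rows = []
    flat = fit.draws_flat()
    a = (1 - level) / 2
    for i, name in enumerate(fit.param_names):
        if not name.startswith("det["):
            continue
        sp = name[len("det[") : name.index("]")]
        term = name.split(":", 1)[1]
        lo, hi = np.quantile(flat[:, i], [a, 1 - a])
        rows.append(
            {
                "species": sp,
                "term": term,
                "mean": float(flat[:, i].mean()),
                "lo": float(lo),
                "hi": float(hi),
            }
        )
    return pd.DataFrame(rows)
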