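"""Backward model selection on 80% credible intervals, and WAIC tables.

The selection ledger mirrors a common occupancy-modelling workflow: per
species (and per covariate buffer scale) a full occupancy design is pruned
backwards — an occupancy term is a removal candidate whenever its 80%
equal-tailed credible interval overlaps zero — while the other species are
held at intercept-only and the detection structure is never touched.  The
per-species winners are then combined into one joint model, pairwise
interaction terms are added and pruned by the same rule, and candidate models
are compared on WAIC against the intercept-only null.

Removal is one term per refit (the term whose posterior mass is most evenly
split around zero goes first), which makes the trace a deterministic function
of the posterior draws; each refit reseeds as ``base_seed + step``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occupancy import OCC_INTERCEPT, FitResult, ModelSpec, StudyData, fit

__all__ = [
    "credible_interval",
    "excludes_zero",
    "SelectionStep",
    "SelectionTrace",
    "backward_select_species",
    "combine_species_models",
    "add_interactions",
    "waic_table",
]

RHAT_WARN = 1.2


def credible_interval(samples, level: float = 0.80) -> tuple[float, float]:
    """Equal-tailed credible interval (linear-interpolation quantiles).

    ``level=0`` degenerates to (median, median) by convention.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample")
    if samples.size < 10:
        raise ValueError("need at least 10 samples for a quantile interval")
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [a, 1.0 - a], method="linear")
    return float(lo), float(hi)


def excludes_zero(ci: tuple[float, float]) -> bool:
    """True iff the interval lies strictly on one side of zero.

    A boundary exactly at zero counts as overlapping (not excluded).
    """
    lo, hi = ci
    if lo > hi:
        raise ValueError("interval endpoints out of order")
    return lo > 0.0 or hi < 0.0


def _tail_mass_at_zero(samples: np.ndarray) -> float:
    """min(P(theta > 0), P(theta < 0)) — large when mass straddles zero."""
    return float(min(np.mean(samples > 0), np.mean(samples < 0)))


@dataclass
class SelectionStep:
    step: int
    term: str
    ci: tuple[float, float]
    decision: str          # "removed" | "retained"
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "term": self.term,
            "ci": list(self.ci),
            "decision": self.decision,
            "note": self.note,
        }


@dataclass
class SelectionTrace:
    label: str
    steps: list[SelectionStep]
    final_spec: ModelSpec
    waics: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "steps": [s.to_dict() for s in self.steps],
            "final_occupancy": {s: list(t) for s, t in self.final_spec.occupancy.items()},
            "final_pairs": {f"{a}|{b}": list(t) for (a, b), t in self.final_spec.pairs.items()},
            "waics": self.waics,
        }


def _prune(
    spec: ModelSpec,
    data: StudyData,
    candidate_names: list[str],
    drop_term,
    label: str,
    level: float,
    base_seed: int,
    fit_options: dict,
) -> SelectionTrace:
    """Shared backward-pruning loop over a set of named coefficients.

    ``candidate_names`` are full parameter names; ``drop_term(spec, name)``
    returns the spec with that term removed.
    """
    steps: list[SelectionStep] = []
    waics: list[float] = []
    remaining = list(candidate_names)
    step = 0
    while True:
        result = fit(spec, data, seed=base_seed + step, **fit_options)
        waics.append(result.waic["waic"])
        idx = [result.param_names.index(n) for n in remaining]
        rhats = result.rhat[idx] if idx else np.array([])
        if idx and np.any(rhats > RHAT_WARN):
            for n in remaining:
                steps.append(
                    SelectionStep(step, n, credible_interval(result.samples(n), level),
                                  "retained", "non-convergent fit; retained conservatively")
                )
            break
        offenders = []
        for n in remaining:
            ci = credible_interval(result.samples(n), level)
            if not excludes_zero(ci):
                offenders.append((n, ci, _tail_mass_at_zero(result.samples(n))))
        if not offenders:
            for n in remaining:
                steps.append(
                    SelectionStep(step, n, credible_interval(result.samples(n), level), "retained")
                )
            break
        # remove the worst offender: largest two-sided tail mass at zero
        name, ci, _ = max(offenders, key=lambda o: o[2])
        steps.append(SelectionStep(step, name, ci, "removed"))
        spec = drop_term(spec, name)
        remaining.remove(name)
        step += 1
    return SelectionTrace(label=label, steps=steps, final_spec=spec, waics=waics)


def backward_select_species(
    full_spec: ModelSpec,
    data: StudyData,
    species: str,
    level: float = 0.80,
    base_seed: int = 0,
    fit_options: dict | None = None,
) -> SelectionTrace:
    """Prune one species' occupancy covariates; other species stay intercept-only.

    Detection designs are held fixed throughout (they are never selection
    candidates).  The intercept is never a candidate.
    """
    fit_options = fit_options or {}
    spec = full_spec
    for s in spec.species:
        if s != species:
            spec = spec.with_occupancy(s, (OCC_INTERCEPT,))
    spec = spec.with_pairs({})
    candidates = [
        f"occ[{species}]:{t}" for t in spec.occupancy[species] if t != OCC_INTERCEPT
    ]

    def drop(sp: ModelSpec, name: str) -> ModelSpec:
        term = name.split(":", 1)[1]
        return sp.with_occupancy(species, tuple(t for t in sp.occupancy[species] if t != term))

    return _prune(spec, data, candidates, drop, f"{species}@{spec.scale or 'default'}",
                  level, base_seed, fit_options)


def combine_species_models(traces: list[SelectionTrace]) -> ModelSpec:
    """Joint spec whose per-species occupancy designs are the per-species winners.

    All traces must come from the same scale; detection designs are taken
    unchanged from the first trace's spec.  No interactions are added here.
    """
    specs = [t.final_spec for t in traces]
    scales = {s.scale for s in specs}
    if len(scales) > 1:
        raise ValueError(f"traces mix buffer scales: {sorted(scales)}")
    base = specs[0]
    occ = dict(base.occupancy)
    for t in traces:
        sp = t.label.split("@", 1)[0]
        occ[sp] = t.final_spec.occupancy[sp]
    return ModelSpec(base.species, occ, {}, base.detection, base.scale, base.dog_species)


def add_interactions(
    base_spec: ModelSpec,
    data: StudyData,
    candidates: tuple[str, ...] = ("settlements", "canals", "roads"),
    pairs: list[tuple[str, str]] | None = None,
    level: float = 0.80,
    base_seed: int = 0,
    fit_options: dict | None = None,
) -> SelectionTrace:
    """Add pairwise co-occurrence terms and prune them by the same CRI rule.

    Every requested pair starts with an intercept plus each candidate
    infrastructure covariate present in the data; pair terms are then
    backward-selected (occupancy and detection designs untouched).  Pairs that
    lose all their terms are dropped.
    """
    fit_options = fit_options or {}
    from .occupancy import species_pairs

    if pairs is None:
        pairs = species_pairs(base_spec.species)
    if not pairs:
        return SelectionTrace("interactions", [], base_spec, [])
    usable = [c for c in candidates if c in data.covariates.columns]
    design = {tuple(p): (OCC_INTERCEPT,) + tuple(usable) for p in pairs}
    spec = base_spec.with_pairs(design)
    candidates_names = [
        f"pair[{a}|{b}]:{t}" for (a, b), terms in spec.pairs.items() for t in terms
    ]

    def drop(sp: ModelSpec, name: str) -> ModelSpec:
        head, term = name.split(":", 1)
        a, b = head[len("pair[") : -1].split("|")
        new_pairs = {}
        for p, terms in sp.pairs.items():
            terms = tuple(t for t in terms if not (p == (a, b) and t == term))
            if terms:
                new_pairs[p] = terms
        return sp.with_pairs(new_pairs)

    return _prune(spec, data, candidates_names, drop, "interactions",
                  level, base_seed, fit_options)


def waic_table(fits: dict[str, FitResult], null_name: str = "null") -> pd.DataFrame:
    """Model-comparison table: name, structure, k, WAIC, ΔWAIC vs the null.

    ΔWAIC = WAIC_null − WAIC_model, so positive values mean better than the
    null and the null's own ΔWAIC is 0.
    """
    if null_name not in fits:
        raise ValueError(f"no fit named {null_name!r} to anchor the table")
    w_null = fits[null_name].waic["waic"]
    rows = []
    for name, f in fits.items():
        occ = "; ".join(
            f"{s}: " + " + ".join(f.spec.occupancy[s]) for s in f.spec.species
        )
        pair = "; ".join(
            f"{a}&{b}: " + " + ".join(t) for (a, b), t in f.spec.pairs.items()
        )
        rows.append(
            {
                "model": name,
                "structure": occ + (f" | {pair}" if pair else ""),
                "k": f.spec.k,
                "waic": f.waic["waic"],
                "delta_waic": w_null - f.waic["waic"],
            }
        )
    return pd.DataFrame(rows)
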