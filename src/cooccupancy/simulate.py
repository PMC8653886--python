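"""Synthetic camera-trap studies with the structure the analysis assumes.

A :class:`Scenario` fixes everything the generator needs: the survey design
(sites x nights, missing nights), true occupancy/interaction/detection
coefficients, the covariate and trail distributions, dog-activity intensity,
and per-species nocturnal activity mixtures (von-Mises components).  Three
presets are provided:

* ``study_scale`` — the survey design of the motivating field study: 40 sites,
  6 nights, 4 species, 7 missing site-nights (233 active of 240), 31/40
  cameras on a trail;
* ``recovery_scale`` — 400 sites for parameter-recovery and coverage checks;
* ``null_scale`` — all covariate and interaction coefficients zero, for
  calibration of the credible-interval selection rule.

Generation is exactly the fitted model run forwards: latent states are drawn
from the multivariate-Bernoulli state distribution, nightly detections are
Bernoulli given presence, dog event counts drive the dog-activity detection
covariate, and photo timestamps are drawn from each species' activity mixture
inside the night windows — so detection histories rebuilt from the photo
records through :mod:`cooccupancy.ingest` reproduce the simulated histories
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import ingest
from .ingest import DetectionHistory, make_schedule
from .occupancy import (
    OCC_INTERCEPT,
    ModelSpec,
    StudyData,
    _Design,
    enumerate_states,
)

__all__ = [
    "Scenario",
    "SyntheticStudy",
    "preset",
    "scenario_model",
    "gen_covariates",
    "gen_occupancy",
    "gen_detections",
    "gen_activity",
    "simulate_study",
    "write_study",
]

TWO_PI = 2.0 * np.pi


def _hour(h: float) -> float:
    """Clock hour to radians."""
    return TWO_PI * (h % 24.0) / 24.0


@dataclass
class Scenario:
    """Complete generating configuration for one synthetic study."""

    name: str
    n_sites: int
    n_nights: int
    species: tuple[str, ...]
    covariate_names: tuple[str, ...]
    occupancy: dict          # species -> {term: coef}
    pairs: dict              # (s, t) -> {term: coef}
    detection: dict          # species -> {term: coef}
    activity: dict           # species -> [(mean_rad, kappa, weight), ...]
    trail_prob: float = 0.775
    dog_rate: float = 1.2    # mean extra dog events on a night with >= 1 event
    extra_event_rate: float = 0.4  # mean extra events for non-dog species
    n_missing: int = 0
    first_night: date = date(2016, 11, 1)
    seed: int = 0

    def __post_init__(self):
        for sp, comps in self.activity.items():
            w = sum(c[2] for c in comps)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"activity weights for {sp!r} sum to {w}, not 1")
        if self.dog_rate < 0:
            raise ValueError("dog_rate must be non-negative")
        if self.n_missing >= self.n_sites * self.n_nights:
            raise ValueError("cannot mask every site-night")


def scenario_model(scn: Scenario) -> tuple[ModelSpec, np.ndarray]:
    """The ModelSpec and true coefficient vector implied by a scenario."""
    spec = ModelSpec(
        species=scn.species,
        occupancy={s: tuple(d) for s, d in scn.occupancy.items()},
        pairs={tuple(p): tuple(d) for p, d in scn.pairs.items()},
        detection={s: tuple(d) for s, d in scn.detection.items()},
        scale=scn.name,
    )
    lookup = {}
    for s, d in scn.occupancy.items():
        for t, v in d.items():
            lookup[f"occ[{s}]:{t}"] = v
    for (a, b), d in {tuple(p): v for p, v in scn.pairs.items()}.items():
        key = (a, b) if scn.species.index(a) < scn.species.index(b) else (b, a)
        for t, v in d.items():
            lookup[f"pair[{key[0]}|{key[1]}]:{t}"] = v
    for s, d in scn.detection.items():
        for t, v in d.items():
            lookup[f"det[{s}]:{t}"] = v
    theta = np.array([lookup[n] for n in spec.param_names])
    return spec, theta


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_SPECIES = ("indian_fox", "jackal", "jungle_cat", "dog")

_ACTIVITY = {
    # bimodal for dog, jungle cat and fox; unimodal for jackal
    "dog": [(_hour(19.0), 3.0, 0.5), (_hour(6.0), 3.0, 0.5)],
    "indian_fox": [(_hour(22.0), 3.0, 0.5), (_hour(3.5), 3.0, 0.5)],
    "jungle_cat": [(_hour(20.0), 3.0, 0.5), (_hour(5.0), 3.0, 0.5)],
    "jackal": [(_hour(1.0), 2.0, 1.0)],
}


def preset(name: str) -> Scenario:
    """A fully specified, seeded scenario by name."""
    if name == "study_scale":
        return Scenario(
            name="study_scale",
            n_sites=40,
            n_nights=6,
            species=_SPECIES,
            covariate_names=(
                "patch_area", "settlements", "forest", "agriculture",
                "fallow", "roads", "canals", "dist_settlement",
            ),
            occupancy={
                "indian_fox": {OCC_INTERCEPT: -0.5, "patch_area": 1.0,
                               "settlements": -0.8, "forest": 0.8},
                "jackal": {OCC_INTERCEPT: -1.2, "patch_area": -0.7, "roads": -0.6},
                "jungle_cat": {OCC_INTERCEPT: 0.1},
                "dog": {OCC_INTERCEPT: 1.0},
            },
            pairs={("indian_fox", "jackal"): {OCC_INTERCEPT: -1.0}},
            detection={
                "indian_fox": {OCC_INTERCEPT: -0.5, "trail": 0.5, "dog_activity": -0.35},
                "jackal": {OCC_INTERCEPT: -1.0, "trail": 1.36},
                "jungle_cat": {OCC_INTERCEPT: -0.7, "trail": 1.5},
                "dog": {OCC_INTERCEPT: 0.3, "trail": -0.8},
            },
            activity=_ACTIVITY,
            trail_prob=31 / 40,
            n_missing=7,
            seed=0,
        )
    if name == "recovery_scale":
        return Scenario(
            name="recovery_scale",
            n_sites=400,
            n_nights=6,
            species=_SPECIES,
            covariate_names=("cov1", "cov2"),
            occupancy={
                "indian_fox": {OCC_INTERCEPT: -0.3, "cov1": 1.0},
                "jackal": {OCC_INTERCEPT: -0.8, "cov1": -0.7},
                "jungle_cat": {OCC_INTERCEPT: 0.0, "cov2": 0.5},
                "dog": {OCC_INTERCEPT: 1.0, "cov2": -0.4},
            },
            pairs={("indian_fox", "jackal"): {OCC_INTERCEPT: -1.2}},
            detection={
                "indian_fox": {OCC_INTERCEPT: -0.3, "trail": 1.0, "dog_activity": -0.35},
                "jackal": {OCC_INTERCEPT: -0.5, "trail": 1.0},
                "jungle_cat": {OCC_INTERCEPT: -0.3},
                "dog": {OCC_INTERCEPT: 0.5, "trail": -0.8},
            },
            activity=_ACTIVITY,
            trail_prob=0.5,
            n_missing=0,
            seed=0,
        )
    if name == "null_scale":
        return Scenario(
            name="null_scale",
            n_sites=150,
            n_nights=6,
            species=_SPECIES,
            covariate_names=("noise1", "noise2"),
            occupancy={
                "indian_fox": {OCC_INTERCEPT: 0.0, "noise1": 0.0, "noise2": 0.0},
                "jackal": {OCC_INTERCEPT: 0.0},
                "jungle_cat": {OCC_INTERCEPT: 0.0},
                "dog": {OCC_INTERCEPT: 0.0},
            },
            pairs={},
            detection={s: {OCC_INTERCEPT: 0.0} for s in _SPECIES},
            activity=_ACTIVITY,
            trail_prob=0.5,
            dog_rate=1.0,
            n_missing=0,
            seed=0,
        )
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def gen_covariates(scn: Scenario, rng=None) -> pd.DataFrame:
    """Site covariate table: i.i.d. standard-normal continuous columns + trail.

    Columns are pre-standardized by construction (population scale); the
    binary ``trail`` is Bernoulli(``scn.trail_prob``).
    """
    rng = np.random.default_rng(scn.seed) if rng is None else rng
    data = {"site_id": [f"s{i+1:03d}" for i in range(scn.n_sites)]}
    for c in scn.covariate_names:
        data[c] = rng.standard_normal(scn.n_sites)
    data["trail"] = (rng.random(scn.n_sites) < scn.trail_prob).astype(int)
    return pd.DataFrame(data)


def _dummy_data(scn: Scenario, covariates: pd.DataFrame) -> StudyData:
    N, J = scn.n_sites, scn.n_nights
    return StudyData(
        y=np.zeros((len(scn.species), N, J)),
        species=scn.species,
        sites=tuple(covariates["site_id"]),
        covariates=covariates.drop(columns=["trail"]),
        trail=covariates["trail"].to_numpy(),
        dog_activity=np.zeros((N, J)),
    )


def gen_occupancy(scn: Scenario, covariates: pd.DataFrame, rng=None) -> np.ndarray:
    """Latent presence matrix z (sites x species) from the state distribution."""
    rng = np.random.default_rng(scn.seed) if rng is None else rng
    spec, theta = scenario_model(scn)
    design = _Design(spec, _dummy_data(scn, covariates))
    logw = design.log_state_weights(theta[None])[0]          # (N, 2^S)
    logw = logw - np.logaddexp.reduce(logw, axis=1, keepdims=True)
    psi = np.exp(logw)
    states = np.array([rng.choice(psi.shape[1], p=row) for row in psi])
    return enumerate_states(len(scn.species))[states].astype(int)


def _sample_mixture(comps, n: int, rng) -> np.ndarray:
    means = np.array([c[0] for c in comps])
    kappas = np.array([c[1] for c in comps])
    weights = np.array([c[2] for c in comps])
    which = rng.choice(len(comps), size=n, p=weights)
    noise = np.empty(n)
    for k in range(len(comps)):
        sel = which == k
        noise[sel] = rng.vonmises(0.0, kappas[k], size=int(sel.sum()))
    return np.mod(means[which] + noise, TWO_PI)


def gen_activity(scn: Scenario, species: str, n: int, rng=None) -> np.ndarray:
    """Draw activity times (radians) from the species' von-Mises mixture."""
    rng = np.random.default_rng(scn.seed) if rng is None else rng
    return _sample_mixture(scn.activity[species], n, rng)


def _night_time_sampler(scn: Scenario, species: str, rng):
    """Sample a clock time (radians) inside the camera window for one species."""
    start = 16.5 / 24.0 * TWO_PI
    end = 8.5 / 24.0 * TWO_PI
    comps = scn.activity[species]

    def one() -> float:
        for _ in range(10_000):
            t = _sample_mixture(comps, 1, rng)[0]
            if t >= start or t <= end:
                return t
        raise RuntimeError("activity mixture has negligible nocturnal mass")

    return one


def _radians_to_timestamp(rad: float, night_date: date) -> pd.Timestamp:
    seconds = rad / TWO_PI * 86400.0
    if rad >= 16.5 / 24.0 * TWO_PI:   # evening of the night's first day
        d = night_date
    else:                              # early morning of the next day
        d = night_date + timedelta(days=1)
    return pd.Timestamp(d) + pd.Timedelta(seconds=round(seconds))


def _event_times(scn, species, night_date, n, rng, min_gap_minutes=10.5):
    """n event timestamps in one night, separated by more than the collapse window."""
    sampler = _night_time_sampler(scn, species, rng)
    for _ in range(10_000):
        ts = sorted(_radians_to_timestamp(sampler(), night_date) for _ in range(n))
        gaps_ok = all(
            (b - a) > pd.Timedelta(minutes=min_gap_minutes) for a, b in zip(ts, ts[1:])
        )
        if gaps_ok:
            return ts
    raise RuntimeError("could not place separated events in the night window")


def gen_detections(
    scn: Scenario, z: np.ndarray, covariates: pd.DataFrame, rng=None
) -> tuple[DetectionHistory, np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Simulate nightly detections, dog activity, photo records and a schedule.

    Dog detections come first (their per-night event counts are the
    dog-activity covariate for the other species); each detected site-night
    then receives one photo per event, timestamped from the species' activity
    mixture inside the night window with separations exceeding the 10-minute
    collapsing window, so the ingest round-trip is exact.
    """
    rng = np.random.default_rng(scn.seed) if rng is None else rng
    spec, theta = scenario_model(scn)
    N, J, S = scn.n_sites, scn.n_nights, len(scn.species)
    sites = list(covariates["site_id"])
    trail = covariates["trail"].to_numpy()

    all_cells = [(sites[i], j + 1) for i in range(N) for j in range(J)]
    miss_ix = rng.choice(len(all_cells), size=scn.n_missing, replace=False)
    inactive = {all_cells[m] for m in miss_ix}
    schedule = make_schedule(sites, J, scn.first_night, inactive)
    active = np.ones((N, J), dtype=bool)
    for sid, night in inactive:
        active[sites.index(sid), night - 1] = False

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    def det_p(sp: str, dog_counts: np.ndarray) -> np.ndarray:
        coefs = scn.detection[sp]
        logit = np.full((N, J), coefs.get(OCC_INTERCEPT, 0.0))
        if "trail" in coefs:
            logit += coefs["trail"] * trail[:, None]
        if "dog_activity" in coefs:
            logit += coefs["dog_activity"] * dog_counts
        return logistic(logit)

    y = np.zeros((S, N, J))
    y[:, ~active] = np.nan
    n_events = np.zeros((S, N, J), dtype=int)
    dog_counts = np.zeros((N, J), dtype=int)
    if "dog" in scn.species:
        dog_ix = scn.species.index("dog")
        p_dog = det_p("dog", np.zeros((N, J)))
        y_dog = (rng.random((N, J)) < p_dog) & active & (z[:, dog_ix] == 1)[:, None]
        dog_counts = np.where(y_dog, 1 + rng.poisson(scn.dog_rate, (N, J)), 0)
        y[dog_ix, active] = y_dog[active].astype(float)
        n_events[dog_ix] = dog_counts
    for s, sp in enumerate(scn.species):
        if sp == "dog":
            continue
        p = det_p(sp, dog_counts)
        det = (rng.random((N, J)) < p) & active & (z[:, s] == 1)[:, None]
        y[s, active] = det[active].astype(float)
        n_events[s] = np.where(det, 1 + rng.poisson(scn.extra_event_rate, (N, J)), 0)

    records = []
    for s, sp in enumerate(scn.species):
        for i in range(N):
            for j in range(J):
                n = n_events[s, i, j]
                if n == 0:
                    continue
                night_date = scn.first_night + timedelta(days=j)
                for ts in _event_times(scn, sp, night_date, n, rng):
                    records.append({"site_id": sites[i], "species": sp, "timestamp": ts})
    photos = pd.DataFrame(records, columns=["site_id", "species", "timestamp"])
    if len(photos):
        photos = photos.sort_values(
            ["site_id", "species", "timestamp"], kind="mergesort"
        ).reset_index(drop=True)

    history = DetectionHistory(y=y, species=scn.species, sites=tuple(sites))
    return history, dog_counts, photos, schedule


# ---------------------------------------------------------------------------
# whole studies
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    scenario: Scenario
    spec: ModelSpec
    theta: np.ndarray
    covariates: pd.DataFrame     # includes trail
    z: np.ndarray                # (N, S)
    history: DetectionHistory
    dog_activity: np.ndarray     # (N, J)
    photos: pd.DataFrame
    schedule: pd.DataFrame
    seed: int = 0

    def study_data(self) -> StudyData:
        return StudyData(
            y=self.history.y,
            species=self.history.species,
            sites=self.history.sites,
            covariates=self.covariates.drop(columns=["trail"]),
            trail=self.covariates["trail"].to_numpy(),
            dog_activity=self.dog_activity,
        )

    def activity_samples(self) -> dict[str, np.ndarray]:
        """Event times (radians) per species from the photo records."""
        from .activity import clock_to_radians

        events = ingest.collapse_photos_to_events(self.photos)
        return {
            sp: clock_to_radians(list(grp["start_time"]))
            for sp, grp in events.groupby("species")
        }


def simulate_study(scn: Scenario, seed: int | None = None) -> SyntheticStudy:
    """Run the whole generator; (scenario, seed) fully determine the output."""
    seed = scn.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    cov = gen_covariates(scn, rngs[0])
    z = gen_occupancy(scn, cov, rngs[1])
    history, dog, photos, schedule = gen_detections(scn, z, cov, rngs[2])
    spec, theta = scenario_model(scn)
    return SyntheticStudy(
        scenario=scn, spec=spec, theta=theta, covariates=cov, z=z,
        history=history, dog_activity=dog, photos=photos, schedule=schedule,
        seed=seed,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write a study to disk in the CSV schemas the ingest module reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    photos = study.photos.copy()
    photos["timestamp"] = photos["timestamp"].map(lambda t: t.isoformat())
    photos.to_csv(out / "photos.csv", index=False)
    sched = study.schedule.copy()
    sched["date"] = sched["date"].map(str)
    sched["start"] = sched["start"].map(lambda t: t.strftime("%H:%M"))
    sched["end"] = sched["end"].map(lambda t: t.strftime("%H:%M"))
    sched.to_csv(out / "schedule.csv", index=False)
    study.covariates.to_csv(out / "covariates_std.csv", index=False)
    study.history.to_frame().to_csv(out / "histories.csv", index=False)
    pd.DataFrame(
        study.dog_activity,
        index=pd.Index(study.history.sites, name="site_id"),
        columns=[f"night{j+1}" for j in range(study.dog_activity.shape[1])],
    ).to_csv(out / "dog_activity.csv")
    scn = asdict(study.scenario)
    scn["first_night"] = str(scn["first_night"])
    scn["pairs"] = {f"{a}|{b}": v for (a, b), v in study.scenario.pairs.items()}
    truth = {
        "scenario": scn,
        "seed": study.seed,
        "theta": dict(zip(study.spec.param_names, study.theta.tolist())),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
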