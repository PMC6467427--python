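"""Synthetic experimental designs and noisy measurement sets.

The generator emulates a mono + pairwise coculture study of an S-species gut
community:

* one mono-species batch experiment per species, sampled every 0.5 h over 24 h
  (48 measurements);
* one pairwise coculture per unordered species pair, sampled every 12 h
  (8 time points, both members measured), with the medium diluted 1/20 once
  every 24 h (batch passaging);
* generating parameters drawn from ``mu_s ~ N(0.3, 0.1^2)``,
  ``alpha_ss ~ N(-1, 0.1^2)``, ``alpha_ss' ~ N(0, 0.1^2)``;
* multiplicative-with-floor measurement noise
  ``sigma_{k,s}(t) = 0.05 * max(0.1, eta_{k,s}(t))``.

The full design for S species therefore has ``S(S+1)/2`` experiments, ``S^2``
differential equations, ``S^2+S`` gLV parameters, and
``48*S + 16*S(S-1)/2`` scalar data points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SimulationError, SpecificationError
from .models import CommunityParameters, Experiment, n_parameters, simulate_experiment

__all__ = [
    "ExperimentDesign",
    "NoiseModel",
    "MeasurementSet",
    "DesignSummary",
    "build_design",
    "summarize_design",
    "draw_parameters",
    "generate_dataset",
    "augment_with_replicates",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise with an additive floor: sigma = scale * max(floor, eta)."""

    scale: float = 0.05
    floor: float = 0.1

    def __post_init__(self):
        if self.scale <= 0 or self.floor <= 0:
            raise SpecificationError("noise scale and floor must be positive")

    def sigma(self, eta):
        return self.scale * np.maximum(self.floor, np.asarray(eta, dtype=float))


@dataclass(frozen=True)
class ExperimentDesign:
    """A set of experiments over a common species pool."""

    species_labels: tuple
    experiments: tuple

    def __post_init__(self):
        object.__setattr__(self, "species_labels", tuple(self.species_labels))
        object.__setattr__(self, "experiments", tuple(self.experiments))
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise SpecificationError("experiment ids must be unique")
        pool = set(self.species_labels)
        for e in self.experiments:
            if not set(e.member_species) <= pool:
                raise SpecificationError(
                    f"experiment {e.experiment_id!r} references species outside the pool"
                )

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self):
        return len(self.experiments)

    def experiment(self, experiment_id) -> Experiment:
        for e in self.experiments:
            if e.experiment_id == experiment_id:
                return e
        raise KeyError(experiment_id)

    def to_dict(self) -> dict:
        return {
            "species_labels": list(self.species_labels),
            "experiments": [
                {
                    "experiment_id": e.experiment_id,
                    "member_species": list(e.member_species),
                    "duration_h": e.duration_h,
                    "sampling_times_h": e.sampling_times_h.tolist(),
                    "initial_abundances": e.initial_abundances.tolist(),
                    "dilution_times_h": e.dilution_times_h.tolist(),
                    "dilution_factor": e.dilution_factor,
                }
                for e in self.experiments
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d) -> "ExperimentDesign":
        exps = [
            Experiment(
                experiment_id=e["experiment_id"],
                member_species=tuple(e["member_species"]),
                duration_h=e["duration_h"],
                sampling_times_h=np.asarray(e["sampling_times_h"]),
                initial_abundances=np.asarray(e["initial_abundances"]),
                dilution_times_h=np.asarray(e["dilution_times_h"]),
                dilution_factor=e["dilution_factor"],
            )
            for e in d["experiments"]
        ]
        return cls(tuple(d["species_labels"]), tuple(exps))

    @classmethod
    def from_json(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class MeasurementSet:
    """Long-format observations: (experiment_id, species, time_h, abundance, std)."""

    records: pd.DataFrame

    COLUMNS = ("experiment_id", "species", "time_h", "abundance", "std")

    def __post_init__(self):
        df = pd.DataFrame(self.records).reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise SpecificationError(f"measurement table missing columns {sorted(missing)}")
        if df.duplicated(["experiment_id", "species", "time_h"]).any():
            raise SpecificationError("duplicate (experiment, species, time) record")
        if (df["std"] <= 0).any():
            raise SpecificationError("measurement standard deviations must be positive")
        object.__setattr__(self, "records", df[list(self.COLUMNS)])

    def __len__(self):
        return len(self.records)

    @property
    def experiment_ids(self):
        return list(dict.fromkeys(self.records["experiment_id"]))

    def for_experiment(self, experiment_id) -> pd.DataFrame:
        return self.records[self.records["experiment_id"] == experiment_id]

    def with_abundance(self, abundance) -> "MeasurementSet":
        """Copy with the abundance column replaced (same order); stds are kept."""
        df = self.records.copy()
        df["abundance"] = np.asarray(abundance, dtype=float)
        return MeasurementSet(df)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementSet":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class DesignSummary:
    """Problem-size bookkeeping for an estimation design."""

    n_species: int
    n_parameters: int
    n_differential_equations: int
    n_experiments: int
    n_data_points: int

    def to_dict(self):
        return dict(self.__dict__)


# ---------------------------------------------------------------------------


def build_design(
    n_species: int,
    mono_sampling_interval_h: float = 0.5,
    mono_duration_h: float = 24.0,
    pairwise_n_samples: int = 8,
    pairwise_sampling_interval_h: float = 12.0,
    dilution_period_h: float = 24.0,
    dilution_factor: float = 1.0 / 20.0,
    initial_abundance: float = 0.01,
    species_labels=None,
) -> ExperimentDesign:
    """Full mono + pairwise design for ``n_species`` community members.

    Pairwise durations cover the last sampling time
    (``pairwise_n_samples * pairwise_sampling_interval_h``), with dilutions at
    every multiple of ``dilution_period_h`` strictly inside the duration.
    """
    if n_species < 1:
        raise SpecificationError("need at least one species")
    if min(mono_sampling_interval_h, pairwise_sampling_interval_h, dilution_period_h) <= 0:
        raise SpecificationError("sampling and dilution intervals must be positive")
    if species_labels is None:
        species_labels = tuple(f"sp{i+1:02d}" for i in range(n_species))
    species_labels = tuple(species_labels)

    mono_times = np.arange(
        mono_sampling_interval_h, mono_duration_h + 1e-9, mono_sampling_interval_h
    )
    pair_times = pairwise_sampling_interval_h * np.arange(1, pairwise_n_samples + 1)
    pair_duration = float(pair_times[-1])
    pair_dilutions = np.arange(dilution_period_h, pair_duration - 1e-9, dilution_period_h)

    experiments = []
    for s in species_labels:
        experiments.append(
            Experiment(
                experiment_id=f"mono-{s}",
                member_species=(s,),
                duration_h=mono_duration_h,
                sampling_times_h=mono_times,
                initial_abundances=np.array([initial_abundance]),
            )
        )
    for i in range(n_species):
        for j in range(i + 1, n_species):
            a, b = species_labels[i], species_labels[j]
            experiments.append(
                Experiment(
                    experiment_id=f"pair-{a}-{b}",
                    member_species=(a, b),
                    duration_h=pair_duration,
                    sampling_times_h=pair_times,
                    initial_abundances=np.array([initial_abundance, initial_abundance]),
                    dilution_times_h=pair_dilutions,
                    dilution_factor=dilution_factor,
                )
            )
    return ExperimentDesign(species_labels, tuple(experiments))


def summarize_design(design: ExperimentDesign, model_form: str = "glv") -> DesignSummary:
    S = len(design.species_labels)
    n_states = sum(e.n_members for e in design)
    n_data = sum(e.n_members * e.sampling_times_h.size for e in design)
    return DesignSummary(
        n_species=S,
        n_parameters=n_parameters(S, model_form),
        n_differential_equations=n_states,
        n_experiments=len(design),
        n_data_points=n_data,
    )


def draw_parameters(
    n_species: int,
    seed: int,
    mu_mean: float = 0.3,
    mu_std: float = 0.1,
    alpha_diag_mean: float = -1.0,
    alpha_diag_std: float = 0.1,
    alpha_offdiag_mean: float = 0.0,
    alpha_offdiag_std: float = 0.1,
    saturations: bool = False,
    saturation_mean: float = 1.0,
    species_labels=None,
) -> CommunityParameters:
    """Draw generating parameters for a synthetic community.

    Growth rates ~ N(0.3, 0.1^2), self-interactions ~ N(-1, 0.1^2),
    cross-interactions ~ N(0, 0.1^2).  When ``saturations`` is requested,
    half-saturation constants are drawn log-normally around ``saturation_mean``
    (the draw distributions only cover the gLV parameters).
    """
    rng = np.random.default_rng(seed)
    if species_labels is None:
        species_labels = tuple(f"sp{i+1:02d}" for i in range(n_species))
    mu = rng.normal(mu_mean, mu_std, n_species)
    alpha = rng.normal(alpha_offdiag_mean, alpha_offdiag_std, (n_species, n_species))
    alpha[np.arange(n_species), np.arange(n_species)] = rng.normal(
        alpha_diag_mean, alpha_diag_std, n_species
    )
    K = None
    if saturations:
        K = saturation_mean * np.exp(rng.normal(0.0, 0.25, (n_species, n_species)))
    return CommunityParameters(species_labels, mu, alpha, K)


def generate_dataset(
    params: CommunityParameters,
    design: ExperimentDesign,
    noise: NoiseModel | None = None,
    seed: int = 0,
    model_form: str = "glv",
    clip_negative: bool = True,
) -> MeasurementSet:
    """Simulate every experiment and perturb the sampled outputs.

    The recorded weight is ``sigma = scale * max(floor, eta_true)`` evaluated on
    the noiseless output, the observation is ``eta_true + N(0, sigma^2)``
    (clipped at 0 by default — abundances are physical), and the same sigma is
    reused downstream as the likelihood weight.
    """
    if noise is None:
        noise = NoiseModel()
    missing = set(design.species_labels) - set(params.species_labels)
    if missing:
        raise SpecificationError(f"parameters missing design species {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for exp in design:
        try:
            traj = simulate_experiment(params, exp, model_form=model_form)
        except SimulationError as err:
            raise SimulationError(
                f"simulation failed for experiment {exp.experiment_id!r}: {err}",
                experiment_id=exp.experiment_id,
                time_h=err.time_h,
            ) from err
        eta_true = traj.at(exp.sampling_times_h)  # (n_times, n_members)
        sigma = noise.sigma(eta_true)
        eta_obs = eta_true + rng.normal(0.0, 1.0, eta_true.shape) * sigma
        if clip_negative:
            eta_obs = np.clip(eta_obs, 0.0, None)
        for it, t in enumerate(exp.sampling_times_h):
            for im, s in enumerate(exp.member_species):
                rows.append(
                    (exp.experiment_id, s, float(t), float(eta_obs[it, im]), float(sigma[it, im]))
                )
    return MeasurementSet(pd.DataFrame(rows, columns=list(MeasurementSet.COLUMNS)))


def augment_with_replicates(
    base: MeasurementSet, n_replicates: int, seed: int = 0, clip_negative: bool = True
) -> MeasurementSet:
    """Replicate a measurement set with fresh noise draws (P2-style augmentation).

    Each replicate re-perturbs the base observations (``eta + N(0, sigma^2)``)
    and is filed under new experiment ids ``<id>-rep<r>``.  Returns the
    augmented :class:`MeasurementSet`; the experiment count multiplies by
    ``n_replicates + 1``.
    """
    if n_replicates < 0:
        raise SpecificationError("n_replicates must be nonnegative")
    if n_replicates == 0:
        return base
    rng = np.random.default_rng(seed)
    frames = [base.records]
    for r in range(1, n_replicates + 1):
        df = base.records.copy()
        eta = df["abundance"].to_numpy() + rng.normal(0.0, 1.0, len(df)) * df["std"].to_numpy()
        if clip_negative:
            eta = np.clip(eta, 0.0, None)
        df["abundance"] = eta
        df["experiment_id"] = df["experiment_id"].astype(str) + f"-rep{r:02d}"
        frames.append(df)
    return MeasurementSet(pd.concat(frames, ignore_index=True))


def replicate_design(design: ExperimentDesign, n_replicates: int) -> ExperimentDesign:
    """Design matching :func:`augment_with_replicates` (replicated experiment ids)."""
    exps = list(design.experiments)
    for r in range(1, n_replicates + 1):
        for e in design:
            exps.append(
                Experiment(
                    experiment_id=f"{e.experiment_id}-rep{r:02d}",
                    member_species=e.member_species,
                    duration_h=e.duration_h,
                    sampling_times_h=e.sampling_times_h,
                    initial_abundances=e.initial_abundances,
                    dilution_times_h=e.dilution_times_h,
                    dilution_factor=e.dilution_factor,
                )
            )
    return ExperimentDesign(design.species_labels, tuple(exps))
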