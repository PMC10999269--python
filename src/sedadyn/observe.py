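"""Observation model: from true abundances to replicate detection counts.

A sedaDNA metabarcoding record scores each taxon in each sediment sample as
the number of positive PCR replicates out of R (typically 8).  Detection is
driven by the taxon's *relative* abundance in the community — metabarcoding
is compositional — through a saturating curve with a single scale
parameter, modulated by a time-constant per-taxon bias (e.g. aquatics and
willows shed disproportionate DNA into the lake) and a small per-replicate
false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import TrajectorySet

__all__ = ["ObservationParams", "SedaRecord", "detection_probability", "sample_record"]


@dataclass
class ObservationParams:
    """Parameters linking relative abundance to replicate detections.

    c
        Detection scale per unit relative abundance (> 0); the single-taxon
        detection probability is 1 - exp(-c * beta_t * rel_abundance).
    beta
        Per-taxon positive bias multipliers (time-constant); scalar 1.0
        means unbiased.
    fp
        Per-replicate false-positive probability in [0, 1).
    n_replicates
        Number of PCR replicates R per sample.
    seed
        Default RNG seed for record generation.
    """

    c: float = 5.0
    beta: np.ndarray | float = 1.0
    fp: float = 0.005
    n_replicates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.c = float(self.c)
        if self.c <= 0:
            raise ValueError("detection scale c must be positive")
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if np.any(self.beta <= 0):
            raise ValueError("bias multipliers beta must be positive")
        self.fp = float(self.fp)
        if not 0.0 <= self.fp < 1.0:
            raise ValueError("false-positive rate fp must lie in [0, 1)")
        self.n_replicates = int(self.n_replicates)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def beta_for(self, taxon: int) -> float:
        if self.beta.size == 1:
            return float(self.beta[0])
        return float(self.beta[taxon])


@dataclass
class SedaRecord:
    """One lake's replicate-detection record.

    detections is a taxon x sample integer DataFrame with counts in
    [0, n_replicates]; ages maps sample ids to calibrated years BP and is
    strictly decreasing toward the core top (oldest sample first).
    """

    lake: str
    ages: pd.Series
    detections: pd.DataFrame
    n_replicates: int = 8
    taxon_meta: pd.DataFrame | None = None
    site_index: int | None = None

    def __post_init__(self) -> None:
        self.ages = pd.Series(self.ages, dtype=float)
        self.detections = self.detections.astype(int)
        if list(self.detections.columns) != list(self.ages.index):
            raise ValueError("detection columns must match age-table sample ids")
        if self.detections.index.has_duplicates:
            raise ValueError("taxon names must be unique")
        d = np.diff(self.ages.to_numpy())
        if self.ages.size > 1 and not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("sample ages must be strictly monotone")
        vals = self.detections.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > self.n_replicates):
            raise ValueError(
                f"detection counts must lie in [0, {self.n_replicates}]"
            )

    @property
    def n_samples(self) -> int:
        return self.ages.size

    @property
    def taxa(self) -> list:
        return list(self.detections.index)

    def subset_samples(self, sample_ids) -> "SedaRecord":
        """Record restricted to the given sample ids (original order kept)."""
        keep = [s for s in self.ages.index if s in set(sample_ids)]
        return SedaRecord(
            lake=self.lake,
            ages=self.ages.loc[keep],
            detections=self.detections[keep],
            n_replicates=self.n_replicates,
            taxon_meta=self.taxon_meta,
            site_index=self.site_index,
        )


def detection_probability(
    obs: ObservationParams, taxon: int, rel_abundance
) -> np.ndarray | float:
    """Per-replicate detection probability p* for one taxon.

    p  = 1 - exp(-c * beta_t * rel_abundance)
    p* = p + (1 - p) * fp

    Monotone nondecreasing in rel_abundance, c and beta_t.
    """
    x = np.asarray(rel_abundance, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("relative abundance must lie in [0, 1]")
    p = 1.0 - np.exp(-obs.c * obs.beta_for(taxon) * x)
    p_star = p + (1.0 - p) * obs.fp
    return float(p_star) if np.isscalar(rel_abundance) else p_star


def relative_abundance(traj: TrajectorySet, site: int, model_times) -> np.ndarray:
    """Compositional abundance (S, T) at one site; an empty community is 0."""
    N = traj.at_times(model_times)[:, site, :]
    total = N.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(total > 0, N / np.where(total > 0, total, 1.0), 0.0)
    return rel


def detection_probabilities(
    traj: TrajectorySet, site: int, model_times, obs: ObservationParams
) -> np.ndarray:
    """Matrix of p* (taxa x samples) for a site at the given model times."""
    rel = relative_abundance(traj, site, model_times)
    beta = obs.beta if obs.beta.size > 1 else np.full(rel.shape[0], obs.beta[0])
    p = 1.0 - np.exp(-obs.c * beta[:, None] * rel)
    return p + (1.0 - p) * obs.fp


def sample_record(
    traj: TrajectorySet,
    site: int,
    sample_ages,
    obs: ObservationParams,
    *,
    lake: str = "lake0",
    taxa: list | None = None,
    seed: int | None = None,
    age_max: float | None = None,
) -> SedaRecord:
    """Draw a seeded replicate-detection record from a true trajectory.

    Sample ages (years BP) map to model time as t = age_max - age, with
    age_max defaulting to the end of the simulated span (core top at the
    end of the simulation).  Counts are Binomial(R, p*) per taxon and
    sample; the draw is reproducible for a fixed seed.
    """
    ages = np.asarray(sample_ages, dtype=float)
    if np.any(np.diff(ages) >= 0):
        ages = np.sort(ages)[::-1]  # store oldest first
    t_end = traj.times[-1] if age_max is None else float(age_max)
    times = t_end - ages
    if times.min() < traj.times[0] - 1e-9 or times.max() > traj.times[-1] + 1e-9:
        bad = ages[np.argmax((times < traj.times[0]) | (times > traj.times[-1]))]
        raise ValueError(f"sample age {bad} maps outside the simulated span")

    p_star = detection_probabilities(traj, site, times, obs)
    rng = np.random.default_rng(obs.seed if seed is None else seed)
    counts = rng.binomial(obs.n_replicates, p_star)

    S = traj.n_species
    taxa = taxa if taxa is not None else [f"taxon{i}" for i in range(S)]
    sample_ids = [f"{lake}_s{j}" for j in range(ages.size)]
    return SedaRecord(
        lake=lake,
        ages=pd.Series(ages, index=sample_ids),
        detections=pd.DataFrame(counts, index=taxa, columns=sample_ids),
        n_replicates=obs.n_replicates,
        site_index=site,
    )
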