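"""Synthetic sparse compositional case/control cohorts.

The generator emulates the statistical structure of taxonomic profiles from
case-control metagenome studies: each taxon has a baseline prevalence
(Beta-distributed across taxa), a log-normal latent abundance when present,
per-sample closure to proportions, and multinomial read sampling at a fixed
or log-normal sequencing depth. Detection limits therefore emerge
mechanically - a taxon with latent proportion p is observed with
probability 1 - (1 - p)^depth.

Two disjoint kinds of class signal can be planted:

* **prevalence-shift** taxa are present more often in cases (the signal
  lives in presence/absence);
* **abundance-shift** taxa are forced fully prevalent in both classes and
  differ only in their log-abundance location (presence carries, by
  construction, no information about the label).

Multi-dataset collections share the taxon universe and signal sets while a
per-dataset batch effect multiplicatively perturbs prevalences and
log-abundance locations, supporting leave-one-dataset-out experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np

from .profiles_io import LabeledCohort, ProfileTable, TaxonLineage

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class PrevalenceSignal:
    """Taxa whose case/control difference is how often they are present."""

    indices: tuple[int, ...] = ()
    delta: float = 0.4  # added to the case prevalence, clipped to [0, 1]
    location: float | None = None  # optional log-abundance location override

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))


@dataclass(frozen=True)
class AbundanceSignal:
    """Fully prevalent taxa whose difference is only their proportion."""

    indices: tuple[int, ...] = ()
    log_fold_change: float = 1.0  # natural-log shift of the case location
    location: float | None = None  # optional log-abundance location override

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))


@dataclass(frozen=True)
class ReadDepth:
    """Per-sample sequencing depth law: constant, or log-normal if sigma > 0."""

    mean_depth: int = 1_000_000
    sigma: float = 0.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma <= 0:
            return np.full(n, int(self.mean_depth), dtype=np.int64)
        mu = math.log(self.mean_depth) - 0.5 * self.sigma**2
        depths = np.round(rng.lognormal(mu, self.sigma, size=n)).astype(np.int64)
        return np.maximum(depths, 1)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic case/control cohort (or collection)."""

    n_control: int = 200
    n_case: int = 200
    n_taxa: int = 300
    prevalence_dist: tuple[float, float] = (2.0, 3.0)  # Beta(a, b), mean 0.4
    loc_mean: float = 0.0  # per-taxon log-abundance location ~ N(loc_mean, loc_sd)
    loc_sd: float = 1.5
    scale: float = 1.0  # within-sample log-normal sd of abundance-when-present
    prevalence_signal: PrevalenceSignal = field(default_factory=PrevalenceSignal)
    abundance_signal: AbundanceSignal = field(default_factory=AbundanceSignal)
    read_depth: ReadDepth = field(default_factory=ReadDepth)
    n_datasets: int = 1
    batch_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_case < 1 or self.n_taxa < 1:
            raise ValueError("sample and taxon counts must be positive")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.batch_effect < 0:
            raise ValueError("batch_effect must be nonnegative")
        overlap = set(self.prevalence_signal.indices) & set(self.abundance_signal.indices)
        if overlap:
            raise ValueError(f"signal index sets overlap: {sorted(overlap)}")
        for idx in (*self.prevalence_signal.indices, *self.abundance_signal.indices):
            if not 0 <= idx < self.n_taxa:
                raise ValueError(f"signal index {idx} outside [0, {self.n_taxa})")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticSpec":
        data = dict(data)
        if "prevalence_signal" in data and isinstance(data["prevalence_signal"], dict):
            data["prevalence_signal"] = PrevalenceSignal(**data["prevalence_signal"])
        if "abundance_signal" in data and isinstance(data["abundance_signal"], dict):
            data["abundance_signal"] = AbundanceSignal(**data["abundance_signal"])
        if "read_depth" in data and isinstance(data["read_depth"], dict):
            data["read_depth"] = ReadDepth(**data["read_depth"])
        if "prevalence_dist" in data:
            data["prevalence_dist"] = tuple(data["prevalence_dist"])
        return cls(**data)


@dataclass
class CohortParams:
    """Latent per-taxon parameters a cohort was generated from (truth)."""

    prev_control: np.ndarray
    prev_case: np.ndarray
    loc_control: np.ndarray
    loc_case: np.ndarray


@dataclass
class SyntheticCohort:
    """A generated cohort plus its generating truth and raw read counts."""

    cohort: LabeledCohort
    truth: SyntheticSpec
    counts: np.ndarray  # samples x taxa integer read counts
    depths: np.ndarray  # per-sample read depth
    params: CohortParams | None = None


def synthetic_taxonomy(n_taxa: int) -> list[TaxonLineage]:
    """Deterministic species lineages with 3 species/genus, 3 genera/family, ...

    The nested grouping gives rank aggregation something real to do.
    """
    taxa = []
    for i in range(n_taxa):
        g, f = i // 3, i // 9
        o, c, p = i // 27, i // 81, i // 243
        source = (
            f"k__Bacteria|p__Phylum{p:02d}|c__Class{c:03d}|o__Order{o:03d}"
            f"|f__Family{f:04d}|g__Genus{g:04d}|s__Species{i:05d}"
        )
        taxa.append(TaxonLineage.from_string(source))
    return taxa


def _draw_params(spec: SyntheticSpec, rng: np.random.Generator) -> CohortParams:
    a, b = spec.prevalence_dist
    prev = rng.beta(a, b, size=spec.n_taxa)
    loc = rng.normal(spec.loc_mean, spec.loc_sd, size=spec.n_taxa)

    prev_control = prev.copy()
    prev_case = prev.copy()
    loc_control = loc.copy()
    loc_case = loc.copy()

    ps = spec.prevalence_signal
    if ps.indices:
        idx = np.asarray(ps.indices)
        prev_case[idx] = np.clip(prev[idx] + ps.delta, 0.0, 1.0)
        if ps.location is not None:
            loc_control[idx] = ps.location
            loc_case[idx] = ps.location
    ab = spec.abundance_signal
    if ab.indices:
        idx = np.asarray(ab.indices)
        prev_control[idx] = 1.0  # presence carries no label information
        prev_case[idx] = 1.0
        if ab.location is not None:
            loc_control[idx] = ab.location
            loc_case[idx] = ab.location
        loc_case[idx] = loc_case[idx] + ab.log_fold_change
    return CohortParams(prev_control, prev_case, loc_control, loc_case)


def _perturb_params(
    params: CohortParams, batch_effect: float, rng: np.random.Generator
) -> CohortParams:
    """Per-dataset multiplicative batch effect on prevalences and locations.

    Two components, both per dataset and per taxon: a shared log-normal
    factor hitting both classes (technical and population differences) at
    scale ``batch_effect``, and independent class-specific factors at half
    that scale (cohort-composition differences such as case definition or
    severity). The class-specific part is what makes models transfer worse
    across datasets than within them, mirroring the cross-study
    heterogeneity of case/control collections.
    """
    n = params.prev_control.shape[0]
    shared = rng.normal(0.0, batch_effect, size=n)
    per_class = rng.normal(0.0, batch_effect / 2.0, size=(2, n))
    loc_shared = rng.normal(0.0, batch_effect, size=n)
    loc_per_class = rng.normal(0.0, batch_effect / 2.0, size=(2, n))
    return CohortParams(
        prev_control=np.clip(
            params.prev_control * np.exp(shared + per_class[0]), 0.0, 1.0
        ),
        prev_case=np.clip(
            params.prev_case * np.exp(shared + per_class[1]), 0.0, 1.0
        ),
        loc_control=params.loc_control + loc_shared + loc_per_class[0],
        loc_case=params.loc_case + loc_shared + loc_per_class[1],
    )


def _simulate_from_params(
    spec: SyntheticSpec,
    params: CohortParams,
    rng: np.random.Generator,
    study_id: str,
    disease: str,
) -> SyntheticCohort:
    n = spec.n_control + spec.n_case
    labels = np.concatenate(
        [np.zeros(spec.n_control, dtype=int), np.ones(spec.n_case, dtype=int)]
    )
    depths = spec.read_depth.draw(n, rng)
    counts = np.zeros((n, spec.n_taxa), dtype=np.int64)
    for i in range(n):
        prev = params.prev_case if labels[i] else params.prev_control
        loc = params.loc_case if labels[i] else params.loc_control
        for _attempt in range(_MAX_REDRAWS + 1):
            present = rng.random(spec.n_taxa) < prev
            if present.any():
                break
        else:
            raise RuntimeError(
                f"sample {i} of {study_id!r} drew zero present taxa "
                f"{_MAX_REDRAWS} times"
            )
        w = np.zeros(spec.n_taxa)
        k = int(present.sum())
        w[present] = np.exp(loc[present] + spec.scale * rng.standard_normal(k))
        proportions = w / w.sum()
        counts[i] = rng.multinomial(int(depths[i]), proportions)
    values = counts / depths[:, None]
    profile = ProfileTable(
        sample_ids=[f"{study_id}_S{i:04d}" for i in range(n)],
        taxa=synthetic_taxonomy(spec.n_taxa),
        values=values,
        rank="species",
    )
    cohort = LabeledCohort(profile=profile, labels=labels,
                           study_id=study_id, disease=disease)
    return SyntheticCohort(cohort=cohort, truth=spec, counts=counts,
                           depths=depths, params=params)


def simulate_cohort(
    spec: SyntheticSpec, study_id: str = "synthetic", disease: str = "synthetic"
) -> SyntheticCohort:
    """Generate one case/control cohort. Fixed seed gives bit-identical output."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    params = _draw_params(spec, rng)
    return _simulate_from_params(spec, params, rng, study_id, disease)


def simulate_multistudy(spec: SyntheticSpec) -> list[SyntheticCohort]:
    """Generate ``spec.n_datasets`` cohorts sharing taxa and signal sets.

    Each dataset applies an independent batch perturbation (scale
    ``spec.batch_effect``); with batch_effect = 0 the datasets are iid draws
    from one specification.
    """
    if spec.n_datasets < 2:
        raise ValueError("simulate_multistudy needs n_datasets >= 2")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_datasets + 1)
    base_params = _draw_params(spec, np.random.default_rng(children[0]))
    cohorts = []
    for d in range(spec.n_datasets):
        rng = np.random.default_rng(children[d + 1])
        params = _perturb_params(base_params, spec.batch_effect, rng)
        cohorts.append(
            _simulate_from_params(spec, params, rng, f"study_{d:02d}", "synthetic")
        )
    return cohorts


def rarefy_counts(
    sc: SyntheticCohort, target_depth: int, seed: int = 0
) -> SyntheticCohort:
    """Subsample each sample's reads to ``target_depth`` without replacement.

    Uses multivariate hypergeometric draws per sample; the relative
    abundances are recomputed from the rarefied counts. Lowering the depth
    can only lose taxa, never gain them.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    low = np.where(sc.depths < target_depth)[0]
    if low.size:
        sid = sc.cohort.profile.sample_ids[low[0]]
        raise ValueError(
            f"sample {sid!r} has depth {int(sc.depths[low[0]])} < target {target_depth}"
        )
    n = sc.counts.shape[0]
    new_counts = np.zeros_like(sc.counts)
    for i in range(n):
        new_counts[i] = rng.multivariate_hypergeometric(sc.counts[i], target_depth)
    depths = np.full(n, int(target_depth), dtype=np.int64)
    profile = ProfileTable(
        sample_ids=list(sc.cohort.profile.sample_ids),
        taxa=list(sc.cohort.profile.taxa),
        values=new_counts / target_depth,
        rank=sc.cohort.profile.rank,
    )
    cohort = LabeledCohort(
        profile=profile, labels=sc.cohort.labels.copy(),
        study_id=sc.cohort.study_id, disease=sc.cohort.disease,
    )
    return SyntheticCohort(cohort=cohort, truth=sc.truth, counts=new_counts,
                           depths=depths, params=sc.params)


def write_truth(spec: SyntheticSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2) + "\n")


def read_truth(path: str | Path) -> SyntheticSpec:
    return SyntheticSpec.from_dict(json.loads(Path(path).read_text()))
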