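"""Synthetic cohorts with a planted disconnection sequence.

Two levels of generation give every downstream stage a known ground truth:

1. **Biomarker level** — draw an N x P disconnectivity matrix directly. Each
   subject carries a latent stage ``k`` in ``[0, P]``; the first ``k`` regions
   of the planted sequence are drawn from a per-region *pathological* Gaussian
   and the rest from a *healthy* Gaussian, then optional linear age/sex
   effects are added and values are clipped to the fraction scale [0, 1].
2. **Geometric level** — build a toy streamline database on a voxel grid and
   realize the same planted order as lesion masks that cover each region's
   "critical voxel set" (the white-matter voxels its streamlines traverse,
   excluding the grey-matter endpoint blobs).

Group labels are correlated with stage: group 0 draws stages from a discrete
triangular distribution favouring low stages, group 1 from one favouring high
stages, emulating a no/mild vs moderate/severe severity split. Defaults mirror
a cohort of 482 subjects, 86 regions, with 103/482 in the severe group.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .disconnectivity import LesionMask, StreamlineDB

__all__ = [
    "PlantedTruth",
    "GeneratorConfig",
    "default_region_ids",
    "stage_pmf",
    "make_biomarker_cohort",
    "make_toy_tractogram",
    "make_lesion_cohort",
]


def default_region_ids(n_regions: int) -> list[str]:
    return [f"region_{i + 1:03d}" for i in range(n_regions)]


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic cohort: true event order and latent stages."""

    sequence: list[str]
    stages: np.ndarray
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=int)
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        p = len(self.sequence)
        if len(set(self.sequence)) != p:
            raise ValueError("planted sequence has repeated region ids")
        if ((self.stages < 0) | (self.stages > p)).any():
            raise ValueError("stages must lie in [0, P]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sequence": list(self.sequence),
                    "stages": self.stages.tolist(),
                    "group_labels": self.group_labels.tolist(),
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["sequence"], np.asarray(d["stages"]), np.asarray(d["group_labels"]))


def stage_pmf(kind, n_regions: int) -> np.ndarray:
    """Probability mass over latent stages {0, ..., P}.

    ``kind`` may be "uniform", "triangular_low" (mass decreasing with stage),
    "triangular_high" (increasing), or an explicit length-(P+1) vector.
    """
    k = np.arange(n_regions + 1)
    if isinstance(kind, str):
        if kind == "uniform":
            w = np.ones_like(k, dtype=float)
        elif kind == "triangular_low":
            w = (n_regions + 1 - k).astype(float)
        elif kind == "triangular_high":
            w = (k + 1).astype(float)
        else:
            raise ValueError(f"unknown stage distribution {kind!r}")
    else:
        w = np.asarray(kind, dtype=float)
        if w.shape != (n_regions + 1,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("explicit stage pmf must be a nonnegative length-(P+1) vector")
    return w / w.sum()


def _broadcast(value, n_regions: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_regions,)).copy()
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class GeneratorConfig:
    """Study conditions for the biomarker-level generator.

    Means and standard deviations are on the disconnectivity fraction scale
    and may be scalars or per-region vectors. The default separation between
    the healthy and pathological components is 2 SD.
    """

    n_subjects: int = 482
    n_regions: int = 86
    healthy_mean: float | np.ndarray = 0.05
    healthy_sd: float | np.ndarray = 0.03
    patho_mean: float | np.ndarray = 0.11
    patho_sd: float | np.ndarray = 0.03
    group1_fraction: float = 103 / 482
    stage_distribution: tuple = ("triangular_low", "triangular_high")
    age_slope: float | np.ndarray = 0.0
    sex_effect: float | np.ndarray = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_regions < 1:
            raise ValueError("n_subjects and n_regions must be positive")
        hm = _broadcast(self.healthy_mean, self.n_regions, "healthy_mean")
        pm = _broadcast(self.patho_mean, self.n_regions, "patho_mean")
        hs = _broadcast(self.healthy_sd, self.n_regions, "healthy_sd")
        ps = _broadcast(self.patho_sd, self.n_regions, "patho_sd")
        if (pm < hm).any():
            raise ValueError("patho_mean must be >= healthy_mean for every region")
        if (hs < 0).any() or (ps < 0).any():
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 < self.group1_fraction < 1.0:
            raise ValueError("group1_fraction must lie in (0, 1)")


def config_for_separation(separation_sd: float, **kwargs) -> GeneratorConfig:
    """Config whose pathological mean sits ``separation_sd`` healthy SDs above
    the healthy mean (both components share sd 0.03)."""
    return GeneratorConfig(patho_mean=0.05 + separation_sd * 0.03, **kwargs)


def _draw_stages(rng: np.random.Generator, pmf: np.ndarray, n: int) -> np.ndarray:
    cdf = np.cumsum(pmf)
    return np.searchsorted(cdf, rng.random(n), side="right").astype(int)


def make_biomarker_cohort(config: GeneratorConfig, sequence: list[str]) -> tuple[Cohort, PlantedTruth]:
    """Draw a cohort whose regions become abnormal in the planted ``sequence``.

    Subject ``n`` at latent stage ``k_n`` draws the first ``k_n`` sequence
    regions from their pathological Gaussians and the rest from healthy ones;
    linear age/sex effects (age centred at 42.5 years) are added afterwards
    and values clipped to [0, 1]. Fully determined by ``config.seed``.
    """
    config.validate()
    region_ids = default_region_ids(config.n_regions)
    if sorted(sequence) != sorted(region_ids):
        raise ValueError("sequence must be a permutation of the generated region ids")
    n, p = config.n_subjects, config.n_regions
    rng = np.random.default_rng(config.seed)

    groups = (rng.random(n) < config.group1_fraction).astype(int)
    pmf0 = stage_pmf(config.stage_distribution[0], p)
    pmf1 = stage_pmf(config.stage_distribution[1], p)
    stages = np.where(groups == 1, _draw_stages(rng, pmf1, n), _draw_stages(rng, pmf0, n))
    age = rng.uniform(25.0, 60.0, n)
    sex = (rng.random(n) < 0.7).astype(int)

    hm = _broadcast(config.healthy_mean, p, "healthy_mean")
    pm = _broadcast(config.patho_mean, p, "patho_mean")
    hs = _broadcast(config.healthy_sd, p, "healthy_sd")
    ps = _broadcast(config.patho_sd, p, "patho_sd")

    # position[j] = 1-based slot of region j in the planted order
    position = np.empty(p, dtype=int)
    for pos, rid in enumerate(sequence, start=1):
        position[region_ids.index(rid)] = pos
    abnormal = stages[:, None] >= position[None, :]

    noise = rng.standard_normal((n, p))
    x = np.where(abnormal, pm + ps * noise, hm + hs * noise)
    x = x + _broadcast(config.age_slope, p, "age_slope") * (age - 42.5)[:, None]
    x = x + _broadcast(config.sex_effect, p, "sex_effect") * sex[:, None]
    np.clip(x, 0.0, 1.0, out=x)

    cohort = Cohort(
        matrix=x,
        region_ids=region_ids,
        subject_ids=[f"sub-{i + 1:04d}" for i in range(n)],
        group_labels=groups,
        age=age,
        sex=sex,
        true_stages=stages,
    )
    return cohort, PlantedTruth(list(sequence), stages, groups)


# --------------------------------------------------------------------------
# Geometric level: toy tractogram and lesion masks
# --------------------------------------------------------------------------

def make_toy_tractogram(
    n_streamlines: int,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    n_regions: int = 4,
    seed: int = 0,
    blob_size: int = 2,
    gap: int = 4,
) -> StreamlineDB:
    """Build a toy streamline database on a voxel grid.

    ``n_regions`` cubic parcellation blobs (side ``blob_size``) are placed on a
    lattice with at least ``gap`` empty voxels between them; streamlines are
    straight densely-voxelized polylines whose endpoints lie inside two blobs.
    Every region is guaranteed to be an endpoint of at least one streamline,
    which requires ``n_streamlines >= ceil(n_regions / 2)``.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if n_streamlines < -(-n_regions // 2):
        raise ValueError(
            f"{n_streamlines} streamlines cannot give all {n_regions} regions an endpoint"
        )
    rng = np.random.default_rng(seed)
    spacing = blob_size + gap
    origins = list(
        itertools.product(*(range(1, s - blob_size, spacing) for s in grid_shape))
    )
    if len(origins) < n_regions:
        raise ValueError(
            f"grid {grid_shape} hosts only {len(origins)} blobs of size {blob_size} "
            f"with gap {gap}; {n_regions} regions requested"
        )
    origins = [origins[i] for i in rng.permutation(len(origins))[:n_regions]]

    parc = np.zeros(grid_shape, dtype=int)
    blob_voxels: list[np.ndarray] = []
    for label, (ox, oy, oz) in enumerate(origins, start=1):
        parc[ox : ox + blob_size, oy : oy + blob_size, oz : oz + blob_size] = label
        vox = np.array(
            list(itertools.product(*(range(o, o + blob_size) for o in (ox, oy, oz))))
        )
        blob_voxels.append(vox)

    # region pairs: first cover every region, then random distinct pairs
    pairs = [(2 * i, 2 * i + 1) for i in range(n_regions // 2)]
    if n_regions % 2:
        pairs.append((n_regions - 1, 0))
    while len(pairs) < n_streamlines:
        a, b = rng.choice(n_regions, size=2, replace=False)
        pairs.append((int(a), int(b)))
    pairs = pairs[:n_streamlines]

    streamlines = []
    for a, b in pairs:
        start = blob_voxels[a][rng.integers(len(blob_voxels[a]))]
        end = blob_voxels[b][rng.integers(len(blob_voxels[b]))]
        npts = 2 * int(np.abs(end - start).max()) + 2
        pts = np.linspace(start, end, npts)
        streamlines.append(pts)
    return StreamlineDB(streamlines, parc)


def critical_voxel_sets(db: StreamlineDB) -> dict[int, set[tuple[int, int, int]]]:
    """White-matter voxels per region: voxels traversed by streamlines connected
    to the region, excluding all labelled (endpoint-blob) voxels."""
    blob = db.parcellation > 0
    sets: dict[int, set] = {int(r): set() for r in db.region_ids}
    for i, s in enumerate(db.streamlines):
        labels = {int(l) for l in db._endpoint_labels[i] if l > 0}
        wm = [tuple(v) for v in s if not blob[tuple(v)]]
        for r in labels:
            sets[r].update(wm)
    return sets


def make_lesion_cohort(
    db: StreamlineDB,
    sequence: list[int],
    stages,
    noise_voxels: int = 0,
    seed: int = 0,
) -> list[LesionMask]:
    """Realize planted stages as lesion masks on the database grid.

    A subject at stage ``k`` receives the union of the critical voxel sets of
    the first ``k`` regions of ``sequence``, plus ``noise_voxels`` random
    voxels outside every critical set.
    """
    stages = np.asarray(stages, dtype=int)
    p = len(sequence)
    if sorted(int(r) for r in sequence) != sorted(int(r) for r in db.region_ids):
        raise ValueError("sequence must be a permutation of the database region ids")
    if ((stages < 0) | (stages > p)).any():
        raise ValueError(f"stages must lie in [0, {p}]")
    rng = np.random.default_rng(seed)
    crit = critical_voxel_sets(db)
    all_crit = set().union(*crit.values()) if crit else set()
    free = np.array(
        [i for i in range(int(np.prod(db.shape))) if np.unravel_index(i, db.shape) not in all_crit]
    )
    masks = []
    for n, k in enumerate(stages):
        vol = np.zeros(db.shape, dtype=np.uint8)
        for r in sequence[:k]:
            for v in crit[int(r)]:
                vol[v] = 1
        if noise_voxels:
            chosen = rng.choice(free, size=min(noise_voxels, len(free)), replace=False)
            vol.ravel()[chosen] = 1
        masks.append(LesionMask(vol, subject_id=f"sub-{n + 1:04d}"))
    return masks
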