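"""End-to-end orchestration: scoring -> preprocessing -> selection -> EBM.

The pipeline runs either on synthetic cohorts with a planted ground truth or
on real inputs (per-subject NIfTI lesion masks, a parcellation volume, a
streamline database and a subject table). The processing order is fixed:

    score -> log transform -> group t-tests + BH -> bootstrap top-k selection
          -> covariate regression (selected columns) -> EBM with bootstrap
          -> randomness test -> staging

A single master seed deterministically spawns per-stage seeds, so a run is
fully reproducible from its config; identical config + seed gives
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort
from .disconnectivity import LesionMask, StreamlineDB, batch_disconnectivity
from .ebm import (
    RandomnessResult,
    SequenceResult,
    bootstrap_sequences,
    randomness_test,
    stage_subjects,
)
from .preprocess import (
    SelectionResult,
    bootstrap_rank_selection,
    log_transform,
    regress_out_covariates,
)
from .synthetic import GeneratorConfig, PlantedTruth, default_region_ids, make_biomarker_cohort

logger = logging.getLogger("disconseq")


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage; partial outputs are invalid."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "real"
    generator: GeneratorConfig | None = None
    planted_sequence: list[str] | None = None  # synthetic; None -> seeded permutation
    subject_table: str | None = None  # real: TSV subject_id, group, age, sex[, mask]
    parcellation: str | None = None
    streamlines: str | None = None  # .trk or plain-text polylines
    n_boot: int = 100
    top_k: int = 20
    epsilon: float = 1e-2
    stage_prior: str = "uniform"
    n_restarts: int = 25
    boot_restarts: int = 2
    seed: int = 0
    outdir: str = "."
    make_plots: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.top_k < 2:
            raise ValueError("top_k must be >= 2")
        if self.stage_prior != "uniform":
            raise ValueError("only the uniform stage prior is configurable by name")
        if self.mode == "real":
            for name in ("subject_table", "parcellation", "streamlines"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"real mode requires an existing {name} path (got {p!r})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.get("generator")
        if isinstance(gen, dict):
            d["generator"] = GeneratorConfig(**gen)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also parses JSON
        return cls.from_dict(data)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where results land is not part of the analysis
        d.pop("make_plots", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run computed, regenerable from config + seed."""

    selection: SelectionResult
    sequence_result: SequenceResult
    randomness: RandomnessResult
    stage_counts: dict[int, int]
    provenance: dict
    recovery_tau: float | None = None  # vs planted truth, when available

    def as_dict(self) -> dict:
        d = {
            "selection": {
                "selected_regions": self.selection.selected_regions,
                "n_boot_effective": self.selection.n_boot_effective,
            },
            "sequence": self.sequence_result.as_dict(),
            "randomness_test": {
                "t": self.randomness.t,
                "p_one_sided": self.randomness.p_one_sided,
                "p_two_sided": self.randomness.p_two_sided,
                "degenerate": self.randomness.degenerate,
            },
            "stage_counts": {str(k): v for k, v in sorted(self.stage_counts.items())},
            "provenance": self.provenance,
        }
        if self.recovery_tau is not None:
            d["recovery_kendall_tau"] = self.recovery_tau
        return d

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)
        self.selection.to_tsv(out / "selection.tsv")
        self.sequence_result.to_json(out / "sequence.json")
        self.sequence_result.positional_variance_frame().to_csv(
            out / "positional_variance.tsv", sep="\t", float_format="%.10g"
        )


def _spawn_seeds(master: int, n: int) -> list[int]:
    return [int(s % 2**31) for s in np.random.SeedSequence(master).generate_state(n)]


def _load_real_cohort(config: RunConfig) -> Cohort:
    table = pd.read_csv(config.subject_table, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "group"):
        if col not in table:
            raise ValueError(f"subject table lacks required column {col!r}")
    stream_path = str(config.streamlines)
    if stream_path.endswith(".trk"):
        db = StreamlineDB.from_trk(stream_path, config.parcellation)
    else:
        db = StreamlineDB.from_text(stream_path, config.parcellation)
    masks = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        path = row.get("mask")
        if path is None or (isinstance(path, float) and np.isnan(path)) or str(path) == "":
            masks.append((sid, None))  # no lesion of this class: scored all-zero
            continue
        if not Path(path).exists():
            raise FileNotFoundError(f"lesion mask for subject {sid!r} not found: {path}")
        masks.append((sid, LesionMask.from_nifti(path, subject_id=sid)))
    block = batch_disconnectivity(masks, db)
    return Cohort(
        matrix=block.to_numpy(),
        region_ids=list(block.columns),
        subject_ids=list(block.index),
        group_labels=table["group"].to_numpy(int),
        age=table["age"].to_numpy(float) if "age" in table else None,
        sex=table["sex"].to_numpy(int) if "sex" in table else None,
    )


def _make_synthetic_cohort(config: RunConfig, seeds: list[int]) -> tuple[Cohort, PlantedTruth]:
    gen = config.generator or GeneratorConfig()
    gen = dataclasses.replace(gen, seed=seeds[0])  # master seed drives generation
    if config.planted_sequence is not None:
        sequence = list(config.planted_sequence)
    else:
        rng = np.random.default_rng(seeds[1])
        ids = default_region_ids(gen.n_regions)
        sequence = [ids[j] for j in rng.permutation(gen.n_regions)]
    return make_biomarker_cohort(gen, sequence)


def _run_from_cohort(cohort: Cohort, config: RunConfig, truth: PlantedTruth | None, seeds: list[int]) -> RunReport:
    t0 = time.perf_counter()

    def stage(name):
        logger.info("stage %-12s t=%.1fs", name, time.perf_counter() - t0)

    try:
        stage("log")
        logged = log_transform(cohort.matrix, config.epsilon)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("log", str(e)) from e

    try:
        stage("selection")
        selection = bootstrap_rank_selection(
            logged,
            cohort.group_labels,
            n_boot=config.n_boot,
            top_k=config.top_k,
            seed=seeds[2],
            region_ids=cohort.region_ids,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("selection", str(e)) from e

    sel_idx = [cohort.region_ids.index(r) for r in selection.selected_regions]
    try:
        stage("covariates")
        if cohort.age is not None and cohort.sex is not None:
            residuals = regress_out_covariates(logged[:, sel_idx], cohort.age, cohort.sex)
        else:
            logger.info("no age/sex covariates present; EBM runs on logged values")
            residuals = logged[:, sel_idx] - logged[:, sel_idx].mean(axis=0)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("covariates", str(e)) from e

    try:
        stage("ebm")
        seq_result = bootstrap_sequences(
            residuals,
            cohort.group_labels,
            n_boot=config.n_boot,
            seed=seeds[3],
            n_restarts=config.n_restarts,
            boot_restarts=config.boot_restarts,
            region_ids=selection.selected_regions,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("ebm", str(e)) from e

    try:
        stage("randomness")
        rnd = randomness_test(seq_result.positional_variance, seq_result.sequence)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("randomness", str(e)) from e

    try:
        stage("staging")
        post = stage_subjects(seq_result.model.probs, seq_result.sequence)
        modal = post.argmax(axis=1)
        stage_counts = {int(k): int(c) for k, c in zip(*np.unique(modal, return_counts=True))}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("staging", str(e)) from e

    recovery_tau = None
    if truth is not None:
        from scipy.stats import kendalltau

        true_pos = {r: i for i, r in enumerate(truth.sequence)}
        rec_ids = seq_result.sequence_ids
        common = [r for r in rec_ids if _strip_class(r) in true_pos or r in true_pos]
        if len(common) >= 2:
            t_pos = [true_pos.get(r, true_pos.get(_strip_class(r))) for r in common]
            r_pos = [rec_ids.index(r) for r in common]
            recovery_tau = float(kendalltau(t_pos, r_pos).statistic)

    import scipy

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"disconseq": __version__, "numpy": np.__version__, "scipy": scipy.__version__},
    }
    report = RunReport(
        selection=selection,
        sequence_result=seq_result,
        randomness=rnd,
        stage_counts=stage_counts,
        provenance=provenance,
        recovery_tau=recovery_tau,
    )
    out = Path(config.outdir)
    report.save(out)
    if config.make_plots:
        from .plotting import event_centre_plot, positional_variance_diagram

        positional_variance_diagram(seq_result, path=out / "positional_variance.png")
        event_centre_plot(seq_result, path=out / "event_centres.png")
    return report


def _strip_class(region_id: str) -> str:
    return region_id.split(":", 1)[1] if ":" in region_id else region_id


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute a full run; all artifacts are written under ``config.outdir``."""
    config.validate()
    seeds = _spawn_seeds(config.seed, 5)
    if config.mode == "synthetic":
        try:
            cohort, truth = _make_synthetic_cohort(config, seeds)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", str(e)) from e
    else:
        try:
            cohort = _load_real_cohort(config)
            truth = None
        except (FileNotFoundError, ValueError) as e:
            raise PipelineError("score", str(e)) from e
    return _run_from_cohort(cohort, config, truth, seeds)


def run_lesion_class_comparison(
    config: RunConfig,
    masks_a,
    masks_b,
    db: StreamlineDB | None = None,
    subjects: pd.DataFrame | None = None,
    class_names: tuple[str, str] = ("a", "b"),
    truth: PlantedTruth | None = None,
) -> RunReport:
    """Joint run over two lesion-mask classes (e.g. rim vs rimless lesions).

    ``masks_a``/``masks_b`` map subject id -> LesionMask or None; a subject
    lacking a class gets all-zero scores for that class's columns. Columns are
    namespaced ``<class>:<region>`` giving a 2P-column matrix processed
    identically downstream. Classes are expected to partition each subject's
    lesions; voxel overlap between classes raises a warning.
    """
    config.validate()
    seeds = _spawn_seeds(config.seed, 5)
    if db is None:
        stream_path = str(config.streamlines)
        if stream_path.endswith(".trk"):
            db = StreamlineDB.from_trk(stream_path, config.parcellation)
        else:
            db = StreamlineDB.from_text(stream_path, config.parcellation)
    if subjects is None:
        subjects = pd.read_csv(config.subject_table, sep="\t", dtype={"subject_id": str})
    ids = [str(s) for s in subjects["subject_id"]]
    da = dict(masks_a.items()) if isinstance(masks_a, dict) else dict(masks_a)
    db_masks = dict(masks_b.items()) if isinstance(masks_b, dict) else dict(masks_b)
    for sid in ids:
        ma, mb = da.get(sid), db_masks.get(sid)
        if ma is not None and mb is not None and (ma.volume & mb.volume).any():
            warnings.warn(f"mask classes overlap for subject {sid!r}; classes should partition lesions", stacklevel=2)
    block_a = batch_disconnectivity([(s, da.get(s)) for s in ids], db)
    block_b = batch_disconnectivity([(s, db_masks.get(s)) for s in ids], db)
    matrix = np.hstack([block_a.to_numpy(), block_b.to_numpy()])
    region_ids = [f"{class_names[0]}:{c}" for c in block_a.columns] + [
        f"{class_names[1]}:{c}" for c in block_b.columns
    ]
    cohort = Cohort(
        matrix=matrix,
        region_ids=region_ids,
        subject_ids=ids,
        group_labels=subjects["group"].to_numpy(int),
        age=subjects["age"].to_numpy(float) if "age" in subjects else None,
        sex=subjects["sex"].to_numpy(int) if "sex" in subjects else None,
    )
    return _run_from_cohort(cohort, config, truth, seeds)
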